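"""Bootstrap confidence intervals for network statistics.

Stance labels come from human raters, so statistics inherit
classification uncertainty; boards are resampled with replacement
(n replicates), the network rebuilt, and the statistic recomputed to get
a percentile CI in the table style "mean (low-high)".
"""

from stancenet import ForumConfig, bootstrap_metric, generate_corpus, generate_users, summarize
from stancenet.metrics import spearman_pair


def mean_degree(layer):
    def metric(M):
        v = M.layers[layer].number_of_nodes()
        return 2.0 * M.layers[layer].number_of_edges() / v if v else float("nan")

    return metric


config = ForumConfig(n_users=800, n_posts_per_layer=(60, 62, 18), seed=9)
posts = generate_corpus(config, generate_users(config))

summaries = []
for layer in "PHA":
    summaries.append(
        bootstrap_metric(posts, mean_degree(layer), n=500, seed=10, statistic=f"mean_degree_{layer}")
    )
summaries.append(
    bootstrap_metric(
        posts, lambda M: spearman_pair(M, "P", "H", "in"), n=500, seed=11, statistic="spearman_PH_in"
    )
)

table = summarize(summaries)
print(table[["statistic", "point", "formatted"]].to_string(index=False))
print("point = full-data value; formatted = bootstrap mean (95% percentile CI)")
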