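from datetime import datetime, timedelta

import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from stancenet.forum_io import Comment, Post
from stancenet.layers import EdgeRecord, build_multilayer
from stancenet.synthetic import ForumConfig, generate_corpus, generate_users

T0 = datetime(2021, 1, 1)


def make_post(board_id, author, label, comments, time=T0, title="疫苗 thread"):
    return Post(
        board_id=board_id,
        author=author,
        time=time,
        title=title,
        label=label,
        comments=comments,
    )


def like(user, minutes=1, text=""):
    return Comment(commenter=user, reaction="like", time=T0 + timedelta(minutes=minutes), text=text)


def record(source, target, layer, weight=2.0, minutes=0, reaction="like"):
    return EdgeRecord(
        source=source,
        target=target,
        layer=layer,
        weight=weight,
        time=T0 + timedelta(minutes=minutes),
        reaction=reaction,
    )


def network_from_triples(triples):
    """Build a MultilayerNetwork from (source, target, layer) triples."""
    return build_multilayer([record(u, v, l) for u, v, l in triples])


@pytest.fixture(scope="session")
def tiny_config():
    return ForumConfig(n_users=300, n_posts_per_layer=(25, 25, 10), n_periods=6, seed=11)


@pytest.fixture(scope="session")
def tiny_corpus(tiny_config):
    truth = generate_users(tiny_config)
    return generate_corpus(tiny_config, truth), truth
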