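"""Brute-force reference implementations used to cross-check the metrics.

Everything here works directly on plain (source, target, layer) triples
with set/dict arithmetic — deliberately independent of networkx and of
the package's own metric code paths.
"""

from __future__ import annotations

import math

import numpy as np

LAYERS = ("P", "H", "A")


def node_set(triples, layer):
    return {u for u, v, l in triples if l == layer} | {v for u, v, l in triples if l == layer}


def in_neighbors(triples, node, layer):
    return {u for u, v, l in triples if l == layer and v == node}


def out_neighbors(triples, node, layer):
    return {v for u, v, l in triples if l == layer and u == node}


def degree(triples, node, layer, direction):
    f = in_neighbors if direction == "in" else out_neighbors
    return len(f(triples, node, layer))


def cross_degree(triples, node, direction):
    f = in_neighbors if direction == "in" else out_neighbors
    out = set()
    for layer in LAYERS:
        out |= f(triples, node, layer)
    return len(out)


def layer_diversity(triples, layer, direction):
    nodes = node_set(triples, layer)
    if not nodes:
        return float("nan")
    return sum(cross_degree(triples, v, direction) for v in nodes) / len(nodes)


def average_ranks(values):
    """Mid-ranks with ties averaged, 1-based."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        mid = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    return ranks


def spearman(xs, ys):
    """Rank-then-Pearson, average ranks for ties."""
    rx, ry = average_ranks(xs), average_ranks(ys)
    if len(set(rx)) < 2 or len(set(ry)) < 2:
        return float("nan")
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman_pair(triples, layer_a, layer_b, direction):
    common = sorted(node_set(triples, layer_a) & node_set(triples, layer_b))
    if len(common) < 2:
        return float("nan")
    xa = [degree(triples, v, layer_a, direction) for v in common]
    xb = [degree(triples, v, layer_b, direction) for v in common]
    return spearman(xa, xb)


def overlap(triples, layer_a, layer_b):
    va, vb = node_set(triples, layer_a), node_set(triples, layer_b)
    if not (va | vb):
        return float("nan")
    return 100.0 * len(va & vb) / len(va | vb)


def entropy(triples, node):
    counts = []
    for layer in LAYERS:
        counts.append(
            len(in_neighbors(triples, node, layer)) + len(out_neighbors(triples, node, layer))
        )
    total = sum(counts)
    if total == 0:
        return float("nan")
    return -sum((c / total) * math.log(c / total) for c in counts if c)


def layer_proportions(triples, nodes, direction):
    sums = {
        layer: sum(degree(triples, v, layer, direction) for v in nodes) for layer in LAYERS
    }
    total = sum(sums.values())
    if total == 0:
        return {layer: float("nan") for layer in LAYERS}
    return {layer: 100.0 * s / total for layer, s in sums.items()}


def random_triples(rng, max_nodes=12, max_records=40):
    """A random toy multilayer as deduplicated (u, v, layer) triples."""
    n_nodes = rng.integers(3, max_nodes + 1)
    nodes = [f"n{i}" for i in range(n_nodes)]
    n_rec = rng.integers(2, max_records + 1)
    triples = set()
    for _ in range(n_rec):
        u, v = rng.choice(n_nodes, size=2, replace=False)
        triples.add((nodes[u], nodes[v], LAYERS[rng.integers(3)]))
    return sorted(triples)
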