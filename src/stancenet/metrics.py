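"""Node-, layer- and network-level chambering statistics.

All degree metrics are distinct-neighbor counts on the aggregated layer
graphs, matching the |N(v)| definitions:

* ``degree``        — d^l_in(v) = |N^l_in(v)|, per layer and direction;
* ``cross_degree``  — d^M_in(v) = |∪_l N^l_in(v)|, the diversity of a
  node's contacts across all three stance layers (same for out);
* ``layer_diversity`` — l^M = mean of cross_degree over the layer's
  nodes, the macro-level chambering indicator;
* ``spearman_pair``   — rank similarity of the per-layer degree vectors
  on the nodes two layers share;
* ``overlap``         — percentage of shared nodes between two layers;
* ``entropy``         — H_v = −Σ_l p(l)_v ln p(l)_v, where p(l)_v is the
  share of v's connections falling in layer l (natural log; 0 for a
  single-layer node, ln 3 for a perfectly even spread);
* ``select_hardliners`` / ``select_diverse`` — the influential-user
  selections (lowest-entropy insiders, highest cross-degree spanners);
* ``fit_power_law``   — re-exported tail fit of a degree distribution.

Undefined statistics (empty layer, zero rank variance, isolated node)
surface as NaN with a log entry, never silently as 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from datetime import datetime
from typing import Callable, Iterable, Sequence

import numpy as np
import scipy.stats

from .forum_io import LAYERS
from .layers import EdgeRecord, MultilayerNetwork, snapshots
from .powerlaw_fit import PowerLawFit, fit_power_law  # noqa: F401  (public re-export)

logger = logging.getLogger(__name__)

__all__ = [
    "degree",
    "cross_degree",
    "layer_diversity",
    "spearman_pair",
    "overlap",
    "connection_counts",
    "entropy",
    "select_hardliners",
    "select_diverse",
    "layer_proportions",
    "hardliner_degrees",
    "fit_power_law",
    "PowerLawFit",
    "MetricSeries",
    "metric_series",
    "mean_layer_degree",
]


def _neighbors(M: MultilayerNetwork, v: str, layer: str, direction: str) -> set[str]:
    g = M.layers[layer]
    if v not in g:
        return set()
    if direction == "in":
        return set(g.predecessors(v))
    if direction == "out":
        return set(g.successors(v))
    raise ValueError(f"direction must be 'in' or 'out', got {direction!r}")


def degree(M: MultilayerNetwork, v: str, layer: str, direction: str) -> int:
    """Distinct in- or out-neighbors of ``v`` within one layer."""
    return len(_neighbors(M, v, layer, direction))


def cross_degree(M: MultilayerNetwork, v: str, direction: str) -> int:
    """Distinct neighbors of ``v`` in the union over all layers."""
    out: set[str] = set()
    for layer in LAYERS:
        out |= _neighbors(M, v, layer, direction)
    return len(out)


def layer_diversity(M: MultilayerNetwork, layer: str, direction: str) -> float:
    """Mean cross-degree over the layer's node set (NaN when empty)."""
    nodes = list(M.layers[layer].nodes)
    if not nodes:
        logger.warning("layer_diversity undefined: layer %s is empty", layer)
        return float("nan")
    return float(np.mean([cross_degree(M, v, direction) for v in nodes]))


def spearman_pair(M: MultilayerNetwork, layer_a: str, layer_b: str, direction: str) -> float:
    """Spearman rank correlation of per-layer degrees on shared nodes.

    Restricted to V^a ∩ V^b with average ranks for ties. NaN (logged)
    when fewer than two common nodes exist or either degree vector has
    zero variance.
    """
    common = sorted(set(M.layers[layer_a].nodes) & set(M.layers[layer_b].nodes))
    if len(common) < 2:
        logger.warning("spearman undefined: %s/%s share %d nodes", layer_a, layer_b, len(common))
        return float("nan")
    xa = [degree(M, v, layer_a, direction) for v in common]
    xb = [degree(M, v, layer_b, direction) for v in common]
    if len(set(xa)) < 2 or len(set(xb)) < 2:
        logger.warning("spearman undefined: zero-variance degrees in %s/%s", layer_a, layer_b)
        return float("nan")
    rho = scipy.stats.spearmanr(xa, xb).statistic
    return float(rho)


def overlap(M: MultilayerNetwork, layer_a: str, layer_b: str, denominator: str = "union") -> float:
    """Percentage of overlapping nodes between two layers.

    ``denominator`` selects the normalization: ``union`` (Jaccard ×100,
    the default), ``min`` (smaller layer), ``sum`` (both layer sizes
    added, double-counting shared nodes), or ``a``/``b`` (one layer's
    size).
    """
    va, vb = set(M.layers[layer_a].nodes), set(M.layers[layer_b].nodes)
    inter = len(va & vb)
    denom = {
        "union": len(va | vb),
        "min": min(len(va), len(vb)),
        "sum": len(va) + len(vb),
        "a": len(va),
        "b": len(vb),
    }[denominator]
    if denom == 0:
        logger.warning("overlap undefined: empty denominator for %s/%s", layer_a, layer_b)
        return float("nan")
    return 100.0 * inter / denom


def connection_counts(M: MultilayerNetwork, v: str, use_comment_counts: bool = False) -> np.ndarray:
    """Per-layer connection counts of ``v`` (both directions).

    Default counts distinct in- plus out-neighbors per layer; with
    ``use_comment_counts`` it sums the raw comment multiplicities on the
    node's incident edges instead.
    """
    counts = np.zeros(len(LAYERS))
    for i, layer in enumerate(LAYERS):
        g = M.layers[layer]
        if v not in g:
            continue
        if use_comment_counts:
            counts[i] = sum(d["count"] for _, _, d in g.in_edges(v, data=True)) + sum(
                d["count"] for _, _, d in g.out_edges(v, data=True)
            )
        else:
            counts[i] = g.in_degree(v) + g.out_degree(v)
    return counts


def entropy(M: MultilayerNetwork, v: str, use_comment_counts: bool = False) -> float:
    """Shannon entropy of v's connection distribution across layers.

    0 for a node active in a single layer, ln 3 for an even three-way
    spread; NaN (logged) for an isolated node.
    """
    counts = connection_counts(M, v, use_comment_counts=use_comment_counts)
    total = counts.sum()
    if total == 0:
        logger.warning("entropy undefined for isolated node %s", v)
        return float("nan")
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def _within_layer_total(M: MultilayerNetwork, v: str, layer: str) -> int:
    g = M.layers[layer]
    return (g.in_degree(v) + g.out_degree(v)) if v in g else 0


def select_hardliners(
    M: MultilayerNetwork,
    layer: str,
    k: int = 30,
    min_activity: int = 10,
    use_comment_counts: bool = False,
) -> list[str]:
    """The ``k`` lowest-entropy nodes of a layer (the entrenched core).

    Candidates are the layer's nodes with at least ``min_activity``
    total connections network-wide; without that floor, every
    one-comment user ties at entropy 0. Ties are broken by higher
    within-layer total degree, then node id. Returns fewer than ``k``
    when the candidate pool is smaller.
    """
    candidates = [
        v
        for v in M.layers[layer].nodes
        if connection_counts(M, v, use_comment_counts=use_comment_counts).sum() >= min_activity
    ]
    candidates.sort(
        key=lambda v: (
            entropy(M, v, use_comment_counts=use_comment_counts),
            -_within_layer_total(M, v, layer),
            v,
        )
    )
    return candidates[:k]


def select_diverse(M: MultilayerNetwork, k: int = 50) -> list[str]:
    """Top-``k`` nodes by total cross-layer degree (the spanners).

    Ranking key is d^M_in + d^M_out, ties broken by entropy descending
    then node id.
    """
    nodes = sorted(M.nodes())
    nodes.sort(
        key=lambda v: (
            -(cross_degree(M, v, "in") + cross_degree(M, v, "out")),
            -entropy(M, v),
            v,
        )
    )
    return nodes[:k]


def layer_proportions(
    M: MultilayerNetwork, nodes: Iterable[str], direction: str
) -> dict[str, float]:
    """Share (%) of a node set's connections landing in each layer.

    Per-layer degrees are summed over the node set and normalized by
    the all-layer total; the three percentages sum to 100.
    """
    nodes = list(nodes)
    sums = {layer: float(sum(degree(M, v, layer, direction) for v in nodes)) for layer in LAYERS}
    total = sum(sums.values())
    if total == 0:
        logger.warning("layer_proportions undefined: zero total %s-degree", direction)
        return {layer: float("nan") for layer in LAYERS}
    return {layer: 100.0 * s / total for layer, s in sums.items()}


def hardliner_degrees(
    M: MultilayerNetwork,
    layer: str,
    hardliners: Sequence[str] | None = None,
    k: int = 30,
    min_activity: int = 10,
) -> dict[str, float]:
    """Mean standardized within-layer degrees of a layer's hardliners.

    Each hardliner's within-layer degree is divided by the layer's mean
    degree in the same direction, so 1.0 means "as connected as a
    typical node of the layer". Returns ``{"out": ..., "in": ...}``;
    NaN when the hardliner set is empty.
    """
    if hardliners is None:
        hardliners = select_hardliners(M, layer, k=k, min_activity=min_activity)
    if not hardliners:
        logger.warning("hardliner_degrees undefined: empty hardliner set in %s", layer)
        return {"out": float("nan"), "in": float("nan")}
    nodes = list(M.layers[layer].nodes)
    out: dict[str, float] = {}
    for direction in ("out", "in"):
        layer_mean = float(np.mean([degree(M, v, layer, direction) for v in nodes]))
        if layer_mean == 0:
            out[direction] = float("nan")
            continue
        vals = [degree(M, v, layer, direction) / layer_mean for v in hardliners]
        out[direction] = float(np.mean(vals))
    return out


def mean_layer_degree(M: MultilayerNetwork, layer: str, direction: str = "in") -> float:
    """Average per-node degree of one layer (NaN when empty).

    With aggregated edges, the in- and out-sums coincide, so for
    reporting "average degree" use twice the edge count over the node
    count — this helper returns the directional mean.
    """
    nodes = list(M.layers[layer].nodes)
    if not nodes:
        return float("nan")
    return float(np.mean([degree(M, v, layer, direction) for v in nodes]))


@dataclass
class MetricSeries:
    """A metric evaluated on cumulative snapshots."""

    times: list[datetime]
    values: np.ndarray  # NaN marks undefined points (gaps), never dropped


def metric_series(
    records: Sequence[EdgeRecord],
    time_points: Sequence[datetime],
    metric: Callable[[MultilayerNetwork], float],
) -> MetricSeries:
    """Evaluate ``metric`` on each cumulative snapshot.

    The final element equals the metric on the static network whenever
    the last time point covers all records.
    """
    snaps = snapshots(records, time_points)
    values = np.array([float(metric(s.network)) for s in snaps])
    return MetricSeries(times=list(time_points), values=values)


def maximum_entropy() -> float:
    """Upper bound of the node entropy (three layers): ln 3."""
    return math.log(3)
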