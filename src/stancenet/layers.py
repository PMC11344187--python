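"""Flatten labeled threads into a directed three-layer network.

Every comment becomes one directed edge record commenter → author, so an
author's indegree counts the distinct users whose attention the author
received. The record's layer follows the post's stance label, except
that a "boo" sends the commenter to the opposing camp: a boo on a
provaccination post lands in the antivaccination layer; a boo on an
antivaccination post is assigned uniformly at random to P or H (the two
plausible opposing stances); symmetrically, a boo on a hesitant post is
assigned uniformly to P or A. Edge weights encode reaction affinity
(like 2, neutral 1, boo 0.2); they are stored on the aggregated edges
but the degree metrics are neighbor counts, so weights only matter for
optional weighted variants.

The three layers G^P, G^H, G^A share a global user namespace; a user may
appear in any subset of layers. Temporal analysis uses cumulative
snapshots: the network restricted to records with time ≤ t_n.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from datetime import datetime
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .forum_io import LAYERS, Post

__all__ = [
    "EdgeRecord",
    "MultilayerNetwork",
    "Snapshot",
    "REACTION_WEIGHTS",
    "assign_comment",
    "flatten",
    "build_multilayer",
    "snapshots",
    "records_to_csv",
    "records_from_csv",
]

#: Reaction -> edge weight (affinity; not used by the count-based degrees).
REACTION_WEIGHTS = {"like": 2.0, "neutral": 1.0, "boo": 0.2}

#: Opposing camps a boo can land in, by the stance of the booed post.
_BOO_TARGETS = {"P": ("A",), "A": ("P", "H"), "H": ("P", "A")}

_TIME_FMT = "%Y-%m-%dT%H:%M:%S"


@dataclass(frozen=True, slots=True)
class EdgeRecord:
    """One flattened comment: a directed commenter→author event."""

    source: str  # commenter
    target: str  # post author
    layer: str
    weight: float
    time: datetime
    reaction: str


def assign_comment(post_label: str, reaction: str, rng: np.random.Generator) -> tuple[str, float]:
    """Layer and weight for one comment on a post with stance ``post_label``.

    Likes and neutral comments join the post's own layer (weights 2 and
    1). Boos (weight 0.2) go to the opposing camp; when two camps
    plausibly oppose the post, one is drawn uniformly from ``rng``.
    """
    if post_label not in LAYERS:
        raise ValueError(
            f"post label {post_label!r} is not a stance layer; exclude neutral/irrelevant upstream"
        )
    if reaction in ("like", "neutral"):
        return post_label, REACTION_WEIGHTS[reaction]
    if reaction != "boo":
        raise ValueError(f"unknown reaction {reaction!r}")
    targets = _BOO_TARGETS[post_label]
    layer = targets[0] if len(targets) == 1 else targets[rng.integers(len(targets))]
    return layer, REACTION_WEIGHTS["boo"]


def flatten(posts: Iterable[Post], seed: int = 0, include_self_loops: bool = False) -> list[EdgeRecord]:
    """One :class:`EdgeRecord` per comment, commenter → author.

    Self-comments (a user commenting on their own post) are dropped by
    default. The boo-reassignment randomness is drawn from a stream
    seeded by ``seed``, so output is deterministic.
    """
    rng = np.random.default_rng(seed)
    records: list[EdgeRecord] = []
    for post in posts:
        if post.label not in LAYERS:
            raise ValueError(f"post {post.board_id} has non-stance label {post.label!r}")
        for c in post.comments:
            if c.commenter == post.author and not include_self_loops:
                continue
            layer, weight = assign_comment(post.label, c.reaction, rng)
            records.append(
                EdgeRecord(
                    source=c.commenter,
                    target=post.author,
                    layer=layer,
                    weight=weight,
                    time=c.time,
                    reaction=c.reaction,
                )
            )
    return records


@dataclass
class MultilayerNetwork:
    """Three directed layer graphs over a shared user namespace.

    Each layer is a :class:`networkx.DiGraph`; parallel records between
    the same (source, target) pair are aggregated into one edge with
    summed ``weight``, comment ``count``, and first/last times. Directed
    and nonmirrored: (u, v) and (v, u) are distinct edges.
    """

    layers: dict[str, nx.DiGraph]

    def __getitem__(self, layer: str) -> nx.DiGraph:
        return self.layers[layer]

    def nodes(self) -> set[str]:
        out: set[str] = set()
        for g in self.layers.values():
            out |= set(g.nodes)
        return out

    def n_edges(self, layer: str) -> int:
        return self.layers[layer].number_of_edges()

    @classmethod
    def empty(cls) -> "MultilayerNetwork":
        return cls({l: nx.DiGraph(layer=l) for l in LAYERS})


def build_multilayer(records: Sequence[EdgeRecord]) -> MultilayerNetwork:
    """Aggregate edge records into the static three-layer network."""
    M = MultilayerNetwork.empty()
    for r in records:
        g = M.layers[r.layer]
        if g.has_edge(r.source, r.target):
            data = g[r.source][r.target]
            data["weight"] += r.weight
            data["count"] += 1
            data["first_time"] = min(data["first_time"], r.time)
            data["last_time"] = max(data["last_time"], r.time)
        else:
            g.add_edge(
                r.source, r.target, weight=r.weight, count=1, first_time=r.time, last_time=r.time
            )
    return M


@dataclass
class Snapshot:
    """The cumulative network at one observation time t_n."""

    time: datetime
    network: MultilayerNetwork


def snapshots(records: Sequence[EdgeRecord], time_points: Sequence[datetime]) -> list[Snapshot]:
    """Cumulative instantiations M_1..M_n at the given time points.

    A record enters every snapshot with ``time_point >= record.time``,
    so snapshots are nested; the final snapshot (at or after the last
    record) equals the static network.
    """
    if any(b < a for a, b in zip(time_points, time_points[1:])):
        raise ValueError("time_points must be sorted ascending")
    ordered = sorted(records, key=lambda r: r.time)
    out: list[Snapshot] = []
    i = 0
    current: list[EdgeRecord] = []
    for t in time_points:
        while i < len(ordered) and ordered[i].time <= t:
            current.append(ordered[i])
            i += 1
        out.append(Snapshot(time=t, network=build_multilayer(current)))
    return out


def records_to_csv(records: Sequence[EdgeRecord], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["source", "target", "layer", "weight", "reaction", "time"])
        for r in records:
            writer.writerow(
                [r.source, r.target, r.layer, r.weight, r.reaction, r.time.strftime(_TIME_FMT)]
            )


def records_from_csv(path) -> list[EdgeRecord]:
    records = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            records.append(
                EdgeRecord(
                    source=row["source"],
                    target=row["target"],
                    layer=row["layer"],
                    weight=float(row["weight"]),
                    time=datetime.strptime(row["time"], _TIME_FMT),
                    reaction=row["reaction"],
                )
            )
    return records
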