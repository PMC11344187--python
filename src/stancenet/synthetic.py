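"""Synthetic stance-labeled forum corpora with known ground truth.

No public deposit of the scraped forum exists, so downstream stages are
exercised on generated corpora that emulate its measured structure:
heavy-tailed (power-law) per-user commenting activity, three stance
layers of unequal size, partial user overlap between layers, a tunable
within-stance commenting probability ("chambering"), hardliner and
spanner user archetypes, and monthly posting bursts.

The generative model, briefly: each user receives a latent stance
(P/H/A), an archetype, and an activity level ``k`` drawn from a discrete
power law ``p(k) ∝ k^-α`` (the user writes exactly ``k`` comments).
Posts are scheduled per layer per month, with burst months receiving a
multiplied share. Each comment first picks a target stance — hardliners
always stay within their own stance, spanners pick uniformly among all
three, background users stay home with probability ``chambering`` and
otherwise pick uniformly among the other two stances — then picks a
concrete post within that stance by preferential attachment (probability
proportional to 1 + comments already received), which reproduces the
heavy-tailed indegrees observed on real bulletin boards.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import scipy.stats

from .forum_io import LAYERS, Comment, Post, format_post

__all__ = ["ForumConfig", "GroundTruth", "generate_users", "generate_corpus", "emit_threads"]

#: Post share of the three stance layers in the study corpus (P:H:A).
DEFAULT_STANCE_WEIGHTS = (1283, 1322, 387)

ARCHETYPES = ("hardliner", "spanner", "background")


class ConfigurationError(ValueError):
    """Raised for an inconsistent :class:`ForumConfig`."""


@dataclass(frozen=True)
class ForumConfig:
    """Parameters of the synthetic forum.

    Defaults mirror the observed structure of the vaccine discussion
    corpus: stance shares proportional to 1283:1322:387 posts, activity
    exponent 2.3 (the fitted degree-distribution exponent), and a
    23-month window starting January 2021 with a posting burst in month
    10 (November 2021, the observed surge).
    """

    n_users: int = 2000
    n_posts_per_layer: tuple[int, int, int] = (257, 264, 77)
    activity_exponent: float = 2.3
    chambering: float = 0.7
    boo_rate: float = 0.10
    neutral_rate: float = 0.30
    hardliner_fraction: float = 0.05
    spanner_fraction: float = 0.05
    n_periods: int = 23
    burst_periods: frozenset[int] = frozenset({10})
    burst_factor: float = 3.0
    stance_weights: tuple[float, float, float] = DEFAULT_STANCE_WEIGHTS
    start: datetime = datetime(2021, 1, 1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_users < 1:
            raise ConfigurationError("n_users must be positive")
        if len(self.n_posts_per_layer) != 3 or any(n < 1 for n in self.n_posts_per_layer):
            raise ConfigurationError("n_posts_per_layer needs three positive counts")
        if self.activity_exponent <= 1:
            raise ConfigurationError("activity_exponent must exceed 1")
        for name in ("chambering", "boo_rate", "neutral_rate", "hardliner_fraction", "spanner_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.boo_rate + self.neutral_rate > 1:
            raise ConfigurationError("boo_rate + neutral_rate must not exceed 1")
        if self.hardliner_fraction + self.spanner_fraction > 1:
            raise ConfigurationError("hardliner_fraction + spanner_fraction must not exceed 1")
        if self.n_periods < 1:
            raise ConfigurationError("n_periods must be positive")
        if any(b < 0 for b in self.burst_periods):
            raise ConfigurationError("burst_periods must be nonnegative month indices")
        # burst months beyond the window simply never occur
        object.__setattr__(
            self,
            "burst_periods",
            frozenset(b for b in self.burst_periods if b < self.n_periods),
        )

    # -- calendar helpers ---------------------------------------------------

    def period_bounds(self, i: int) -> tuple[datetime, datetime]:
        """Half-open [start, end) of month ``i`` of the window."""
        month0 = self.start.year * 12 + (self.start.month - 1) + i
        year, month = divmod(month0, 12)
        start = datetime(year, month + 1, 1)
        ndays = calendar.monthrange(year, month + 1)[1]
        return start, start + timedelta(days=ndays)

    def period_boundaries(self) -> list[datetime]:
        """The ``n_periods`` month-end time points t_1..t_n."""
        return [self.period_bounds(i)[1] for i in range(self.n_periods)]


@dataclass
class GroundTruth:
    """Latent generator state the tests compare against."""

    user_stance: dict[str, str]
    user_archetype: dict[str, str]
    activity: dict[str, int]
    post_counts: np.ndarray  # (n_periods, 3) posts per period per layer
    users_by_stance: dict[str, list[str]] = field(default_factory=dict)

    def to_csv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("user,stance,archetype,activity\n")
            for u in sorted(self.user_stance):
                fh.write(
                    f"{u},{self.user_stance[u]},{self.user_archetype[u]},{self.activity[u]}\n"
                )


def _rng(config: ForumConfig, stream: int) -> np.random.Generator:
    # independent named streams off the one root seed
    return np.random.default_rng([config.seed, stream])


def generate_users(config: ForumConfig) -> GroundTruth:
    """Draw latent stances, archetypes, activity levels and the post schedule.

    Activity levels are zeta-distributed (discrete power law on k ≥ 1
    with exponent ``activity_exponent``); the level is the exact number
    of comments the user will write. The per-period post schedule is
    multinomial with burst months upweighted by ``burst_factor``.
    """
    rng = _rng(config, 0)
    users = [f"u{i:05d}" for i in range(config.n_users)]
    w = np.asarray(config.stance_weights, dtype=float)
    stances = rng.choice(list(LAYERS), size=config.n_users, p=w / w.sum())
    arch_p = [
        config.hardliner_fraction,
        config.spanner_fraction,
        1 - config.hardliner_fraction - config.spanner_fraction,
    ]
    archetypes = rng.choice(list(ARCHETYPES), size=config.n_users, p=arch_p)
    activity = scipy.stats.zipf.rvs(config.activity_exponent, size=config.n_users, random_state=rng)

    intensity = np.array(
        [config.burst_factor if i in config.burst_periods else 1.0 for i in range(config.n_periods)]
    )
    intensity /= intensity.sum()
    post_counts = np.column_stack(
        [rng.multinomial(n, intensity) for n in config.n_posts_per_layer]
    )  # (n_periods, 3)

    truth = GroundTruth(
        user_stance={u: str(s) for u, s in zip(users, stances)},
        user_archetype={u: str(a) for u, a in zip(users, archetypes)},
        activity={u: int(k) for u, k in zip(users, activity)},
        post_counts=post_counts,
    )
    truth.users_by_stance = {
        layer: [u for u in users if truth.user_stance[u] == layer] for layer in LAYERS
    }
    for layer, members in truth.users_by_stance.items():
        if not members:
            raise ConfigurationError(
                f"no user drew stance {layer}; increase n_users or its stance weight"
            )
    return truth


def _pick_target_stance(
    stance: str, archetype: str, chambering: float, rng: np.random.Generator
) -> str:
    if archetype == "hardliner":
        return stance
    if archetype == "spanner":
        return LAYERS[rng.integers(3)]
    if rng.random() < chambering:
        return stance
    others = [l for l in LAYERS if l != stance]
    return others[rng.integers(2)]


def _uniform_time(rng: np.random.Generator, lo: datetime, hi: datetime) -> datetime:
    span = (hi - lo).total_seconds()
    return (lo + timedelta(seconds=float(rng.uniform(0, span)))).replace(microsecond=0)


def generate_corpus(config: ForumConfig, truth: GroundTruth) -> list[Post]:
    """Generate the labeled posts with their comments.

    Deterministic given ``config.seed``. Post labels equal the author's
    latent stance; comment reaction marks are sampled independently from
    (boo_rate, neutral_rate, remainder=like); comment timestamps fall
    within the post's month, at or after the post.
    """
    rng = _rng(config, 1)

    # posts, scheduled per (period, layer); authors are same-stance users
    # weighted by activity (active users also post more)
    posts: list[Post] = []
    posts_by_layer: dict[str, list[Post]] = {l: [] for l in LAYERS}
    period_end: dict[str, datetime] = {}
    n_board = 0
    for i in range(config.n_periods):
        lo, hi = config.period_bounds(i)
        for j, layer in enumerate(LAYERS):
            members = truth.users_by_stance[layer]
            weights = np.array([truth.activity[u] for u in members], dtype=float)
            weights /= weights.sum()
            for _ in range(int(truth.post_counts[i, j])):
                author = members[rng.choice(len(members), p=weights)]
                board_id = f"B{n_board:06d}"
                n_board += 1
                post = Post(
                    board_id=board_id,
                    author=author,
                    time=_uniform_time(rng, lo, hi),
                    title=f"[{layer}] 疫苗討論串 {board_id}",
                    label=layer,
                )
                posts.append(post)
                posts_by_layer[layer].append(post)
                period_end[board_id] = hi

    # comments: per-user counts are the power-law activity draws; targets
    # chosen stance-first, then preferential attachment within the stance
    received = {l: np.zeros(len(posts_by_layer[l])) for l in LAYERS}
    reactions = ("boo", "neutral", "like")
    react_p = [config.boo_rate, config.neutral_rate, 1 - config.boo_rate - config.neutral_rate]
    for user in sorted(truth.user_stance):
        stance = truth.user_stance[user]
        archetype = truth.user_archetype[user]
        for k in range(truth.activity[user]):
            target = _pick_target_stance(stance, archetype, config.chambering, rng)
            pool = posts_by_layer[target]
            pref = (1.0 + received[target]) / (len(pool) + received[target].sum())
            idx = int(rng.choice(len(pool), p=pref))
            received[target][idx] += 1
            post = pool[idx]
            reaction = reactions[rng.choice(3, p=react_p)]
            ctime = _uniform_time(rng, post.time, period_end[post.board_id])
            text = f"{user} 第{k + 1}則回覆 關於疫苗的看法與討論內容"
            post.comments.append(
                Comment(commenter=user, reaction=reaction, time=ctime, text=text)
            )

    for post in posts:
        post.comments.sort(key=lambda c: (c.time, c.commenter))
    posts.sort(key=lambda p: (p.time, p.board_id))
    return posts


def emit_threads(posts: list[Post], destination) -> list[Path]:
    """Write posts in the thread-text dialect.

    ``destination`` ending in ``.txt`` gets the whole corpus in one
    file; otherwise it is treated as a directory receiving one file per
    board. Returns the paths written.
    """
    dest = Path(destination)
    if dest.suffix == ".txt":
        dest.parent.mkdir(parents=True, exist_ok=True)
        with open(dest, "w", encoding="utf-8") as fh:
            for p in posts:
                fh.write(format_post(p))
                fh.write("\n")
        return [dest]
    dest.mkdir(parents=True, exist_ok=True)
    paths = []
    for p in posts:
        path = dest / f"{p.board_id}.txt"
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(format_post(p))
        paths.append(path)
    return paths
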