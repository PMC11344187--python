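"""Discrete power-law fitting for degree distributions.

Maximum-likelihood estimation of the tail exponent δ in
p(d) ∝ d^(−δ) for d ≥ x_min, with x_min chosen by minimizing the
Kolmogorov–Smirnov distance between the empirical tail and the fitted
model, and a semi-parametric bootstrap goodness-of-fit p-value: small p
signals deviation from a power law. The discrete likelihood uses the
Hurwitz zeta normalization ζ(δ, x_min).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import zeta

logger = logging.getLogger(__name__)

__all__ = ["PowerLawFit", "fit_power_law", "sample_power_law"]

_DELTA_BOUNDS = (1.01, 6.0)


@dataclass(frozen=True)
class PowerLawFit:
    """Result of a discrete power-law tail fit."""

    exponent: float  # δ
    xmin: int
    ks_distance: float
    p_value: float  # goodness of fit; NaN when bootstrap disabled
    n_tail: int  # observations with degree >= xmin


def _mle_exponent(tail: np.ndarray, xmin: int) -> float:
    """Exact discrete MLE of δ for the tail at fixed x_min."""
    n = tail.size
    sum_log = np.log(tail).sum()

    def nll(delta: float) -> float:
        return n * np.log(zeta(delta, xmin)) + delta * sum_log

    res = minimize_scalar(nll, bounds=_DELTA_BOUNDS, method="bounded")
    return float(res.x)


def _model_cdf(x: np.ndarray, delta: float, xmin: int) -> np.ndarray:
    """P(X <= x) for the discrete power law on [xmin, inf)."""
    z = zeta(delta, xmin)
    return 1.0 - zeta(delta, x + 1.0) / z


def _ks(tail_sorted: np.ndarray, delta: float, xmin: int) -> float:
    values, counts = np.unique(tail_sorted, return_counts=True)
    ecdf = np.cumsum(counts) / tail_sorted.size
    return float(np.abs(ecdf - _model_cdf(values.astype(float), delta, xmin)).max())


def _fit_at_best_xmin(data: np.ndarray, candidates: np.ndarray, min_tail: int) -> tuple[float, int, float]:
    best = None
    for xmin in candidates:
        tail = data[data >= xmin]
        if tail.size < min_tail:
            continue
        delta = _mle_exponent(tail, int(xmin))
        d = _ks(np.sort(tail), delta, int(xmin))
        if best is None or d < best[2]:
            best = (delta, int(xmin), d)
    if best is None:
        raise ValueError("no x_min candidate leaves a large enough tail")
    return best


def sample_power_law(
    n: int, delta: float, xmin: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` values from the discrete power law on [xmin, inf).

    Uses the continuous-approximation inverse transform
    x = floor((xmin − 1/2)(1 − u)^(−1/(δ−1)) + 1/2), accurate for the
    tail shapes this module fits and fast enough for bootstrap use.
    """
    u = rng.random(n)
    x = np.floor((xmin - 0.5) * (1.0 - u) ** (-1.0 / (delta - 1.0)) + 0.5)
    return x.astype(np.int64)


def fit_power_law(
    degrees,
    n_bootstrap: int = 100,
    seed: int | np.random.Generator = 0,
    min_n: int = 50,
    min_tail: int = 10,
    min_tail_fraction: float = 0.05,
    max_candidates: int = 50,
) -> PowerLawFit:
    """Fit the degree-distribution tail with a discrete power law.

    Parameters
    ----------
    degrees
        Observed degree counts; zeros are discarded.
    n_bootstrap
        Semi-parametric bootstrap replicates for the goodness-of-fit
        p-value (0 disables the test; p is then NaN).
    min_n
        Floor on the number of nonzero degrees (fits on fewer points are
        too unstable to report).
    min_tail, min_tail_fraction
        An x_min candidate must leave a tail of at least ``min_tail``
        points and at least ``min_tail_fraction`` of the data; the
        fraction floor stops x_min from drifting so far out that any
        smooth tail looks locally power-law.
    max_candidates
        Cap on x_min candidates (quantile-spaced when exceeded).
    """
    data = np.asarray(degrees, dtype=np.int64)
    data = data[data > 0]
    if data.size < min_n:
        raise ValueError(f"need at least {min_n} nonzero degrees, got {data.size}")
    uniq = np.unique(data)
    if uniq.size < 2:
        raise ValueError("degenerate degree distribution (all values equal)")
    min_tail = max(min_tail, int(np.ceil(min_tail_fraction * data.size)))
    candidates = uniq[:-1]  # at least two distinct values in any tail
    if candidates.size > max_candidates:
        idx = np.unique(np.linspace(0, candidates.size - 1, max_candidates).astype(int))
        candidates = candidates[idx]

    delta, xmin, ks_obs = _fit_at_best_xmin(data, candidates, min_tail)

    p_value = float("nan")
    if n_bootstrap > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        body = data[data < xmin]
        p_tail = (data >= xmin).mean()
        n_exceed = 0
        for _ in range(n_bootstrap):
            take_tail = rng.random(data.size) < p_tail
            n_tail_b = int(take_tail.sum())
            parts = []
            if n_tail_b:
                parts.append(sample_power_law(n_tail_b, delta, xmin, rng))
            if data.size - n_tail_b:
                if body.size:
                    parts.append(rng.choice(body, size=data.size - n_tail_b, replace=True))
                else:
                    parts.append(sample_power_law(data.size - n_tail_b, delta, xmin, rng))
            synth = np.concatenate(parts)
            u = np.unique(synth)
            cand = u[:-1] if u.size > 1 else u
            if cand.size > max_candidates:
                idx = np.unique(np.linspace(0, cand.size - 1, max_candidates).astype(int))
                cand = cand[idx]
            try:
                _, _, ks_b = _fit_at_best_xmin(synth, cand, min_tail)
            except ValueError:
                continue
            if ks_b >= ks_obs:
                n_exceed += 1
        p_value = n_exceed / n_bootstrap
        if p_value <= 0.05:
            logger.info("power-law fit rejected at 5%% (p=%.3f)", p_value)

    return PowerLawFit(
        exponent=delta,
        xmin=int(xmin),
        ks_distance=ks_obs,
        p_value=p_value,
        n_tail=int((data >= xmin).sum()),
    )
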