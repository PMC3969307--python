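"""Circular descriptive statistics and hypothesis tests.

Implements the mean resultant vector, circular median, Rayleigh test of
uniformity, Watson-Williams multi-sample test of mean directions, the
circular-linear correlation coefficient, and the phase-to-time conversion
used to express phase offsets in milliseconds.

Angles are radians; results use the [-pi, pi] convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, InvalidInputError

__all__ = [
    "CircSummary",
    "RayleighResult",
    "WatsonWilliamsResult",
    "CircLinCorrResult",
    "wrap_angle",
    "circ_mean_resultant",
    "circ_median",
    "rayleigh_test",
    "watson_williams",
    "circ_linear_corr",
    "phase_to_time",
]


def wrap_angle(theta):
    """Wrap angles to [-pi, pi] (pi maps to pi, -pi to -pi... both ends kept)."""
    return np.angle(np.exp(1j * np.asarray(theta, dtype=float)))


@dataclass(frozen=True)
class CircSummary:
    mean_angle: float
    resultant_length: float
    n: int


@dataclass(frozen=True)
class RayleighResult:
    z: float
    p: float
    n: int


@dataclass(frozen=True)
class WatsonWilliamsResult:
    F: float
    df1: int
    df2: int
    p: float
    pooled_resultant: float
    warning: str | None = None


@dataclass(frozen=True)
class CircLinCorrResult:
    r: float
    p: float
    n: int
    p_permutation: float | None = None


def _angles(angles) -> np.ndarray:
    a = np.asarray(angles, dtype=float).ravel()
    if a.size == 0:
        raise InvalidInputError("empty angle sample")
    if not np.all(np.isfinite(a)):
        raise InvalidInputError("angles contain non-finite values")
    return a


def circ_mean_resultant(angles) -> CircSummary:
    """Circular mean direction and mean resultant length.

    The mean angle is the argument of the mean unit vector and the
    resultant length its modulus (1 iff all angles coincide mod 2*pi).
    """
    a = _angles(angles)
    v = np.mean(np.exp(1j * a))
    return CircSummary(
        mean_angle=float(np.angle(v)),
        resultant_length=float(min(np.abs(v), 1.0)),
        n=a.size,
    )


def _circ_dist_sum(candidates: np.ndarray, sample: np.ndarray) -> np.ndarray:
    # circular distance pi - |pi - |a - b|| summed over the sample
    d = np.abs(candidates[:, None] - sample[None, :]) % (2 * np.pi)
    return np.sum(np.pi - np.abs(np.pi - d), axis=1)


def circ_median(angles) -> float:
    """Angle minimizing the summed circular distance to the sample.

    The objective is piecewise linear with breakpoints at the sample
    angles and their antipodes, so evaluating breakpoints and arc
    midpoints finds the exact minimum; plateau ties are broken by the
    circular mean of all minimizers.
    """
    a = wrap_angle(_angles(angles))
    if a.size == 1:
        return float(a[0])
    breaks = np.unique(wrap_angle(np.concatenate([a, a + np.pi])))
    # midpoints of adjacent arcs, including the wrap-around arc
    ext = np.concatenate([breaks, [breaks[0] + 2 * np.pi]])
    mids = wrap_angle((ext[:-1] + ext[1:]) / 2.0)
    cand = np.concatenate([breaks, mids])
    cost = _circ_dist_sum(cand, a)
    minimum = np.min(cost)
    winners = cand[cost <= minimum + 1e-9]
    if winners.size == 1:
        return float(winners[0])
    return circ_mean_resultant(winners).mean_angle


def rayleigh_test(angles) -> RayleighResult:
    """Rayleigh test of circular uniformity; z = n * Rbar^2.

    p uses Zar's finite-n approximation,
    ``exp(sqrt(1 + 4n + 4(n^2 - R^2)) - (1 + 2n))`` with R = n*Rbar.
    """
    a = _angles(angles)
    n = a.size
    if n < 4:
        raise InsufficientDataError(f"Rayleigh test needs n >= 4, got {n}")
    rbar = circ_mean_resultant(a).resultant_length
    big_r = n * rbar
    z = n * rbar**2
    p = float(np.exp(np.sqrt(1 + 4 * n + 4 * (n**2 - big_r**2)) - (1 + 2 * n)))
    return RayleighResult(z=float(z), p=min(p, 1.0), n=n)


def _est_kappa(rbar: float) -> float:
    # Fisher's three-piece approximation of the von Mises concentration
    if rbar < 0.53:
        return 2 * rbar + rbar**3 + 5 * rbar**5 / 6
    if rbar < 0.85:
        return -0.4 + 1.39 * rbar + 0.43 / (1 - rbar)
    return 1.0 / (rbar**3 - 4 * rbar**2 + 3 * rbar)


def watson_williams(groups, min_pooled_resultant: float = 0.45) -> WatsonWilliamsResult:
    """Watson-Williams test for equality of mean directions across groups.

    A circular analogue of one-way ANOVA. Assumes concentrated von Mises
    samples; when the pooled within-group resultant falls below
    ``min_pooled_resultant`` the result carries a warning flag instead of
    raising (callers typically pre-screen with a Rayleigh test).
    """
    groups = [_angles(g) for g in groups]
    k = len(groups)
    if k < 2:
        raise InvalidInputError("need at least two groups")
    for g in groups:
        if g.size < 5:
            raise InsufficientDataError("each group needs n >= 5")
    ns = np.array([g.size for g in groups])
    n_total = int(ns.sum())
    # unnormalized resultants per group and pooled
    ri = np.array([g.size * circ_mean_resultant(g).resultant_length for g in groups])
    all_angles = np.concatenate(groups)
    big_r = n_total * circ_mean_resultant(all_angles).resultant_length
    rw = float(ri.sum() / n_total)  # pooled within-group mean resultant
    warning = None
    if rw < min_pooled_resultant:
        warning = (
            f"pooled within-group resultant {rw:.3f} < {min_pooled_resultant}; "
            "concentration assumption questionable"
        )
        warnings.warn(warning, stacklevel=2)
    kappa = _est_kappa(rw)
    correction = 1 + 3 / (8 * kappa) if kappa > 0 else 1.0
    df1, df2 = k - 1, n_total - k
    denom = n_total - ri.sum()
    if denom <= 0:  # all angles identical within groups
        f_stat = np.inf if ri.sum() - big_r > 1e-12 else 0.0
    else:
        f_stat = correction * (df2 * (ri.sum() - big_r)) / (df1 * denom)
    f_stat = max(float(f_stat), 0.0)
    p = float(stats.f.sf(f_stat, df1, df2))
    return WatsonWilliamsResult(F=f_stat, df1=df1, df2=df2, p=p,
                                pooled_resultant=rw, warning=warning)


def circ_linear_corr(angles, x, n_permutations: int = 0,
                     seed: int | None = None) -> CircLinCorrResult:
    """Circular-linear correlation between angles and a linear variable.

    r = sqrt((rxc^2 + rxs^2 - 2*rxc*rxs*rcs) / (1 - rcs^2)) from the
    pairwise Pearson correlations of x with cos(theta), sin(theta) and of
    cos with sin. The asymptotic p comes from n*r^2 ~ chi2(2); an optional
    seeded permutation p is available for small samples.
    """
    a = _angles(angles)
    xv = np.asarray(x, dtype=float).ravel()
    if a.size != xv.size:
        raise InvalidInputError("angles and x must have equal length")
    n = a.size
    if n < 6:
        raise InsufficientDataError(f"circular-linear correlation needs n >= 6, got {n}")
    if np.ptp(xv) == 0:
        raise InvalidInputError("x is constant")

    def _r(a_, x_):
        c, s = np.cos(a_), np.sin(a_)
        rxc = np.corrcoef(x_, c)[0, 1]
        rxs = np.corrcoef(x_, s)[0, 1]
        rcs = np.corrcoef(c, s)[0, 1]
        num = rxc**2 + rxs**2 - 2 * rxc * rxs * rcs
        val = num / (1 - rcs**2)
        return float(np.sqrt(min(max(val, 0.0), 1.0)))

    r = _r(a, xv)
    p = float(stats.chi2.sf(n * r**2, 2))
    p_perm = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            if _r(a, rng.permutation(xv)) >= r:
                count += 1
        p_perm = (count + 1) / (n_permutations + 1)
    return CircLinCorrResult(r=r, p=p, n=n, p_permutation=p_perm)


def phase_to_time(delta_phase: float, f: float) -> float:
    """Convert a phase offset (radians) on an f-Hz cycle to milliseconds.

    ``delta_phase / (2*pi) * 1000 / f``; e.g. 0.31*pi at 4 Hz -> 38.75 ms.
    """
    if f <= 0:
        raise InvalidInputError(f"frequency must be positive, got {f}")
    return float(delta_phase / (2 * np.pi) * 1000.0 / f)
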