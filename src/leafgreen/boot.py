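"""Bootstrap inference for the pixel-weighted color statistics.

The sampling distribution of each weighted statistic is approximated by
resampling green codes from the categorical distribution given by the pixel
weights W_i: one replicate draws ``n_draw`` codes i.i.d. with probability
W_i, forms empirical weights from the draw, and recomputes the statistic.
95% percentile intervals over ``n_rep`` replicates (default 2000) give the
confidence bounds; treatment differences are replicate-wise contrasts of
independently resampled groups.

``n_draw`` defaults to the profile's own green-pixel total (capped at 1e5),
i.e. the empirical pixel population is resampled at its own size — the
standard nonparametric bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .greenness import GreenProfile

__all__ = [
    "STATISTIC_LABELS",
    "BootstrapResult",
    "ContrastResult",
    "ci_percentile",
    "bootstrap_stats",
    "contrast",
    "DEFAULT_N_REP",
    "DEFAULT_ALPHA",
    "MAX_DEFAULT_DRAW",
]

STATISTIC_LABELS = ("R", "G", "B", "R/G", "B/G")
DEFAULT_N_REP = 2000
DEFAULT_ALPHA = 0.05
MAX_DEFAULT_DRAW = 100_000


@dataclass
class BootstrapResult:
    """Point estimate, replicates and percentile CI for one statistic."""

    group: object
    statistic: str
    point: float
    replicates: np.ndarray = field(repr=False)
    ci_low: float
    ci_high: float
    n_rep: int
    n_draw: int
    alpha: float
    seed: object = None


@dataclass
class ContrastResult:
    """Percentile CI for the difference of one statistic between two groups."""

    pair: tuple[object, object]
    statistic: str
    point: float
    ci_low: float
    ci_high: float
    replicates: np.ndarray = field(repr=False, default=None)


def ci_percentile(replicates: np.ndarray, alpha: float = DEFAULT_ALPHA) -> tuple[float, float]:
    """Empirical alpha/2 and 1 - alpha/2 quantiles (linear interpolation).

    A constant replicate vector yields a zero-width interval.
    """
    reps = np.asarray(replicates, dtype=float)
    if reps.size < 2:
        raise ValueError("need at least two replicates for a percentile interval")
    if not np.isfinite(reps).all():
        raise ValueError("replicates contain non-finite values")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    lo, hi = np.quantile(reps, [alpha / 2.0, 1.0 - alpha / 2.0], method="linear")
    return float(lo), float(hi)


def bootstrap_stats(
    profile: GreenProfile,
    n_rep: int = DEFAULT_N_REP,
    n_draw: int | None = None,
    *,
    alpha: float = DEFAULT_ALPHA,
    seed: "int | np.random.Generator | None" = None,
) -> list[BootstrapResult]:
    """Bootstrap the five weighted statistics of one profile.

    Each replicate draws ``n_draw`` codes from Categorical(W), turns the
    draw counts into empirical weights, and evaluates all five statistics.
    Identical inputs and seed produce bit-identical replicates.
    """
    if n_rep < 1:
        raise ValueError(f"n_rep must be >= 1, got {n_rep}")
    if n_draw is None:
        n_draw = min(profile.total_pixels, MAX_DEFAULT_DRAW)
    if n_draw < 1:
        raise ValueError(f"n_draw must be >= 1, got {n_draw}")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = rng.multinomial(n_draw, profile.weights, size=n_rep)  # (n_rep, m)
    emp_w = counts / float(n_draw)

    ch = profile.channels()
    r, g, b = ch[:, 0], ch[:, 1], ch[:, 2]
    values = np.column_stack([r, g, b, r / g, b / g])  # (m, 5)
    reps = emp_w @ values  # (n_rep, 5)
    points = profile.weights @ values

    out = []
    for j, label in enumerate(STATISTIC_LABELS):
        lo, hi = ci_percentile(reps[:, j], alpha)
        out.append(
            BootstrapResult(
                group=profile.label,
                statistic=label,
                point=float(points[j]),
                replicates=reps[:, j].copy(),
                ci_low=lo,
                ci_high=hi,
                n_rep=n_rep,
                n_draw=n_draw,
                alpha=alpha,
                seed=seed if not isinstance(seed, np.random.Generator) else None,
            )
        )
    return out


def contrast(
    results_a: list[BootstrapResult],
    results_b: list[BootstrapResult],
    *,
    alpha: float | None = None,
) -> list[ContrastResult]:
    """Replicate-wise differences A - B with percentile CIs.

    The two groups must have been resampled independently with equal
    ``n_rep``; replicates are paired by index.  Reversing the arguments
    negates the point estimate and mirrors the interval.
    """
    by_stat_b = {res.statistic: res for res in results_b}
    out = []
    for res_a in results_a:
        if res_a.statistic not in by_stat_b:
            raise ValueError(f"statistic {res_a.statistic!r} missing from second group")
        res_b = by_stat_b[res_a.statistic]
        if res_a.n_rep != res_b.n_rep:
            raise ValueError(
                f"replicate counts differ ({res_a.n_rep} vs {res_b.n_rep}) for {res_a.statistic!r}"
            )
        a = alpha if alpha is not None else res_a.alpha
        diffs = res_a.replicates - res_b.replicates
        lo, hi = ci_percentile(diffs, a)
        out.append(
            ContrastResult(
                pair=(res_a.group, res_b.group),
                statistic=res_a.statistic,
                point=res_a.point - res_b.point,
                ci_low=lo,
                ci_high=hi,
                replicates=diffs,
            )
        )
    return out
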