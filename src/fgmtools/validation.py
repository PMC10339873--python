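"""Analytical assay validation: parallelism and spike-recovery accuracy.

Parallelism asks whether a serially diluted pool of fecal extracts displaces
antibody the way the standards do: both series are fit as straight lines in
(log10 dose, percent bound) over the quasi-linear region of the logistic,
and the slope difference is tested with an extra-sum-of-squares ANCOVA F
test (dose x series interaction in the two-line model, denominator
df = n_total - 4). The pool's 50%-binding dilution picks the working
dilution, subject to a 1:10 floor against solvent matrix interference.

Accuracy asks whether spiked standards are recovered 1:1 after subtracting
the known spike: ordinary least squares of observed on expected, accepted
at r^2 > 0.95 and slope within 0.8-1.2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy.stats import f as scipy_f

from .config import PipelineConfig

__all__ = [
    "ParallelismResult",
    "AccuracyResult",
    "parallelism_test",
    "accuracy_test",
    "choose_working_dilution",
]


@dataclass(frozen=True)
class ParallelismResult:
    standard_slope: float
    pool_slope: float
    f_statistic: float
    p_value: float
    parallel: bool  # p > alpha: slopes indistinguishable
    binding50_dilution: float | None  # dilution factor giving 50 %B, or None
    alpha: float = 0.05
    df_num: int = 1
    df_den: int = 0


@dataclass(frozen=True)
class AccuracyResult:
    slope: float
    intercept: float
    r_squared: float
    accepted: bool
    n: int = 0


def _line_fit(logdose: np.ndarray, pb: np.ndarray) -> float:
    """OLS slope of %B on log10 dose."""
    X = sm.add_constant(logdose)
    return float(sm.OLS(pb, X).fit().params[1])


def interpolate_binding50(
    pool: Sequence[tuple[float, float]]
) -> float | None:
    """Dilution factor at which the pool reaches 50 %B.

    Linear interpolation in (dilution factor, %B) between the two points
    bracketing 50% — e.g. 1:4 at 55 %B and 1:8 at 45 %B interpolate to 1:6.
    Returns None when all points sit on one side of 50%.
    """
    pts = sorted(((float(d), float(p)) for d, p in pool), key=lambda t: t[0])
    for (d0, p0), (d1, p1) in zip(pts, pts[1:]):
        if (p0 - 50.0) * (p1 - 50.0) <= 0:
            if p0 == p1:
                return (d0 + d1) / 2.0
            return d0 + (p0 - 50.0) / (p0 - p1) * (d1 - d0)
    return None


def parallelism_test(
    standards: Sequence[tuple[float, float]],
    pool: Sequence[tuple[float, float]],
    config: PipelineConfig | None = None,
    linear_region: tuple[float, float] | None = None,
) -> ParallelismResult:
    """Test slope equality of standards vs a serially diluted pool.

    Parameters
    ----------
    standards
        (concentration pg/mL, percent bound) points.
    pool
        (dilution factor, percent bound) points; the dose proxy is
        1/dilution (neat = 1), since only relative dose matters for slope
        comparison.
    """
    cfg = config or PipelineConfig()
    lo, hi = linear_region or cfg.linear_region_pb

    std = [(math.log10(x), pb) for x, pb in standards if lo <= pb <= hi]
    pl = [(math.log10(1.0 / d), pb) for d, pb in pool if lo <= pb <= hi]
    if len(std) < 3 or len(pl) < 3:
        raise ValueError(
            "need >= 3 points per series inside the linear region "
            f"({len(std)} standard, {len(pl)} pool)"
        )

    x = np.array([t[0] for t in std] + [t[0] for t in pl])
    y = np.array([t[1] for t in std] + [t[1] for t in pl])
    g = np.array([0.0] * len(std) + [1.0] * len(pl))  # series indicator

    # two-line model: y ~ 1 + x + g + x:g ; the interaction carries the
    # slope difference, tested by extra sum of squares with df = (1, n - 4)
    X_full = np.column_stack([np.ones_like(x), x, g, x * g])
    X_red = X_full[:, :3]  # common slope, separate intercepts
    sse_full = float(sm.OLS(y, X_full).fit().ssr)
    sse_red = float(sm.OLS(y, X_red).fit().ssr)
    df_den = len(x) - 4
    tss = float(np.sum((y - y.mean()) ** 2))
    if sse_full <= 1e-12 * max(tss, 1.0):
        # both lines fit exactly: no evidence of non-parallelism
        f_stat, p_val = 0.0, 1.0
    else:
        f_stat = max(sse_red - sse_full, 0.0) / (sse_full / df_den)
        p_val = float(scipy_f.sf(f_stat, 1, df_den))

    std_slope = _line_fit(np.array([t[0] for t in std]),
                          np.array([t[1] for t in std]))
    pool_slope = _line_fit(np.array([t[0] for t in pl]),
                           np.array([t[1] for t in pl]))
    return ParallelismResult(
        standard_slope=std_slope,
        pool_slope=pool_slope,
        f_statistic=f_stat,
        p_value=p_val,
        parallel=p_val > cfg.parallelism_alpha,
        binding50_dilution=interpolate_binding50(pool),
        alpha=cfg.parallelism_alpha,
        df_num=1,
        df_den=df_den,
    )


def accuracy_test(
    expected: Sequence[float],
    observed: Sequence[float],
    config: PipelineConfig | None = None,
) -> AccuracyResult:
    """Spike-recovery regression: OLS of observed on expected concentration.

    ``expected`` are the standard concentrations after subtracting the known
    spike contribution; acceptance requires r^2 > 0.95 and a slope in the
    0.8-1.2 band.
    """
    cfg = config or PipelineConfig()
    x = np.asarray(expected, dtype=float)
    y = np.asarray(observed, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("expected/observed must be equal-length, n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("expected concentrations have zero variance")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    slope = float(fit.params[1])
    intercept = float(fit.params[0])
    r2 = float(fit.rsquared)
    lo, hi = cfg.accuracy_slope_band
    accepted = (r2 > cfg.accuracy_r2_min) and (lo <= slope <= hi)
    return AccuracyResult(
        slope=slope, intercept=intercept, r_squared=r2,
        accepted=accepted, n=int(x.size),
    )


def choose_working_dilution(
    result: ParallelismResult,
    floor: float = 10.0,
    override: float | None = None,
) -> float:
    """Working dilution = the 50%-binding dilution, not below the floor.

    The floor (default 1:10) guards against methanol matrix interference;
    a pool binding 50% at 1:6 is therefore run at 1:10, while one at 1:30
    keeps its 1:30.
    """
    b50 = override if override is not None else result.binding50_dilution
    if b50 is None:
        raise ValueError("no 50%-binding dilution available and no override")
    return max(float(b50), float(floor))
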