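"""Four-parameter logistic (4PL) standard curves.

The competitive-assay dose-response model is

    y(x) = d + (a - d) / (1 + (x / c)^b)

with ``a`` the response at zero dose, ``d`` the response at infinite dose,
``c`` the inflection concentration (EC50, pg/mL) and ``b`` the slope
factor. In a competitive EIA the response falls with dose (a > d, b > 0).
Fitting is unweighted least squares on duplicate-mean percent bound;
back-calculation uses the closed-form inverse

    x(y) = c * ((a - d) / (y - d) - 1)^(1/b).
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "FourPLParams",
    "StandardCurve",
    "CurveFitError",
    "CurveRangeError",
    "RangeSide",
    "four_pl",
    "fit_4pl",
    "inverse_4pl",
]


class CurveFitError(RuntimeError):
    """4PL fit did not converge; carries the initializer and a data summary."""


class RangeSide(str, enum.Enum):
    ABOVE_CURVE = "ABOVE_CURVE"  # response beyond the high-dose asymptote side
    BELOW_CURVE = "BELOW_CURVE"  # response beyond the zero-dose asymptote side


class CurveRangeError(ValueError):
    """Response cannot be inverted; ``side`` says which asymptote was crossed."""

    def __init__(self, side: RangeSide, message: str):
        super().__init__(message)
        self.side = side


def four_pl(x, a: float, b: float, c: float, d: float):
    """4PL response y(x) = d + (a - d) / (1 + (x/c)^b); vectorized in x."""
    x = np.asarray(x, dtype=float)
    return d + (a - d) / (1.0 + (x / c) ** b)


@dataclass(frozen=True)
class FourPLParams:
    """Fitted 4PL coefficients (see module docstring for the model)."""

    a: float  # response at zero dose
    b: float  # slope factor
    c: float  # inflection concentration, pg/mL
    d: float  # response at infinite dose

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError(f"inflection concentration c must be > 0, got {self.c}")
        if self.a == self.d:
            raise ValueError("degenerate 4PL: a == d")

    def response(self, x) -> np.ndarray | float:
        return four_pl(x, self.a, self.b, self.c, self.d)

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class StandardCurve:
    """A fitted standard curve for one plate, with its calibrated dose range."""

    params: FourPLParams
    residual_sse: float
    range_low: float  # lowest standard, pg/mL
    range_high: float  # highest standard, pg/mL
    plate_id: str = ""

    def __post_init__(self) -> None:
        if not self.range_low < self.range_high:
            raise ValueError("range_low must be < range_high")
        if not math.isfinite(self.residual_sse):
            raise ValueError("fit residuals not finite")

    def to_json(self, path: str) -> None:
        """Audit sidecar: curve parameters and diagnostics for one plate."""
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "plate_id": self.plate_id,
                    "a": self.params.a,
                    "b": self.params.b,
                    "c": self.params.c,
                    "d": self.params.d,
                    "residual_sse": self.residual_sse,
                    "range_low_pg_ml": self.range_low,
                    "range_high_pg_ml": self.range_high,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path: str) -> "StandardCurve":
        with open(path, "r", encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(
            params=FourPLParams(a=d["a"], b=d["b"], c=d["c"], d=d["d"]),
            residual_sse=d["residual_sse"],
            range_low=d["range_low_pg_ml"],
            range_high=d["range_high_pg_ml"],
            plate_id=d.get("plate_id", ""),
        )


# fallback initializer grid tried in order when the default start fails
_FALLBACK_B = (0.5, 1.0, 2.0)
_FALLBACK_C_SCALE = (0.2, 1.0, 5.0)


def fit_4pl(
    standards: Sequence[tuple[float, float]],
    plate_id: str = "",
    asymptotes: str = "percent_bound",
) -> StandardCurve:
    """Least-squares 4PL fit to (concentration pg/mL, response) points.

    With ``asymptotes="percent_bound"`` (the default, matching curves fit on
    duplicate-mean %B/B0), the asymptotes are fixed at their definitional
    values a = 100 (zero dose binds maximally) and d = 0 (infinite dose
    displaces all antibody) and only (b, c) are estimated — the classical
    constrained B/B0 fit, which stabilises the EC50 on short standard
    ladders. ``asymptotes="free"`` estimates all four parameters (for
    OD-space or otherwise un-normalised responses).

    Deterministic: starts from a = max response, d = min response,
    c = geometric mean of doses, b = 1, with a fixed fallback grid if the
    first attempt fails. Requires >= 4 distinct concentrations.
    """
    if asymptotes not in ("percent_bound", "free"):
        raise ValueError("asymptotes must be 'percent_bound' or 'free'")
    pts = [(float(x), float(y)) for x, y in standards]
    if any(x <= 0 for x, _ in pts):
        raise ValueError("standard concentrations must be positive")
    if any(not math.isfinite(y) for _, y in pts):
        raise ValueError("responses must be finite")
    doses = sorted({x for x, _ in pts})
    if len(doses) < 4:
        raise ValueError(
            f"4PL fit needs >= 4 distinct concentrations, got {len(doses)}"
        )
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])

    a0, d0 = float(y.max()), float(y.min())
    c0 = float(np.exp(np.mean(np.log(x))))
    starts = [(a0, 1.0, c0, d0)]
    starts += [
        (a0, b0, c0 * s, d0) for b0 in _FALLBACK_B for s in _FALLBACK_C_SCALE
    ]

    last_err: Exception | None = None
    for a_s, b_s, c_s, d_s in starts:
        try:
            if asymptotes == "percent_bound":
                model = lambda xx, b, c: four_pl(xx, 100.0, b, c, 0.0)  # noqa: E731
                popt, _ = curve_fit(
                    model, x, y, p0=(b_s, c_s),
                    bounds=([1e-6, 1e-12], np.inf), maxfev=20000,
                )
                popt = (100.0, popt[0], popt[1], 0.0)
            else:
                popt, _ = curve_fit(
                    four_pl, x, y, p0=(a_s, b_s, c_s, d_s),
                    bounds=([-np.inf, 1e-6, 1e-12, -np.inf], np.inf),
                    maxfev=20000,
                )
        except (RuntimeError, ValueError) as err:  # non-convergence
            last_err = err
            continue
        params = FourPLParams(a=float(popt[0]), b=float(popt[1]),
                              c=float(popt[2]), d=float(popt[3]))
        sse = float(np.sum((np.asarray(params.response(x)) - y) ** 2))
        return StandardCurve(
            params=params,
            residual_sse=sse,
            range_low=doses[0],
            range_high=doses[-1],
            plate_id=plate_id,
        )
    raise CurveFitError(
        f"4PL fit failed for plate {plate_id!r}: start={starts[0]}, "
        f"n={len(pts)}, dose range [{doses[0]}, {doses[-1]}], "
        f"response range [{y.min():.4g}, {y.max():.4g}]: {last_err}"
    )


def inverse_4pl(response: float, curve: StandardCurve) -> float:
    """Back-calculate concentration (pg/mL) from a response on the curve.

    Valid only for responses strictly between the two asymptotes; outside
    that band raises :class:`CurveRangeError` whose ``side`` distinguishes
    ABOVE_CURVE (past the high-dose asymptote, i.e. more concentrated than
    the curve can resolve) from BELOW_CURVE.
    """
    p = curve.params
    lo, hi = min(p.a, p.d), max(p.a, p.d)
    # orientation: which asymptote corresponds to infinite dose
    falling = (p.a > p.d) == (p.b > 0)
    if not (lo < response < hi):
        if response >= hi:
            side = RangeSide.BELOW_CURVE if falling else RangeSide.ABOVE_CURVE
        else:
            side = RangeSide.ABOVE_CURVE if falling else RangeSide.BELOW_CURVE
        raise CurveRangeError(
            side,
            f"response {response:.4g} outside open asymptote band "
            f"({lo:.4g}, {hi:.4g}): {side.value}",
        )
    ratio = (p.a - p.d) / (response - p.d) - 1.0
    return p.c * ratio ** (1.0 / p.b)
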