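"""Exposure–response functions: tabulated spline curves and the GEMM family.

Two risk models are supported.  Tabulated curves (:class:`TabulatedERF`)
represent meta-regression spline output as knot tables with central / low /
high branches carrying the 95% interval; the Global Exposure Mortality Model
(:class:`GEMMParams`) is the parametric logistic-log family

    RR(z) = exp( θ · log(1 + z/α) · ω(z) ),   ω(z) = 1 / (1 + exp(−(z − μ)/ν))

with z the concentration excess over the counterfactual.  Both are anchored so
that RR = 1 at and below the theoretical minimum risk exposure level (TMREL),
4.15 μg/m³ by default: no excess risk is assumed below it.

The attributable fraction AF = (RR − 1)/RR converts relative risk into the
share of baseline deaths attributable to the exposure.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .grids import AGE_CLASSES

#: Default theoretical minimum risk exposure level (μg/m³).
DEFAULT_TMREL = 4.15

BRANCHES: tuple[str, ...] = ("central", "low", "high")

#: Sentinel age-group label for curves that apply to every adult age class.
ALL_AGES = "ALL"


class Cause(str, Enum):
    """The six adult causes of death with quantified PM2.5 risk."""

    IHD = "IHD"          # ischemic heart disease
    STROKE = "STROKE"
    COPD = "COPD"        # chronic obstructive pulmonary disease
    LC = "LC"            # lung cancer
    LRI = "LRI"          # lower respiratory infections
    T2D = "T2D"          # type II diabetes

    @property
    def age_dependent(self) -> bool:
        """Whether the relative risk varies with age (cardiovascular causes)."""
        return self in (Cause.IHD, Cause.STROKE)


CAUSES: tuple[Cause, ...] = tuple(Cause)


class CurveError(ValueError):
    """A curve violates the ERF contract (ordering, positivity, anchoring)."""


class CoverageError(KeyError):
    """A required (country, cause, age-group) entry is missing."""


@dataclass(frozen=True)
class TabulatedERF:
    """Relative-risk curve tabulated at concentration knots.

    ``rr_central``, ``rr_low`` and ``rr_high`` are evaluated at ``knots``
    (μg/m³, strictly ascending).  Between knots RR is linear in concentration;
    beyond the last knot it is constant.  After TMREL scaling every branch
    equals exactly 1 on [0, tmrel].
    """

    cause: Cause
    age_group: str  # one of AGE_CLASSES or ALL_AGES
    knots: np.ndarray
    rr_central: np.ndarray
    rr_low: np.ndarray
    rr_high: np.ndarray
    tmrel: float = DEFAULT_TMREL
    scaled: bool = False

    def __post_init__(self) -> None:
        for name in ("knots", "rr_central", "rr_low", "rr_high"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.shape != self.knots.shape:
                raise CurveError(f"{name} length does not match knots")
        if self.age_group != ALL_AGES and self.age_group not in AGE_CLASSES:
            raise CurveError(f"unknown age group {self.age_group!r}")
        if np.any(np.diff(self.knots) <= 0):
            raise CurveError("knots must be strictly ascending")
        if self.knots[0] > self.tmrel:
            raise CurveError("first knot must not exceed the TMREL")
        if np.any(self.rr_low > self.rr_central) or np.any(self.rr_central > self.rr_high):
            raise CurveError("branches must satisfy low <= central <= high at every knot")
        for name in ("rr_central", "rr_low", "rr_high"):
            branch = getattr(self, name)
            if np.any(branch <= 0):
                raise CurveError(f"{name} must be positive")
            if np.any(np.diff(branch) < 0):
                raise CurveError(f"{name} must be non-decreasing in concentration")
        if self.scaled and np.any(self.rr_low < 1.0 - 1e-12):
            raise CurveError("scaled curves must have RR >= 1 everywhere")

    def _branch(self, branch: str) -> np.ndarray:
        try:
            return {"central": self.rr_central, "low": self.rr_low,
                    "high": self.rr_high}[branch]
        except KeyError:
            raise ValueError(f"unknown branch {branch!r}") from None


def scale_to_tmrel(raw: TabulatedERF) -> TabulatedERF:
    """Anchor each branch of a raw curve to RR = 1 at the TMREL.

    Each branch is divided by its own (linearly interpolated) value at
    ``raw.tmrel``, and the curve below the TMREL is pinned to exactly 1:
    concentrations in [0, tmrel] carry no excess risk.
    """
    scaled: dict[str, np.ndarray] = {}
    for name in ("rr_central", "rr_low", "rr_high"):
        branch = getattr(raw, name)
        anchor = float(np.interp(raw.tmrel, raw.knots, branch))
        if anchor <= 0:
            raise CurveError(f"{name} is non-positive at the TMREL")
        vals = branch / anchor
        vals = np.where(raw.knots <= raw.tmrel, 1.0, np.maximum(vals, 1.0))
        scaled[name] = vals
    return replace(raw, scaled=True, **scaled)


def evaluate_rr(
    erf: TabulatedERF, conc: float | np.ndarray, branch: str = "central"
) -> float | np.ndarray:
    """Relative risk at a concentration, from a TMREL-scaled tabulated curve.

    Piecewise-linear between knots, constant beyond the last knot, and exactly
    1 for concentrations at or below the TMREL.
    """
    if not erf.scaled:
        raise CurveError("curve must be TMREL-scaled before evaluation")
    vals = erf._branch(branch)
    conc_arr = np.asarray(conc, dtype=float)
    rr = np.interp(conc_arr, erf.knots, vals)  # np.interp clamps at both ends
    rr = np.where(conc_arr <= erf.tmrel, 1.0, rr)
    return float(rr) if np.isscalar(conc) or conc_arr.ndim == 0 else rr


@dataclass(frozen=True)
class GEMMParams:
    """Parameters of one GEMM curve.

    theta (and its standard error) set the log-risk scale; alpha (μg/m³)
    controls low-concentration curvature; mu and nu (μg/m³) place and widen
    the logistic weighting; counterfactual is the zero-excess concentration.
    """

    cause: Cause
    age_group: str = ALL_AGES
    theta: float = 0.1430
    theta_se: float = 0.01807
    alpha: float = 1.6
    mu: float = 15.5
    nu: float = 36.8
    counterfactual: float = DEFAULT_TMREL

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.nu <= 0:
            raise CurveError("alpha and nu must be positive")
        if self.theta < 0:
            raise CurveError("theta must be non-negative")


def gemm_rr(
    p: GEMMParams, conc: float | np.ndarray, branch: str = "central"
) -> float | np.ndarray:
    """Relative risk from the GEMM logistic-log form.

    ``z = max(0, conc − counterfactual)``; low/high branches replace θ with
    θ ∓ 1.96·θ_se.  RR(z = 0) = 1 exactly.
    """
    if branch == "central":
        theta = p.theta
    elif branch == "low":
        theta = p.theta - 1.96 * p.theta_se
    elif branch == "high":
        theta = p.theta + 1.96 * p.theta_se
    else:
        raise ValueError(f"unknown branch {branch!r}")
    conc_arr = np.asarray(conc, dtype=float)
    z = np.maximum(0.0, conc_arr - p.counterfactual)
    omega = 1.0 / (1.0 + np.exp(-(z - p.mu) / p.nu))
    rr = np.exp(theta * np.log1p(z / p.alpha) * omega)
    return float(rr) if np.isscalar(conc) or conc_arr.ndim == 0 else rr


def attributable_fraction(rr: float | np.ndarray) -> float | np.ndarray:
    """Attributable fraction AF = (RR − 1)/RR, in [0, 1) for RR ≥ 1."""
    rr_arr = np.asarray(rr, dtype=float)
    if np.any(rr_arr < 1.0):
        raise ValueError("attributable fraction requires RR >= 1")
    af = (rr_arr - 1.0) / rr_arr
    return float(af) if np.isscalar(rr) or rr_arr.ndim == 0 else af


class CurveSet:
    """Lookup of TMREL-scaled curves by (cause, age group).

    Age-dependent causes (IHD, stroke) need one curve per age class;
    the other causes may use a single ``ALL`` curve applied to every class.
    """

    def __init__(self, curves: Iterable[TabulatedERF]):
        self._curves: dict[tuple[Cause, str], TabulatedERF] = {}
        for c in curves:
            erf = c if c.scaled else scale_to_tmrel(c)
            self._curves[(erf.cause, erf.age_group)] = erf

    def lookup(self, cause: Cause, age_group: str) -> TabulatedERF:
        for key in ((cause, age_group), (cause, ALL_AGES)):
            if key in self._curves:
                return self._curves[key]
        raise CoverageError(f"no curve for cause {cause.value}, age group {age_group}")

    def validate_coverage(self) -> None:
        """Raise :class:`CoverageError` naming the first missing pair."""
        for cause in CAUSES:
            for age in AGE_CLASSES:
                self.lookup(cause, age)

    def __iter__(self):
        return iter(self._curves.values())

    def __len__(self) -> int:
        return len(self._curves)


def curves_from_frame(df: pd.DataFrame, tmrel: float = DEFAULT_TMREL) -> CurveSet:
    """Build a curve set from a long table.

    Expected columns: cause, age_group, conc, rr_central, rr_low, rr_high
    (the curve-table CSV layout).
    """
    curves = []
    for (cause, age), grp in df.groupby(["cause", "age_group"], sort=True):
        grp = grp.sort_values("conc")
        curves.append(TabulatedERF(
            cause=Cause(cause), age_group=str(age),
            knots=grp["conc"].to_numpy(),
            rr_central=grp["rr_central"].to_numpy(),
            rr_low=grp["rr_low"].to_numpy(),
            rr_high=grp["rr_high"].to_numpy(),
            tmrel=tmrel,
        ))
    return CurveSet(curves)


def curves_to_frame(curves: CurveSet) -> pd.DataFrame:
    """Inverse of :func:`curves_from_frame` (full precision)."""
    rows = []
    for erf in curves:
        for i, c in enumerate(erf.knots):
            rows.append({
                "cause": erf.cause.value, "age_group": erf.age_group, "conc": c,
                "rr_central": erf.rr_central[i], "rr_low": erf.rr_low[i],
                "rr_high": erf.rr_high[i],
            })
    return pd.DataFrame(rows)


def gemm_curve_set(
    params: Mapping[Cause, GEMMParams] | Iterable[GEMMParams],
    knots: np.ndarray | None = None,
) -> CurveSet:
    """Tabulate GEMM curves onto knots so the mortality engine can use them.

    A dense knot grid (default 0.25 μg/m³ steps to 300) keeps the linear
    interpolation error far below the risk-model uncertainty.
    """
    if knots is None:
        knots = np.arange(0.0, 300.25, 0.25)
    if isinstance(params, Mapping):
        params = params.values()
    curves = []
    for p in params:
        rr = {b: np.asarray(gemm_rr(p, knots, b)) for b in BRANCHES}
        # Guard against theta - 1.96 se < 0 producing RR < 1 on the low branch.
        for b in BRANCHES:
            rr[b] = np.maximum(rr[b], 1.0)
        curves.append(TabulatedERF(
            cause=p.cause, age_group=p.age_group, knots=knots,
            rr_central=rr["central"], rr_low=np.minimum(rr["low"], rr["central"]),
            rr_high=np.maximum(rr["high"], rr["central"]),
            tmrel=p.counterfactual, scaled=True,
        ))
    return CurveSet(curves)
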