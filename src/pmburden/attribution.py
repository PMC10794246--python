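"""Source attribution: carbonaceous-aerosol shares, scenario differencing,
toxicity weighting and the linearity diagnostic.

The carbonaceous contribution is the total-PM2.5 excess mortality times the
cell-wise mass fraction aCA/PM2.5.  Under the two-fold-toxicity assumption the
fraction is doubled (capped at 1) while total PM2.5 mortality is held
constant — carbonaceous particles are weighted as twice as toxic per unit
mass, not re-run through the risk curves at inflated concentrations.

A sector's contribution to mortality is estimated by zero-out differencing:
BASE minus the scenario with that sector's emissions removed.  Because
atmospheric chemistry is not exactly linear in emissions, the linearity
diagnostic compares five times the 20%-reduction concentration response with
the 100%-removal response; a ratio of 1 everywhere means the response is
linear and the differencing attribution is exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import NamedTuple

import numpy as np
import pandas as pd

from .grids import ConcentrationField, GridAlignmentError, GridSpec, aca_fraction
from .mortality import MortalityResult


@dataclass(frozen=True)
class ToxicityAssumption:
    """Multiplier on the aCA mass fraction: 1 = equal toxicity, 2 = two-fold."""

    factor: float = 1.0

    def __post_init__(self) -> None:
        if not self.factor > 0:
            raise ValueError("toxicity factor must be positive")


EQUAL_TOXICITY = ToxicityAssumption(1.0)
TWOFOLD_TOXICITY = ToxicityAssumption(2.0)


@dataclass
class ScenarioSet:
    """Named scenarios, each holding a PM2.5 and an aCA concentration field."""

    fields: dict[str, dict[str, ConcentrationField]]

    def __post_init__(self) -> None:
        if "BASE" not in self.fields:
            raise ValueError("a ScenarioSet requires the BASE scenario")
        grids = {f.grid for per in self.fields.values() for f in per.values()}
        if len(grids) > 1:
            raise GridAlignmentError("all scenario fields must share one GridSpec")
        for label, per in self.fields.items():
            if set(per) != {"PM25", "ACA"}:
                raise ValueError(f"scenario {label!r} must hold PM25 and ACA fields")

    @property
    def grid(self) -> GridSpec:
        return self.fields["BASE"]["PM25"].grid

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.fields)

    def pm25(self, label: str) -> ConcentrationField:
        return self.fields[label]["PM25"]

    def aca(self, label: str) -> ConcentrationField:
        return self.fields[label]["ACA"]


def aca_attribution(
    m: MortalityResult,
    aca: ConcentrationField,
    pm: ConcentrationField,
    tox: ToxicityAssumption = EQUAL_TOXICITY,
) -> MortalityResult:
    """Carbonaceous-aerosol share of a PM2.5 mortality result.

    Per cell and stratum: ``M_aCA = M_PM2.5 × min(1, factor × aCA/PM2.5)``.
    With factor 1 this is the plain mass-fraction attribution; the cap keeps
    the attributed deaths within the total under any factor.
    """
    if m.grid != aca.grid or m.grid != pm.grid:
        raise GridAlignmentError("mortality and concentration grids differ")
    if aca.scenario != m.scenario or pm.scenario != m.scenario:
        raise GridAlignmentError(
            f"scenario mismatch: mortality {m.scenario!r}, "
            f"aCA {aca.scenario!r}, PM2.5 {pm.scenario!r}"
        )
    weight = np.minimum(1.0, tox.factor * aca_fraction(aca, pm))
    return MortalityResult(grid=m.grid, scenario=m.scenario,
                           values=m.values * weight)


class SectorContribution(NamedTuple):
    """Element-wise BASE − scenario difference plus a negativity diagnostic.

    ``values`` mirrors the input shape (ndarray, DataFrame or scalar);
    ``n_negative`` counts entries pushed negative by nonlinear chemistry —
    they are retained, not clipped.
    """

    values: object
    n_negative: int


def sector_contribution(m_base, m_scen) -> SectorContribution:
    """Avoidable mortality attributable to a sector: BASE − scenario.

    Accepts matching :class:`MortalityResult` objects (difference per cell and
    stratum, returned as an ndarray), aligned DataFrames with a ``deaths``
    column, ndarrays, or plain totals.
    """
    if isinstance(m_base, MortalityResult) and isinstance(m_scen, MortalityResult):
        if m_base.grid != m_scen.grid:
            raise GridAlignmentError("mortality results are on different grids")
        diff = m_base.values - m_scen.values
        return SectorContribution(diff, int(np.sum(diff < 0)))
    if isinstance(m_base, pd.DataFrame) and isinstance(m_scen, pd.DataFrame):
        keys = [c for c in m_base.columns if c != "deaths"]
        if list(m_base.columns) != list(m_scen.columns):
            raise GridAlignmentError("aggregate tables have different columns")
        left = m_base.set_index(keys)["deaths"] if keys else m_base["deaths"]
        right = m_scen.set_index(keys)["deaths"] if keys else m_scen["deaths"]
        if len(left) != len(right) or (keys and not left.index.equals(right.index)):
            raise GridAlignmentError("aggregate tables are not aligned")
        diff = (left - right).reset_index(name="deaths") if keys else \
            pd.DataFrame({"deaths": left - right})
        return SectorContribution(diff, int((diff["deaths"] < 0).sum()))
    a, b = np.asarray(m_base, dtype=float), np.asarray(m_scen, dtype=float)
    if a.shape != b.shape:
        raise GridAlignmentError(f"shape mismatch {a.shape} vs {b.shape}")
    diff = a - b
    if diff.ndim == 0:
        return SectorContribution(float(diff), int(diff < 0))
    return SectorContribution(diff, int(np.sum(diff < 0)))


def share_percent(part: float, whole: float, decimals: int = 0) -> float:
    """Percentage 100·part/whole, rounded half-away-from-zero to ``decimals``."""
    if whole <= 0:
        raise ValueError("whole must be positive")
    if part < 0:
        raise ValueError("part must be non-negative")
    pct = Decimal(100 * part) / Decimal(whole)
    q = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class LinearityDiagnostic:
    """Per-cell linearity ratio and its domain summary.

    ``ratio`` is 5·(BASE − scen20)/(BASE − scen100) with NaN where the
    100%-removal response is below ``epsilon``; ``mean_ratio`` is the
    unweighted mean over valid cells.  A mean of 1 means the concentration
    response scales linearly with the emission reduction.
    """

    ratio: np.ndarray
    mean_ratio: float
    n_valid: int
    n_excluded: int
    epsilon: float


def linearity_diagnostic(
    base: ConcentrationField,
    scen100: ConcentrationField,
    scen20: ConcentrationField,
    epsilon: float = 0.01,
) -> LinearityDiagnostic:
    """Check that 5× the 20%-reduction response matches full removal."""
    if base.grid != scen100.grid or base.grid != scen20.grid:
        raise GridAlignmentError("scenario fields are on different grids")
    full = base.values - scen100.values
    partial = base.values - scen20.values
    valid = np.abs(full) > epsilon
    ratio = np.full(base.grid.shape, np.nan)
    ratio[valid] = 5.0 * partial[valid] / full[valid]
    n_valid = int(valid.sum())
    mean = float(np.nanmean(ratio)) if n_valid else float("nan")
    return LinearityDiagnostic(
        ratio=ratio, mean_ratio=mean, n_valid=n_valid,
        n_excluded=int((~valid).sum()), epsilon=epsilon,
    )
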