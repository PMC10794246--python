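"""Gridded, cause- and age-stratified excess mortality.

Per grid cell, the excess deaths attributable to ambient PM2.5 are

    M(x, y) = Σ_{j,k}  BMR(country(x,y), j, k) · POP(x,y, k) · AF(RR_j,k(c(x,y)))

summed over causes j and adult age classes k, with AF = (RR − 1)/RR and RR
evaluated from the (cause, age) exposure–response curve at the cell's
annual-mean concentration c.  Baseline mortality rates are country-level
(deaths · person⁻¹ · yr⁻¹) broadcast to cells via the country mask; cells
outside the mask contribute zero regardless of concentration.  The three
uncertainty branches propagate the curves' 95% bounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .grids import (
    AGE_CLASSES,
    ConcentrationField,
    CountryMask,
    GridAlignmentError,
    GridSpec,
    PopulationGrid,
)
from .risk import (
    BRANCHES,
    CAUSES,
    Cause,
    CoverageError,
    CurveSet,
    attributable_fraction,
    evaluate_rr,
)


@dataclass
class BaselineMortalityTable:
    """Country × cause × age-class baseline mortality rates.

    Rates are deaths per person per year.  The table must be complete over
    ``countries`` × 6 causes × 12 age classes.
    """

    frame: pd.DataFrame  # columns: country, cause, age_group, rate

    def __post_init__(self) -> None:
        required = {"country", "cause", "age_group", "rate"}
        if not required.issubset(self.frame.columns):
            raise ValueError(f"BMR table needs columns {sorted(required)}")
        if (self.frame["rate"] < 0).any():
            raise ValueError("baseline mortality rates must be non-negative")
        self._lut = self.frame.set_index(["country", "cause", "age_group"])["rate"]
        if self._lut.index.has_duplicates:
            raise ValueError("duplicate (country, cause, age_group) rows")

    @property
    def countries(self) -> tuple[str, ...]:
        return tuple(sorted(self.frame["country"].unique()))

    def rate(self, country: str, cause: Cause, age_group: str) -> float:
        try:
            return float(self._lut.loc[(country, cause.value, age_group)])
        except KeyError:
            raise CoverageError(
                f"missing baseline rate for ({country}, {cause.value}, {age_group})"
            ) from None

    def validate_coverage(self, countries: Iterable[str]) -> None:
        for country in countries:
            for cause in CAUSES:
                for age in AGE_CLASSES:
                    self.rate(country, cause, age)


@dataclass
class MortalityResult:
    """Excess deaths · yr⁻¹ per cell, stratified by cause × age × branch.

    ``values`` has shape (6 causes, 12 age classes, 3 branches, n_rows,
    n_cols) ordered as :data:`~pmburden.risk.CAUSES`, :data:`AGE_CLASSES`,
    :data:`~pmburden.risk.BRANCHES`.
    """

    grid: GridSpec
    scenario: str
    values: np.ndarray

    def __post_init__(self) -> None:
        expected = (len(CAUSES), len(AGE_CLASSES), len(BRANCHES), *self.grid.shape)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != expected:
            raise ValueError(f"values shape {self.values.shape} != {expected}")
        if np.any(self.values < 0):
            raise ValueError("excess deaths must be non-negative")

    def branch_index(self, branch: str) -> int:
        return BRANCHES.index(branch)

    def total(self, branch: str = "central") -> float:
        """Domain-total excess deaths per year for one uncertainty branch."""
        return float(self.values[:, :, self.branch_index(branch)].sum())

    def cell_totals(self, branch: str = "central") -> np.ndarray:
        """Per-cell excess deaths summed over causes and age classes."""
        return self.values[:, :, self.branch_index(branch)].sum(axis=(0, 1))


def gridded_excess_mortality(
    conc: ConcentrationField,
    pop: PopulationGrid,
    bmr: BaselineMortalityTable,
    erfs: CurveSet,
    mask: CountryMask,
) -> MortalityResult:
    """Evaluate the excess-mortality sum per cell, cause, age and branch.

    Raises
    ------
    CoverageError
        If a (country, cause, age) baseline rate or a (cause, age) curve is
        missing, naming the missing entry.
    GridAlignmentError
        If the inputs are not on one grid.
    """
    if conc.species != "PM25":
        raise GridAlignmentError("mortality is driven by the PM25 field")
    if any(g != conc.grid for g in (pop.grid, mask.grid)):
        raise GridAlignmentError("conc, pop and mask must share one GridSpec")

    countries = mask.countries
    bmr.validate_coverage(countries)
    erfs.validate_coverage()

    # Broadcast country-level BMR to cells: country index map per cell.
    code_index = {code: i for i, code in enumerate(countries)}
    idx_map = np.full(mask.grid.shape, -1, dtype=int)
    for code, i in code_index.items():
        idx_map[mask.values == code] = i
    in_domain = idx_map >= 0

    out = np.zeros((len(CAUSES), len(AGE_CLASSES), len(BRANCHES), *conc.grid.shape))
    for jc, cause in enumerate(CAUSES):
        for jk, age in enumerate(AGE_CLASSES):
            erf = erfs.lookup(cause, age)
            rates = np.array([bmr.rate(c, cause, age) for c in countries])
            rate_map = np.where(in_domain, rates[np.clip(idx_map, 0, None)], 0.0)
            base = rate_map * pop.values[jk]
            for jb, branch in enumerate(BRANCHES):
                rr = evaluate_rr(erf, conc.values, branch)
                out[jc, jk, jb] = base * attributable_fraction(rr)
    return MortalityResult(grid=conc.grid, scenario=conc.scenario, values=out)


def aggregate_mortality(
    m: MortalityResult,
    mask: CountryMask | None = None,
    by: Sequence[str] = (),
) -> pd.DataFrame:
    """Marginal sums of a mortality result.

    ``by`` is any subset of {"country", "cause", "age_group", "branch"};
    everything not retained is summed over (cells included).  The grand total
    is invariant under the choice of ``by``.  Aggregating by country requires
    the mask; out-of-mask cells are dropped (they are zero by construction).
    """
    valid = {"country", "cause", "age_group", "branch"}
    by = list(by)
    unknown = set(by) - valid
    if unknown:
        raise ValueError(f"unknown grouping keys {sorted(unknown)}")
    if "country" in by and mask is None:
        raise TypeError("grouping by country requires a CountryMask")
    if mask is not None and mask.grid != m.grid:
        raise GridAlignmentError("mask grid does not match result grid")

    rows = []
    if "country" in by:
        groups = [(code, mask.values == code) for code in mask.countries]
    else:
        groups = [(None, np.ones(m.grid.shape, dtype=bool))]

    for country, sel in groups:
        sub = m.values[:, :, :, sel]  # (cause, age, branch, cells)
        for jc, cause in enumerate(CAUSES):
            for jk, age in enumerate(AGE_CLASSES):
                for jb, branch in enumerate(BRANCHES):
                    rows.append({
                        "country": country, "cause": cause.value,
                        "age_group": age, "branch": branch,
                        "deaths": sub[jc, jk, jb].sum(),
                    })
    df = pd.DataFrame(rows)
    if not by:
        return pd.DataFrame({"deaths": [df["deaths"].sum()]})
    out = df.groupby(by, sort=True, as_index=False)["deaths"].sum()
    return out
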