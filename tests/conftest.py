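"""Shared fixtures: small synthetic studies and a brute-force mortality oracle.

The oracle evaluates the excess-mortality sum cell by cell with scalar
lookups — a literal triple loop over cells × causes × ages — and stays
independent of the vectorized engine it cross-checks.
"""

import numpy as np
import pytest

import pmburden as pb
from pmburden.grids import AGE_CLASSES, NO_COUNTRY
from pmburden.risk import BRANCHES, CAUSES


def brute_force_mortality(conc, pop, bmr, erfs, mask, branches=BRANCHES):
    """Literal per-cell evaluation of the excess-mortality sum."""
    out = np.zeros((len(CAUSES), len(AGE_CLASSES), len(branches), *conc.grid.shape))
    for i in range(conc.grid.n_rows):
        for j in range(conc.grid.n_cols):
            code = mask.values[i, j]
            if code == NO_COUNTRY:
                continue
            c = conc.values[i, j]
            for jc, cause in enumerate(CAUSES):
                for jk, age in enumerate(AGE_CLASSES):
                    erf = erfs.lookup(cause, age)
                    rate = bmr.rate(code, cause, age)
                    persons = pop.values[jk, i, j]
                    for jb, br in enumerate(branches):
                        rr = pb.evaluate_rr(erf, c, br)
                        out[jc, jk, jb, i, j] = (
                            rate * persons * pb.attributable_fraction(rr))
    return out


@pytest.fixture(scope="session")
def small_spec():
    """A 10×10 study small enough for brute-force cross-checks."""
    return pb.SyntheticSpec(
        grid=pb.GridSpec(n_rows=10, n_cols=10, cell_size=5.0),
        seed=7, n_countries=2, n_cities=3, population_total=2e6,
    )


@pytest.fixture(scope="session")
def small_study(small_spec):
    return pb.generate_study(small_spec)


@pytest.fixture(scope="session")
def study():
    """The default-size (60×60, 4-country) synthetic study."""
    return pb.generate_study(pb.SyntheticSpec(seed=11))


def single_cell_study(conc_value, rate, persons, rr_at_conc):
    """One land cell, one cause effectively active, a curve hitting a known RR.

    Returns (conc, pop, bmr, erfs, mask) where only the first age class is
    populated and only IHD has a nonzero baseline rate, so total deaths are
    rate × persons × AF(rr_at_conc).
    """
    import pandas as pd

    grid = pb.GridSpec(1, 1, 5.0)
    conc = pb.ConcentrationField(grid, "PM25", "BASE", np.array([[conc_value]]))
    pop_values = np.zeros((12, 1, 1))
    pop_values[0, 0, 0] = persons
    pop = pb.PopulationGrid(grid, pop_values)
    mask = pb.CountryMask(grid, np.array([["ZZ"]]))
    rows = [
        {"country": "ZZ", "cause": cause.value, "age_group": age,
         "rate": rate if cause is pb.Cause.IHD else 0.0}
        for cause in pb.CAUSES for age in AGE_CLASSES
    ]
    bmr = pb.BaselineMortalityTable(pd.DataFrame(rows))
    # Linear curve through (tmrel, 1) and (conc_value, rr_at_conc).
    curves = []
    for cause in pb.CAUSES:
        ages = AGE_CLASSES if cause.age_dependent else [pb.ALL_AGES]
        for age in ages:
            curves.append(pb.TabulatedERF(
                cause=cause, age_group=age,
                knots=np.array([0.0, 4.15, conc_value]),
                rr_central=np.array([1.0, 1.0, rr_at_conc]),
                rr_low=np.array([1.0, 1.0, rr_at_conc]),
                rr_high=np.array([1.0, 1.0, rr_at_conc]),
                scaled=True,
            ))
    return conc, pop, bmr, pb.CurveSet(curves), mask
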