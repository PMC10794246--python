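"""Synthetic study inputs with the statistical structure the pipeline assumes.

Real runs of this kind consume chemistry-transport model output (gridded
annual-mean PM2.5 and carbonaceous-aerosol concentrations per emission
scenario), gridded census population, and country-level baseline mortality
and risk-curve tables.  None of those are redistributable here, so this
module generates stand-ins that reproduce the features the pipeline relies
on:

* sector-additive, spatially smooth concentration surfaces (Gaussian kernel
  mixtures around sampled city locations, one correlation length per sector),
  with the carbonaceous mass a fixed per-sector share of the sector's PM2.5;
* a tunable nonlinearity γ that adds a symmetric sector cross-term, breaking
  the additivity that zero-out attribution assumes (γ = 0 is exactly linear);
* population clustered log-normally around the same cities and split across
  the 12 adult age classes with an old-skewed distribution;
* contiguous country blocks (Voronoi of random seed points) with a sea rim;
* baseline mortality rates rising with age within plausible per-cause ranges;
* monotone, supralinear (concave above the TMREL) relative-risk curves with
  ordered low/central/high branches.

Everything is deterministic given ``SyntheticSpec.seed``.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .attribution import ScenarioSet
from .grids import AGE_CLASSES, NO_COUNTRY, ConcentrationField, CountryMask, GridSpec, PopulationGrid
from .mortality import BaselineMortalityTable
from .risk import (
    ALL_AGES,
    CAUSES,
    DEFAULT_TMREL,
    Cause,
    CurveSet,
    GEMMParams,
    TabulatedERF,
    gemm_curve_set,
    scale_to_tmrel,
)

SECTORS: tuple[str, ...] = ("RES", "TRA", "OTHER", "BACKGROUND")

#: Standard scenario definitions: sector → fraction of emissions removed.
SCENARIO_REDUCTIONS: dict[str, dict[str, float]] = {
    "BASE": {},
    "RES100": {"RES": 1.0},
    "RES20": {"RES": 0.2},
    "TRA100": {"TRA": 1.0},
    "TRA20": {"TRA": 0.2},
}


@dataclass(frozen=True)
class SectorParams:
    """Amplitude (μg/m³), spatial correlation length (km) and aCA mass share."""

    amplitude: float
    correlation_length: float
    aca_mass_share: float

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if not 0 <= self.aca_mass_share <= 1:
            raise ValueError("aca_mass_share must lie in [0, 1]")


# Defaults sized so the BASE population-weighted PM2.5 per country lands in
# the 3–21 μg/m³ range typical of Europe, and the domain aCA/PM2.5 fraction
# in the few-percent-to-~20% range.  Carbonaceous shares are highest for
# residential combustion (wood/coal burning), lower for traffic exhaust,
# marginal for the regional background.
DEFAULT_SECTORS: dict[str, SectorParams] = {
    "RES": SectorParams(amplitude=7.0, correlation_length=45.0, aca_mass_share=0.45),
    "TRA": SectorParams(amplitude=4.5, correlation_length=35.0, aca_mass_share=0.25),
    "OTHER": SectorParams(amplitude=5.5, correlation_length=80.0, aca_mass_share=0.10),
    "BACKGROUND": SectorParams(amplitude=5.0, correlation_length=400.0, aca_mass_share=0.02),
}

#: Old-skewed split of the adult population over the 12 age classes (sums to 1).
AGE_SHARES: np.ndarray = np.array(
    [0.100, 0.100, 0.095, 0.090, 0.090, 0.090,
     0.085, 0.080, 0.075, 0.070, 0.060, 0.065]
)

#: Plausible adult all-age mean baseline rates (deaths/person/yr) per cause.
DEFAULT_BMR_RANGES: dict[Cause, tuple[float, float]] = {
    Cause.IHD: (1.5e-3, 4.0e-3),
    Cause.STROKE: (0.8e-3, 2.5e-3),
    Cause.COPD: (0.3e-3, 1.2e-3),
    Cause.LC: (0.4e-3, 1.0e-3),
    Cause.LRI: (0.1e-3, 0.5e-3),
    Cause.T2D: (0.1e-3, 0.6e-3),
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Everything needed to generate one reproducible synthetic study."""

    grid: GridSpec = GridSpec(n_rows=60, n_cols=60, cell_size=5.0)
    seed: int = 0
    n_countries: int = 4
    n_cities: int = 8
    sectors: Mapping[str, SectorParams] = field(
        default_factory=lambda: dict(DEFAULT_SECTORS))
    gamma: float = 0.0
    population_total: float = 40e6
    clustering_exponent: float = 1.5
    bmr_ranges: Mapping[Cause, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BMR_RANGES))
    erf_family: str = "tabulated"  # or "gemm"
    tmrel: float = DEFAULT_TMREL

    def __post_init__(self) -> None:
        if set(self.sectors) != set(SECTORS):
            raise ValueError(f"sectors must be exactly {SECTORS}")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        if self.n_countries < 1 or self.n_cities < 1:
            raise ValueError("need at least one country and one city")
        if self.erf_family not in ("tabulated", "gemm"):
            raise ValueError(f"unknown erf family {self.erf_family!r}")


def _rng(spec: SyntheticSpec, stream: str) -> np.random.Generator:
    """Independent, reproducible stream per artifact (order-insensitive)."""
    # crc32, not hash(): str hashing is salted per interpreter process.
    return np.random.default_rng([spec.seed, zlib.crc32(stream.encode())])


def _city_locations(spec: SyntheticSpec) -> np.ndarray:
    """City (x, y) positions, shared by concentration and population fields."""
    rng = _rng(spec, "cities")
    x0, x1, y0, y1 = (spec.grid.x[0], spec.grid.x[-1], spec.grid.y[0], spec.grid.y[-1])
    # Keep cities off the outer 10% rim so plumes stay inside the domain.
    mx, my = 0.1 * (x1 - x0), 0.1 * (y1 - y0)
    xs = rng.uniform(x0 + mx, x1 - mx, spec.n_cities)
    ys = rng.uniform(y0 + my, y1 - my, spec.n_cities)
    return np.column_stack([xs, ys])


def _kernel_surface(
    grid: GridSpec, centers: np.ndarray, weights: np.ndarray, length: float
) -> np.ndarray:
    """Normalized Gaussian kernel mixture; peak value 1."""
    yy, xx = np.meshgrid(grid.y, grid.x, indexing="ij")
    surf = np.zeros(grid.shape)
    for (cx, cy), w in zip(centers, weights):
        d2 = (xx - cx) ** 2 + (yy - cy) ** 2
        surf += w * np.exp(-d2 / (2.0 * length**2))
    peak = surf.max()
    return surf / peak if peak > 0 else surf


def generate_sector_fields(
    spec: SyntheticSpec,
) -> dict[str, dict[str, ConcentrationField]]:
    """Per-sector PM2.5 and aCA surfaces (scenario label ``SECTOR``).

    Each sector's PM2.5 is a smooth kernel mixture over the shared city set
    with that sector's correlation length, scaled to its amplitude; the
    sector's aCA is exactly ``aca_mass_share`` times its PM2.5.
    """
    cities = _city_locations(spec)
    out: dict[str, dict[str, ConcentrationField]] = {}
    for sector in SECTORS:
        params = spec.sectors[sector]
        rng = _rng(spec, f"sector:{sector}")
        weights = rng.uniform(0.3, 1.0, len(cities))
        surf = _kernel_surface(spec.grid, cities, weights, params.correlation_length)
        pm = params.amplitude * surf
        out[sector] = {
            "PM25": ConcentrationField(spec.grid, "PM25", sector, pm),
            "ACA": ConcentrationField(spec.grid, "ACA", sector,
                                      params.aca_mass_share * pm),
        }
    return out


def compose_scenario(
    sectors: Mapping[str, Mapping[str, ConcentrationField]],
    reductions: Mapping[str, float],
    gamma: float = 0.0,
    label: str | None = None,
) -> dict[str, ConcentrationField]:
    """Combine sector fields into one scenario's PM2.5 and aCA fields.

    PM2.5 is the background plus the emission-scaled anthropogenic sectors,
    plus ``gamma`` times a symmetric quadratic term (products of the scaled
    anthropogenic fields over unordered sector pairs, self-pairs included,
    normalized by the BASE term's domain maximum).  Self-pairs matter: pure
    cross products are linear in any one sector's emission scaling, so only
    the quadratic self-interaction makes a single-sector scenario response
    genuinely nonlinear — which is what the linearity diagnostic probes.
    γ = 0 gives exact linear composition, so BASE − RES100 equals the
    residential field identically.  aCA composes linearly from the
    per-sector carbonaceous masses; the quadratic term stands for secondary
    inorganic formation and carries no carbonaceous mass.
    """
    unknown = set(reductions) - set(sectors)
    if unknown:
        raise ValueError(f"reductions reference unknown sectors {sorted(unknown)}")
    for s, r in reductions.items():
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"reduction for {s} must lie in [0, 1], got {r}")

    grid = next(iter(sectors.values()))["PM25"].grid
    anthro = [s for s in sectors if s != "BACKGROUND"]
    scale = {s: 1.0 - reductions.get(s, 0.0) for s in sectors}

    pm = np.zeros(grid.shape)
    aca = np.zeros(grid.shape)
    if "BACKGROUND" in sectors:
        pm = pm + sectors["BACKGROUND"]["PM25"].values
        aca = aca + sectors["BACKGROUND"]["ACA"].values
    for s in anthro:
        pm = pm + scale[s] * sectors[s]["PM25"].values
        aca = aca + scale[s] * sectors[s]["ACA"].values

    if gamma > 0 and anthro:
        cross = np.zeros(grid.shape)
        base_cross = np.zeros(grid.shape)
        for i, s in enumerate(anthro):
            for t in anthro[i:]:
                fs, ft = sectors[s]["PM25"].values, sectors[t]["PM25"].values
                cross += (scale[s] * fs) * (scale[t] * ft)
                base_cross += fs * ft
        norm = base_cross.max()
        if norm > 0:
            pm = pm + gamma * cross / norm

    if label is None:
        label = _label_for_reductions(reductions)
    return {
        "PM25": ConcentrationField(grid, "PM25", label, pm),
        "ACA": ConcentrationField(grid, "ACA", label, aca),
    }


def _label_for_reductions(reductions: Mapping[str, float]) -> str:
    for name, red in SCENARIO_REDUCTIONS.items():
        if dict(red) == dict(reductions):
            return name
    return "+".join(f"{s}{int(100 * r)}" for s, r in sorted(reductions.items())) or "BASE"


def generate_scenario_set(spec: SyntheticSpec) -> ScenarioSet:
    """The five standard scenarios composed from one set of sector fields."""
    sectors = generate_sector_fields(spec)
    fields = {
        name: compose_scenario(sectors, red, spec.gamma, label=name)
        for name, red in SCENARIO_REDUCTIONS.items()
    }
    return ScenarioSet(fields)


def generate_population(spec: SyntheticSpec) -> PopulationGrid:
    """Log-normal population clustered near the cities, split by age class.

    The per-cell density is a city kernel surface raised to the clustering
    exponent times log-normal noise, normalized to the spec total and then
    rounded to whole persons per cell and class.
    """
    rng = _rng(spec, "population")
    cities = _city_locations(spec)
    weights = rng.uniform(0.5, 1.0, len(cities))
    surf = _kernel_surface(spec.grid, cities, weights, 30.0)
    # The additive floor keeps rural cells populated (no empty countries).
    density = (surf + 0.05) ** spec.clustering_exponent
    density *= rng.lognormal(mean=0.0, sigma=0.6, size=spec.grid.shape)
    density *= spec.population_total / density.sum()
    values = np.round(AGE_SHARES[:, None, None] * density[None, :, :])
    return PopulationGrid(grid=spec.grid, values=values)


def generate_country_mask(spec: SyntheticSpec) -> CountryMask:
    """Contiguous country blocks (Voronoi of seed points) with a sea rim."""
    rng = _rng(spec, "mask")
    codes = [_country_code(i) for i in range(spec.n_countries)]
    seeds_x = rng.uniform(spec.grid.x[0], spec.grid.x[-1], spec.n_countries)
    seeds_y = rng.uniform(spec.grid.y[0], spec.grid.y[-1], spec.n_countries)
    yy, xx = np.meshgrid(spec.grid.y, spec.grid.x, indexing="ij")
    d2 = (xx[..., None] - seeds_x) ** 2 + (yy[..., None] - seeds_y) ** 2
    nearest = np.argmin(d2, axis=-1)
    values = np.array(codes, dtype="U8")[nearest]
    rim = 2  # sea cells on the domain edge exercise the out-of-mask path
    if spec.grid.n_rows > 2 * rim and spec.grid.n_cols > 2 * rim:
        values[:rim, :] = NO_COUNTRY
        values[-rim:, :] = NO_COUNTRY
        values[:, :rim] = NO_COUNTRY
        values[:, -rim:] = NO_COUNTRY
    return CountryMask(grid=spec.grid, values=values, registry=tuple(codes))


def _country_code(i: int) -> str:
    return chr(ord("A") + i // 26) + chr(ord("A") + i % 26)


#: Relative age gradient: mortality rates roughly double per decade of age.
_AGE_GRADIENT = 2.0 ** (np.arange(len(AGE_CLASSES)) / 2.0)
_AGE_GRADIENT = _AGE_GRADIENT / _AGE_GRADIENT.mean()


def generate_bmr(spec: SyntheticSpec) -> BaselineMortalityTable:
    """Country × cause × age baseline rates within the per-cause ranges.

    Each country draws an all-age mean rate per cause uniformly from the
    cause's range; age-class rates follow a gradient that doubles every ten
    years of age (normalized to preserve the drawn mean).
    """
    rng = _rng(spec, "bmr")
    rows = []
    for i in range(spec.n_countries):
        country = _country_code(i)
        for cause in CAUSES:
            lo, hi = spec.bmr_ranges[cause]
            mean_rate = rng.uniform(lo, hi)
            for age, grad in zip(AGE_CLASSES, _AGE_GRADIENT):
                rows.append({"country": country, "cause": cause.value,
                             "age_group": age, "rate": mean_rate * grad})
    return BaselineMortalityTable(pd.DataFrame(rows))


#: Saturating-exponential RR amplitudes per cause (unitless excess at high
#: concentration) and e-folding scales (μg/m³), loosely echoing the relative
#: steepness of published curves: cardiovascular and respiratory causes rise
#: fastest at low concentrations.
_ERF_SHAPES: dict[Cause, tuple[float, float]] = {
    Cause.IHD: (0.55, 14.0),
    Cause.STROKE: (0.45, 14.0),
    Cause.COPD: (0.40, 16.0),
    Cause.LC: (0.35, 18.0),
    Cause.LRI: (0.45, 12.0),
    Cause.T2D: (0.35, 10.0),
}

_ERF_KNOTS = np.array(
    [0.0, 2.0, 4.15, 5.0, 6.0, 8.0, 10.0, 12.0, 15.0, 20.0, 25.0, 30.0,
     40.0, 60.0, 100.0]
)


def generate_erfs(spec: SyntheticSpec) -> CurveSet:
    """Monotone, concave (supralinear) TMREL-anchored curve set.

    Central curves are saturating exponentials in the excess concentration
    over the TMREL — steepest at low concentrations, as meta-analytic PM2.5
    curves are.  Low/high branches scale the excess risk by 0.75 / 1.30.  The
    age-dependent causes (IHD, stroke) get one curve per age class with risk
    attenuating at older ages; other causes one ALL-ages curve.
    """
    if spec.erf_family == "gemm":
        return gemm_curve_set(
            [replace(_DEFAULT_GEMM[c], counterfactual=spec.tmrel) for c in CAUSES]
        )
    rng = _rng(spec, "erfs")
    curves = []
    for cause in CAUSES:
        amp0, scale0 = _ERF_SHAPES[cause]
        amp0 *= rng.uniform(0.9, 1.1)
        scale0 *= rng.uniform(0.9, 1.1)
        if cause.age_dependent:
            for i, age in enumerate(AGE_CLASSES):
                amp = amp0 * (1.0 - 0.05 * i)  # excess risk attenuates with age
                curves.append(_saturating_curve(cause, age, amp, scale0, spec.tmrel))
        else:
            curves.append(_saturating_curve(cause, ALL_AGES, amp0, scale0, spec.tmrel))
    return CurveSet(curves)


def _saturating_curve(
    cause: Cause, age_group: str, amplitude: float, scale: float, tmrel: float
) -> TabulatedERF:
    excess = np.maximum(0.0, _ERF_KNOTS - tmrel)
    central = 1.0 + amplitude * (1.0 - np.exp(-excess / scale))
    raw = TabulatedERF(
        cause=cause, age_group=age_group, knots=_ERF_KNOTS,
        rr_central=central,
        rr_low=1.0 + 0.75 * (central - 1.0),
        rr_high=1.0 + 1.30 * (central - 1.0),
        tmrel=tmrel,
    )
    return scale_to_tmrel(raw)


_DEFAULT_GEMM: dict[Cause, GEMMParams] = {
    # NCD+LRI-like magnitude for the dominant cardiovascular cause, smaller
    # theta for the rest; synthetic stand-ins for sensitivity runs.
    Cause.IHD: GEMMParams(Cause.IHD, theta=0.2969, theta_se=0.01787,
                          alpha=1.9, mu=12.0, nu=40.2),
    Cause.STROKE: GEMMParams(Cause.STROKE, theta=0.2720, theta_se=0.07697,
                             alpha=6.2, mu=16.7, nu=23.7),
    Cause.COPD: GEMMParams(Cause.COPD, theta=0.2510, theta_se=0.06762,
                           alpha=6.5, mu=2.5, nu=32.0),
    Cause.LC: GEMMParams(Cause.LC, theta=0.2942, theta_se=0.06147,
                         alpha=6.2, mu=9.3, nu=29.8),
    Cause.LRI: GEMMParams(Cause.LRI, theta=0.4468, theta_se=0.11735,
                          alpha=6.4, mu=5.7, nu=8.4),
    Cause.T2D: GEMMParams(Cause.T2D, theta=0.1430, theta_se=0.01807,
                          alpha=1.6, mu=15.5, nu=36.8),
}


@dataclass
class SyntheticStudy:
    """A complete generated study: everything the pipeline consumes."""

    spec: SyntheticSpec
    scenarios: ScenarioSet
    population: PopulationGrid
    mask: CountryMask
    bmr: BaselineMortalityTable
    erfs: CurveSet


def generate_study(spec: SyntheticSpec) -> SyntheticStudy:
    """Generate all inputs for one synthetic study (deterministic in seed)."""
    return SyntheticStudy(
        spec=spec,
        scenarios=generate_scenario_set(spec),
        population=generate_population(spec),
        mask=generate_country_mask(spec),
        bmr=generate_bmr(spec),
        erfs=generate_erfs(spec),
    )
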