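"""End-to-end pipeline driver, run configuration and report rendering.

A run goes: load (or generate) inputs → regrid concentrations to the health
grid → population-weighted exposure summaries → gridded excess mortality per
scenario → carbonaceous attribution under each toxicity factor → scenario
differencing → linearity diagnostics → rendered report tables.  Stored
outputs keep full precision; the rounding profile applies only to rendered
reports (domain totals to the nearest thousand deaths, country rows to whole
deaths, percentages half-away-from-zero).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import io as pio
from .attribution import (
    LinearityDiagnostic,
    ScenarioSet,
    ToxicityAssumption,
    aca_attribution,
    linearity_diagnostic,
    sector_contribution,
    share_percent,
)
from .grids import (
    CountryMask,
    GridSpec,
    PopulationGrid,
    country_aggregate,
    population_weighted_mean,
    regrid_field,
)
from .mortality import (
    BaselineMortalityTable,
    MortalityResult,
    aggregate_mortality,
    gridded_excess_mortality,
)
from .risk import BRANCHES, DEFAULT_TMREL, CurveSet
from .synthetic import SyntheticSpec, SyntheticStudy, generate_study

logger = logging.getLogger(__name__)

SECTOR_SCENARIOS = ("RES100", "RES20", "TRA100", "TRA20")


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run.

    Either ``synthetic`` is set (inputs are generated) or ``inputs`` maps
    the on-disk paths: scenario label → {pm25, aca} NetCDF paths, plus
    population, mask, mask_codes, bmr and erf paths.
    """

    output_dir: Path = Path("out")
    synthetic: SyntheticSpec | None = None
    inputs: Mapping[str, object] | None = None
    tmrel: float = DEFAULT_TMREL
    risk_model: str = "MRBRT_TABULATED"  # or "GEMM"
    toxicity_factors: tuple[float, ...] = (1.0, 2.0)
    difference_scenarios: tuple[str, ...] = SECTOR_SCENARIOS
    linearity_epsilon: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tmrel <= 0:
            raise ValueError("tmrel must be positive")
        if self.risk_model not in ("MRBRT_TABULATED", "GEMM"):
            raise ValueError(f"unknown risk model {self.risk_model!r}")
        if self.synthetic is None and self.inputs is None:
            self.synthetic = SyntheticSpec(seed=self.seed)
        self.output_dir = Path(self.output_dir)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw, base_dir=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base_dir: Path = Path(".")) -> "RunConfig":
        kwargs: dict = {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            syn = dict(raw["synthetic"])
            if "grid" in syn:
                syn["grid"] = GridSpec(**syn["grid"])
            kwargs["synthetic"] = SyntheticSpec(**syn)
        if "inputs" in raw and raw["inputs"] is not None:
            inputs = dict(raw["inputs"])
            kwargs["inputs"] = _resolve_paths(inputs, base_dir)
        for key in ("tmrel", "risk_model", "linearity_epsilon", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        if "toxicity_factors" in raw:
            kwargs["toxicity_factors"] = tuple(raw["toxicity_factors"])
        if "difference_scenarios" in raw:
            kwargs["difference_scenarios"] = tuple(raw["difference_scenarios"])
        if "output_dir" in raw:
            out = Path(raw["output_dir"])
            kwargs["output_dir"] = out if out.is_absolute() else base_dir / out
        return cls(**kwargs)

    def config_hash(self) -> str:
        """Stable hash of the configuration, logged with every run."""
        blob = repr(self).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _resolve_paths(node, base_dir: Path):
    if isinstance(node, dict):
        return {k: _resolve_paths(v, base_dir) for k, v in node.items()}
    p = Path(node)
    return str(p if p.is_absolute() else base_dir / p)


@dataclass
class StudyInputs:
    """Loaded (or generated) inputs, aligned on the health grid."""

    scenarios: ScenarioSet
    population: PopulationGrid
    mask: CountryMask
    bmr: BaselineMortalityTable
    erfs: CurveSet


@dataclass
class ReportBundle:
    """All tables and diagnostics produced by one run."""

    exposure: pd.DataFrame          # country × scenario pop-weighted means
    mortality: dict[str, MortalityResult]
    totals: pd.DataFrame            # scenario × cause × toxicity × branch deaths
    country_avoidable: pd.DataFrame
    shares: pd.DataFrame            # per-country sector shares (Fig.-2 style)
    linearity: dict[str, LinearityDiagnostic]
    log: dict


def load_inputs(cfg: RunConfig) -> StudyInputs:
    """Generate synthetic inputs or read the configured files."""
    if cfg.synthetic is not None:
        study: SyntheticStudy = generate_study(cfg.synthetic)
        return StudyInputs(
            scenarios=study.scenarios, population=study.population,
            mask=study.mask, bmr=study.bmr, erfs=study.erfs,
        )
    paths = cfg.inputs
    fields = {
        label: {
            "PM25": pio.read_field(p["pm25"]),
            "ACA": pio.read_field(p["aca"]),
        }
        for label, p in paths["scenarios"].items()
    }
    return StudyInputs(
        scenarios=ScenarioSet(fields),
        population=pio.read_population(paths["population"]),
        mask=pio.read_mask(paths["mask"], paths["mask_codes"]),
        bmr=pio.read_bmr(paths["bmr"]),
        erfs=pio.read_curves(paths["erf"], tmrel=cfg.tmrel),
    )


def align_to_health_grid(inputs: StudyInputs) -> StudyInputs:
    """Bilinearly regrid concentration fields onto the population/mask grid."""
    target = inputs.mask.grid
    if inputs.scenarios.grid == target:
        return inputs
    fields = {
        label: {
            sp: regrid_field(inputs.scenarios.fields[label][sp], target, "bilinear")
            for sp in ("PM25", "ACA")
        }
        for label in inputs.scenarios.labels
    }
    return StudyInputs(
        scenarios=ScenarioSet(fields), population=inputs.population,
        mask=inputs.mask, bmr=inputs.bmr, erfs=inputs.erfs,
    )


def exposure_table(inputs: StudyInputs) -> pd.DataFrame:
    """Country-level population-weighted PM2.5 and aCA per scenario."""
    rows = []
    for label in inputs.scenarios.labels:
        pm = inputs.scenarios.pm25(label)
        aca = inputs.scenarios.aca(label)
        for country in inputs.mask.countries:
            rows.append({
                "country": country, "scenario": label,
                "pw_pm25": population_weighted_mean(pm, inputs.population,
                                                    inputs.mask, country),
                "pw_aca": population_weighted_mean(aca, inputs.population,
                                                   inputs.mask, country),
            })
    df = pd.DataFrame(rows)
    df["aca_fraction_pct"] = 100.0 * df["pw_aca"] / df["pw_pm25"]
    return df


def run_pipeline(cfg: RunConfig, write: bool = True) -> ReportBundle:
    """Execute the full assessment and (optionally) write the report CSVs."""
    inputs = align_to_health_grid(load_inputs(cfg))
    scen_labels = inputs.scenarios.labels
    exposure = exposure_table(inputs)

    mortality: dict[str, MortalityResult] = {}
    for label in scen_labels:
        mortality[label] = gridded_excess_mortality(
            inputs.scenarios.pm25(label), inputs.population, inputs.bmr,
            inputs.erfs, inputs.mask,
        )

    totals = _totals_table(inputs, mortality, cfg.toxicity_factors)
    country_avoidable = _country_avoidable_table(inputs, mortality,
                                                 cfg.difference_scenarios)
    shares = _shares_table(inputs, mortality)

    linearity: dict[str, LinearityDiagnostic] = {}
    for sector in ("RES", "TRA"):
        full, part = f"{sector}100", f"{sector}20"
        if full in scen_labels and part in scen_labels:
            linearity[sector] = linearity_diagnostic(
                inputs.scenarios.pm25("BASE"), inputs.scenarios.pm25(full),
                inputs.scenarios.pm25(part), epsilon=cfg.linearity_epsilon,
            )

    log = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed if cfg.synthetic is None else cfg.synthetic.seed,
        "n_scenarios": len(scen_labels),
        "n_countries": len(inputs.mask.countries),
        "n_exposure_rows": len(exposure),
        "n_total_rows": len(totals),
        "n_country_rows": len(country_avoidable),
        "linearity_mean": {k: v.mean_ratio for k, v in linearity.items()},
    }
    logger.info("pipeline run %s", log)

    bundle = ReportBundle(
        exposure=exposure, mortality=mortality, totals=totals,
        country_avoidable=country_avoidable, shares=shares,
        linearity=linearity, log=log,
    )
    if write:
        write_reports(bundle, cfg.output_dir)
    return bundle


def _totals_table(
    inputs: StudyInputs,
    mortality: Mapping[str, MortalityResult],
    toxicity_factors: tuple[float, ...],
) -> pd.DataFrame:
    """Domain totals by scenario × cause × branch for PM2.5 and aCA shares."""
    rows = []
    for label, m in mortality.items():
        by_cause = aggregate_mortality(m, inputs.mask, by=["cause", "branch"])
        for _, r in by_cause.iterrows():
            rows.append({"scenario": label, "exposure": "PM25", "toxicity": 0.0,
                         "cause": r["cause"], "branch": r["branch"],
                         "deaths": r["deaths"]})
        for factor in toxicity_factors:
            attributed = aca_attribution(
                m, inputs.scenarios.aca(label), inputs.scenarios.pm25(label),
                ToxicityAssumption(factor),
            )
            by_cause = aggregate_mortality(attributed, inputs.mask,
                                           by=["cause", "branch"])
            for _, r in by_cause.iterrows():
                rows.append({"scenario": label, "exposure": "ACA",
                             "toxicity": factor, "cause": r["cause"],
                             "branch": r["branch"], "deaths": r["deaths"]})
    return pd.DataFrame(rows)


def _country_avoidable_table(
    inputs: StudyInputs,
    mortality: Mapping[str, MortalityResult],
    difference_scenarios: tuple[str, ...],
) -> pd.DataFrame:
    """Per-country avoidable deaths (BASE − scenario) with CI columns."""
    rows = []
    base = mortality["BASE"]
    for label in difference_scenarios:
        if label not in mortality:
            continue
        diff, n_negative = sector_contribution(base, mortality[label])
        for jb, branch in enumerate(BRANCHES):
            per_cell = diff[:, :, jb].sum(axis=(0, 1))
            per_country = country_aggregate(per_cell, inputs.mask, "sum")
            for country, deaths in per_country.items():
                rows.append({"country": country, "scenario": label,
                             "branch": branch, "avoidable_deaths": deaths,
                             "n_negative_cells": n_negative})
    if not rows:
        return pd.DataFrame(
            columns=["country", "scenario", "branch", "avoidable_deaths",
                     "n_negative_cells"])
    return pd.DataFrame(rows)


def _shares_table(
    inputs: StudyInputs, mortality: Mapping[str, MortalityResult]
) -> pd.DataFrame:
    """Per-country sector shares of BASE mortality (RES / TRA / OTHER)."""
    have = {"RES100", "TRA100"}.issubset(mortality.keys())
    if not have:
        return pd.DataFrame(columns=["country", "res_pct", "tra_pct", "other_pct"])
    base = mortality["BASE"]
    base_by_country = country_aggregate(base.cell_totals(), inputs.mask, "sum")
    rows = []
    for country, total in base_by_country.items():
        if total <= 0:
            continue
        parts = {}
        for sector, label in (("res", "RES100"), ("tra", "TRA100")):
            diff, _ = sector_contribution(base, mortality[label])
            per_cell = diff[:, :, BRANCHES.index("central")].sum(axis=(0, 1))
            contrib = float(per_cell[inputs.mask.values == country].sum())
            parts[sector] = share_percent(max(contrib, 0.0), total, decimals=1)
        rows.append({
            "country": country,
            "res_pct": parts["res"], "tra_pct": parts["tra"],
            "other_pct": round(100.0 - parts["res"] - parts["tra"], 1),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Report rendering


def round_half_away(value: float, decimals: int = 0) -> float:
    """Round half away from zero (the reporting convention for shares)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(value).quantize(q, rounding=ROUND_HALF_UP))


def format_thousands(deaths: float) -> str:
    """Domain totals rendered in thousand deaths, e.g. 12963 → \"13\"."""
    return f"{round_half_away(deaths / 1000.0):.0f}"


def format_mean_ci(mean: float, low: float, high: float,
                   thousands: bool = False) -> str:
    """The report cell format \"mean (low–high)\"."""
    fmt = format_thousands if thousands else lambda v: f"{round_half_away(v):.0f}"
    return f"{fmt(mean)} ({fmt(low)}–{fmt(high)})"


def render_country_avoidable(table: pd.DataFrame) -> pd.DataFrame:
    """Country rows with one \"mean (low–high)\" column per scenario."""
    out: dict[str, dict[str, str]] = {}
    if len(table):
        pivot = table.pivot_table(index=["country", "scenario"], columns="branch",
                                  values="avoidable_deaths", aggfunc="sum")
        for (country, scenario), row in pivot.iterrows():
            out.setdefault(country, {})[scenario] = format_mean_ci(
                row["central"], row["low"], row["high"])
    rendered = pd.DataFrame.from_dict(out, orient="index").sort_index()
    rendered.index.name = "country"
    return rendered.reset_index()


def render_totals(totals: pd.DataFrame) -> pd.DataFrame:
    """Scenario × cause table in thousand deaths, split by exposure/toxicity."""
    if not len(totals):
        return pd.DataFrame(columns=["exposure", "toxicity", "cause", "scenario",
                                     "deaths"])
    pivot = totals.pivot_table(
        index=["exposure", "toxicity", "cause", "scenario"], columns="branch",
        values="deaths", aggfunc="sum").reset_index()
    pivot["deaths"] = [
        format_mean_ci(r["central"], r["low"], r["high"], thousands=True)
        for _, r in pivot.iterrows()
    ]
    return pivot[["exposure", "toxicity", "cause", "scenario", "deaths"]]


def write_reports(bundle: ReportBundle, output_dir: str | Path) -> None:
    """Write full-precision CSVs plus rendered report tables and the run log."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.exposure.to_csv(out / "exposure.csv", index=False)
    bundle.totals.to_csv(out / "totals.csv", index=False)
    bundle.country_avoidable.to_csv(out / "country_avoidable.csv", index=False)
    bundle.shares.to_csv(out / "sector_shares.csv", index=False)
    render_totals(bundle.totals).to_csv(out / "report_totals.csv", index=False)
    render_country_avoidable(bundle.country_avoidable).to_csv(
        out / "report_country_avoidable.csv", index=False)
    for label, m in bundle.mortality.items():
        pio.write_mortality(m, out / f"mortality_{label}.nc")
    log = dict(bundle.log)
    log["linearity"] = {
        k: {"mean_ratio": v.mean_ratio, "n_valid": v.n_valid,
            "n_excluded": v.n_excluded}
        for k, v in bundle.linearity.items()
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)
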