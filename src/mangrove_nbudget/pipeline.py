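"""End-to-end orchestration: load a bundle, run every stage, write reports.

Stage order: core loading -> per-core period budgets -> bootstrap estimates
and site/period comparisons -> estuary-wide upscaling -> food-N flow model
-> porewater and isotope summaries.  A manifest (config echo, seed, package
version) accompanies every run; identical config + seed reproduces the
bundle byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

try:
    from importlib.metadata import version as _dist_version
    _pkg_version = _dist_version("mangrove-nbudget")
except Exception:  # pragma: no cover - not installed
    _pkg_version = "unknown"

from mangrove_nbudget.core_model import (
    HISTORIC,
    RECENT,
    PeriodDefinition,
    SedimentCore,
    assign_period,
    attach_sars,
    read_core_table,
    read_porewater_table,
    read_sar_table,
    read_site_table,
)
from mangrove_nbudget.nitrogen_budget import (
    core_period_stock,
    molar_cn,
    n_accumulation_rate,
    normalize_stock_rate,
)
from mangrove_nbudget.bootstrap_engine import (
    BootstrapEstimate,
    bootstrap_derived,
    bootstrap_mean,
    compare_estimates,
    pool_site,
    substream,
)
from mangrove_nbudget.upscaling import (
    GridSpec,
    SiteValueDistribution,
    estuary_estimate,
    aboveground_n_stock,
    skew_from_sample,
)
from mangrove_nbudget.flow_model import (
    WATERSHED_AREA_HA,
    FlowConfig,
    buffer_area,
    child_stock_check,
    flow_budget,
)
from mangrove_nbudget.porewater_chem import (
    seasonal_site_comparison,
    summarize as summarize_porewater,
)
from mangrove_nbudget.isotope_profiles import (
    compare_term,
    fit_profile,
    simultaneous_bounds,
)

logger = logging.getLogger(__name__)

PERIODS = (RECENT, HISTORIC)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and record."""


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run."""

    input_dir: str
    output_dir: str
    seed: int = 0
    n_boot: int = 1000
    n_iterations: int = 100
    cell_size: float = 20.0
    idw_power: float = 2.0
    skew_default: float = 1.5
    flow: FlowConfig = field(default_factory=FlowConfig)
    periods: tuple[PeriodDefinition, ...] = PERIODS

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        flow = FlowConfig(**raw.pop("flow", {}))
        periods = tuple(
            PeriodDefinition(p["name"], p["start_year"], p["end_year"])
            for p in raw.pop("periods", [])
        ) or PERIODS
        return cls(flow=flow, periods=periods, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["periods"] = [dataclasses.asdict(p) for p in self.periods]
        return d


# ---------------------------------------------------------------------------
# stage helpers (usable standalone)

def core_budgets(cores: list[SedimentCore],
                 periods=PERIODS) -> pd.DataFrame:
    """Deterministic per-core, per-period stock/accumulation/C:N table."""
    rows = []
    for core in cores:
        for period in periods:
            slices = assign_period(core, period)
            stock = core_period_stock(core, period)
            sar = core.sar_by_period.get(period.name)
            if slices:
                bd = float(np.mean([s.bulk_density for s in slices]))
                fn = float(np.mean([s.n_fraction for s in slices]))
                cn = float(np.mean([
                    molar_cn(s.c_fraction, s.n_fraction)
                    for s in slices if s.n_fraction > 0
                ]))
            else:
                bd = fn = cn = float("nan")
            accum = (n_accumulation_rate(sar, bd, fn)
                     if sar is not None and slices else float("nan"))
            rows.append(
                {
                    "site_id": core.site_id,
                    "core_id": core.core_id,
                    "period": period.name,
                    "stock_mg_ha": stock.value,
                    "stock_rate_mg_ha_y": normalize_stock_rate(stock),
                    "accum_g_m2_y": accum,
                    "cn_molar_mean": cn,
                    "n_slices": len(slices),
                }
            )
    return pd.DataFrame(rows)


def bootstrap_budgets(
    cores: list[SedimentCore],
    periods=PERIODS,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Bootstrap every core/period quantity and pool per-site estimates.

    Returns the estimates table and a nested dict
    ``estimates[quantity][period][site or core key]`` retaining the
    :class:`BootstrapEstimate` objects for comparisons.
    """
    table = []
    kept: dict = {}

    def keep(quantity, period, key, est):
        kept.setdefault(quantity, {}).setdefault(period, {})[key] = est

    for core in cores:
        rng = substream(seed, core.core_id)
        for period in periods:
            slices = assign_period(core, period)
            if not slices:
                continue
            fn = [s.n_fraction for s in slices]
            bd = [s.bulk_density for s in slices]
            d15n = [s.d15n for s in slices if s.d15n is not None]
            sar = core.sar_by_period.get(period.name)
            thickness = sum(s.thickness_cm for s in slices)

            est_fn = bootstrap_mean(fn, n_boot, rng)
            keep("percent_n", period.name, core.core_id, _scale(est_fn, 100.0))
            if d15n:
                keep("d15n", period.name, core.core_id,
                     bootstrap_mean(d15n, n_boot, rng))
            if sar is not None:
                keep("accum_g_m2_y", period.name, core.core_id,
                     bootstrap_derived([sar], bd, fn, "accumulation",
                                       n_boot, rng))
            keep("stock_mg_ha", period.name, core.core_id,
                 bootstrap_derived([0.0], bd, fn, "stock", n_boot, rng,
                                   thickness_cm=thickness))

    sites = sorted({c.site_id for c in cores})
    by_site = {s: [c.core_id for c in cores if c.site_id == s] for s in sites}
    for quantity, by_period in list(kept.items()):
        for period, by_key in list(by_period.items()):
            for site, core_ids in by_site.items():
                members = [by_key[cid] for cid in core_ids if cid in by_key]
                if members:
                    keep(quantity, period, f"site:{site}", pool_site(members))

    for quantity, by_period in kept.items():
        for period, by_key in by_period.items():
            for key, est in by_key.items():
                is_site = key.startswith("site:")
                table.append(
                    {
                        "site_id": key.removeprefix("site:") if is_site
                        else next(c.site_id for c in cores
                                  if c.core_id == key),
                        "core_id": "" if is_site else key,
                        "level": "site" if is_site else "core",
                        "period": period,
                        "quantity": quantity,
                        "mean": est.mean,
                        "lower": est.lower,
                        "upper": est.upper,
                        "n_boot": est.n_boot,
                    }
                )
    return pd.DataFrame(table), kept


def _scale(est: BootstrapEstimate, factor: float) -> BootstrapEstimate:
    return BootstrapEstimate(
        mean=est.mean * factor,
        lower=est.lower * factor,
        upper=est.upper * factor,
        n_boot=est.n_boot,
        replicate_values=est.replicate_values * factor,
    )


def comparison_calls(kept: dict, cores: list[SedimentCore],
                     periods=PERIODS) -> pd.DataFrame:
    """Overlap-based significance calls: sites within period, periods within core.

    Temporal stock comparisons use the period-normalised (per-year)
    replicates so the 46-year recent and 40-year historic windows are
    commensurable.
    """
    rows = []
    duration = {p.name: p.duration_y for p in periods}
    for quantity, by_period in kept.items():
        # spatial: site vs site within each period
        for period, by_key in by_period.items():
            site_keys = sorted(k for k in by_key if k.startswith("site:"))
            for i, a in enumerate(site_keys):
                for b in site_keys[i + 1:]:
                    rows.append(
                        {
                            "comparison": "site_within_period",
                            "quantity": quantity,
                            "period": period,
                            "a": a.removeprefix("site:"),
                            "b": b.removeprefix("site:"),
                            "call": compare_estimates(by_key[a], by_key[b]),
                        }
                    )
        # temporal: recent vs historic within each core
        period_names = [p.name for p in periods]
        if len(period_names) >= 2:
            pa, pb = period_names[0], period_names[1]
            for core in cores:
                ea = by_period.get(pa, {}).get(core.core_id)
                eb = by_period.get(pb, {}).get(core.core_id)
                if ea is None or eb is None:
                    continue
                if quantity == "stock_mg_ha":
                    ea = _scale(ea, 1.0 / duration[pa])
                    eb = _scale(eb, 1.0 / duration[pb])
                rows.append(
                    {
                        "comparison": "period_within_core",
                        "quantity": quantity,
                        "period": f"{pa}_vs_{pb}",
                        "a": core.core_id,
                        "b": core.core_id,
                        "call": compare_estimates(ea, eb),
                    }
                )
    return pd.DataFrame(rows)


def site_distributions(
    values_by_site: dict[str, list[float]],
    skew_default: float = 1.5,
) -> dict[str, SiteValueDistribution]:
    """Per-site skewed distributions with the core-sample means and sds."""
    dists = {}
    for site, values in values_by_site.items():
        arr = np.asarray(values, dtype=float)
        if arr.size == 0 or np.isnan(arr).any():
            raise ValueError(f"site {site!r}: empty or NaN value sample")
        sd = float(arr.std(ddof=1)) if arr.size >= 2 else 0.0
        dists[site] = SiteValueDistribution(
            site_id=site,
            mean=float(arr.mean()),
            sd=sd,
            skew=skew_from_sample(arr, default=skew_default),
        )
    return dists


# ---------------------------------------------------------------------------
# the full run

def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write one summary per stage plus a manifest."""
    indir = Path(config.input_dir)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    def stage(name):
        logger.info("stage: %s", name)

    # --- load ------------------------------------------------------------
    stage("load")
    try:
        cores = read_core_table(indir / "cores.csv")
        if (indir / "sars.csv").exists():
            attach_sars(cores, read_sar_table(indir / "sars.csv"))
        sites = read_site_table(indir / "sites.csv")
        porewater = read_porewater_table(indir / "porewater.csv")
        populations = pd.read_csv(indir / "populations.csv")
        grid_meta = json.loads((indir / "grid.json").read_text())
        grid = GridSpec.from_mask_csv(indir / "mask.csv",
                                      cell_size=grid_meta["cell_size_m"])
        ag = pd.read_csv(indir / "aboveground.csv") \
            if (indir / "aboveground.csv").exists() else None
    except Exception as exc:
        raise StageError(f"load: {exc}") from exc

    locations = {s.site_id: s.location for s in sites}
    missing = sorted({c.site_id for c in cores} - set(locations))
    if missing:
        raise StageError(f"load: cores reference sites with no location: "
                         f"{missing}")

    # --- deterministic budgets -------------------------------------------
    stage("budget")
    budgets = core_budgets(cores, config.periods)
    budgets.to_csv(outdir / "budget.csv", index=False, float_format="%.17g")

    # --- bootstrap --------------------------------------------------------
    stage("bootstrap")
    estimates, kept = bootstrap_budgets(cores, config.periods,
                                        config.n_boot, config.seed)
    estimates.to_csv(outdir / "estimates.csv", index=False,
                     float_format="%.17g")
    comparisons = comparison_calls(kept, cores, config.periods)
    comparisons.to_csv(outdir / "comparisons.csv", index=False)

    # --- upscaling --------------------------------------------------------
    stage("upscale")
    upscale: dict = {"area_ha": grid.total_area_ha}
    rng = np.random.default_rng(config.seed)
    component_totals: dict[str, float] = {}
    for period in config.periods:
        sub = budgets[budgets["period"] == period.name]
        stocks = {s: g["stock_mg_ha"].tolist()
                  for s, g in sub.groupby("site_id")}
        accums = {s: (g["accum_g_m2_y"] / 100.0).dropna().tolist()
                  for s, g in sub.groupby("site_id")}
        est_stock = estuary_estimate(
            site_distributions(stocks, config.skew_default), locations, grid,
            config.n_iterations, config.idw_power,
            np.random.default_rng(rng.integers(0, 2**31)))
        est_accum = estuary_estimate(
            site_distributions(accums, config.skew_default), locations, grid,
            config.n_iterations, config.idw_power,
            np.random.default_rng(rng.integers(0, 2**31)))
        upscale[period.name] = {
            "soil_total_mg": est_stock.total_mean,
            "soil_total_se": est_stock.total_se,
            "soil_areal_mg_ha": est_stock.areal_mean,
            "soil_total_mg_y": est_accum.total_mean,
            "soil_total_mg_y_se": est_accum.total_se,
            "soil_areal_mg_ha_y": est_accum.areal_mean,
        }
        component_totals[period.name] = est_stock.total_mean
    if ag is not None:
        ag_stocks = {}
        ag_accums = {}
        composition = {s.site_id: s.species_composition for s in sites}
        for _, row in ag.iterrows():
            site = row["site_id"]
            ag_stocks[site] = [aboveground_n_stock(
                composition[site], row["ag_biomass_mg_ha"])]
            ag_accums[site] = [row["ag_accum_g_m2_y"] / 100.0]
        est_ag = estuary_estimate(
            site_distributions(ag_stocks, config.skew_default), locations,
            grid, config.n_iterations, config.idw_power,
            np.random.default_rng(rng.integers(0, 2**31)))
        est_ag_accum = estuary_estimate(
            site_distributions(ag_accums, config.skew_default), locations,
            grid, config.n_iterations, config.idw_power,
            np.random.default_rng(rng.integers(0, 2**31)))
        upscale["aboveground"] = {
            "total_mg": est_ag.total_mean,
            "total_se": est_ag.total_se,
            "areal_mg_ha": est_ag.areal_mean,
            "total_mg_y": est_ag_accum.total_mean,
            "areal_mg_ha_y": est_ag_accum.areal_mean,
        }
        soil = sum(component_totals.values())
        upscale["soil_share_of_total_n"] = soil / (soil + est_ag.total_mean)
    (outdir / "upscale.json").write_text(json.dumps(upscale, indent=2))

    # --- flows ------------------------------------------------------------
    stage("flows")
    flow_rows = []
    for _, row in populations.iterrows():
        unit = str(row["unit"])
        area = WATERSHED_AREA_HA if unit == "watershed" else buffer_area(500.0)
        fb = flow_budget(unit, float(row["population"]), area, config.flow)
        flow_rows.append(dataclasses.asdict(fb))
    flows = pd.DataFrame(flow_rows)
    flows.to_csv(outdir / "flows.csv", index=False, float_format="%.17g")
    watershed_pop = populations.loc[
        populations["unit"] == "watershed", "population"]
    child = (child_stock_check(float(watershed_pop.iloc[0]), config.flow)
             if not watershed_pop.empty else None)
    if child is not None:
        (outdir / "child_check.json").write_text(json.dumps(child, indent=2))

    # --- porewater --------------------------------------------------------
    stage("porewater")
    pw_summary = summarize_porewater(porewater)
    pw_summary.to_csv(outdir / "porewater_summary.csv", index=False,
                      float_format="%.17g")
    pw_calls = []
    for analyte in ("nh4", "din", "po4"):
        try:
            report = seasonal_site_comparison(porewater, analyte)
        except ValueError as exc:
            logger.warning("porewater comparison skipped for %s: %s",
                           analyte, exc)
            continue
        c = report.contrasts.copy()
        c.insert(0, "analyte", analyte)
        pw_calls.append(c)
    if pw_calls:
        pd.concat(pw_calls).to_csv(outdir / "porewater_comparisons.csv",
                                   index=False, float_format="%.17g")

    # --- isotopes ---------------------------------------------------------
    stage("isotopes")
    fits = []
    for site in sorted({c.site_id for c in cores}):
        core = next(c for c in cores if c.site_id == site)
        pts = [(s.depth_mid, s.d34s) for s in core.slices
               if s.d34s is not None]
        if len(pts) < 4:
            continue
        fits.append(fit_profile([p[0] for p in pts], [p[1] for p in pts],
                                "auto", site_id=site))
    fits = simultaneous_bounds(fits)
    iso_rows = []
    for f in fits:
        row = {"site_id": f.site_id, "model_form": f.model_form,
               "residual_sd": f.residual_sd,
               "adjusted_level": f.adjusted_level}
        for term in ("intercept", "slope", "quadratic"):
            est = f.coefficients.get(term)
            lo, hi = f.term_bounds.get(term, (None, None))
            row[term] = est
            row[f"{term}_lo"] = lo
            row[f"{term}_hi"] = hi
        iso_rows.append(row)
    pd.DataFrame(iso_rows).to_csv(outdir / "isotope_fits.csv", index=False,
                                  float_format="%.17g")
    iso_comparisons = []
    for i, a in enumerate(fits):
        for b in fits[i + 1:]:
            for term in ("intercept", "slope", "quadratic"):
                if term not in a.term_bounds and term not in b.term_bounds:
                    continue
                iso_comparisons.append(
                    {"a": a.site_id, "b": b.site_id, "term": term,
                     "call": compare_term(a, b, term)}
                )
    pd.DataFrame(iso_comparisons).to_csv(outdir / "isotope_comparisons.csv",
                                         index=False)

    # --- manifest ---------------------------------------------------------
    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "package_version": _pkg_version,
        "n_cores": len(cores),
        "n_sites": len(sites),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {"budgets": budgets, "estimates": estimates,
            "comparisons": comparisons, "upscale": upscale,
            "flows": flows, "manifest": manifest}
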