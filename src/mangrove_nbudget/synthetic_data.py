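"""Synthetic estuaries with the statistical structure the analysis assumes.

Generates sediment cores (1-cm surface slices, 2-cm below 3 cm), porewater
samples, site records, and population tables for a five-site peri-urban
estuary patterned on a peri-urban Caribbean lagoon system: a dredged,
well-flushed urban canal end; a clogged, sewage-influenced canal end; a
low-bulk-density, high-%N lagoon; an intermediate lagoon with a dredged
inlet; and an isolated, hypersaline forest with the least urbanisation.
Every generated bundle carries a :class:`GroundTruth` record computed
deterministically from the template means, so recovery tests can compare
pipeline output against known truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from mangrove_nbudget.core_model import (
    CoreSlice,
    PeriodDefinition,
    PorewaterSample,
    SedimentCore,
    SiteRecord,
    HISTORIC,
    RECENT,
    write_core_table,
    write_porewater_table,
    write_sar_table,
    write_site_table,
)
from mangrove_nbudget.nitrogen_budget import ATOMIC_WEIGHT_C, ATOMIC_WEIGHT_N
from mangrove_nbudget.upscaling import (
    GridSpec,
    IdwSurface,
    SiteValueDistribution,
    draw_skew_normal,
)

#: collection year of the simulated coring campaign
COLLECTION_YEAR = 2016
#: default synthetic mangrove area, hectares (five equal patches)
DEFAULT_AREA_HA = 2313.0


@dataclass(frozen=True)
class PeriodStats:
    """Within-site moments of the budget ingredients for one time period."""

    n_fraction_mean: float
    n_fraction_sd: float
    bulk_density_mean: float
    bulk_density_sd: float
    sar_mm_y: float

    def __post_init__(self) -> None:
        if not 0.003 <= self.n_fraction_mean <= 0.02:
            raise ValueError(
                f"n_fraction mean {self.n_fraction_mean} outside the "
                "observed envelope [0.003, 0.02]"
            )
        if not 0.1 < self.bulk_density_mean < 1.1:
            raise ValueError(
                f"bulk density mean {self.bulk_density_mean} outside (0.1, 1.1)"
            )
        if not 1.0 < self.sar_mm_y < 7.0:
            raise ValueError(f"SAR {self.sar_mm_y} outside (1, 7) mm y^-1")


@dataclass(frozen=True)
class SiteTemplate:
    """Everything needed to simulate one mangrove site."""

    site_id: str
    urban_index: int
    location: tuple[float, float]
    recent: PeriodStats
    historic: PeriodStats
    d15n_means: dict[str, float]          # period name -> permil
    d34s_profile: tuple[float, float, float, float]  # a, b, c, noise sd
    cn_molar: float = 22.0
    skew: float = 1.8
    species_composition: dict[str, float] = field(default_factory=dict)
    ag_biomass_mg_ha: float = 120.0
    ag_accum_g_m2_y: float = 2.0
    population: int = 1000
    porewater_means: dict[str, dict[str, float]] = field(default_factory=dict)

    def stats_for(self, period: PeriodDefinition) -> PeriodStats:
        return self.recent if period.name == "recent" else self.historic


@dataclass
class GroundTruth:
    """True per-site and estuary-wide quantities implied by template means."""

    site_period: dict    # site -> period -> {stock, accumulation, thickness}
    estuary: dict        # period -> {soil_total_mg, ...}; plus aboveground

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"site_period": self.site_period,
                        "estuary": self.estuary}, indent=2)
        )


def default_templates() -> list[SiteTemplate]:
    """Five sites spanning the urbanisation/flushing gradient.

    Means are placed so the deterministic per-site budgets land inside the
    observed envelopes: recent accumulation from ~3.7 (low-density lagoon)
    to ~27.8 g m^-2 y^-1 (clogged canal), historic rates 3-8.5 g m^-2 y^-1,
    and recent stocks above historic ones except at the dredged canal end.
    """
    sep = 3000.0  # metres between neighbouring patches

    def pw(nh4, nox, po4, sal, ph):
        return {"nh4": nh4, "nox": nox, "po4": po4, "salinity": sal, "ph": ph}

    return [
        SiteTemplate(
            site_id="canal_west", urban_index=100, location=(0.0, 0.0),
            recent=PeriodStats(0.0049, 0.0008, 0.85, 0.10, 2.5),
            historic=PeriodStats(0.0049, 0.0008, 0.85, 0.10, 2.0),
            d15n_means={"recent": 2.8, "historic": 3.9},
            d34s_profile=(2.0, 0.25, -0.003, 0.5),
            cn_molar=25.0,
            species_composition={"Laguncularia racemosa": 0.6,
                                 "Avicennia germinans": 0.3,
                                 "Rhizophora mangle": 0.1},
            ag_biomass_mg_ha=110.0, ag_accum_g_m2_y=1.8, population=3953,
            porewater_means={"wet": pw(24.5, 0.3, 1.7, 16.0, 7.1),
                             "dry": pw(36.2, 5.8, 3.8, 9.7, 7.1)},
        ),
        SiteTemplate(
            site_id="canal_east", urban_index=95, location=(sep, 0.0),
            recent=PeriodStats(0.0074, 0.0012, 0.62, 0.09, 6.0),
            historic=PeriodStats(0.0050, 0.0009, 0.60, 0.09, 2.5),
            d15n_means={"recent": 3.9, "historic": 3.9},
            d34s_profile=(14.0, -0.5, 0.008, 0.5),
            cn_molar=20.0,
            species_composition={"Laguncularia racemosa": 0.5,
                                 "Avicennia germinans": 0.4,
                                 "Rhizophora mangle": 0.1},
            ag_biomass_mg_ha=130.0, ag_accum_g_m2_y=3.0, population=4303,
            porewater_means={"wet": pw(20.8, 2.3, 49.8, 24.7, 8.2),
                             "dry": pw(125.8, 1.0, 93.4, 20.4, 8.2)},
        ),
        SiteTemplate(
            site_id="lagoon_sanjose", urban_index=60, location=(2 * sep, 0.0),
            recent=PeriodStats(0.0124, 0.0018, 0.16, 0.03, 1.5),
            historic=PeriodStats(0.0097, 0.0015, 0.16, 0.03, 1.2),
            d15n_means={"recent": 5.1, "historic": 7.2},
            d34s_profile=(8.0, -0.15, 0.0, 0.5),
            cn_molar=27.0,
            species_composition={"Laguncularia racemosa": 0.4,
                                 "Rhizophora mangle": 0.4,
                                 "Avicennia germinans": 0.2},
            ag_biomass_mg_ha=100.0, ag_accum_g_m2_y=1.7, population=1729,
            porewater_means={"wet": pw(34.6, 0.4, 4.2, 15.0, 7.9),
                             "dry": pw(27.8, 1.4, 4.7, 17.6, 7.9)},
        ),
        SiteTemplate(
            site_id="lagoon_torrecilla", urban_index=40,
            location=(3 * sep, 0.0),
            recent=PeriodStats(0.0076, 0.0012, 0.45, 0.07, 3.5),
            historic=PeriodStats(0.0060, 0.0010, 0.45, 0.07, 2.5),
            d15n_means={"recent": 5.6, "historic": 5.6},
            d34s_profile=(4.0, -0.3, 0.005, 0.5),
            cn_molar=25.0,
            species_composition={"Rhizophora mangle": 0.5,
                                 "Laguncularia racemosa": 0.3,
                                 "Avicennia germinans": 0.2},
            ag_biomass_mg_ha=140.0, ag_accum_g_m2_y=2.2, population=517,
            porewater_means={"wet": pw(24.9, 1.2, 8.3, 22.7, 7.6),
                             "dry": pw(22.5, 0.6, 9.1, 27.5, 7.6)},
        ),
        SiteTemplate(
            site_id="pinones", urban_index=1, location=(4 * sep, 0.0),
            recent=PeriodStats(0.0154, 0.0023, 0.25, 0.04, 5.5),
            historic=PeriodStats(0.0080, 0.0013, 0.25, 0.04, 3.8),
            d15n_means={"recent": 3.7, "historic": 3.8},
            d34s_profile=(13.0, -0.4, 0.006, 0.5),
            cn_molar=12.0,
            species_composition={"Rhizophora mangle": 0.6,
                                 "Avicennia germinans": 0.2,
                                 "Laguncularia racemosa": 0.2},
            ag_biomass_mg_ha=160.0, ag_accum_g_m2_y=2.5, population=36,
            porewater_means={"wet": pw(1057.3, 0.0, 3.9, 67.2, 4.7),
                             "dry": pw(451.0, 0.3, 31.6, 72.6, 4.7)},
        ),
    ]


# ---------------------------------------------------------------------------
# core generation

def slice_boundaries(core_depth_cm: float) -> list[tuple[float, float]]:
    """1-cm slices to 3 cm, then 2-cm slices to the core bottom."""
    edges = [0.0, 1.0, 2.0, 3.0]
    while edges[-1] + 2.0 <= core_depth_cm + 1e-9:
        edges.append(edges[-1] + 2.0)
    return list(zip(edges, edges[1:]))


def depth_to_date(depth_cm: float, template: SiteTemplate) -> float:
    """Linear-within-period apparent age at *depth_cm*.

    Depth accumulates at the recent SAR back to the recent/historic break
    and at the historic SAR below it (and beyond 1930 at the same rate).
    """
    rate_recent = template.recent.sar_mm_y / 10.0    # cm y^-1
    rate_historic = template.historic.sar_mm_y / 10.0
    break_depth = (COLLECTION_YEAR - HISTORIC.end_year) * rate_recent
    if depth_cm <= break_depth:
        return COLLECTION_YEAR - depth_cm / rate_recent
    return HISTORIC.end_year - (depth_cm - break_depth) / rate_historic


def _period_for_date(date: float) -> PeriodDefinition:
    return RECENT if date >= HISTORIC.end_year else HISTORIC


def generate_core(
    template: SiteTemplate,
    core_id: str,
    seed: int | np.random.Generator = 0,
    core_depth_cm: float = 45.0,
    noise_scale: float = 1.0,
) -> SedimentCore:
    """One synthetic dated core drawn from the template's distributions.

    Values are drawn per slice from right-skewed distributions with the
    template's period moments (sds multiplied by *noise_scale*; 0 gives a
    deterministic core equal to the template means) and clipped to physical
    ranges.  Slices older than the historic window reuse the historic
    moments.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    slices = []
    for top, bottom in slice_boundaries(core_depth_cm):
        mid = 0.5 * (top + bottom)
        date = depth_to_date(mid, template)
        stats = template.stats_for(_period_for_date(date))

        fn = _draw(stats.n_fraction_mean, stats.n_fraction_sd * noise_scale,
                   template.skew, rng)
        fn = float(np.clip(fn, 1e-5, 0.0999))
        bd = _draw(stats.bulk_density_mean,
                   stats.bulk_density_sd * noise_scale, template.skew, rng)
        bd = float(np.clip(bd, 0.05, 2.59))
        cfrac = float(np.clip(
            fn * template.cn_molar * ATOMIC_WEIGHT_C / ATOMIC_WEIGHT_N,
            0.0, 0.599))
        d15n_mean = template.d15n_means.get(
            _period_for_date(date).name,
            template.d15n_means.get("historic", 0.0))
        d15n = d15n_mean + 0.3 * noise_scale * rng.standard_normal()
        a, b, c, nsd = template.d34s_profile
        d34s = a + b * mid + c * mid**2 \
            + nsd * noise_scale * rng.standard_normal()
        slices.append(
            CoreSlice(depth_top=top, depth_bottom=bottom, mid_date=date,
                      bulk_density=bd, n_fraction=fn, c_fraction=cfrac,
                      d15n=float(d15n), d34s=float(d34s))
        )
    return SedimentCore(
        core_id=core_id,
        site_id=template.site_id,
        slices=slices,
        sar_by_period={"recent": template.recent.sar_mm_y,
                       "historic": template.historic.sar_mm_y},
    )


def _draw(mean: float, sd: float, skew: float,
          rng: np.random.Generator) -> float:
    if sd == 0:
        return mean
    dist = SiteValueDistribution(site_id="", mean=mean, sd=sd, skew=skew)
    return float(draw_skew_normal(dist, rng))


# ---------------------------------------------------------------------------
# estuary bundles

@dataclass
class EstuaryBundle:
    """A complete synthetic input set plus its ground truth."""

    cores: list[SedimentCore]
    sites: list[SiteRecord]
    porewater: list[PorewaterSample]
    populations: dict[str, int]
    grid: GridSpec
    ground_truth: GroundTruth
    aboveground: dict[str, dict[str, float]] = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_core_table(self.cores, outdir / "cores.csv")
        write_sar_table(self.cores, outdir / "sars.csv")
        write_site_table(self.sites, outdir / "sites.csv")
        write_porewater_table(self.porewater, outdir / "porewater.csv")
        with open(outdir / "populations.csv", "w") as fh:
            fh.write("unit,population\n")
            for unit, pop in self.populations.items():
                fh.write(f"{unit},{pop}\n")
        with open(outdir / "aboveground.csv", "w") as fh:
            fh.write("site_id,ag_biomass_mg_ha,ag_accum_g_m2_y\n")
            for site, rec in self.aboveground.items():
                fh.write(f"{site},{rec['ag_biomass_mg_ha']:.17g},"
                         f"{rec['ag_accum_g_m2_y']:.17g}\n")
        self.grid.to_mask_csv(outdir / "mask.csv")
        with open(outdir / "grid.json", "w") as fh:
            json.dump({"cell_size_m": self.grid.cell_size}, fh)
        self.ground_truth.to_json(outdir / "ground_truth.json")


def patch_mask(
    locations: list[tuple[float, float]],
    cell_size: float = 20.0,
    total_area_ha: float = DEFAULT_AREA_HA,
) -> GridSpec:
    """Circular mangrove patches of equal area centred on the sites."""
    n = len(locations)
    radius = np.sqrt(total_area_ha * 1e4 / (n * np.pi))
    centres = []
    for cx, cy in locations:
        half = int(np.ceil(radius / cell_size))
        offsets = (np.arange(-half, half + 1) + 0.5) * cell_size
        xx, yy = np.meshgrid(cx + offsets, cy + offsets)
        inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2
        centres.append(np.column_stack([xx[inside], yy[inside]]))
    return GridSpec(cell_size=cell_size, mask=np.vstack(centres))


def _ground_truth(templates: list[SiteTemplate], grid: GridSpec,
                  core_depth_cm: float) -> GroundTruth:
    site_period: dict = {}
    for t in templates:
        site_period[t.site_id] = {}
        thickness = {p.name: 0.0 for p in (RECENT, HISTORIC)}
        for top, bottom in slice_boundaries(core_depth_cm):
            date = depth_to_date(0.5 * (top + bottom), t)
            for p in (RECENT, HISTORIC):
                if p.contains(date):
                    thickness[p.name] += bottom - top
        for p in (RECENT, HISTORIC):
            st = t.stats_for(p)
            site_period[t.site_id][p.name] = {
                "thickness_cm": thickness[p.name],
                "stock_mg_ha": st.bulk_density_mean * thickness[p.name]
                * st.n_fraction_mean * 100.0,
                "accumulation_g_m2_y": st.sar_mm_y * st.bulk_density_mean
                * st.n_fraction_mean * 1000.0,
            }

    surface = IdwSurface({t.site_id: t.location for t in templates}, grid)
    estuary: dict = {"area_ha": grid.total_area_ha}
    for p in (RECENT, HISTORIC):
        stocks = {t.site_id: site_period[t.site_id][p.name]["stock_mg_ha"]
                  for t in templates}
        accums = {t.site_id:
                  site_period[t.site_id][p.name]["accumulation_g_m2_y"] / 100.0
                  for t in templates}  # Mg ha^-1 y^-1
        estuary[p.name] = {
            "soil_total_mg": surface.total(stocks),
            "soil_total_mg_y": surface.total(accums),
        }
    ag_stocks = {}
    ag_accums = {}
    for t in templates:
        n_weighted = sum(
            prop * _species_n(sp)
            for sp, prop in t.species_composition.items()
        )
        ag_stocks[t.site_id] = t.ag_biomass_mg_ha * n_weighted
        ag_accums[t.site_id] = t.ag_accum_g_m2_y / 100.0
    estuary["aboveground"] = {
        "total_mg": surface.total(ag_stocks),
        "total_mg_y": surface.total(ag_accums),
    }
    return GroundTruth(site_period=site_period, estuary=estuary)


def _species_n(species: str) -> float:
    from mangrove_nbudget.upscaling import SPECIES_N_CONTENT
    return SPECIES_N_CONTENT[species]


def generate_estuary(
    templates: list[SiteTemplate] | None = None,
    grid: GridSpec | None = None,
    cores_per_site: int = 2,
    seed: int = 0,
    noise_scale: float = 1.0,
    core_depth_cm: float = 45.0,
    cell_size: float = 20.0,
    porewater_n: int = 5,
) -> EstuaryBundle:
    """A full synthetic input bundle plus its deterministic ground truth."""
    if templates is None:
        templates = default_templates()
    if len(templates) < 2:
        raise ValueError("need at least 2 site templates")
    if grid is None:
        grid = patch_mask([t.location for t in templates], cell_size=cell_size)

    rng = np.random.default_rng(seed)
    cores = []
    for t in templates:
        for k in range(cores_per_site):
            sub = np.random.default_rng(rng.integers(0, 2**31))
            cores.append(
                generate_core(t, core_id=f"{t.site_id}_c{k + 1}", seed=sub,
                              core_depth_cm=core_depth_cm,
                              noise_scale=noise_scale)
            )

    sites = [
        SiteRecord(site_id=t.site_id, urban_index=t.urban_index,
                   location=t.location,
                   species_composition=dict(t.species_composition))
        for t in templates
    ]

    porewater = []
    for t in templates:
        for season, means in t.porewater_means.items():
            for _ in range(porewater_n):
                nh4 = max(0.0, means["nh4"]
                          * (1 + 0.3 * noise_scale * rng.standard_normal()))
                nox = max(0.0, means["nox"]
                          * (1 + 0.3 * noise_scale * rng.standard_normal()))
                po4 = max(1e-3, means["po4"]
                          * (1 + 0.3 * noise_scale * rng.standard_normal()))
                porewater.append(
                    PorewaterSample(
                        site_id=t.site_id, season=season,
                        nh4=nh4, nox=nox,
                        nox_detected=nox > 0.05,
                        po4=po4,
                        salinity=means["salinity"], ph=means["ph"],
                    )
                )

    populations = {t.site_id: t.population for t in templates}
    populations["watershed"] = 769_000

    aboveground = {
        t.site_id: {"ag_biomass_mg_ha": t.ag_biomass_mg_ha,
                    "ag_accum_g_m2_y": t.ag_accum_g_m2_y}
        for t in templates
    }

    return EstuaryBundle(
        cores=cores,
        sites=sites,
        porewater=porewater,
        populations=populations,
        grid=grid,
        ground_truth=_ground_truth(templates, grid, core_depth_cm),
        aboveground=aboveground,
    )
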