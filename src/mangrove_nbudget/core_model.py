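"""Domain types for dated sediment cores, sites, and porewater samples.

Depth convention: centimetres below the sediment surface, positive downward,
with slice intervals half-open ``[top, bottom)``.  Nitrogen and carbon are
stored internally as mass *fractions* (0-1); the tabular interfaces exchange
them as percent, matching how core laboratories report them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd


class SchemaError(ValueError):
    """A tabular input is missing mandatory columns."""


class ValidationError(ValueError):
    """A record violates a domain invariant."""


@dataclass(frozen=True)
class PeriodDefinition:
    """A deposition window ``[start_year, end_year)`` on the calendar axis."""

    name: str
    start_year: float
    end_year: float

    def __post_init__(self) -> None:
        if not self.start_year < self.end_year:
            raise ValidationError(
                f"period {self.name!r}: start_year {self.start_year} must be "
                f"< end_year {self.end_year}"
            )

    @property
    def duration_y(self) -> float:
        return self.end_year - self.start_year

    def contains(self, year: float) -> bool:
        return self.start_year <= year < self.end_year


#: Recent decades of rapid urbanisation (46 y).
RECENT = PeriodDefinition("recent", 1970, 2016)
#: Historic decades of mangrove recovery (40 y).
HISTORIC = PeriodDefinition("historic", 1930, 1970)


@dataclass(frozen=True)
class CoreSlice:
    """One dated depth interval of a sediment core.

    Parameters
    ----------
    depth_top, depth_bottom : float
        Interval bounds in cm below the surface, ``top < bottom``.
    mid_date : float
        Calendar year assigned to the slice by the age-depth model.
    bulk_density : float
        Dry bulk density, g cm^-3.
    n_fraction, c_fraction : float
        Nitrogen and carbon mass fractions (0-1), i.e. %N / 100.
    d15n, d34s : float or None
        Stable isotope ratios in per-mil, optional.
    """

    depth_top: float
    depth_bottom: float
    mid_date: float
    bulk_density: float
    n_fraction: float
    c_fraction: float = 0.0
    d15n: float | None = None
    d34s: float | None = None

    def __post_init__(self) -> None:
        if not self.depth_top < self.depth_bottom:
            raise ValidationError(
                f"slice depth_top {self.depth_top} must be < depth_bottom "
                f"{self.depth_bottom}"
            )
        if not 0 < self.bulk_density <= 2.6:
            raise ValidationError(
                f"bulk_density {self.bulk_density} outside (0, 2.6] g cm^-3"
            )
        if not 0 <= self.n_fraction < 0.1:
            raise ValidationError(f"n_fraction {self.n_fraction} outside [0, 0.1)")
        if not 0 <= self.c_fraction < 0.6:
            raise ValidationError(f"c_fraction {self.c_fraction} outside [0, 0.6)")

    @property
    def thickness_cm(self) -> float:
        return self.depth_bottom - self.depth_top

    @property
    def depth_mid(self) -> float:
        return 0.5 * (self.depth_top + self.depth_bottom)


@dataclass
class SedimentCore:
    """An ordered stack of dated slices plus per-period accretion rates."""

    core_id: str
    site_id: str
    slices: list[CoreSlice]
    sar_by_period: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.slices:
            raise ValidationError(f"core {self.core_id!r} has no slices")
        ordered = sorted(self.slices, key=lambda s: s.depth_top)
        for above, below in zip(ordered, ordered[1:]):
            if below.depth_top < above.depth_bottom - 1e-9:
                raise ValidationError(
                    f"core {self.core_id!r}: slices {above.depth_top}-"
                    f"{above.depth_bottom} and {below.depth_top}-"
                    f"{below.depth_bottom} cm overlap"
                )
            if below.mid_date > above.mid_date + 1e-9:
                raise ValidationError(
                    f"core {self.core_id!r}: mid_date increases with depth at "
                    f"{below.depth_top} cm"
                )
        self.slices = ordered
        for period, sar in self.sar_by_period.items():
            if not 0 < sar < 20:
                raise ValidationError(
                    f"core {self.core_id!r}: SAR {sar} mm y^-1 for period "
                    f"{period!r} outside (0, 20)"
                )


@dataclass
class SiteRecord:
    """A mangrove study site: location, urbanisation, species mix."""

    site_id: str
    urban_index: int
    location: tuple[float, float]
    species_composition: dict[str, float] = field(default_factory=dict)
    buffer_radius: float = 500.0

    def __post_init__(self) -> None:
        if not 1 <= self.urban_index <= 100:
            raise ValidationError(
                f"site {self.site_id!r}: urban_index {self.urban_index} "
                "outside [1, 100]"
            )
        if self.species_composition:
            total = sum(self.species_composition.values())
            if any(p < 0 for p in self.species_composition.values()):
                raise ValidationError(
                    f"site {self.site_id!r}: negative species proportion"
                )
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValidationError(
                    f"site {self.site_id!r}: species proportions sum to "
                    f"{total}, expected 1"
                )


@dataclass(frozen=True)
class PorewaterSample:
    """One porewater measurement: N species, phosphate, context."""

    site_id: str
    season: str
    nh4: float
    nox: float
    nox_detected: bool = True
    po4: float = 0.0
    salinity: float | None = None
    ph: float | None = None

    def __post_init__(self) -> None:
        if self.season not in ("wet", "dry"):
            raise ValidationError(f"season {self.season!r} must be wet or dry")
        for name, value, detected in (
            ("nh4", self.nh4, True),
            ("nox", self.nox, self.nox_detected),
            ("po4", self.po4, True),
        ):
            if detected and value < 0:
                raise ValidationError(f"{name} concentration {value} < 0")


# ---------------------------------------------------------------------------
# period assignment

def assign_period(core: SedimentCore, period: PeriodDefinition) -> list[CoreSlice]:
    """Slices of *core* deposited within *period* (half-open on end_year).

    A slice dated exactly on a period boundary belongs to the later period,
    so 1970 falls in the recent (1970-2016) window, not the historic one.
    """
    return [s for s in core.slices if period.contains(s.mid_date)]


# ---------------------------------------------------------------------------
# tabular IO

CORE_COLUMNS = [
    "core_id",
    "site_id",
    "depth_top_cm",
    "depth_bottom_cm",
    "mid_date",
    "bulk_density_gcm3",
    "percent_n",
    "percent_c",
    "d15n_permil",
    "d34s_permil",
]

SITE_COLUMNS = ["site_id", "urban_index", "x_m", "y_m", "species", "proportion"]

POREWATER_COLUMNS = [
    "site_id",
    "season",
    "nh4_um",
    "nox_um",
    "nox_detected",
    "po4_um",
    "salinity_psu",
    "ph",
]


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing columns: {missing}")


def read_core_table(path: str | Path) -> list[SedimentCore]:
    """Read a core-slice CSV into validated :class:`SedimentCore` objects.

    %N and %C are given in percent in the file and converted to mass
    fractions on read.  Unparseable rows raise with their line number;
    overlapping slices raise a :class:`ValidationError` naming the core.
    """
    df = pd.read_csv(path)
    _require_columns(df, CORE_COLUMNS[:8], "core")
    cores: list[SedimentCore] = []
    for (core_id, site_id), group in df.groupby(["core_id", "site_id"], sort=False):
        slices = []
        for idx, row in group.iterrows():
            try:
                slices.append(
                    CoreSlice(
                        depth_top=float(row["depth_top_cm"]),
                        depth_bottom=float(row["depth_bottom_cm"]),
                        mid_date=float(row["mid_date"]),
                        bulk_density=float(row["bulk_density_gcm3"]),
                        n_fraction=float(row["percent_n"]) / 100.0,
                        c_fraction=float(row["percent_c"]) / 100.0,
                        d15n=_opt_float(row.get("d15n_permil")),
                        d34s=_opt_float(row.get("d34s_permil")),
                    )
                )
            except (TypeError, ValueError) as exc:
                # +2: one for the header line, one for 0-based indexing
                raise ValidationError(
                    f"core table line {idx + 2} (core {core_id!r}): {exc}"
                ) from exc
        cores.append(SedimentCore(core_id=str(core_id), site_id=str(site_id),
                                  slices=slices))
    return cores


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    return float(value)


def write_core_table(cores: Iterable[SedimentCore], path: str | Path) -> None:
    """Write cores as a slice-per-row CSV (inverse of :func:`read_core_table`)."""
    rows = []
    for core in cores:
        for s in core.slices:
            rows.append(
                {
                    "core_id": core.core_id,
                    "site_id": core.site_id,
                    "depth_top_cm": s.depth_top,
                    "depth_bottom_cm": s.depth_bottom,
                    "mid_date": s.mid_date,
                    "bulk_density_gcm3": s.bulk_density,
                    "percent_n": s.n_fraction * 100.0,
                    "percent_c": s.c_fraction * 100.0,
                    "d15n_permil": s.d15n,
                    "d34s_permil": s.d34s,
                }
            )
    pd.DataFrame(rows, columns=CORE_COLUMNS).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_site_table(path: str | Path) -> list[SiteRecord]:
    """Read the long-format site CSV (one row per site x species)."""
    df = pd.read_csv(path)
    _require_columns(df, SITE_COLUMNS[:4], "site")
    sites = []
    for site_id, group in df.groupby("site_id", sort=False):
        first = group.iloc[0]
        composition = {}
        if "species" in group.columns:
            for _, row in group.iterrows():
                if isinstance(row.get("species"), str) and row["species"].strip():
                    composition[row["species"]] = float(row["proportion"])
        sites.append(
            SiteRecord(
                site_id=str(site_id),
                urban_index=int(first["urban_index"]),
                location=(float(first["x_m"]), float(first["y_m"])),
                species_composition=composition,
            )
        )
    return sites


def write_site_table(sites: Iterable[SiteRecord], path: str | Path) -> None:
    rows = []
    for site in sites:
        composition = site.species_composition or {"": float("nan")}
        for species, prop in composition.items():
            rows.append(
                {
                    "site_id": site.site_id,
                    "urban_index": site.urban_index,
                    "x_m": site.location[0],
                    "y_m": site.location[1],
                    "species": species,
                    "proportion": prop,
                }
            )
    pd.DataFrame(rows, columns=SITE_COLUMNS).to_csv(
        path, index=False, float_format="%.17g"
    )


SAR_COLUMNS = ["core_id", "period", "sar_mm_y"]


def read_sar_table(path: str | Path) -> dict[str, dict[str, float]]:
    """Read per-core, per-period sediment accretion rates (mm y^-1)."""
    df = pd.read_csv(path)
    _require_columns(df, SAR_COLUMNS, "sar")
    out: dict[str, dict[str, float]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["core_id"]), {})[str(row["period"])] = \
            float(row["sar_mm_y"])
    return out


def write_sar_table(cores: Iterable[SedimentCore], path: str | Path) -> None:
    rows = [
        {"core_id": c.core_id, "period": period, "sar_mm_y": sar}
        for c in cores
        for period, sar in c.sar_by_period.items()
    ]
    pd.DataFrame(rows, columns=SAR_COLUMNS).to_csv(
        path, index=False, float_format="%.17g"
    )


def attach_sars(cores: Iterable[SedimentCore],
                sars: Mapping[str, Mapping[str, float]]) -> None:
    """Attach accretion rates read via :func:`read_sar_table` to cores."""
    for core in cores:
        if core.core_id in sars:
            core.sar_by_period = dict(sars[core.core_id])


def read_porewater_table(path: str | Path) -> list[PorewaterSample]:
    df = pd.read_csv(path)
    _require_columns(df, POREWATER_COLUMNS[:6], "porewater")
    samples = []
    for _, row in df.iterrows():
        samples.append(
            PorewaterSample(
                site_id=str(row["site_id"]),
                season=str(row["season"]),
                nh4=float(row["nh4_um"]),
                nox=float(row["nox_um"]),
                nox_detected=bool(row["nox_detected"]),
                po4=float(row["po4_um"]),
                salinity=_opt_float(row.get("salinity_psu")),
                ph=_opt_float(row.get("ph")),
            )
        )
    return samples


def write_porewater_table(samples: Iterable[PorewaterSample],
                          path: str | Path) -> None:
    rows = [
        {
            "site_id": s.site_id,
            "season": s.season,
            "nh4_um": s.nh4,
            "nox_um": s.nox,
            "nox_detected": s.nox_detected,
            "po4_um": s.po4,
            "salinity_psu": s.salinity,
            "ph": s.ph,
        }
        for s in samples
    ]
    pd.DataFrame(rows, columns=POREWATER_COLUMNS).to_csv(
        path, index=False, float_format="%.17g"
    )
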