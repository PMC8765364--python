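"""Porewater nutrient stoichiometry and seasonal/site comparisons.

Nitrate + nitrite (NOx) is frequently below detection in mangrove porewater;
DIN is reported as NH4+ + NOx with non-detects set to zero by default (the
more conservative variability estimate) or to the detection limit.  Site and
season effects are assessed on ln-transformed concentrations with a two-way
fixed-effects ANOVA and Bonferroni-adjusted pairwise contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from mangrove_nbudget.core_model import PorewaterSample

#: default NOx detection limit, uM
DEFAULT_DETECTION_LIMIT = 0.05

NonDetectPolicy = Literal["zero", "detection_limit"]


@dataclass(frozen=True)
class NutrientSummary:
    """DIN and molar N:P for one site/season cell."""

    site_id: str
    season: str
    din: float
    np_molar: float
    nondetect_policy: NonDetectPolicy = "zero"


def din(
    nh4: float,
    nox: float | None,
    policy: NonDetectPolicy = "zero",
    dl: float = DEFAULT_DETECTION_LIMIT,
    nox_detected: bool = True,
) -> float:
    """Dissolved inorganic nitrogen, uM: NH4+ plus NOx.

    A non-detected NOx (``nox_detected=False`` or ``nox=None``) contributes
    zero under the default policy, or the detection limit *dl* under
    ``"detection_limit"``.
    """
    if nh4 < 0:
        raise ValueError("nh4 must be >= 0")
    detected = nox_detected and nox is not None
    if detected and nox < 0:
        raise ValueError("detected nox must be >= 0")
    if detected:
        return nh4 + nox
    return nh4 + (dl if policy == "detection_limit" else 0.0)


def np_molar_ratio(din_um: float, po4_um: float) -> float:
    """Molar N:P ratio of DIN over phosphate (both already uM)."""
    if po4_um <= 0:
        raise ValueError("N:P ratio undefined for po4 <= 0")
    return din_um / po4_um


def summarize(
    samples: Iterable[PorewaterSample],
    policy: NonDetectPolicy = "zero",
    dl: float = DEFAULT_DETECTION_LIMIT,
) -> pd.DataFrame:
    """Per site x season means +/- SE of nutrients and the molar N:P ratio.

    Mirrors the layout of a porewater summary table: concentrations as
    mean +/- standard error, with the N:P ratio of the cell means rounded
    to one decimal.
    """
    rows = []
    for s in samples:
        rows.append(
            {
                "site_id": s.site_id,
                "season": s.season,
                "nh4": s.nh4,
                "din": din(s.nh4, s.nox, policy, dl, s.nox_detected),
                "po4": s.po4,
            }
        )
    df = pd.DataFrame(rows)
    out = []
    for (site, season), g in df.groupby(["site_id", "season"], sort=False):
        n = len(g)
        rec = {"site_id": site, "season": season, "n": n}
        for col in ("nh4", "din", "po4"):
            rec[f"{col}_mean"] = g[col].mean()
            rec[f"{col}_se"] = g[col].std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
        rec["np_molar"] = round(
            np_molar_ratio(rec["din_mean"], rec["po4_mean"]), 1
        )
        out.append(rec)
    return pd.DataFrame(out)


@dataclass
class ComparisonReport:
    """Two-way factorial comparison of a porewater analyte.

    ``anova`` is the type-II ANOVA table of the ln-transformed model with
    interaction; ``contrasts`` lists every site-within-season and
    season-within-site pairwise contrast with its Bonferroni-adjusted call
    at familywise level 0.05; ``shapiro_p`` reports the residual normality
    check.
    """

    analyte: str
    anova: pd.DataFrame
    contrasts: pd.DataFrame
    shapiro_p: float
    alpha: float = 0.05
    n_comparisons: int = 0

    def significant_contrasts(self) -> pd.DataFrame:
        return self.contrasts[self.contrasts["significant"]]


def seasonal_site_comparison(
    samples: Sequence[PorewaterSample],
    analyte: Literal["nh4", "din", "po4"] = "din",
    policy: NonDetectPolicy = "zero",
    dl: float = DEFAULT_DETECTION_LIMIT,
    alpha: float = 0.05,
) -> ComparisonReport:
    """Site x season factorial comparison of one analyte.

    Values are ln(x + dl) transformed (the offset guards zeros under the
    zero non-detect policy), decomposed into site, season, and interaction
    effects by OLS, and followed by all pairwise site-within-season and
    season-within-site contrasts.  Contrast t-tests use the pooled residual
    variance; significance is Bonferroni-adjusted so the family of contrasts
    holds level *alpha*.
    """
    rows = []
    for s in samples:
        value = {
            "nh4": s.nh4,
            "din": din(s.nh4, s.nox, policy, dl, s.nox_detected),
            "po4": s.po4,
        }[analyte]
        rows.append({"site_id": s.site_id, "season": s.season, "value": value})
    df = pd.DataFrame(rows)
    if df["site_id"].nunique() < 2 or df["season"].nunique() < 2:
        raise ValueError("need >= 2 sites and both seasons")
    cell_sizes = df.groupby(["site_id", "season"]).size()
    thin = cell_sizes[cell_sizes < 2]
    if not thin.empty:
        raise ValueError(
            f"insufficient replication (<2) in cells: {list(thin.index)}"
        )

    df["ln_value"] = np.log(df["value"] + dl)
    model = smf.ols("ln_value ~ C(site_id) * C(season)", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    resid = model.resid
    # Shapiro degenerates on an identically-zero residual vector
    shapiro_p = 1.0 if np.allclose(resid, 0) else float(
        stats.shapiro(resid).pvalue
    )

    cells = df.groupby(["site_id", "season"])["ln_value"].agg(["mean", "size"])
    mse = model.mse_resid
    df_resid = model.df_resid

    pairs: list[tuple[tuple[str, str], tuple[str, str], str]] = []
    sites = sorted(df["site_id"].unique())
    seasons = sorted(df["season"].unique())
    for season in seasons:
        for i, a in enumerate(sites):
            for b in sites[i + 1:]:
                pairs.append(((a, season), (b, season), "site_within_season"))
    for site in sites:
        for i, a in enumerate(seasons):
            for b in seasons[i + 1:]:
                pairs.append(((site, a), (site, b), "season_within_site"))

    n_comp = len(pairs)
    records = []
    for cell_a, cell_b, family in pairs:
        ma, na = cells.loc[cell_a, "mean"], cells.loc[cell_a, "size"]
        mb, nb = cells.loc[cell_b, "mean"], cells.loc[cell_b, "size"]
        se = np.sqrt(mse * (1.0 / na + 1.0 / nb))
        if se == 0:
            p = 1.0 if np.isclose(ma, mb) else 0.0
        else:
            t = (ma - mb) / se
            p = 2.0 * stats.t.sf(abs(t), df_resid)
        p_adj = min(1.0, p * n_comp)
        records.append(
            {
                "family": family,
                "cell_a": "/".join(cell_a),
                "cell_b": "/".join(cell_b),
                "diff_ln": ma - mb,
                "p_raw": p,
                "p_bonferroni": p_adj,
                "significant": bool(p_adj < alpha),
            }
        )
    return ComparisonReport(
        analyte=analyte,
        anova=anova,
        contrasts=pd.DataFrame(records),
        shapiro_p=shapiro_p,
        alpha=alpha,
        n_comparisons=n_comp,
    )
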