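"""Polynomial depth models of stable-isotope profiles.

Sulfur isotope (d34S) depth profiles are fit with linear and quadratic
forms; the quadratic is kept when its curvature term is significant.  Sites
are compared term-by-term with confidence bounds widened (Bonferroni) so the
probability of wrongly calling any pair of sites different across the whole
family of comparisons stays at 5%.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy import stats

ModelForm = Literal["linear", "quadratic"]
TermName = Literal["intercept", "slope", "quadratic"]

#: residual variance below which a fit is treated as exact
_EXACT_TOL = 1e-18


@dataclass(frozen=True)
class ProfileFit:
    """A fitted depth polynomial with per-term confidence bounds.

    ``coefficients`` maps term name to estimate (per-mil units: intercept
    in permil, slope in permil cm^-1, quadratic in permil cm^-2);
    ``std_errors`` the matching standard errors; ``term_bounds`` the
    intervals at ``adjusted_level`` (95% unadjusted until
    :func:`simultaneous_bounds` is applied).
    """

    site_id: str
    model_form: ModelForm
    coefficients: dict[str, float]
    std_errors: dict[str, float]
    df_resid: int
    residual_sd: float
    term_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    adjusted_level: float = 0.95

    def __post_init__(self) -> None:
        has_quad = "quadratic" in self.coefficients
        if has_quad != (self.model_form == "quadratic"):
            raise ValueError("quadratic term present iff model_form quadratic")
        for term, (lo, hi) in self.term_bounds.items():
            if lo > hi:
                raise ValueError(f"term {term!r}: bounds not ordered")


def _ols(depths: np.ndarray, y: np.ndarray, degree: int):
    """Least squares on a depth polynomial; returns beta, se, df, resid var."""
    X = np.vander(depths, degree + 1, increasing=True)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df_resid = len(y) - (degree + 1)
    s2 = float(resid @ resid) / df_resid if df_resid > 0 else 0.0
    if s2 < _EXACT_TOL:
        s2 = 0.0
    cov = s2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    return beta, se, df_resid, s2


def _bounds(coefficients, std_errors, df_resid, level) -> dict:
    tcrit = stats.t.ppf(0.5 + level / 2.0, df_resid) if df_resid > 0 else np.inf
    out = {}
    for term, est in coefficients.items():
        se = std_errors[term]
        half = 0.0 if se == 0 else tcrit * se
        out[term] = (est - half, est + half)
    return out


def fit_profile(
    depths: Sequence[float],
    d34s: Sequence[float],
    form: Literal["auto", "linear", "quadratic"] = "auto",
    site_id: str = "",
    alpha: float = 0.05,
) -> ProfileFit:
    """Fit a d34S (or other isotope) depth profile by ordinary least squares.

    Depths are slice midpoints in cm.  Under ``form="auto"`` the quadratic
    model is selected when its curvature term is significant at *alpha*
    (for an exactly-fitting profile, when the curvature is non-negligible),
    otherwise the linear model is kept.
    """
    d = np.asarray(depths, dtype=float)
    y = np.asarray(d34s, dtype=float)
    if d.shape != y.shape or d.ndim != 1:
        raise ValueError("depths and d34s must be equal-length 1-D sequences")
    min_pts = {"linear": 3, "quadratic": 4, "auto": 4}[form]
    if len(d) < min_pts:
        raise ValueError(f"need >= {min_pts} points for form {form!r}")

    chosen: ModelForm
    if form == "auto":
        beta, se, df_resid, s2 = _ols(d, y, 2)
        if s2 == 0.0:
            scale = max(np.abs(beta).max(), 1.0)
            quad_significant = abs(beta[2]) > 1e-9 * scale
        else:
            t = beta[2] / se[2]
            quad_significant = 2 * stats.t.sf(abs(t), df_resid) < alpha
        chosen = "quadratic" if quad_significant else "linear"
    else:
        chosen = form

    degree = 2 if chosen == "quadratic" else 1
    beta, se, df_resid, s2 = _ols(d, y, degree)
    names = ["intercept", "slope", "quadratic"][: degree + 1]
    coefficients = dict(zip(names, map(float, beta)))
    std_errors = dict(zip(names, map(float, se)))
    fit = ProfileFit(
        site_id=site_id,
        model_form=chosen,
        coefficients=coefficients,
        std_errors=std_errors,
        df_resid=df_resid,
        residual_sd=float(np.sqrt(s2)),
    )
    return replace(fit, term_bounds=_bounds(coefficients, std_errors,
                                            df_resid, 0.95))


def simultaneous_bounds(
    fits: Sequence[ProfileFit],
    n_comparisons: int | None = None,
    overall_level: float = 0.95,
) -> list[ProfileFit]:
    """Re-derive term bounds at a familywise-adjusted confidence level.

    Each term's interval is computed at per-comparison level
    ``1 - (1 - overall_level) / n_comparisons`` (Bonferroni), so the chance
    of wrongly declaring any two sites different across all comparisons is
    held at ``1 - overall_level``.  When *n_comparisons* is omitted it
    defaults to (number of unordered site pairs) x (number of shared terms).
    """
    if n_comparisons is None:
        n_sites = len(fits)
        n_pairs = n_sites * (n_sites - 1) // 2
        shared = set.intersection(*(set(f.coefficients) for f in fits)) \
            if fits else set()
        n_comparisons = max(1, n_pairs * len(shared))
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    level = 1.0 - (1.0 - overall_level) / n_comparisons
    return [
        replace(
            f,
            term_bounds=_bounds(f.coefficients, f.std_errors, f.df_resid,
                                level),
            adjusted_level=level,
        )
        for f in fits
    ]


def compare_term(fit_a: ProfileFit, fit_b: ProfileFit, term: TermName) -> str:
    """``"different"`` iff the term's closed bound intervals are disjoint.

    Comparing a quadratic term between a quadratic and a linear fit returns
    ``"not_comparable"``; a term present in neither fit is a contract error.
    """
    in_a = term in fit_a.term_bounds
    in_b = term in fit_b.term_bounds
    if not in_a and not in_b:
        raise ValueError(f"term {term!r} absent from both fits")
    if not (in_a and in_b):
        return "not_comparable"
    lo_a, hi_a = fit_a.term_bounds[term]
    lo_b, hi_b = fit_b.term_bounds[term]
    disjoint = hi_a < lo_b or hi_b < lo_a
    return "different" if disjoint else "not_different"
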