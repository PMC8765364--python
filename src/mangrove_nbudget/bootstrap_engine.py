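"""Percentile bootstrap estimation and overlap-based comparisons.

Per-parameter means and 95% bounds come from 1,000 with-replacement
resamples within a core and time period; derived quantities (stock,
accumulation) propagate uncertainty by randomly pairing the ingredient
measurements rather than tying them to a common depth; site-level bounds
pool the replicate values of both cores (2,000 values).  Two estimates
differ significantly iff their percentile bounds do not overlap.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

DEFAULT_N_BOOT = 1000
_PERCENTILES = (2.5, 97.5)


@dataclass(frozen=True)
class BootstrapEstimate:
    """Mean and 2.5th/97.5th-percentile bounds of B bootstrap replicates."""

    mean: float
    lower: float
    upper: float
    n_boot: int
    replicate_values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.n_boot != len(self.replicate_values):
            raise ValueError("n_boot must equal len(replicate_values)")
        if not self.lower <= self.upper:
            raise ValueError("lower bound exceeds upper bound")

    @property
    def interval(self) -> tuple[float, float]:
        return (self.lower, self.upper)


def _finish(replicates: np.ndarray) -> BootstrapEstimate:
    lower, upper = np.percentile(replicates, _PERCENTILES)
    return BootstrapEstimate(
        mean=float(replicates.mean()),
        lower=float(lower),
        upper=float(upper),
        n_boot=len(replicates),
        replicate_values=replicates,
    )


def substream(seed: int, label: str) -> np.random.Generator:
    """A reproducible per-record random stream derived from (seed, label).

    Keying the stream on the record label (e.g. the core id) makes results
    independent of the order in which cores are processed.
    """
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(label.encode("utf-8"))])
    )


def bootstrap_mean(
    values: Sequence[float],
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | np.random.Generator = 0,
) -> BootstrapEstimate:
    """Percentile bootstrap of the sample mean.

    Each replicate is the mean of a with-replacement resample of the same
    size as *values*; the estimate is the mean of the replicates and the
    bounds their empirical 2.5th/97.5th percentiles.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot bootstrap an empty sample")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    idx = rng.integers(0, arr.size, size=(n_boot, arr.size))
    return _finish(arr[idx].mean(axis=1))


def bootstrap_derived(
    sar_values: Sequence[float],
    bd_values: Sequence[float],
    fn_values: Sequence[float],
    formula: Literal["accumulation", "stock"] = "accumulation",
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | np.random.Generator = 0,
    thickness_cm: float | None = None,
    draws_per_replicate: int = 1,
) -> BootstrapEstimate:
    """Random-pairing bootstrap of a derived quantity.

    Each replicate draws a SAR, a bulk density, and an N fraction
    independently and uniformly from their respective within-core samples —
    deliberately *not* from the same depth — and applies the budget formula:
    accumulation (g m^-2 y^-1) or stock (Mg ha^-1, which additionally needs
    the period's *thickness_cm*).  For ``formula="stock"`` the SAR sample is
    ignored (stock is bulk density x thickness x N fraction).

    With ``draws_per_replicate > 1`` the replicate statistic is the mean of
    that many paired draws instead of a single derived value; the default of
    one draw per replicate keeps the full measurement-to-measurement spread
    in the bounds.
    """
    sar = np.asarray(sar_values, dtype=float)
    bd = np.asarray(bd_values, dtype=float)
    fn = np.asarray(fn_values, dtype=float)
    if sar.size == 0 or bd.size == 0 or fn.size == 0:
        raise ValueError("all ingredient samples must be non-empty")
    if formula == "stock" and thickness_cm is None:
        raise ValueError("stock formula requires thickness_cm")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)

    m = draws_per_replicate
    shape = (n_boot, m)
    sar_draw = sar[rng.integers(0, sar.size, size=shape)]
    bd_draw = bd[rng.integers(0, bd.size, size=shape)]
    fn_draw = fn[rng.integers(0, fn.size, size=shape)]
    if formula == "accumulation":
        derived = sar_draw * bd_draw * fn_draw * 1000.0
    elif formula == "stock":
        derived = bd_draw * thickness_cm * fn_draw * 100.0
    else:
        raise ValueError(f"unknown formula {formula!r}")
    return _finish(derived.mean(axis=1))


def pool_site(core_estimates: Sequence[BootstrapEstimate]) -> BootstrapEstimate:
    """Pool the replicate values of several core estimates into site bounds.

    Concatenates the retained replicates (1,000 per core, 2,000 for the
    usual two-core site) and recomputes the mean and percentile bounds on
    the pooled collection.
    """
    if not core_estimates:
        raise ValueError("need at least one estimate to pool")
    for est in core_estimates:
        if est.replicate_values is None or len(est.replicate_values) == 0:
            raise ValueError("estimate lacks retained replicate values")
    return _finish(np.concatenate([e.replicate_values for e in core_estimates]))


def compare_estimates(a: BootstrapEstimate, b: BootstrapEstimate) -> str:
    """``"significant"`` iff the closed percentile intervals are disjoint.

    A shared endpoint counts as overlap (conservative).
    """
    disjoint = a.upper < b.lower or b.upper < a.lower
    return "significant" if disjoint else "not_significant"
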