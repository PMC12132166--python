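"""AF-stratified permutation tests for lead-variant properties.

Two tests are provided:

* :func:`perm_test_median_diff` — is the median paired imputation-quality
  difference at a set of lead variants larger in magnitude than for random
  variant sets with the same allele-frequency composition drawn from a
  genome-wide pool?
* :func:`perm_test_fold_change` — is the proportion of lead variants
  satisfying a predicate elevated relative to random pool samples?

Null sampling is without replacement (a lead set is a subset of real
variants, not an i.i.d. draw); the stratified variants match the lead
set's per-AF-stratum counts exactly in every replicate.  All reported
P-values use the add-one (r + 1) / (n + 1) correction, so p is never 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from ._rng import substream

__all__ = [
    "DEFAULT_AF_BINS",
    "PermutationResult",
    "perm_test_fold_change",
    "perm_test_median_diff",
]

# minor-allele-scale bin edges; the interior edges define the strata
DEFAULT_AF_BINS: tuple[float, ...] = (0.0, 0.001, 0.005, 0.01, 0.05, 0.1, 0.25, 0.5)


@dataclass
class PermutationResult:
    """Observed statistic, permutation P-value and bootstrap CI."""

    observed: float
    n_perm: int
    p_value: float
    tail: str
    ci_low: float
    ci_high: float
    strata: tuple[float, ...] | None
    seed: int
    null_median: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "observed": self.observed,
            "n_perm": self.n_perm,
            "p_value": self.p_value,
            "tail": self.tail,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "strata": list(self.strata) if self.strata is not None else None,
            "seed": self.seed,
            "null_median": self.null_median,
        }


def _strata_of(af: np.ndarray, bins: Sequence[float]) -> np.ndarray:
    maf = np.minimum(np.asarray(af, dtype=float), 1.0 - np.asarray(af, dtype=float))
    return np.digitize(maf, np.asarray(bins, dtype=float)[1:-1], right=False)


def _sample_wor(rng: np.random.Generator, pool_size: int, k: int, n_draws: int) -> np.ndarray:
    """n_draws independent without-replacement samples of k from range(pool_size).

    Vectorized via per-row random keys and argpartition; returns an
    (n_draws, k) index matrix.
    """
    if k > pool_size:
        raise ValueError("cannot sample more than the pool size without replacement")
    out = np.empty((n_draws, k), dtype=np.int64)
    if k == pool_size:
        out[:] = np.arange(pool_size)[None, :]
        return out
    chunk = max(1, int(5_000_000 // max(pool_size, 1)))
    for lo in range(0, n_draws, chunk):
        hi = min(lo + chunk, n_draws)
        keys = rng.random((hi - lo, pool_size))
        out[lo:hi] = np.argpartition(keys, k - 1, axis=1)[:, :k]
    return out


def _stratified_null_medians(
    rng: np.random.Generator,
    pool_values: np.ndarray,
    pool_strata: np.ndarray,
    counts: dict[int, int],
    n_draws: int,
) -> np.ndarray:
    """Medians of stratified without-replacement samples from the pool."""
    k_total = sum(counts.values())
    samples = np.empty((n_draws, k_total))
    col = 0
    for stratum, k in sorted(counts.items()):
        idx = np.flatnonzero(pool_strata == stratum)
        picks = _sample_wor(rng, idx.size, k, n_draws)
        samples[:, col : col + k] = pool_values[idx[picks]]
        col += k
    return np.median(samples, axis=1)


def perm_test_median_diff(
    lead_set: pd.DataFrame,
    pool: pd.DataFrame,
    n_perm: int = 10_000,
    af_bins: Sequence[float] = DEFAULT_AF_BINS,
    seed: int = 0,
    n_boot: int = 1_000,
) -> PermutationResult:
    """AF-stratified permutation test of the median paired INFO difference.

    ``lead_set`` and ``pool`` need columns ``af`` and ``info_diff`` (local
    minus global imputation quality).  The observed statistic is the median
    ``info_diff`` over the lead set; each null replicate recomputes it on a
    without-replacement pool sample matching the lead set's per-stratum
    counts.  The two-tailed P-value is centered on the null median:
    ``p = (1 + #{|T_null - med| >= |T_obs - med|}) / (n_perm + 1)``.  The CI
    is the 95% percentile interval of a stratified bootstrap of the
    observed statistic.

    Raises
    ------
    ValueError
        If a stratum holds fewer pool variants than lead variants (the
        offending stratum is named).
    """
    for frame, name in ((lead_set, "lead_set"), (pool, "pool")):
        if not {"af", "info_diff"}.issubset(frame.columns):
            raise ValueError(f"{name} needs 'af' and 'info_diff' columns")
    if len(lead_set) == 0:
        raise ValueError("lead_set is empty")

    bins = tuple(af_bins)
    lead_strata = _strata_of(lead_set["af"].to_numpy(), bins)
    pool_strata = _strata_of(pool["af"].to_numpy(), bins)
    pool_values = pool["info_diff"].to_numpy(dtype=float)
    lead_values = lead_set["info_diff"].to_numpy(dtype=float)

    counts = {int(s): int(c) for s, c in zip(*np.unique(lead_strata, return_counts=True))}
    for stratum, need in counts.items():
        have = int((pool_strata == stratum).sum())
        if have < need:
            lo = bins[stratum] if stratum < len(bins) else bins[-1]
            raise ValueError(
                f"stratum {stratum} (MAF >= {lo}) holds {have} pool variants but needs {need}"
            )

    observed = float(np.median(lead_values))
    rng = substream(seed, "perm.median_diff")
    nulls = _stratified_null_medians(rng, pool_values, pool_strata, counts, n_perm)
    center = float(np.median(nulls))
    exceed = int(np.sum(np.abs(nulls - center) >= abs(observed - center)))
    p = (1 + exceed) / (n_perm + 1)

    boot_rng = substream(seed, "perm.median_diff.boot")
    boot = np.empty(n_boot)
    groups = [np.flatnonzero(lead_strata == s) for s in sorted(counts)]
    for b in range(n_boot):
        resampled = np.concatenate([lead_values[g[boot_rng.integers(0, g.size, g.size)]] for g in groups])
        boot[b] = np.median(resampled)
    ci_low, ci_high = np.percentile(boot, [2.5, 97.5])

    return PermutationResult(
        observed=observed,
        n_perm=n_perm,
        p_value=float(p),
        tail="two",
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        strata=bins,
        seed=seed,
        null_median=center,
    )


def perm_test_fold_change(
    lead_set: pd.DataFrame,
    pool: pd.DataFrame,
    predicate: Callable[[pd.DataFrame], np.ndarray],
    n_perm: int = 10_000,
    seed: int = 0,
    stratified: bool = False,
    af_bins: Sequence[float] = DEFAULT_AF_BINS,
    n_boot: int = 1_000,
) -> PermutationResult:
    """Permutation test of the fold change in a lead-variant proportion.

    The observed statistic is ``prop(lead satisfies predicate) /
    prop(pool satisfies predicate)``; null replicates are fold changes of
    uniform (or AF-stratified, if ``stratified``) without-replacement pool
    samples of the lead-set size.  One-tailed P:
    ``(1 + #{null >= observed}) / (n_perm + 1)``.

    Raises
    ------
    ValueError
        If no pool variant satisfies the predicate.
    """
    if len(lead_set) == 0:
        raise ValueError("lead_set is empty")
    pool_flags = np.asarray(predicate(pool), dtype=bool)
    lead_flags = np.asarray(predicate(lead_set), dtype=bool)
    pool_prop = pool_flags.mean()
    if pool_prop == 0:
        raise ValueError("pool proportion is zero; fold change undefined")
    k = len(lead_set)
    observed = float(lead_flags.mean() / pool_prop)

    rng = substream(seed, "perm.fold_change")
    if stratified:
        lead_strata = _strata_of(lead_set["af"].to_numpy(), tuple(af_bins))
        pool_strata = _strata_of(pool["af"].to_numpy(), tuple(af_bins))
        counts = {int(s): int(c) for s, c in zip(*np.unique(lead_strata, return_counts=True))}
        for stratum, need in counts.items():
            if int((pool_strata == stratum).sum()) < need:
                raise ValueError(f"stratum {stratum} holds fewer pool variants than required")
        null_props = np.zeros(n_perm)
        for stratum, kk in sorted(counts.items()):
            idx = np.flatnonzero(pool_strata == stratum)
            picks = _sample_wor(rng, idx.size, kk, n_perm)
            null_props += pool_flags[idx[picks]].sum(axis=1)
        null_props /= k
    else:
        picks = _sample_wor(rng, len(pool), k, n_perm)
        null_props = pool_flags[picks].mean(axis=1)
    nulls = null_props / pool_prop
    p = (1 + int(np.sum(nulls >= observed))) / (n_perm + 1)

    boot_rng = substream(seed, "perm.fold_change.boot")
    boot_picks = boot_rng.integers(0, k, size=(n_boot, k))
    boot = lead_flags[boot_picks].mean(axis=1) / pool_prop
    ci_low, ci_high = np.percentile(boot, [2.5, 97.5])

    return PermutationResult(
        observed=observed,
        n_perm=n_perm,
        p_value=float(p),
        tail="one",
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        strata=tuple(af_bins) if stratified else None,
        seed=seed,
        null_median=float(np.median(nulls)),
    )
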