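"""Array batch-effect LRT filtering and SV near-duplicate deduplication."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["BatchLrtResult", "batch_lrt", "batch_lrt_scan", "dedup_svs"]


@dataclass
class BatchLrtResult:
    """Likelihood-ratio test of array indicators on one SNP's genotypes."""

    lrt: float
    df: int
    p: float
    reject: bool
    alpha_bonferroni: float


def _check_design(pcs: np.ndarray, arrays: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    arrays = np.asarray(arrays)
    levels = np.unique(arrays)
    if levels.size < 2:
        raise ValueError("need at least two arrays")
    counts = np.array([(arrays == lev).sum() for lev in levels])
    if counts.min() < 2:
        raise ValueError("every array needs at least two individuals")
    pcs = np.asarray(pcs, dtype=float)
    n = arrays.size
    if pcs.shape[0] != n:
        raise ValueError("PC rows must match individuals")
    X_red = np.column_stack([np.ones(n), pcs])
    if np.linalg.matrix_rank(X_red) < X_red.shape[1]:
        raise ValueError("PC columns are collinear")
    dummies = np.column_stack([(arrays == lev).astype(float) for lev in levels[1:]])
    X_full = np.column_stack([X_red, dummies])
    return X_red, X_full, levels.size


def _rss(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    coef, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    return np.einsum("ij,ij->j", resid, resid)


def batch_lrt(
    genotypes: np.ndarray,
    pcs: np.ndarray,
    arrays: np.ndarray,
    n_tests: int = 1,
    alpha: float = 0.05,
) -> BatchLrtResult:
    """Gaussian likelihood-ratio test for array batch effects on one SNP.

    Compares the linear models G ~ 1 + PCs + array indicators against
    G ~ 1 + PCs; the statistic ``n * ln(RSS_reduced / RSS_full)`` is
    referred to a chi-square with (number of arrays - 1) degrees of
    freedom.  ``reject`` applies the Bonferroni level ``alpha / n_tests``.

    Raises
    ------
    ValueError
        If any array has fewer than two individuals or the PCs are
        collinear.
    """
    g = np.asarray(genotypes, dtype=float).reshape(-1, 1)
    X_red, X_full, n_arrays = _check_design(pcs, arrays)
    n = g.shape[0]
    rss_red = float(_rss(X_red, g)[0])
    rss_full = float(_rss(X_full, g)[0])
    lrt = max(0.0, n * np.log(rss_red / rss_full)) if rss_full > 0 else 0.0
    df = n_arrays - 1
    p = float(stats.chi2.sf(lrt, df)) if lrt > 0 else 1.0
    threshold = alpha / n_tests
    return BatchLrtResult(lrt=lrt, df=df, p=p, reject=p < threshold, alpha_bonferroni=threshold)


def batch_lrt_scan(
    genotypes: np.ndarray,
    pcs: np.ndarray,
    arrays: np.ndarray,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Vectorized :func:`batch_lrt` over a genotype matrix (individuals x SNPs).

    Bonferroni correction uses the number of scanned SNPs.  Returns a frame
    with columns snp, lrt, df, p, reject.
    """
    G = np.asarray(genotypes, dtype=float)
    X_red, X_full, n_arrays = _check_design(pcs, arrays)
    n, m = G.shape
    rss_red = _rss(X_red, G)
    rss_full = _rss(X_full, G)
    with np.errstate(divide="ignore", invalid="ignore"):
        lrt = n * np.log(rss_red / rss_full)
    lrt = np.where(np.isfinite(lrt), np.maximum(lrt, 0.0), 0.0)
    df = n_arrays - 1
    p = stats.chi2.sf(lrt, df)
    threshold = alpha / m
    return pd.DataFrame({"snp": np.arange(m), "lrt": lrt, "df": df, "p": p, "reject": p < threshold})


def _pct_diff(a: float, b: float, denom: str) -> float:
    if a == b:
        return 0.0
    if denom == "mean":
        return abs(a - b) / ((a + b) / 2.0) * 100.0
    if denom == "max":
        return abs(a - b) / max(a, b) * 100.0
    raise ValueError("denom must be 'mean' or 'max'")


def dedup_svs(
    records: pd.DataFrame,
    window: int = 100,
    pct_max: float = 1.0,
    denom: str = "mean",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove near-duplicate SV records.

    Candidate pairs share chromosome and type with both |start difference|
    and |end difference| within ``window`` bp.  Pairs are processed greedily
    in ascending (|dstart| + |dend|) order, skipping pairs with an already-
    removed member: equal allele counts remove the shorter record (ties:
    the later record in sort order); otherwise, if both the AC and AF
    percent differences are below ``pct_max``, the lower-AC record is
    removed; otherwise both are kept.

    Returns (kept records, removed records with a ``reason`` column); the
    operation is idempotent.

    Raises
    ------
    ValueError
        On a negative window.
    """
    if window < 0:
        raise ValueError("window must be non-negative")
    required = {"chrom", "start", "end", "svtype", "length", "ac", "af"}
    if not required.issubset(records.columns):
        raise ValueError(f"missing columns {sorted(required - set(records.columns))}")

    df = records.sort_values(["chrom", "start"], kind="mergesort").reset_index()
    pairs: list[tuple[int, int, int]] = []  # (dist, i, j) row positions in df
    for chrom, grp in df.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        types = grp["svtype"].to_numpy()
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                ds = abs(int(starts[b]) - int(starts[a]))
                if ds > window:
                    break  # starts sorted
                de = abs(int(ends[b]) - int(ends[a]))
                if de <= window and types[a] == types[b]:
                    pairs.append((ds + de, int(idx[a]), int(idx[b])))

    pairs.sort()
    removed_rows: list[tuple[int, str]] = []
    removed_set: set[int] = set()
    for _, i, j in pairs:
        if i in removed_set or j in removed_set:
            continue
        ri, rj = df.loc[i], df.loc[j]
        if int(ri["ac"]) == int(rj["ac"]):
            if ri["length"] < rj["length"]:
                victim = i
            elif rj["length"] < ri["length"]:
                victim = j
            else:
                victim = j  # equal length and AC: drop the later record
            removed_rows.append((victim, "equal_ac_shorter"))
            removed_set.add(victim)
        else:
            d_ac = _pct_diff(float(ri["ac"]), float(rj["ac"]), denom)
            d_af = _pct_diff(float(ri["af"]), float(rj["af"]), denom)
            if d_ac < pct_max and d_af < pct_max:
                victim = i if ri["ac"] < rj["ac"] else j
                removed_rows.append((victim, "similar_ac_lower"))
                removed_set.add(victim)

    removed = df.loc[[r for r, _ in removed_rows]].copy()
    removed["reason"] = [reason for _, reason in removed_rows]
    kept = df.drop(index=list(removed_set))
    kept = kept.set_index("index").sort_index()
    kept.index.name = records.index.name
    removed = removed.set_index("index")
    removed.index.name = records.index.name
    return kept, removed
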