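"""Founder-enrichment statistics, variant prioritization and carrier inference."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from ._rng import substream
from .synth.genealogy import Genealogy

__all__ = [
    "EnrichmentResult",
    "carrier_frequency_ci",
    "classify",
    "enrichment_fold",
    "fisher_or",
    "mrca_carriers",
    "prioritize_variants",
]

_CLINVAR_CANDIDATE = {"P", "LP", "conflicting"}


@dataclass
class EnrichmentResult:
    """Cohort/reference fold enrichment for one variant."""

    fold: float  # +inf when af_ref == 0 and af_cohort > 0
    enriched: bool
    af_cohort: float
    af_ref: float


def enrichment_fold(
    af_cohort: float,
    af_ref: float,
    maf_min: float = 0.001,
    fold_min: float = 4.0,
) -> EnrichmentResult:
    """Fold = af_cohort / af_ref; enriched iff af_cohort >= maf_min and fold >= fold_min.

    A zero reference frequency with a non-zero cohort frequency yields an
    infinite fold (which satisfies any finite threshold); both zero yields
    NaN and not-enriched.

    Raises
    ------
    ValueError
        If either frequency lies outside [0, 1].
    """
    for name, f in (("af_cohort", af_cohort), ("af_ref", af_ref)):
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {f}")
    if af_ref == 0.0:
        fold = math.inf if af_cohort > 0 else math.nan
    else:
        fold = af_cohort / af_ref
    enriched = af_cohort >= maf_min and fold >= fold_min
    return EnrichmentResult(fold=fold, enriched=bool(enriched), af_cohort=af_cohort, af_ref=af_ref)


def classify(
    af_cohort: np.ndarray,
    af_ref: np.ndarray,
    maf_min: float = 0.001,
    fold_min: float = 4.0,
) -> pd.DataFrame:
    """Vectorized :func:`enrichment_fold` over frequency arrays."""
    ac = np.asarray(af_cohort, dtype=float)
    ar = np.asarray(af_ref, dtype=float)
    if np.any((ac < 0) | (ac > 1)) or np.any((ar < 0) | (ar > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(ar > 0, ac / ar, np.where(ac > 0, np.inf, np.nan))
    enriched = (ac >= maf_min) & (fold >= fold_min)
    return pd.DataFrame({"fold": fold, "enriched": enriched})


def fisher_or(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Odds ratio and central two-sided Fisher exact P for [[a, b], [c, d]].

    The OR is the sample odds ratio with the Haldane-Anscombe +0.5
    correction applied to every cell when any cell is zero.  The P-value is
    the sum of hypergeometric probabilities of tables no more probable than
    the observed one (at fixed margins).

    Raises
    ------
    ValueError
        On negative counts or a zero margin.
    """
    counts = (a, b, c, d)
    if any(int(x) != x or x < 0 for x in counts):
        raise ValueError("counts must be non-negative integers")
    a, b, c, d = (int(x) for x in counts)
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise ValueError("all margins of the 2x2 table must be positive")

    if min(a, b, c, d) == 0:
        aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        aa, bb, cc, dd = a, b, c, d
    or_estimate = (aa * dd) / (bb * cc)

    total = a + b + c + d
    row1 = a + b
    col1 = a + c
    support = np.arange(max(0, col1 - (c + d)), min(row1, col1) + 1)
    # hypergeometric log-pmf over the support, via log-gamma
    lg = gammaln
    log_pmf = (
        lg(row1 + 1) - lg(support + 1) - lg(row1 - support + 1)
        + lg(total - row1 + 1) - lg(col1 - support + 1) - lg(total - row1 - col1 + support + 1)
        - (lg(total + 1) - lg(col1 + 1) - lg(total - col1 + 1))
    )
    pmf = np.exp(log_pmf)
    p_obs = float(pmf[support == a][0])
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    return or_estimate, min(p, 1.0)


_DEFAULT_RULES: tuple[str, ...] = ("clinvar_or_plof", "maf", "cadd_or_splice")


def prioritize_variants(
    annots: pd.DataFrame,
    rules: Sequence[str] | None = None,
    *,
    af_ref_max: float = 0.01,
    cadd_min: float = 15.0,
    spliceai_min: float = 0.8,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the variant-prioritization rule chain.

    Default chain, in order:

    1. ``clinvar_or_plof`` — keep variants with ClinVar class in
       {P, LP, conflicting} or a pLoF flag.
    2. ``maf`` — keep variants with reference-population AF <= 1%.
    3. ``cadd_or_splice`` — keep variants with CADD >= 15, or splice
       candidates with SpliceAI >= 0.8.

    Missing annotation values fail their rule.  Expected columns:
    ``clinvar``, ``plof``, ``af_ref``, ``cadd``, ``spliceai`` (only those
    used by enabled rules are required).  Returns the surviving rows and
    per-rule removal counts.

    Raises
    ------
    ValueError
        On an unknown rule name.
    """
    chain = tuple(rules) if rules is not None else _DEFAULT_RULES
    unknown = set(chain) - {"clinvar_or_plof", "maf", "cadd_or_splice"}
    if unknown:
        raise ValueError(f"unknown rule(s): {sorted(unknown)}")

    df = annots.copy()
    removed: dict[str, int] = {}
    for rule in chain:
        before = len(df)
        if rule == "clinvar_or_plof":
            clinvar_ok = df.get("clinvar", pd.Series("none", index=df.index)).isin(_CLINVAR_CANDIDATE)
            plof_ok = df.get("plof", pd.Series(False, index=df.index)).fillna(False).astype(bool)
            df = df[clinvar_ok | plof_ok]
        elif rule == "maf":
            af = pd.to_numeric(df.get("af_ref", pd.Series(np.nan, index=df.index)), errors="coerce")
            df = df[af <= af_ref_max]
        elif rule == "cadd_or_splice":
            cadd = pd.to_numeric(df.get("cadd", pd.Series(np.nan, index=df.index)), errors="coerce")
            splice = pd.to_numeric(df.get("spliceai", pd.Series(np.nan, index=df.index)), errors="coerce")
            df = df[(cadd >= cadd_min) | (splice >= spliceai_min)]
        removed[rule] = before - len(df)
    return df, removed


def mrca_carriers(tree: Genealogy, known_carriers: Sequence[str]) -> tuple[int, float, set[str]]:
    """MRCA of the known carriers and the implied expanded carrier set.

    Returns ``(mrca_node, tmrca, expanded)`` where ``tmrca`` is the MRCA's
    node time in generations and ``expanded`` is the set of all leaves
    descending from the MRCA (a superset of the known carriers); internal
    nodes are not individuals.

    Raises
    ------
    ValueError
        On an empty carrier set or an unknown leaf label.
    """
    carriers = list(known_carriers)
    if not carriers:
        raise ValueError("known_carriers must be non-empty")
    label_to_leaf = {lab: i for i, lab in enumerate(tree.leaf_labels)}
    try:
        nodes = [label_to_leaf[lab] for lab in carriers]
    except KeyError as exc:
        raise ValueError(f"unknown leaf label {exc.args[0]!r}") from None

    def lca_pair(u: int, v: int) -> int:
        # climb whichever node sits lower until the two paths meet
        while u != v:
            if tree.time[u] <= tree.time[v]:
                u = int(tree.parent[u])
            else:
                v = int(tree.parent[v])
            if u < 0 or v < 0:
                raise RuntimeError("walked past the root; malformed tree")
        return u

    mrca = nodes[0]
    for node in nodes[1:]:
        mrca = lca_pair(mrca, node)
    expanded = tree.leaves_below(mrca)
    return mrca, float(tree.time[mrca]), expanded


def carrier_frequency_ci(
    carrier: Mapping[str, bool] | pd.Series,
    region: Mapping[str, str] | pd.Series,
    n_boot: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-region carrier frequency with a percentile bootstrap 95% CI.

    ``carrier`` maps individual -> carrier status and ``region`` maps
    individual -> region label.  Bootstrapping resamples individuals with
    replacement within each region (equivalent, for a binary trait, to
    binomial resampling of the carrier count).  Individuals without a
    region raise; regions present in ``region`` but empty after alignment
    are skipped with a warning.
    """
    carrier = pd.Series(carrier, dtype=bool)
    region = pd.Series(region)
    if not carrier.index.isin(region.index).all():
        raise ValueError("every individual needs a region label")
    region = region.loc[carrier.index]
    rng = substream(seed, "carrier_ci")

    rows = []
    for reg, idx in carrier.groupby(region).groups.items():
        flags = carrier.loc[idx].to_numpy()
        n = flags.size
        if n == 0:
            warnings.warn(f"region {reg!r} is empty; skipped", stacklevel=2)
            continue
        k = int(flags.sum())
        freq = k / n
        boot = rng.binomial(n, freq, size=n_boot) / n
        lo, hi = np.percentile(boot, [2.5, 97.5])
        rows.append({"region": reg, "n": n, "carriers": k, "frequency": freq, "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows, columns=["region", "n", "carriers", "frequency", "ci_low", "ci_high"])
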