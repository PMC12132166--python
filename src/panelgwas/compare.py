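"""Cross-approach locus matching and imputation-panel benchmarking.

Loci called under different imputation approaches for the same trait are
matched into clusters by >= 1 bp interval overlap with transitive closure;
the membership pattern of each cluster over the approaches defines the
Venn partition.  Additional routines compute per-subset summaries, per-
individual variant-recovery/concordance statistics, and the relative
recovery ratio of cohort-enriched variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .loci import Locus
from .synth.panels import ImputedPanel

__all__ = [
    "LocusCluster",
    "PATTERN_LABELS",
    "SubsetSummary",
    "VennPartition",
    "match_loci",
    "recovery_stats",
    "relative_recovery_ratio",
    "subset_summary",
]

# Canonical letters for the 7 membership patterns of {local, global, meta}.
# This is a fixed internal convention, configurable by passing another map.
PATTERN_LABELS: dict[frozenset, str] = {
    frozenset({"local"}): "A",
    frozenset({"local", "meta"}): "B",
    frozenset({"local", "global"}): "C",
    frozenset({"global", "meta"}): "D",
    frozenset({"global"}): "E",
    frozenset({"meta"}): "F",
    frozenset({"local", "global", "meta"}): "core",
}


@dataclass
class LocusCluster:
    """Loci from different approaches matched to one genomic signal."""

    trait: str
    chrom: str
    start: int
    end: int
    loci: list[Locus]
    pattern: frozenset

    @property
    def approaches(self) -> set[str]:
        return set(self.pattern)

    def lead_for(self, approach_priority: Sequence[str]) -> tuple[Locus, str] | None:
        """Representative locus by approach priority (first present wins)."""
        for app in approach_priority:
            for locus in self.loci:
                if locus.approach == app:
                    return locus, app
        return None


@dataclass
class VennPartition:
    """Clusters of matched loci with their membership patterns."""

    clusters: list[LocusCluster]
    approaches: list[str]
    min_overlap: int = 1

    def pattern_counts(self) -> dict[frozenset, int]:
        counts: dict[frozenset, int] = {}
        for c in self.clusters:
            counts[c.pattern] = counts.get(c.pattern, 0) + 1
        return counts

    def subset(self, pattern: frozenset) -> list[LocusCluster]:
        return [c for c in self.clusters if c.pattern == frozenset(pattern)]


def match_loci(loci: Sequence[Locus], min_overlap: int = 1) -> VennPartition:
    """Match same-trait loci across approaches into overlap clusters.

    Two loci are connected if they are on the same chromosome and their
    intervals overlap by at least ``min_overlap`` bp; clusters are the
    connected components (so an A-B and B-C overlap joins A, B and C even
    when A and C are disjoint).
    """
    loci = list(loci)
    approaches = sorted({l.approach for l in loci})
    parent = list(range(len(loci)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    by_group: dict[tuple[str, str], list[int]] = {}
    for idx, locus in enumerate(loci):
        by_group.setdefault((locus.trait, locus.chrom), []).append(idx)

    for idxs in by_group.values():
        idxs = sorted(idxs, key=lambda i: loci[i].start)
        for a_pos, i in enumerate(idxs):
            for j in idxs[a_pos + 1 :]:
                if loci[j].start > loci[i].end - min_overlap + 1:
                    break
                overlap = min(loci[i].end, loci[j].end) - max(loci[i].start, loci[j].start) + 1
                if overlap >= min_overlap:
                    union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(len(loci)):
        groups.setdefault(find(i), []).append(i)

    clusters = []
    for idxs in groups.values():
        members = [loci[i] for i in idxs]
        clusters.append(
            LocusCluster(
                trait=members[0].trait,
                chrom=members[0].chrom,
                start=min(l.start for l in members),
                end=max(l.end for l in members),
                loci=members,
                pattern=frozenset(l.approach for l in members),
            )
        )
    clusters.sort(key=lambda c: (c.trait, c.chrom, c.start))
    return VennPartition(clusters=clusters, approaches=approaches, min_overlap=min_overlap)


@dataclass
class SubsetSummary:
    """Per-Venn-subset lead-variant summary."""

    pattern: frozenset
    label: str
    n_loci: int
    n_lead_absent_in_alternate: int
    median_info_diff: float  # local - global, over leads present in both panels
    median_lead_af: float
    n_paired: int = 0


def subset_summary(
    partition: VennPartition,
    panel_meta: pd.DataFrame,
    *,
    local: str = "local",
    global_: str = "global",
    labels: dict[frozenset, str] | None = None,
    approach_priority: Sequence[str] = ("local", "meta", "global"),
) -> list[SubsetSummary]:
    """Summarize each membership pattern of the partition.

    ``panel_meta`` is indexed by variant key (chrom, pos, ref, alt) with
    columns ``present_<panel>``, ``info_<panel>`` for the local and global
    panels and ``af_local``.  For every cluster the representative lead is
    taken from the highest-priority approach present; it counts as "absent
    in the alternate panel" when the other single-panel's presence flag is
    false, and contributes a paired INFO difference (local - global) only
    when present in both panels.
    """
    labels = PATTERN_LABELS if labels is None else labels
    out: list[SubsetSummary] = []
    for pattern in sorted(partition.pattern_counts(), key=lambda p: labels.get(p, str(sorted(p)))):
        clusters = partition.subset(pattern)
        diffs: list[float] = []
        afs: list[float] = []
        n_absent = 0
        for cluster in clusters:
            rep = cluster.lead_for(approach_priority)
            if rep is None:
                continue
            locus, rep_app = rep
            key = locus.lead
            if key not in panel_meta.index:
                continue
            row = panel_meta.loc[key]
            alternate = global_ if rep_app != global_ else local
            if not bool(row[f"present_{alternate}"]):
                n_absent += 1
            if bool(row[f"present_{local}"]) and bool(row[f"present_{global_}"]):
                diffs.append(float(row[f"info_{local}"]) - float(row[f"info_{global_}"]))
            if f"af_{local}" in row.index:
                afs.append(float(row[f"af_{local}"]))
        out.append(
            SubsetSummary(
                pattern=pattern,
                label=labels.get(pattern, "+".join(sorted(pattern))),
                n_loci=len(clusters),
                n_lead_absent_in_alternate=n_absent,
                median_info_diff=float(np.median(diffs)) if diffs else float("nan"),
                median_lead_af=float(np.median(afs)) if afs else float("nan"),
                n_paired=len(diffs),
            )
        )
    return out


def recovery_stats(
    truth: np.ndarray,
    panel_a: ImputedPanel,
    panel_b: ImputedPanel,
    well_imputed_info: float = 0.3,
    hard_call_margin: float | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-individual counts of variants recovered by panel A but not B.

    A variant counts toward an individual's recovery if the individual
    carries it in truth (dosage >= 1), panel A has it with INFO above
    ``well_imputed_info``, and panel B is missing it or has INFO at or
    below the threshold.  Concordance is the fraction of hard-called panel-A
    genotypes (dosage rounded to the nearest of {0,1,2}; no-call when the
    distance exceeds ``hard_call_margin``) equal to truth over those
    variants.

    Returns a per-individual frame (recovered, concordance) and a summary
    dict with cohort means and standard errors.

    Raises
    ------
    ValueError
        If the panels share no variants with the truth matrix.
    """
    truth = np.asarray(truth)
    n, m = truth.shape
    if panel_a.dosage.shape != (n, m) or panel_b.dosage.shape != (n, m):
        raise ValueError("panels and truth must share the variant set")
    if m == 0:
        raise ValueError("no overlapping variants")

    well_a = panel_a.present & (np.nan_to_num(panel_a.info, nan=-1.0) > well_imputed_info)
    well_b = panel_b.present & (np.nan_to_num(panel_b.info, nan=-1.0) > well_imputed_info)
    eligible = well_a & ~well_b  # per-variant

    carried = truth >= 1
    recover_mask = carried & eligible[None, :]
    recovered = recover_mask.sum(axis=1)

    hard = np.round(np.clip(panel_a.dosage, 0, 2))
    if hard_call_margin is not None:
        no_call = np.abs(panel_a.dosage - hard) > hard_call_margin
    else:
        no_call = np.zeros_like(hard, dtype=bool)
    match = (hard == truth) & ~no_call
    with np.errstate(invalid="ignore"):
        concord = np.where(recovered > 0, (match & recover_mask).sum(axis=1) / np.maximum(recovered, 1), np.nan)

    per_ind = pd.DataFrame({"recovered": recovered, "concordance": concord})
    conc = per_ind["concordance"].dropna()
    summary = {
        "mean_recovered": float(per_ind["recovered"].mean()),
        "se_recovered": float(per_ind["recovered"].std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
        "mean_concordance": float(conc.mean()) if len(conc) else float("nan"),
        "se_concordance": float(conc.std(ddof=1) / np.sqrt(len(conc))) if len(conc) > 1 else float("nan"),
    }
    return per_ind, summary


def relative_recovery_ratio(
    table: pd.DataFrame,
    fold_min: float = 8.0,
    ref_af_max: float = 0.05,
) -> float:
    """Enrichment of panel-A-specific recovery among cohort-enriched variants.

    ``table`` has one row per variant with boolean columns ``in_truth``,
    ``recovered_a``, ``missing_b`` and frequency columns ``af_cohort``,
    ``af_ref``.  The ratio is

        P(event | fold >= fold_min and af_ref < ref_af_max)
        / P(event | af_ref < ref_af_max)

    where the event is ``in_truth & recovered_a & missing_b``.

    Raises
    ------
    ValueError
        If the enriched stratum is empty or the background event
        probability is zero.
    """
    required = {"in_truth", "recovered_a", "missing_b", "af_cohort", "af_ref"}
    if not required.issubset(table.columns):
        raise ValueError(f"missing columns {sorted(required - set(table.columns))}")
    event = table["in_truth"] & table["recovered_a"] & table["missing_b"]
    background = table["af_ref"] < ref_af_max
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = table["af_cohort"] / table["af_ref"]
    enriched = background & (fold >= fold_min)
    if not enriched.any():
        raise ValueError("enriched stratum is empty")
    if not background.any():
        raise ValueError("background stratum is empty")
    p_bg = event[background].mean()
    if p_bg == 0:
        raise ValueError("background event probability is zero; ratio undefined")
    return float(event[enriched].mean() / p_bg)
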