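"""Independent genome-wide-significant locus calling.

Every significant variant seeds a window of +-flank bp; overlapping or
immediately adjacent windows on a chromosome are merged transitively into
one locus per (trait, approach), whose lead is the member with the lowest
P-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["Locus", "call_loci", "filter_for_loci", "loci_to_bed", "loci_to_json"]

VariantKey = tuple[str, int, str, str]


@dataclass
class Locus:
    """A merged genome-wide-significant interval (1-based inclusive)."""

    trait: str
    approach: str
    chrom: str
    start: int
    end: int
    lead: VariantKey
    lead_p: float
    members: list[VariantKey] = field(default_factory=list)
    index_variants: list[VariantKey] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("locus start must be <= end")

    def overlaps(self, other: "Locus") -> bool:
        return self.chrom == other.chrom and self.start <= other.end and other.start <= self.end


def filter_for_loci(
    stats: pd.DataFrame,
    mac_min: float = 20,
    info_min: float = 0.3,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep rows with MAC strictly above ``mac_min`` and INFO strictly above
    ``info_min`` (boundary values are removed).

    Returns the filtered table and the per-criterion removal counts.

    Raises
    ------
    ValueError
        If the MAC or INFO column is missing.
    """
    for col in ("MAC", "INFO"):
        if col not in stats.columns:
            raise ValueError(f"missing required column {col!r}")
    mac_ok = stats["MAC"] > mac_min
    info_ok = stats["INFO"] > info_min
    report = {
        "removed_mac": int((~mac_ok).sum()),
        "removed_info": int((~info_ok).sum()),
        "kept": int((mac_ok & info_ok).sum()),
    }
    return stats[mac_ok & info_ok].copy(), report


def _key(row) -> VariantKey:
    return (str(row.CHROM), int(row.POS), str(row.REF), str(row.ALT))


def call_loci(
    stats: pd.DataFrame,
    p_threshold: float = 5e-8,
    flank: int = 500_000,
    chrom_lengths: Mapping[str, int] | None = None,
    merge_gap: int = 1,
) -> list[Locus]:
    """Call independent significant loci per (trait, approach).

    Each variant with PVAL < ``p_threshold`` seeds the window
    ``[pos - flank, pos + flank]`` clipped at 1 (and at the chromosome end
    when ``chrom_lengths`` is given).  Windows on a chromosome whose gap is
    at most ``merge_gap`` bp (overlapping or immediately adjacent by
    default) are merged transitively.  The lead is the member with the
    lowest P; ties break by position, then alternate allele.
    """
    required = {"CHROM", "POS", "PVAL"}
    if not required.issubset(stats.columns):
        raise ValueError(f"missing required columns {sorted(required - set(stats.columns))}")
    df = stats.copy()
    if "TRAIT" not in df:
        df["TRAIT"] = "trait"
    if "APPROACH" not in df:
        df["APPROACH"] = "panel"
    if "REF" not in df:
        df["REF"] = "."
    if "ALT" not in df:
        df["ALT"] = "."

    sig = df[df["PVAL"] < p_threshold]
    loci: list[Locus] = []
    for (trait, approach, chrom), grp in sig.groupby(["TRAIT", "APPROACH", "CHROM"], sort=True):
        grp = grp.sort_values(["POS", "ALT"])
        pos = grp["POS"].to_numpy(dtype=np.int64)
        starts = np.maximum(pos - flank, 1)
        ends = pos + flank
        if chrom_lengths is not None and chrom in chrom_lengths:
            ends = np.minimum(ends, chrom_lengths[chrom])
        # transitive merge over position-sorted windows
        cluster_start = int(starts[0])
        cluster_end = int(ends[0])
        rows = [grp.iloc[0]]
        clusters: list[tuple[int, int, list]] = []
        for i in range(1, len(grp)):
            if int(starts[i]) - cluster_end <= merge_gap:
                cluster_end = max(cluster_end, int(ends[i]))
                rows.append(grp.iloc[i])
            else:
                clusters.append((cluster_start, cluster_end, rows))
                cluster_start, cluster_end, rows = int(starts[i]), int(ends[i]), [grp.iloc[i]]
        clusters.append((cluster_start, cluster_end, rows))

        for start, end, members in clusters:
            sub = pd.DataFrame(members)
            best = sub.sort_values(["PVAL", "POS", "ALT"], kind="mergesort").iloc[0]
            loci.append(
                Locus(
                    trait=str(trait),
                    approach=str(approach),
                    chrom=str(chrom),
                    start=start,
                    end=end,
                    lead=_key(best),
                    lead_p=float(best.PVAL),
                    members=[_key(r) for r in sub.itertuples(index=False)],
                )
            )
    return loci


def loci_to_bed(loci: Sequence[Locus]) -> pd.DataFrame:
    """Loci as a BED-like frame (0-based half-open coordinates)."""
    return pd.DataFrame(
        {
            "chrom": [l.chrom for l in loci],
            "start": [l.start - 1 for l in loci],
            "end": [l.end for l in loci],
            "name": [f"{l.trait}:{l.approach}:{l.lead[0]}_{l.lead[1]}_{l.lead[2]}_{l.lead[3]}" for l in loci],
        }
    )


def loci_to_json(loci: Sequence[Locus]) -> list[dict]:
    return [
        {
            "trait": l.trait,
            "approach": l.approach,
            "chrom": l.chrom,
            "start": l.start,
            "end": l.end,
            "lead": list(l.lead),
            "lead_p": l.lead_p,
            "n_members": len(l.members),
            "members": [list(k) for k in l.members],
            "index_variants": [list(k) for k in l.index_variants],
        }
        for l in loci
    ]
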