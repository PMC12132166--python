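"""Synthetic SV callsets with planted near-duplicate pairs."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .._rng import substream

__all__ = ["SVCallset", "simulate_sv_callset"]

_N_DIPLOID = 1000  # AF denominator: allele count over 2 * N chromosomes


@dataclass
class SVCallset:
    """Records plus ground-truth duplicate pairing.

    ``records`` columns: chrom, start, end, svtype, length, ac, af
    (coordinates 0-based half-open).  ``pairs`` has one row per planted
    near-duplicate: original/duplicate row indices and the AC percent
    difference drawn for the pair.
    """

    records: pd.DataFrame
    pairs: pd.DataFrame


def simulate_sv_callset(
    n_svs: int,
    dup_fraction: float,
    seed: int,
    ac_diff_pct: float = 0.0,
    max_offset: int = 50,
) -> SVCallset:
    """Simulate an SV callset where a fraction of records has a near-duplicate.

    Base records are spaced far apart (>= 10 kb) so only planted pairs fall
    within the deduplication window.  Each planted duplicate shifts both
    breakpoints by at most ``max_offset`` bp (keeping the duplicate strictly
    shorter when ACs are equal, so the expected removal is unambiguous) and
    perturbs the allele count by ``ac_diff_pct`` percent of the mean.

    Raises
    ------
    ValueError
        If ``dup_fraction`` is outside [0, 1].
    """
    if not 0.0 <= dup_fraction <= 1.0:
        raise ValueError("dup_fraction must be in [0, 1]")
    if n_svs < 1:
        raise ValueError("n_svs must be positive")
    rng = substream(seed, "sv_callset")

    chroms = rng.choice(["chr1", "chr2", "chr3"], size=n_svs)
    starts = rng.integers(0, 10_000, size=n_svs) + np.arange(n_svs, dtype=np.int64) * 50_000
    lengths = rng.integers(300, 20_000, size=n_svs)
    types = rng.choice(["DEL", "DUP"], size=n_svs, p=[0.9, 0.1])
    acs = rng.integers(50, 400, size=n_svs)

    rows = {
        "chrom": chroms,
        "start": starts,
        "end": starts + lengths,
        "svtype": types,
        "length": lengths,
        "ac": acs,
    }
    base = pd.DataFrame(rows)

    n_dups = int(round(dup_fraction * n_svs))
    dup_of = rng.choice(n_svs, size=n_dups, replace=False)
    dup_rows = []
    pair_rows = []
    for k, i in enumerate(sorted(dup_of)):
        ds = int(rng.integers(-max_offset, max_offset + 1))
        # duplicate strictly shorter: end offset pulls the end leftward of ds
        de = ds - int(rng.integers(1, max_offset + 1))
        start = int(base.at[i, "start"]) + ds
        end = int(base.at[i, "end"]) + de
        ac = int(base.at[i, "ac"])
        if ac_diff_pct > 0:
            # |a - b| / mean(a, b) == pct/100  =>  b = a * (200 - pct) / (200 + pct)
            ac_dup = max(1, int(round(ac * (200.0 - ac_diff_pct) / (200.0 + ac_diff_pct))))
        else:
            ac_dup = ac
        dup_rows.append(
            {
                "chrom": base.at[i, "chrom"],
                "start": start,
                "end": end,
                "svtype": base.at[i, "svtype"],
                "length": end - start,
                "ac": ac_dup,
            }
        )
        pair_rows.append({"original": i, "duplicate": n_svs + k, "ac_diff_pct": ac_diff_pct})

    records = pd.concat([base, pd.DataFrame(dup_rows)], ignore_index=True) if dup_rows else base
    records["af"] = records["ac"] / (2 * _N_DIPLOID)
    pairs = pd.DataFrame(pair_rows, columns=["original", "duplicate", "ac_diff_pct"])
    return SVCallset(records=records, pairs=pairs)
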