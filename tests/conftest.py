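import numpy as np
import pandas as pd
import pytest

from panelgwas import synth


@pytest.fixture(scope="session")
def small_cohort() -> synth.CohortData:
    cfg = synth.SimConfig(
        n_individuals=800,
        n_variants=60,
        seed=11,
        n_causal=1,
        effect_sizes=[0.4],
    )
    return synth.simulate_cohort(cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_stats(rows: list[dict]) -> pd.DataFrame:
    """Summary-statistics frame with sensible defaults for omitted columns."""
    defaults = {
        "CHROM": "chr1",
        "POS": 1000,
        "REF": "A",
        "ALT": "G",
        "AF": 0.1,
        "INFO": 0.9,
        "MAC": 100,
        "N": 1000,
        "BETA": 0.0,
        "SE": 1.0,
        "PVAL": 0.5,
        "TRAIT": "trait",
        "APPROACH": "panel",
    }
    return pd.DataFrame([{**defaults, **row} for row in rows])


def oracle_merge_windows(positions, flank=500_000, merge_gap=1):
    """Brute-force interval union: repeatedly merge any overlapping or
    immediately adjacent pair until a fixpoint is reached.

    Returns sorted (start, end, member_positions) triples.  Independent of
    the package's sorted sweep in loci.call_loci.
    """
    intervals = [[max(1, p - flank), p + flank, {p}] for p in positions]
    changed = True
    while changed:
        changed = False
        for i in range(len(intervals)):
            for j in range(i + 1, len(intervals)):
                a, b = intervals[i], intervals[j]
                if a[0] <= b[1] + merge_gap and b[0] <= a[1] + merge_gap:
                    a[0] = min(a[0], b[0])
                    a[1] = max(a[1], b[1])
                    a[2] |= b[2]
                    del intervals[j]
                    changed = True
                    break
            if changed:
                break
    return sorted((s, e, frozenset(m)) for s, e, m in intervals)
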