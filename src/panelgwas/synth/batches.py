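"""Multi-array genotype batches with optional planted batch effects."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .._rng import substream

__all__ = ["BatchData", "simulate_array_batches"]


@dataclass
class BatchData:
    """Genotype batches across arrays plus the planted-shift ground truth."""

    genotypes: np.ndarray  # individuals x snps, values in {0, 1, 2}
    arrays: np.ndarray  # per-individual array index
    pcs: np.ndarray  # individuals x 4, independent of array under the null
    afs: np.ndarray  # generating AF per SNP (un-shifted)
    shifted: np.ndarray  # bool per SNP: AF shifted by delta in the last array
    delta: float

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.genotypes, columns=[f"snp{j}" for j in range(self.genotypes.shape[1])])
        df.insert(0, "array", self.arrays)
        for k in range(self.pcs.shape[1]):
            df.insert(k + 1, f"PC{k + 1}", self.pcs[:, k])
        return df


def simulate_array_batches(
    n_per_array: Sequence[int],
    n_snps: int,
    delta: float,
    seed: int,
    shifted_fraction: float = 0.1,
    n_pcs: int = 4,
) -> BatchData:
    """Simulate genotypes across arrays with an AF shift planted in one array.

    Genotypes are binomial(2, AF) at a common per-SNP AF drawn uniformly on
    [0.05, 0.5].  A ``shifted_fraction`` of SNPs has its AF shifted by
    ``delta`` in the last array; with ``delta = 0`` no SNP is shifted.  PCs
    are standard normal, independent of array membership.

    Raises
    ------
    ValueError
        If fewer than two arrays are given, or if the shift pushes any AF
        outside (0, 1).
    """
    if len(n_per_array) < 2:
        raise ValueError("need at least two arrays")
    if any(n < 1 for n in n_per_array):
        raise ValueError("every array needs at least one individual")
    if n_snps < 1:
        raise ValueError("n_snps must be positive")
    rng = substream(seed, "array_batches")

    afs = rng.uniform(0.05, 0.5, size=n_snps)
    shifted = np.zeros(n_snps, dtype=bool)
    if delta != 0.0:
        n_shift = int(round(shifted_fraction * n_snps))
        shifted[rng.choice(n_snps, size=n_shift, replace=False)] = True
        if np.any(afs[shifted] + delta <= 0) or np.any(afs[shifted] + delta >= 1):
            raise ValueError("delta pushes a planted AF outside (0, 1)")

    arrays = np.repeat(np.arange(len(n_per_array)), n_per_array)
    n = arrays.size
    af_matrix = np.tile(afs, (n, 1))
    last = arrays == len(n_per_array) - 1
    af_matrix[np.ix_(last, shifted)] += delta
    genotypes = rng.binomial(2, af_matrix).astype(np.int8)
    pcs = rng.standard_normal((n, n_pcs))
    return BatchData(genotypes=genotypes, arrays=arrays, pcs=pcs, afs=afs, shifted=shifted, delta=delta)
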