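"""Diploid cohort simulation with planted causal effects.

Genotypes are drawn under Hardy-Weinberg at each variant's generating AF;
the phenotype is a linear combination of standardized causal dosages,
covariate effects and Gaussian noise.  Causal identities and generating
parameters are recorded in the variant metadata as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .._rng import substream
from .config import SimConfig

__all__ = ["CohortData", "simulate_cohort"]

# fixed, documented covariate effects on the raw phenotype scale
_COVARIATE_EFFECTS = {"sex": 0.10, "age_c": 0.010, "age2_c": -0.0005}
_PC_EFFECT = 0.05


@dataclass
class CohortData:
    """Simulated cohort: dosages, phenotype, covariates and variant metadata.

    ``dosage`` is individuals x variants with values in {0, 1, 2}.
    ``variants`` has one row per variant: chrom, pos, ref, alt, af
    (generating AF), is_causal, beta.
    """

    dosage: np.ndarray
    phenotype: np.ndarray
    covariates: pd.DataFrame
    variants: pd.DataFrame
    config: SimConfig

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    def empirical_af(self) -> np.ndarray:
        return self.dosage.mean(axis=0) / 2.0


def _draw_afs(rng: np.random.Generator, config: SimConfig) -> np.ndarray:
    """Truncated-Beta AFs via inverse-CDF so truncation costs no rejections."""
    lo = 1.0 / (2.0 * config.n_individuals)
    hi = 1.0 - lo
    law = config.af_law
    dist = stats.beta(law.alpha, law.beta)
    u = rng.uniform(dist.cdf(lo), dist.cdf(hi), size=config.n_variants)
    return np.clip(dist.ppf(u), lo, hi)


def _unique_positions(rng: np.random.Generator, length: int, n: int) -> np.ndarray:
    """n distinct 1-based positions on [1, length], without materializing the range."""
    if n > length:
        raise ValueError("more variants than base pairs on a chromosome")
    out: np.ndarray = np.empty(0, dtype=np.int64)
    while out.size < n:
        draw = rng.integers(1, length + 1, size=2 * (n - out.size) + 8)
        out = np.unique(np.concatenate([out, draw]))
        if out.size > n:
            out = rng.choice(out, size=n, replace=False)
    return np.sort(out)


def _place_variants(rng: np.random.Generator, config: SimConfig) -> pd.DataFrame:
    chroms = list(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    which = rng.choice(len(chroms), size=config.n_variants, p=probs)
    pos = np.empty(config.n_variants, dtype=np.int64)
    for i, c in enumerate(chroms):
        mask = which == i
        n = int(mask.sum())
        pos[mask] = _unique_positions(rng, int(lengths[i]), n)
    alleles = np.array(list("ACGT"))
    ref = alleles[rng.integers(0, 4, size=config.n_variants)]
    alt = np.array([alleles[(list(alleles).index(r) + k) % 4] for r, k in zip(ref, rng.integers(1, 4, size=config.n_variants))])
    order = np.lexsort((pos, which))
    return pd.DataFrame(
        {
            "chrom": np.array(chroms)[which][order],
            "pos": pos[order],
            "ref": ref[order],
            "alt": alt[order],
        }
    )


def _simulate_covariates(rng: np.random.Generator, config: SimConfig) -> pd.DataFrame:
    n = config.n_individuals
    cov = pd.DataFrame(index=pd.RangeIndex(n, name="individual"))
    cov["sex"] = rng.integers(0, 2, size=n)
    age = rng.uniform(40.0, 70.0, size=n)
    cov["age"] = age
    cov["age2"] = age**2
    cov["array"] = rng.integers(0, config.n_arrays, size=n)
    for k in range(1, config.n_pcs + 1):
        cov[f"PC{k}"] = rng.standard_normal(n)
    return cov


def simulate_cohort(config: SimConfig) -> CohortData:
    """Simulate a diploid cohort under ``config``.

    Raises
    ------
    ValueError
        If the configuration is inconsistent (e.g. n_causal > n_variants;
        checked at SimConfig construction).
    """
    af_rng = substream(config.seed, "cohort.af")
    geno_rng = substream(config.seed, "cohort.genotypes")
    covar_rng = substream(config.seed, "cohort.covariates")
    noise_rng = substream(config.seed, "cohort.noise")
    causal_rng = substream(config.seed, "cohort.causal")

    if config.fixed_afs is not None:
        afs = np.asarray(config.fixed_afs, dtype=float)
    else:
        afs = _draw_afs(af_rng, config)
    variants = _place_variants(af_rng, config)
    variants["af"] = afs

    dosage = geno_rng.binomial(2, afs, size=(config.n_individuals, config.n_variants)).astype(np.int8)

    causal_idx = np.sort(causal_rng.choice(config.n_variants, size=config.n_causal, replace=False))
    is_causal = np.zeros(config.n_variants, dtype=bool)
    is_causal[causal_idx] = True
    beta = np.zeros(config.n_variants)
    beta[causal_idx] = np.asarray(config.effect_sizes, dtype=float)
    variants["is_causal"] = is_causal
    variants["beta"] = beta

    covariates = _simulate_covariates(covar_rng, config)

    genetic = np.zeros(config.n_individuals)
    for j in causal_idx:
        g = dosage[:, j].astype(float)
        sd = g.std()
        if sd > 0:
            genetic += beta[j] * (g - g.mean()) / sd

    cov_effect = (
        _COVARIATE_EFFECTS["sex"] * covariates["sex"].to_numpy()
        + _COVARIATE_EFFECTS["age_c"] * (covariates["age"].to_numpy() - 55.0)
        + _COVARIATE_EFFECTS["age2_c"] * (covariates["age2"].to_numpy() - 55.0**2) / 55.0
    )
    for k in range(1, config.n_pcs + 1):
        cov_effect += _PC_EFFECT * covariates[f"PC{k}"].to_numpy()

    phenotype = genetic + cov_effect + noise_rng.normal(0.0, config.noise_sd, size=config.n_individuals)

    return CohortData(
        dosage=dosage,
        phenotype=phenotype,
        covariates=covariates,
        variants=variants,
        config=config,
    )
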