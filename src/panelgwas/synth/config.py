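"""Configuration objects for the synthetic-data generators."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "AFLaw",
    "EnrichmentSpec",
    "PanelSpec",
    "SimConfig",
    "step_info_curve",
]


@dataclass(frozen=True)
class AFLaw:
    """Beta-shaped cohort allele-frequency law, truncated away from 0 and 1.

    Frequencies are drawn from Beta(alpha, beta) restricted to
    [1/(2N), 1 - 1/(2N)] so every variant is polymorphic in a cohort of N
    diploid individuals.
    """

    alpha: float = 0.5
    beta: float = 0.5

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("Beta shape parameters must be positive")


def step_info_curve(edges: Sequence[float], values: Sequence[float]) -> Callable[[np.ndarray], np.ndarray]:
    """Build a piecewise-constant INFO-vs-AF curve.

    ``edges`` are interior breakpoints on cohort AF; ``values`` has
    ``len(edges) + 1`` entries, one per bin. All values must lie in [0, 1].
    """
    edges = np.asarray(edges, dtype=float)
    values = np.asarray(values, dtype=float)
    if values.size != edges.size + 1:
        raise ValueError("need len(edges) + 1 INFO values")
    if np.any((values < 0) | (values > 1)):
        raise ValueError("target INFO outside [0, 1]")

    def curve(af: np.ndarray) -> np.ndarray:
        return values[np.digitize(np.asarray(af, dtype=float), edges)]

    return curve


@dataclass(frozen=True)
class PanelSpec:
    """One imputation panel: an INFO-vs-AF curve plus a variant dropout rule.

    ``info_curve`` maps a cohort-AF vector to per-variant target INFO in
    [0, 1].  ``dropout`` receives the variant-metadata table and returns a
    boolean mask of variants the panel does NOT contain (e.g. a global panel
    missing cohort-enriched rare variants); ``None`` keeps every variant.
    """

    panel_id: str
    info_curve: Callable[[np.ndarray], np.ndarray]
    dropout: Callable[["object"], np.ndarray] | None = None


def _default_fold_sampler(rng: np.random.Generator, size: int) -> np.ndarray:
    # folds comfortably above the x4 classification threshold
    return rng.uniform(5.0, 12.0, size=size)


@dataclass(frozen=True)
class EnrichmentSpec:
    """Planted founder-enrichment structure for the reference-population AF.

    ``fraction`` of variants (among those with cohort AF >= ``maf_min``) get
    a reference AF equal to cohort AF divided by a fold drawn from
    ``fold_sampler``; the rest drift by a log-normal factor of scale
    ``drift_sd`` on the log scale.
    """

    fraction: float = 0.0
    fold_sampler: Callable[[np.random.Generator, int], np.ndarray] = _default_fold_sampler
    maf_min: float = 0.001
    drift_sd: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("enrichment fraction must be in [0, 1]")
        if self.drift_sd < 0:
            raise ValueError("drift_sd must be non-negative")


@dataclass
class SimConfig:
    """Full synthetic-cohort configuration; ``seed`` determines everything."""

    n_individuals: int
    n_variants: int
    seed: int
    chrom_lengths: Mapping[str, int] = field(default_factory=lambda: {"chr1": 248_956_422})
    af_law: AFLaw = field(default_factory=AFLaw)
    n_causal: int = 0
    effect_sizes: Sequence[float] = ()
    noise_sd: float = 1.0
    panel_specs: Sequence[PanelSpec] = ()
    enrichment_spec: EnrichmentSpec = field(default_factory=EnrichmentSpec)
    n_arrays: int = 2
    n_pcs: int = 10
    fixed_afs: Sequence[float] | None = None  # overrides af_law when given

    def __post_init__(self) -> None:
        if self.fixed_afs is not None:
            if len(self.fixed_afs) != self.n_variants:
                raise ValueError("fixed_afs must have length n_variants")
            if any(not 0.0 < f < 1.0 for f in self.fixed_afs):
                raise ValueError("fixed AFs must lie in (0, 1)")
        if self.n_individuals <= 0 or self.n_variants <= 0:
            raise ValueError("counts must be positive")
        if self.n_causal < 0 or self.n_causal > self.n_variants:
            raise ValueError("n_causal must be in [0, n_variants]")
        if len(self.effect_sizes) != self.n_causal:
            raise ValueError("effect_sizes must have length n_causal")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not self.chrom_lengths:
            raise ValueError("chrom_lengths must be non-empty")
        if any(l <= 0 for l in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be positive")
        if self.n_arrays < 1:
            raise ValueError("n_arrays must be >= 1")
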