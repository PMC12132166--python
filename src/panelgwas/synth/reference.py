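"""Reference-population AF with a planted fraction of cohort-enriched variants."""

from __future__ import annotations

import numpy as np

from .._rng import substream
from .config import EnrichmentSpec

__all__ = ["simulate_reference_af"]

_AF_FLOOR = 1e-8


def simulate_reference_af(
    cohort_afs: np.ndarray,
    enrichment_spec: EnrichmentSpec,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate reference-population AFs with planted enrichment.

    A fraction of variants (chosen among those with cohort AF >= the spec's
    ``maf_min``, so they qualify for downstream classification) get reference
    AF = cohort AF / fold; the rest drift by a log-normal factor.  All
    frequencies are clipped to the open interval (0, 1).

    Returns
    -------
    (reference_af, planted_mask)
    """
    afs = np.asarray(cohort_afs, dtype=float)
    if np.any((afs <= 0) | (afs >= 1)):
        raise ValueError("cohort AFs must lie in (0, 1)")
    rng = substream(seed, "reference_af")
    m = afs.size

    n_enriched = int(round(enrichment_spec.fraction * m))
    eligible = np.flatnonzero(afs >= enrichment_spec.maf_min)
    if n_enriched > eligible.size:
        raise ValueError(
            f"cannot plant {n_enriched} enriched variants: only {eligible.size} "
            f"variants have cohort AF >= {enrichment_spec.maf_min}"
        )
    planted = np.zeros(m, dtype=bool)
    if n_enriched:
        planted[rng.choice(eligible, size=n_enriched, replace=False)] = True

    ref = afs * np.exp(rng.normal(0.0, enrichment_spec.drift_sd, size=m))
    if n_enriched:
        folds = np.asarray(enrichment_spec.fold_sampler(rng, n_enriched), dtype=float)
        if np.any(folds <= 0):
            raise ValueError("enrichment fold must be positive")
        ref[planted] = afs[planted] / folds
    ref = np.clip(ref, _AF_FLOOR, 1.0 - _AF_FLOOR)
    return ref, planted
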