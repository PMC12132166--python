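"""Imputed-panel simulation with AF-dependent quality and variant dropout.

Noise model: for a variant with true dosage g and target quality q, the
imputed dosage is ``mean(g) + sqrt(q) * (g - mean(g)) + eps`` with eps
Gaussian of variance ``(1 - q) * var(g)``, so the imputed dosage has the
same variance as the truth and corr^2(imputed, true) ~= q.  Dosages are
clipped to [0, 2].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .._rng import substream
from .cohort import CohortData
from .config import PanelSpec

__all__ = ["ImputedPanel", "make_meta_panel", "simulate_imputed_panels"]


@dataclass
class ImputedPanel:
    """One panel's imputation output over the cohort's variant set.

    ``present`` marks variants the panel contains; absent variants carry
    NaN dosages and NaN INFO.
    """

    panel_id: str
    present: np.ndarray
    dosage: np.ndarray
    info: np.ndarray

    def __post_init__(self) -> None:
        finite = self.info[self.present]
        if finite.size and (np.nanmin(finite) < 0 or np.nanmax(finite) > 1):
            raise ValueError("INFO outside [0, 1]")
        if not np.all(np.isnan(self.dosage[:, ~self.present])):
            raise ValueError("absent variants must have no dosages")


def _impute(rng: np.random.Generator, truth: np.ndarray, info: np.ndarray) -> np.ndarray:
    g = truth.astype(float)
    mean = g.mean(axis=0)
    var = g.var(axis=0)
    r = np.sqrt(info)
    eps = rng.standard_normal(g.shape) * np.sqrt((1.0 - info) * var)
    exact = info >= 1.0
    out = mean + r * (g - mean) + eps
    out[:, exact] = g[:, exact]
    return np.clip(out, 0.0, 2.0)


def simulate_imputed_panels(
    cohort: CohortData,
    panel_specs: Sequence[PanelSpec],
    seed: int | None = None,
) -> list[ImputedPanel]:
    """Simulate one ImputedPanel per spec from the cohort's true dosages.

    ``seed`` defaults to the cohort's own seed; each panel uses an
    independent substream keyed by its panel_id.
    """
    if seed is None:
        seed = cohort.config.seed
    af = cohort.variants["af"].to_numpy()
    panels: list[ImputedPanel] = []
    for spec in panel_specs:
        info = np.asarray(spec.info_curve(af), dtype=float)
        if np.any((info < 0) | (info > 1)):
            raise ValueError(f"panel {spec.panel_id!r}: target INFO outside [0, 1]")
        present = np.ones(cohort.n_variants, dtype=bool)
        if spec.dropout is not None:
            dropped = np.asarray(spec.dropout(cohort.variants), dtype=bool)
            if dropped.shape != present.shape:
                raise ValueError("dropout mask has wrong length")
            present = ~dropped
        rng = substream(seed, f"panels.{spec.panel_id}")
        dosage = _impute(rng, cohort.dosage, info)
        dosage[:, ~present] = np.nan
        info = info.copy()
        info[~present] = np.nan
        panels.append(ImputedPanel(panel_id=spec.panel_id, present=present, dosage=dosage, info=info))
    return panels


def make_meta_panel(panels: Sequence[ImputedPanel], panel_id: str = "meta") -> ImputedPanel:
    """Combine panels: per variant take dosages/INFO from the highest-INFO member.

    Presence is the union of member presence.  Ties go to the earliest panel
    in ``panels`` (by convention the local panel is listed first).  This is a
    deliberate simplification of weighted meta-imputation.
    """
    if not panels:
        raise ValueError("need at least one member panel")
    n, m = panels[0].dosage.shape
    present = np.zeros(m, dtype=bool)
    dosage = np.full((n, m), np.nan)
    info = np.full(m, np.nan)
    best = np.full(m, -np.inf)
    for panel in panels:
        cand = np.where(panel.present, panel.info, -np.inf)
        take = cand > best  # strict: ties keep the earlier panel
        best = np.where(take, cand, best)
        present |= panel.present
        dosage[:, take] = panel.dosage[:, take]
        info[take] = panel.info[take]
    return ImputedPanel(panel_id=panel_id, present=present, dosage=dosage, info=info)
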