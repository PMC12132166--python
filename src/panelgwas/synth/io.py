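"""Plain-text writers for the synthetic datasets.

Everything is emitted as uncompressed text: dosage matrix TSV or a minimal
VCF with a DS FORMAT field, phenotype/covariate TSV, variant metadata TSV,
genealogy Newick, SV BED-like TSV (0-based half-open) and a ground-truth
JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortData
from .genealogy import Genealogy
from .svs import SVCallset

__all__ = [
    "write_cohort",
    "write_dosage_tsv",
    "write_dosage_vcf",
    "write_genealogy",
    "write_sv_tsv",
]


def write_dosage_tsv(path: str | Path, dosage: np.ndarray, variants: pd.DataFrame) -> None:
    """Variants as rows (chrom, pos, ref, alt, then one column per individual)."""
    n = dosage.shape[0]
    out = variants[["chrom", "pos", "ref", "alt"]].copy()
    mat = pd.DataFrame(dosage.T, columns=[f"S{i}" for i in range(n)], index=out.index)
    pd.concat([out, mat], axis=1).to_csv(path, sep="\t", index=False, float_format="%.4g")


def write_dosage_vcf(path: str | Path, dosage: np.ndarray, variants: pd.DataFrame, info: np.ndarray | None = None) -> None:
    """Minimal VCF 4.2 with per-sample DS values (and optional INFO=R2)."""
    n = dosage.shape[0]
    samples = [f"S{i}" for i in range(n)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Imputed dosage">\n')
        fh.write('##INFO=<ID=R2,Number=1,Type=Float,Description="Imputation quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for j, row in enumerate(variants.itertuples(index=False)):
            info_field = "." if info is None or np.isnan(info[j]) else f"R2={info[j]:.4f}"
            ds = "\t".join(f"{dosage[i, j]:.3f}" for i in range(n))
            fh.write(f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t{info_field}\tDS\t{ds}\n")


def write_genealogy(path: str | Path, tree: Genealogy) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


def write_sv_tsv(path: str | Path, callset: SVCallset) -> None:
    callset.records.to_csv(path, sep="\t", index=False)


def write_cohort(out_dir: str | Path, cohort: CohortData, vcf: bool = False) -> dict[str, str]:
    """Write a full cohort to ``out_dir``; returns the map of written files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    if vcf:
        write_dosage_vcf(out / "dosages.vcf", cohort.dosage.astype(float), cohort.variants)
        files["dosages"] = str(out / "dosages.vcf")
    else:
        write_dosage_tsv(out / "dosages.tsv", cohort.dosage, cohort.variants)
        files["dosages"] = str(out / "dosages.tsv")

    pheno = cohort.covariates.copy()
    pheno.insert(0, "phenotype", cohort.phenotype)
    pheno.insert(0, "individual", [f"S{i}" for i in range(cohort.n_individuals)])
    pheno.to_csv(out / "phenotype.tsv", sep="\t", index=False)
    files["phenotype"] = str(out / "phenotype.tsv")

    cohort.variants.to_csv(out / "variants.tsv", sep="\t", index=False)
    files["variants"] = str(out / "variants.tsv")

    truth = {
        "seed": cohort.config.seed,
        "n_individuals": cohort.n_individuals,
        "n_variants": cohort.n_variants,
        "causal": [
            {"chrom": r.chrom, "pos": int(r.pos), "ref": r.ref, "alt": r.alt, "beta": float(r.beta)}
            for r in cohort.variants[cohort.variants["is_causal"]].itertuples(index=False)
        ],
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    files["truth"] = str(out / "truth.json")
    return files
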