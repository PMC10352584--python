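"""Plain-text I/O: count/metadata TSVs, minimal VCF v4.2 and truth JSON."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from haeseq.clinical import PatientRecord
from haeseq.normalize import CountMatrix
from haeseq.variants import VariantRecord


def write_counts(matrix: CountMatrix, counts_path, samples_path) -> None:
    matrix.counts.to_csv(counts_path, sep="\t", index_label="gene")
    matrix.samples.to_csv(samples_path, sep="\t", index_label="sample_id")


def read_counts(counts_path, samples_path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col="gene")
    samples = pd.read_csv(samples_path, sep="\t", index_col="sample_id")
    return CountMatrix(counts, samples)


_PATIENT_COLUMNS = [
    "patient_id",
    "role",
    "onset_age_years",
    "attacks_avg_5y",
    "attacks_max_year",
    "attacks_last_year",
    "ltp",
    "serping1_class",
    "family_id",
]


def write_patients(patients: Sequence[PatientRecord], path) -> None:
    rows = []
    for p in patients:
        rows.append(
            {
                "patient_id": p.patient_id,
                "role": p.role,
                "onset_age_years": "" if p.onset_age_years is None else p.onset_age_years,
                "attacks_avg_5y": "" if p.attacks_avg_5y is None else p.attacks_avg_5y,
                "attacks_max_year": "" if p.attacks_max_year is None else p.attacks_max_year,
                "attacks_last_year": "" if p.attacks_last_year is None else p.attacks_last_year,
                "ltp": int(p.ltp),
                "serping1_class": p.serping1_class,
                "family_id": p.family_id or "",
            }
        )
    pd.DataFrame(rows, columns=_PATIENT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_patients(path) -> list[PatientRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str, "family_id": str})

    def _opt(v, cast):
        return None if pd.isna(v) or v == "" else cast(v)

    out = []
    for _, row in df.iterrows():
        out.append(
            PatientRecord(
                patient_id=str(row["patient_id"]),
                role=str(row["role"]),
                onset_age_years=_opt(row.get("onset_age_years"), lambda x: int(float(x))),
                attacks_avg_5y=_opt(row.get("attacks_avg_5y"), float),
                attacks_max_year=_opt(row.get("attacks_max_year"), float),
                attacks_last_year=_opt(row.get("attacks_last_year"), float),
                ltp=bool(int(row.get("ltp", 0))),
                serping1_class=str(row.get("serping1_class", "none")),
                family_id=_opt(row.get("family_id"), str),
            )
        )
    return out


_GT = {0: "0/0", 1: "0/1", 2: "1/1", None: "./."}
_GT_INV = {"0/0": 0, "0/1": 1, "1/0": 1, "1/1": 2, "./.": None}


def write_variants_vcf(
    variants: Sequence[VariantRecord], vcf_path, individuals: Sequence[str]
) -> None:
    """Minimal VCF v4.2 (1-based positions, GT-only FORMAT)."""
    lines = [
        "##fileformat=VCFv4.2",
        "##source=haeseq-simulate",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    contigs = sorted({v.chrom for v in variants})
    for c in contigs:
        lines.append(f"##contig=<ID={c}>")
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    header += list(individuals)
    lines.append("\t".join(header))
    for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
        fields = [v.chrom, str(v.pos), ".", v.ref, v.alt, ".", "PASS", ".", "GT"]
        fields += [_GT[v.genotypes.get(i)] for i in individuals]
        lines.append("\t".join(fields))
    Path(vcf_path).write_text("\n".join(lines) + "\n")


def write_variant_annotations(variants: Sequence[VariantRecord], path) -> None:
    rows = [
        {
            "key": v.key,
            "gene": v.gene,
            "consequence": v.consequence,
            "cadd": v.cadd,
            "polyphen_hvar": v.polyphen_hvar,
            "polyphen_hdiv": v.polyphen_hdiv,
            "sift": v.sift,
            "population_frequency": (
                "" if v.population_frequency is None else v.population_frequency
            ),
        }
        for v in variants
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_variants(vcf_path, annotations_path) -> list[VariantRecord]:
    """Read a VCF (via pysam) plus the annotation TSV keyed chrom:pos:ref:alt."""
    import pysam

    ann = pd.read_csv(annotations_path, sep="\t", dtype={"key": str}).set_index("key")
    out = []
    with pysam.VariantFile(str(vcf_path)) as vf:
        individuals = list(vf.header.samples)
        for rec in vf:
            alt = rec.alts[0] if rec.alts else "."
            key = f"{rec.chrom}:{rec.pos}:{rec.ref}:{alt}"
            a = ann.loc[key]
            genotypes = {}
            for ind in individuals:
                gt = rec.samples[ind]["GT"]
                if gt is None or any(x is None for x in gt):
                    genotypes[ind] = None
                else:
                    genotypes[ind] = int(sum(gt))
            popf = a["population_frequency"]
            out.append(
                VariantRecord(
                    chrom=str(rec.chrom),
                    pos=int(rec.pos),
                    ref=str(rec.ref),
                    alt=str(alt),
                    gene=str(a["gene"]),
                    consequence=str(a["consequence"]),
                    cadd=float(a["cadd"]),
                    polyphen_hvar=str(a["polyphen_hvar"]),
                    polyphen_hdiv=str(a["polyphen_hdiv"]),
                    sift=str(a["sift"]),
                    population_frequency=None if pd.isna(popf) else float(popf),
                    genotypes=genotypes,
                )
            )
    return out


def write_truth(truth: dict, path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
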