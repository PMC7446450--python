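"""Readers and writers for the external formats the pipeline touches.

Supported inputs: VCF 4.2 with per-sample allelic depths (``AD``), flat
variant TSVs, long-form coverage TSVs (sample/gene/target/depth), clinical
CSVs, CADD annotation TSVs keyed by (chrom, pos, ref, alt), and GMT gene
sets.  TSVs are UTF-8 tab-separated with a header row; CSVs comma-separated.

Writers emit the same canonical flat formats so that every collection
round-trips field-for-field.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Dict, List, Set

import numpy as np
import pandas as pd
import pysam

from .records import (
    COVERAGE_COLUMNS,
    OUTCOME_COLUMNS,
    SAMPLE_COLUMNS,
    VARIANT_COLUMNS,
    Cohort,
    CoverageRecord,
    derive_responder,
)

_VARIANT_TSV_REQUIRED = ["patient_id", "sample_id", "chrom", "pos", "ref", "alt", "alt_count", "depth"]


def read_variant_calls(path, samples: pd.DataFrame) -> pd.DataFrame:
    """Read per-sample variant observations from a VCF or flat TSV.

    ``samples`` is the sample-metadata table; every sample column in the
    input must be present there (unknown sample ids are a hard error).
    Multi-allelic VCF records are decomposed into one observation per
    alternate allele; VAF is recomputed from the allelic counts.
    """
    path = Path(path)
    if path.suffix in (".vcf",) or str(path).endswith((".vcf.gz", ".vcf.bgz")):
        df = _read_vcf(path, samples)
    else:
        df = _read_variant_tsv(path, samples)
    df = df.sort_values(["patient_id", "sample_id", "chrom", "pos", "ref", "alt"]).reset_index(drop=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        df["vaf"] = np.where(df["depth"] > 0, df["alt_count"] / df["depth"], np.nan)
    return df[VARIANT_COLUMNS]


def _read_vcf(path, samples: pd.DataFrame) -> pd.DataFrame:
    sample_to_patient = dict(zip(samples["sample_id"], samples["patient_id"]))
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        unknown = [s for s in vcf.header.samples if s not in sample_to_patient]
        if unknown:
            raise ValueError(f"VCF samples not in sample metadata: {unknown}")
        for rec in vcf:
            gene = rec.info.get("GENE", "")
            if isinstance(gene, tuple):
                gene = gene[0]
            for sname in rec.samples:
                call = rec.samples[sname]
                ad = call.get("AD")
                if ad is None:
                    raise ValueError(
                        f"missing allelic depths (AD) at {rec.chrom}:{rec.pos} sample {sname}"
                    )
                if all(a is None for a in ad):
                    continue  # no-call: sample does not cover this record
                ad = [0 if a is None else int(a) for a in ad]
                depth = int(sum(ad))
                if depth == 0:
                    continue  # sample does not cover this record
                for i, alt in enumerate(rec.alts or ()):
                    rows.append(
                        (sample_to_patient[sname], sname, str(rec.chrom), int(rec.pos),
                         rec.ref, alt, ad[i + 1], depth, str(gene) if gene else "", np.nan, "")
                    )
    return pd.DataFrame(
        rows,
        columns=["patient_id", "sample_id", "chrom", "pos", "ref", "alt",
                 "alt_count", "depth", "gene", "cadd", "consequence"],
    )


def _read_variant_tsv(path, samples: pd.DataFrame) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    missing = [c for c in _VARIANT_TSV_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"variant TSV {path} is missing required columns: {missing}")
    unknown = set(df["sample_id"]) - set(samples["sample_id"])
    if unknown:
        raise ValueError(f"variant TSV references unknown samples: {sorted(unknown)}")
    for c in ("gene", "consequence"):
        df[c] = df[c].fillna("").astype(str) if c in df.columns else ""
    if "cadd" not in df.columns:
        df["cadd"] = np.nan
    return df


def write_variant_calls(variants: pd.DataFrame, path) -> None:
    variants[VARIANT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_coverage_table(path) -> pd.DataFrame:
    """Read a long-form per-target coverage TSV (sample_id, gene, target, depth).

    Duplicate (sample, gene, target) rows are a hard error; target ordering
    within a gene follows the ``target`` column.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "target": str})
    missing = [c for c in COVERAGE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"coverage TSV {path} is missing columns: {missing}")
    dup = df.duplicated(subset=["sample_id", "gene", "target"])
    if dup.any():
        raise ValueError(
            f"duplicate (sample, gene, target) rows in {path}: "
            f"{df.loc[dup, ['sample_id', 'gene', 'target']].values.tolist()[:5]}"
        )
    return df[COVERAGE_COLUMNS].sort_values(COVERAGE_COLUMNS[:3]).reset_index(drop=True)


def coverage_records(coverage: pd.DataFrame) -> List[CoverageRecord]:
    """Aggregate the long-form coverage table into per-(sample, gene) records."""
    recs = []
    for (sample_id, gene), grp in coverage.groupby(["sample_id", "gene"], sort=True):
        recs.append(CoverageRecord(sample_id, gene, tuple(grp.sort_values("target")["depth"])))
    return recs


def write_coverage_table(coverage: pd.DataFrame, path) -> None:
    coverage[COVERAGE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_clinical(path):
    """Read the clinical CSV into (samples, outcomes) tables.

    Required columns: patient_id, sample_id, material, timepoint_days, phase.
    Optional: ca125 (IU/mL), pfi_months (per patient; first non-missing wins).
    The responder truth label is derived, never read: poor iff PFI <= 12
    months, good iff PFI > 12, missing otherwise.
    """
    df = pd.read_csv(path)
    required = ["patient_id", "sample_id", "material", "timepoint_days", "phase"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"clinical CSV {path} is missing columns: {missing}")
    if "ca125" not in df.columns:
        df["ca125"] = np.nan
    samples = df[SAMPLE_COLUMNS].copy()
    samples["timepoint_days"] = samples["timepoint_days"].astype(int)

    if "pfi_months" in df.columns:
        pfi = df.groupby("patient_id")["pfi_months"].apply(
            lambda s: s.dropna().iloc[0] if s.notna().any() else np.nan
        )
    else:
        pfi = pd.Series(np.nan, index=sorted(df["patient_id"].unique()))
    outcomes = pd.DataFrame({
        "patient_id": pfi.index,
        "pfi_months": pfi.values,
    })
    outcomes["responder_truth"] = [derive_responder(x) for x in outcomes["pfi_months"]]

    no_germline = [
        p for p, grp in samples.groupby("patient_id") if "germline" not in set(grp["material"])
    ]
    if no_germline:
        warnings.warn(
            f"patients without a germline sample (somatic filtering will fail for them): {no_germline}"
        )
    return samples.reset_index(drop=True), outcomes.reset_index(drop=True)


def write_clinical(samples: pd.DataFrame, outcomes: pd.DataFrame, path) -> None:
    merged = samples.merge(outcomes[["patient_id", "pfi_months"]], on="patient_id", how="left")
    merged.to_csv(path, index=False)


def read_cadd(path) -> pd.DataFrame:
    """CADD annotation TSV keyed by (chrom, pos, ref, alt) with a ``cadd`` column."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    required = ["chrom", "pos", "ref", "alt", "cadd"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"CADD TSV {path} is missing columns: {missing}")
    return df[required]


def annotate_cadd(variants: pd.DataFrame, cadd: pd.DataFrame) -> pd.DataFrame:
    """Attach CADD scores by variant key; unannotated variants keep NaN."""
    out = variants.drop(columns=["cadd"], errors="ignore").merge(
        cadd.drop_duplicates(subset=["chrom", "pos", "ref", "alt"]),
        on=["chrom", "pos", "ref", "alt"], how="left",
    )
    if "vaf" not in out.columns:
        with np.errstate(invalid="ignore", divide="ignore"):
            out["vaf"] = np.where(out["depth"] > 0, out["alt_count"] / out["depth"], np.nan)
    return out[VARIANT_COLUMNS]


def read_gmt(path) -> Dict[str, Set[str]]:
    """Read GMT gene sets: name, description, then tab-separated gene symbols.

    Gene order is discarded and duplicates within a set collapse; duplicate
    set names are a hard error.
    """
    sets: Dict[str, Set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise ValueError(f"malformed GMT line {lineno} in {path}")
        name = parts[0]
        if name in sets:
            raise ValueError(f"duplicate gene-set name {name!r} at line {lineno} in {path}")
        genes = {g for g in parts[2:] if g}
        if not genes:
            warnings.warn(f"gene set {name!r} at line {lineno} is empty")
        sets[name] = genes
    return sets


def write_gmt(sets: Dict[str, Set[str]], path) -> None:
    lines = [f"{name}\t-\t" + "\t".join(sorted(genes)) for name, genes in sets.items()]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def ingest(vcf_or_tsv, clinical_csv, coverage_tsv=None, cadd_tsv=None) -> Cohort:
    """Assemble a :class:`Cohort` bundle from the raw input files."""
    samples, outcomes = read_clinical(clinical_csv)
    variants = read_variant_calls(vcf_or_tsv, samples)
    cadd = read_cadd(cadd_tsv) if cadd_tsv else None
    if cadd is not None:
        variants = annotate_cadd(variants, cadd)
    coverage = read_coverage_table(coverage_tsv) if coverage_tsv else pd.DataFrame(columns=COVERAGE_COLUMNS)
    return Cohort(variants=variants, samples=samples, coverage=coverage, outcomes=outcomes, cadd=cadd)
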