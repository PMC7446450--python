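"""Shared domain records and the in-memory cohort container.

All genomic coordinates are 1-based and fully closed (VCF convention)
throughout the package.  A variant is keyed by ``(chrom, pos, ref, alt)``;
:func:`variant_key` renders the canonical string form used in audit tables
and reports.

Bulk pipeline stages operate on :class:`pandas.DataFrame` tables with the
column layouts documented here; the frozen dataclasses are typed row views
for users who prefer records over frames.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

MATERIALS = ("plasma", "tissue", "germline")
PHASES = ("pretreatment", "on_treatment", "post_treatment", "follow_up", "progression")

#: Canonical column order for the long-form variant observation table.
VARIANT_COLUMNS = [
    "patient_id", "sample_id", "chrom", "pos", "ref", "alt",
    "alt_count", "depth", "vaf", "gene", "cadd", "consequence",
]

#: Canonical columns of the sample metadata table.
SAMPLE_COLUMNS = ["patient_id", "sample_id", "material", "timepoint_days", "phase", "ca125"]

#: Long-form coverage table: one row per sequencing target.
COVERAGE_COLUMNS = ["sample_id", "gene", "target", "depth"]

OUTCOME_COLUMNS = ["patient_id", "pfi_months", "responder_truth"]


def variant_key(chrom, pos, ref, alt) -> str:
    return f"{chrom}:{int(pos)}:{ref}:{alt}"


def add_key_column(variants: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of ``variants`` with a string ``key`` column."""
    out = variants.copy()
    out["key"] = (
        out["chrom"].astype(str) + ":" + out["pos"].astype(int).astype(str)
        + ":" + out["ref"].astype(str) + ":" + out["alt"].astype(str)
    )
    return out


@dataclass(frozen=True)
class VariantObservation:
    """One variant measured in one sample: the atomic unit of tracking."""

    patient_id: str
    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    alt_count: int
    depth: int
    gene: str = ""
    cadd: Optional[float] = None
    consequence: str = ""

    def __post_init__(self):
        if self.depth < 0 or not (0 <= self.alt_count <= self.depth):
            raise ValueError(
                f"invalid allelic counts at {self.key}: alt={self.alt_count} depth={self.depth}"
            )

    @property
    def key(self) -> str:
        return variant_key(self.chrom, self.pos, self.ref, self.alt)

    @property
    def vaf(self) -> float:
        """alt_count / depth; NaN (undefined, flagged) at zero depth."""
        return self.alt_count / self.depth if self.depth > 0 else float("nan")


@dataclass(frozen=True)
class SampleRecord:
    patient_id: str
    sample_id: str
    material: str
    timepoint_days: int
    phase: str
    ca125: Optional[float] = None

    def __post_init__(self):
        if self.material not in MATERIALS:
            raise ValueError(f"unknown material {self.material!r} for {self.sample_id}")
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r} for {self.sample_id}")


@dataclass(frozen=True)
class CoverageRecord:
    """Per-(sample, gene) panel coverage; mean_depth is always recomputed."""

    sample_id: str
    gene: str
    per_target_depth: tuple

    def __post_init__(self):
        if len(self.per_target_depth) < 1:
            raise ValueError(f"gene {self.gene} in {self.sample_id} has zero targets")

    @property
    def n_targets(self) -> int:
        return len(self.per_target_depth)

    @property
    def mean_depth(self) -> float:
        return float(np.mean(self.per_target_depth))


def derive_responder(pfi_months) -> Optional[str]:
    """PFI stratification: poor iff PFI <= 12 months, good iff > 12."""
    if pfi_months is None or (isinstance(pfi_months, float) and np.isnan(pfi_months)):
        return None
    return "poor" if pfi_months <= 12 else "good"


@dataclass(frozen=True)
class ClinicalOutcome:
    patient_id: str
    pfi_months: Optional[float] = None

    @property
    def responder_truth(self) -> Optional[str]:
        return derive_responder(self.pfi_months)


@dataclass
class Cohort:
    """Ingested study bundle: variants, samples, coverage, outcomes, CADD.

    ``variants`` holds raw per-sample observations (:data:`VARIANT_COLUMNS`),
    ``samples`` the clinical sample metadata, ``coverage`` the long-form
    per-target depths, ``outcomes`` one row per patient, and ``cadd`` an
    optional annotation table keyed by (chrom, pos, ref, alt).
    """

    variants: pd.DataFrame
    samples: pd.DataFrame
    coverage: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=COVERAGE_COLUMNS))
    outcomes: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=OUTCOME_COLUMNS))
    cadd: Optional[pd.DataFrame] = None

    def __post_init__(self):
        self.variants = _with_columns(self.variants, VARIANT_COLUMNS)
        self.samples = _with_columns(self.samples, SAMPLE_COLUMNS)
        self.coverage = _with_columns(self.coverage, COVERAGE_COLUMNS)
        self.outcomes = _with_columns(self.outcomes, OUTCOME_COLUMNS)
        self.validate()

    def validate(self) -> None:
        v = self.variants
        if len(v):
            if (v["depth"] < 0).any() or (v["alt_count"] > v["depth"]).any() or (v["alt_count"] < 0).any():
                bad = v[(v["alt_count"] > v["depth"]) | (v["alt_count"] < 0) | (v["depth"] < 0)]
                raise ValueError(f"invalid allelic counts in {len(bad)} variant rows")
            unknown = set(v["sample_id"]) - set(self.samples["sample_id"])
            if unknown:
                raise ValueError(f"variant rows reference unknown samples: {sorted(unknown)}")
        bad_mat = set(self.samples["material"]) - set(MATERIALS)
        if bad_mat:
            raise ValueError(f"unknown sample materials: {sorted(bad_mat)}")

    def patients(self) -> list:
        return sorted(self.samples["patient_id"].unique())

    def germline_sample(self, patient_id: str) -> Optional[str]:
        g = self.samples[
            (self.samples["patient_id"] == patient_id) & (self.samples["material"] == "germline")
        ]
        return None if g.empty else g["sample_id"].iloc[0]

    def plasma_samples(self, patient_id: str) -> pd.DataFrame:
        """Plasma samples of a patient, sorted by timepoint then sample_id."""
        s = self.samples[
            (self.samples["patient_id"] == patient_id) & (self.samples["material"] == "plasma")
        ]
        return s.sort_values(["timepoint_days", "sample_id"]).reset_index(drop=True)

    # -- serialization (single JSON bundle, the `ingest` output format) -----

    def to_json(self, path) -> None:
        payload = {
            "variants": self.variants.to_dict(orient="list"),
            "samples": self.samples.to_dict(orient="list"),
            "coverage": self.coverage.to_dict(orient="list"),
            "outcomes": self.outcomes.to_dict(orient="list"),
            "cadd": None if self.cadd is None else self.cadd.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload, default=_json_default))

    @classmethod
    def from_json(cls, path) -> "Cohort":
        payload = json.loads(Path(path).read_text())
        return cls(
            variants=pd.DataFrame(payload["variants"], columns=None if payload["variants"] else VARIANT_COLUMNS),
            samples=pd.DataFrame(payload["samples"], columns=None if payload["samples"] else SAMPLE_COLUMNS),
            coverage=pd.DataFrame(payload["coverage"], columns=None if payload["coverage"] else COVERAGE_COLUMNS),
            outcomes=pd.DataFrame(payload["outcomes"], columns=None if payload["outcomes"] else OUTCOME_COLUMNS),
            cadd=None if payload.get("cadd") is None else pd.DataFrame(payload["cadd"]),
        )


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _with_columns(df: pd.DataFrame, columns: Iterable[str]) -> pd.DataFrame:
    df = df.copy()
    for c in columns:
        if c not in df.columns:
            df[c] = np.nan if c in ("ca125", "cadd", "pfi_months", "vaf") else (
                "" if c in ("gene", "consequence", "responder_truth") else df.get(c)
            )
    if "vaf" in columns and len(df):
        # VAF is always recomputed from counts; any input vaf column is ignored.
        with np.errstate(invalid="ignore", divide="ignore"):
            df["vaf"] = np.where(df["depth"] > 0, df["alt_count"] / df["depth"], np.nan)
    return df
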