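"""Somatic filter chain for tracked ctDNA variants.

A variant is tracked for a patient when it
(1) shows at most background-level evidence in the patient's germline
    blood control (<= 2 alt reads, or VAF <= 0.001),
(2) reaches >= 1% VAF in at least one plasma or tumor-tissue sample,
(3) is not annotated as functionally irrelevant (CADD < 15; missing
    scores pass with a flag, since indels are often unscored), and
(4) is not a cross-patient artifact: an identical (chrom, pos, ref, alt)
    key recurring in >= 2 patients after the per-patient filters, outside
    the known-cancer whitelist, is removed from every patient.

All thresholds are inclusive on the keep side.  The chain emits an audit
table with one row per (patient, variant, rule).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import FrozenSet, List, Optional

import numpy as np
import pandas as pd

from .records import Cohort, add_key_column

RULE_GERMLINE = "germline_evidence"
RULE_DETECTION = "below_detection"
RULE_CADD = "low_cadd"
RULE_ARTIFACT = "cross_patient_artifact"

#: TP53 is mutated in essentially all HGSOC; true recurrences must survive
#: the cross-patient artifact rule.
DEFAULT_WHITELIST = frozenset({"TP53"})


@dataclass(frozen=True)
class FilterConfig:
    min_detection_vaf: float = 0.01
    germline_max_reads: int = 2
    germline_max_vaf: float = 0.001
    min_cadd: float = 15.0
    artifact_min_patients: int = 2
    whitelist: FrozenSet[str] = DEFAULT_WHITELIST
    strict_cadd: bool = False  # when True, a missing CADD score fails the filter

    def __post_init__(self):
        if not (0 < self.min_detection_vaf < 1):
            raise ValueError("min_detection_vaf must lie in (0, 1)")
        if min(self.germline_max_reads, self.germline_max_vaf, self.min_cadd,
               self.artifact_min_patients) < 0:
            raise ValueError("filter thresholds must be nonnegative")


@dataclass(frozen=True)
class FilterOutcome:
    patient_id: str
    key: str
    reasons: tuple = ()
    flags: tuple = ()

    @property
    def kept(self) -> bool:
        return not self.reasons


@dataclass
class FilterResult:
    """Output of :func:`run_filter_chain`."""

    tracked: pd.DataFrame          # kept observations (non-germline samples), with `key`
    audit: pd.DataFrame            # patient_id, key, rule, fired
    outcomes: List[FilterOutcome] = field(default_factory=list)
    warnings: List[str] = field(default_factory=list)

    def tracked_keys(self, patient_id: str) -> List[str]:
        t = self.tracked[self.tracked["patient_id"] == patient_id]
        return sorted(t["key"].unique())

    def n_tracked(self, patient_id: str) -> int:
        return len(self.tracked_keys(patient_id))


def _patient_variant_table(variants: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """One row per (patient, key) with germline evidence, max tumor VAF and CADD."""
    v = add_key_column(variants).merge(
        samples[["sample_id", "material"]], on="sample_id", how="left"
    )
    tumor = v[v["material"] != "germline"]
    agg = tumor.groupby(["patient_id", "key"], sort=True).agg(
        max_vaf=("vaf", "max"),
        gene=("gene", "first"),
        cadd=("cadd", "first"),
    ).reset_index()

    germ = v[v["material"] == "germline"].groupby(["patient_id", "key"]).agg(
        germline_alt=("alt_count", "sum"), germline_depth=("depth", "sum")
    ).reset_index()
    agg = agg.merge(germ, on=["patient_id", "key"], how="left")
    agg["germline_alt"] = agg["germline_alt"].fillna(0).astype(int)
    agg["germline_depth"] = agg["germline_depth"].fillna(0).astype(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        agg["germline_vaf"] = np.where(
            agg["germline_depth"] > 0, agg["germline_alt"] / agg["germline_depth"], 0.0
        )
    return agg


def germline_filter(table: pd.DataFrame, config: FilterConfig) -> pd.Series:
    """Pass iff germline alt reads <= max reads OR germline VAF <= max VAF."""
    return (table["germline_alt"] <= config.germline_max_reads) | (
        table["germline_vaf"] <= config.germline_max_vaf
    )


def detection_filter(table: pd.DataFrame, config: FilterConfig) -> pd.Series:
    """Pass iff max VAF over the patient's plasma/tissue samples >= threshold."""
    return table["max_vaf"] >= config.min_detection_vaf


def cadd_filter(table: pd.DataFrame, config: FilterConfig) -> pd.Series:
    """Fail iff CADD is present and < threshold; missing passes unless strict."""
    present = table["cadd"].notna()
    ok = ~present | (table["cadd"] >= config.min_cadd)
    if config.strict_cadd:
        ok &= present
    return ok


def cross_patient_artifact_filter(table: pd.DataFrame, kept: pd.Series,
                                  config: FilterConfig) -> pd.Series:
    """Pass unless the key recurs in >= N patients post-filter, off-whitelist.

    Operates on the cohort-wide per-(patient, key) table; ``kept`` marks rows
    surviving the per-patient rules.  A failing key is removed from *every*
    patient carrying it.
    """
    counts = table.loc[kept].groupby("key")["patient_id"].nunique()
    recurrent = set(counts[counts >= config.artifact_min_patients].index)
    whitelisted = table["gene"].isin(config.whitelist) | table["key"].isin(config.whitelist)
    return ~(table["key"].isin(recurrent) & ~whitelisted)


def run_filter_chain(cohort: Cohort, config: FilterConfig = FilterConfig()) -> FilterResult:
    """Apply germline, detection, CADD, then cross-patient artifact filters."""
    msgs: List[str] = []
    if cohort.variants.empty:
        empty = add_key_column(cohort.variants)
        return FilterResult(tracked=empty, audit=pd.DataFrame(columns=["patient_id", "key", "rule", "fired"]))

    v = add_key_column(cohort.variants).merge(
        cohort.samples[["sample_id", "material"]], on="sample_id", how="left"
    )
    patients_with_tumor = set(v.loc[v["material"] != "germline", "patient_id"])
    if not patients_with_tumor:
        msgs.append("cohort contains only germline samples; zero tracked variants")
        warnings.warn(msgs[-1])
        return FilterResult(
            tracked=v.iloc[0:0].drop(columns=["material"]),
            audit=pd.DataFrame(columns=["patient_id", "key", "rule", "fired"]),
            warnings=msgs,
        )
    no_germline = sorted(
        p for p in patients_with_tumor if cohort.germline_sample(p) is None
    )
    if no_germline:
        raise ValueError(f"no germline sample for patients: {no_germline}")

    table = _patient_variant_table(cohort.variants, cohort.samples)
    table = table[table["patient_id"].isin(patients_with_tumor)].reset_index(drop=True)

    pass_germ = germline_filter(table, config)
    pass_det = detection_filter(table, config)
    pass_cadd = cadd_filter(table, config)
    kept_stage1 = pass_germ & pass_det & pass_cadd
    pass_art = cross_patient_artifact_filter(table, kept_stage1, config)
    kept = kept_stage1 & pass_art

    audit = pd.concat([
        pd.DataFrame({"patient_id": table["patient_id"], "key": table["key"],
                      "rule": rule, "fired": ~ok.to_numpy()})
        for rule, ok in [(RULE_GERMLINE, pass_germ), (RULE_DETECTION, pass_det),
                         (RULE_CADD, pass_cadd), (RULE_ARTIFACT, pass_art)]
    ], ignore_index=True)

    outcomes = []
    fired_by = audit[audit["fired"]].groupby(["patient_id", "key"])["rule"].apply(tuple)
    missing_cadd = table["cadd"].isna()
    for row, keep_it, no_score in zip(table.itertuples(index=False), kept, missing_cadd):
        reasons = () if keep_it else fired_by.get((row.patient_id, row.key), ())
        flags = ("cadd_missing",) if no_score and not config.strict_cadd else ()
        outcomes.append(FilterOutcome(row.patient_id, row.key, reasons, flags))

    kept_pairs = table.loc[kept, ["patient_id", "key"]]
    tracked = v[v["material"] != "germline"].merge(kept_pairs, on=["patient_id", "key"])
    tracked = tracked.drop(columns=["material"]).reset_index(drop=True)
    return FilterResult(tracked=tracked, audit=audit, outcomes=outcomes, warnings=msgs)
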