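"""Knowledgebase matching and ESCAT-ranked actionability reporting.

Alterations that survived the somatic filter chain (mutations) or carry a
bootstrap-supported non-neutral call (CNAs) are matched against a flat
TSV knowledgebase of gene/alteration-class -> drug associations, each
annotated with an ESCAT tier.  ESCAT is a closed, totally ordered
vocabulary (I-A most actionable ... X); findings are ranked by tier, then
by supporting VAF.

The bundled ``data/knowledgebase.tsv`` is a small illustrative fixture
encoding well-known ovarian-cancer associations (ERBB2 amplification ->
trastuzumab, BRCA2/RAD51C loss -> PARP inhibitors, CDKN1B/CDKN2B loss ->
CDK4/6 inhibitors, ...); supply a curated knowledgebase for real use.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

ESCAT_TIERS = ["I-A", "I-B", "I-C", "II-A", "II-B", "III-A", "III-B", "IV", "V", "X"]
TIER_RANK: Dict[str, int] = {t: i for i, t in enumerate(ESCAT_TIERS)}

MUTATION_CLASSES = {"mutation_lof", "mutation_gof", "mutation_any"}
CNA_CLASSES = {"amplification", "deletion", "germline_deletion"}
ALTERATION_CLASSES = MUTATION_CLASSES | CNA_CLASSES
ASSOCIATIONS = {"sensitivity", "resistance"}

KB_COLUMNS = ["gene", "alteration_class", "variant_pattern", "drug",
              "association", "escat_tier", "evidence_note", "source"]


@dataclass(frozen=True)
class KnowledgebaseEntry:
    gene: str
    alteration_class: str
    drug: str
    association: str
    escat_tier: str
    variant_pattern: str = ""
    evidence_note: str = ""
    source: str = ""


def bundled_knowledgebase_path() -> Path:
    return Path(resources.files("ctdna_monitor").joinpath("data/knowledgebase.tsv"))


def load_knowledgebase(path=None) -> pd.DataFrame:
    """Load and validate the flat TSV knowledgebase (hard error, row-numbered)."""
    path = bundled_knowledgebase_path() if path is None else path
    kb = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in KB_COLUMNS if c not in kb.columns]
    if missing:
        raise ValueError(f"knowledgebase {path} is missing columns: {missing}")
    errors = []
    for i, row in kb.iterrows():
        rowno = i + 2  # header is line 1
        if not row["gene"]:
            errors.append(f"row {rowno}: empty gene")
        if row["alteration_class"] not in ALTERATION_CLASSES:
            errors.append(f"row {rowno}: unknown alteration_class {row['alteration_class']!r}")
        if row["association"] not in ASSOCIATIONS:
            errors.append(f"row {rowno}: unknown association {row['association']!r}")
        if row["escat_tier"] not in TIER_RANK:
            errors.append(f"row {rowno}: unknown ESCAT tier {row['escat_tier']!r}")
    if errors:
        raise ValueError("malformed knowledgebase rows:\n" + "\n".join(errors))
    return kb[KB_COLUMNS]


def match_alterations(mutations: pd.DataFrame, cna_calls: pd.DataFrame,
                      kb: pd.DataFrame) -> pd.DataFrame:
    """Match patient alterations against the knowledgebase.

    ``mutations``: one row per tracked (patient, variant) with columns
    patient_id, key, gene, max_vaf and optional consequence (matched
    exactly against ``variant_pattern`` when the entry carries one).
    ``cna_calls``: patient_id, gene, call (amp/del), optional is_germline
    and log2_ratio.  Matching is deterministic and order-invariant; adding
    knowledgebase entries never removes findings.
    """
    findings: List[dict] = []

    if len(mutations):
        mut_kb = kb[kb["alteration_class"].isin(MUTATION_CLASSES)]
        for m in mutations.sort_values(["patient_id", "key"]).itertuples(index=False):
            hits = mut_kb[mut_kb["gene"] == m.gene]
            patterned = hits["variant_pattern"] != ""
            consequence = getattr(m, "consequence", "") or ""
            hits = hits[~patterned | (hits["variant_pattern"] == consequence)]
            for e in hits.itertuples(index=False):
                findings.append(_finding(m.patient_id, "mutation", m.key, m.gene, e,
                                         evidence=float(getattr(m, "max_vaf", np.nan)),
                                         high_confidence=True))

    if len(cna_calls):
        direction_class = {"amp": {"amplification"}, "del": {"deletion", "germline_deletion"}}
        cna_kb = kb[kb["alteration_class"].isin(CNA_CLASSES)]
        for c in cna_calls.sort_values(["patient_id", "gene"]).itertuples(index=False):
            if c.call not in direction_class:
                continue
            classes = direction_class[c.call]
            is_germline = bool(getattr(c, "is_germline", False))
            hits = cna_kb[(cna_kb["gene"] == c.gene) & cna_kb["alteration_class"].isin(classes)]
            for e in hits.itertuples(index=False):
                if e.alteration_class == "germline_deletion" and not is_germline:
                    continue
                findings.append(_finding(
                    c.patient_id, "cna", f"{c.gene}:{c.call}", c.gene, e,
                    evidence=float(getattr(c, "log2_ratio", np.nan)),
                    high_confidence=True,
                ))

    cols = ["patient_id", "alteration_type", "alteration", "gene", "drug", "association",
            "escat_tier", "tier_rank", "evidence", "high_confidence"]
    return pd.DataFrame(findings, columns=cols)


def _finding(patient_id, alteration_type, alteration, gene, entry, evidence, high_confidence):
    return {
        "patient_id": patient_id, "alteration_type": alteration_type,
        "alteration": alteration, "gene": gene, "drug": entry.drug,
        "association": entry.association, "escat_tier": entry.escat_tier,
        "tier_rank": TIER_RANK[entry.escat_tier], "evidence": evidence,
        "high_confidence": high_confidence,
    }


def rank_findings(findings: pd.DataFrame) -> pd.DataFrame:
    """Order findings by ESCAT tier, then supporting evidence (VAF) descending."""
    if findings.empty:
        return findings
    return findings.sort_values(
        ["patient_id", "tier_rank", "evidence", "gene"],
        ascending=[True, True, False, True],
    ).reset_index(drop=True)


def best_tier(findings: pd.DataFrame, patient_id: str) -> Optional[str]:
    f = findings[findings["patient_id"] == patient_id]
    if f.empty:
        return None
    return ESCAT_TIERS[int(f["tier_rank"].min())]


def cohort_actionability_summary(findings: pd.DataFrame, cohort_size: int) -> int:
    """Percent of patients with >= 1 high-confidence finding (integer-rounded)."""
    if cohort_size <= 0:
        raise ValueError("cohort size must be positive")
    if findings.empty:
        return 0
    n = findings.loc[findings["high_confidence"], "patient_id"].nunique()
    return int(round(100.0 * n / cohort_size))
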