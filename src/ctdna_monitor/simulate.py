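"""Synthetic longitudinal ctDNA cohorts and deterministic worked fixtures.

The generator emulates a 12-patient HGSOC study design: per patient one
germline blood control and one pretreatment tumor tissue at 200x, six
longitudinal plasma samples at 1000x on a ~500-gene panel, six cycles of
platinum-taxane chemotherapy starting at day 0 (one cycle / 21 days).

Clone model.  Each patient carries a truncal TP53 clone (cellular
fraction 1) plus subclones with cellular fractions CF_i.  A variant's
expected VAF in a sample is::

    VAF = 0.5 * f_material * CF_i * decay_i ** cycles(t)

(heterozygous variants, so allele dosage 0.5; ``f_material`` is the
sample-type tumor fraction).  Good responders' clones decay at 0.1/cycle.
Poor responders are a mixture capturing chemoresistance: the truncal
clone and 40% of subclones decay at 0.8/cycle while the remaining
subclones persist (multiplier 1.0), and the truncal clone rebounds at the
progression sample.  Observed alt counts are Binomial(depth, VAF);
germline controls see Binomial(depth, 3e-4) contamination at somatic
sites.  Cross-patient artifacts are planted at identical keys in four
patients with expected VAF ~ Uniform(0.005, 0.02).  Per-gene target
depths are negative binomial with mean scaled by the copy-number mixture
(f*c + 2(1-f))/2.

The cohort *structure* (patients, clones, CF values, artifact keys, CNA
events, responder labels) comes from a fixed internal layout; the
sampling ``seed`` only redraws read counts, so truth tables are identical
across seeds.  The two ``emit_fixture_*`` bundles are fully deterministic
tables (nothing sampled) anchoring the worked examples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import io as cio
from .records import (
    COVERAGE_COLUMNS, OUTCOME_COLUMNS, SAMPLE_COLUMNS, VARIANT_COLUMNS,
    Cohort, derive_responder, variant_key,
)

_LAYOUT_SEED = 20190503  # fixed: layout is independent of the sampling seed

CHROMATIN_GENES = ("KMT2A", "KMT2B", "KMT2D", "KDM5A", "SUZ12", "SMARCD1", "SMARCA4")
ACTIONABLE_MUTATION_GENES = {"P01": "PTEN", "P02": "NF1", "P07": "BRCA2", "P08": "ERBB4"}
ACTIONABLE_AMP_GENES = {"P03": "PIK3CA", "P09": "ERBB2", "P10": "MAPK1"}

CYCLE_DAYS = 21
N_CYCLES = 6


def cycles_completed(day: float) -> int:
    """Chemotherapy cycles completed by day t (cycle 1 starts day 0)."""
    return int(np.clip(math.floor(day / CYCLE_DAYS), 0, N_CYCLES))


def expected_vaf(initial_vaf: float, decay: float, cycles: int) -> float:
    """Closed-form expected VAF after a number of chemotherapy cycles."""
    return initial_vaf * decay ** cycles


@dataclass(frozen=True)
class CloneSpec:
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    cellular_fraction: float
    decay: float
    truncal: bool = False

    @property
    def key(self) -> str:
        return variant_key(self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class PatientSpec:
    patient_id: str
    responder: str                      # truth label: good | poor
    pfi_months: float
    f_plasma0: float                    # pretreatment plasma tumor fraction
    f_tissue: float
    clones: Tuple[CloneSpec, ...]
    cna_events: Tuple[Tuple[str, int], ...] = ()   # (gene, copies)


@dataclass(frozen=True)
class ArtifactSpec:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    vaf: float
    patients: Tuple[str, ...]

    @property
    def key(self) -> str:
        return variant_key(self.chrom, self.pos, self.ref, self.alt)


@dataclass
class SimulationConfig:
    n_patients: int = 12
    n_good: int = 6
    panel_genes: int = 500
    plasma_depth: int = 1000
    tissue_depth: int = 200
    germline_depth: int = 200
    n_timepoints: int = 6
    good_decay: float = 0.1
    poor_decay: float = 0.8
    poor_persistent_fraction: float = 0.6  # share of poor subclones with multiplier 1.0
    progression_rebound: float = 0.8       # truncal factor floor at progression (poor)
    germline_error: float = 3e-4
    n_artifacts: int = 8
    artifact_patients_each: int = 4
    artifact_vaf_range: Tuple[float, float] = (0.005, 0.02)
    coverage_dispersion: float = 200.0     # negative-binomial size parameter
    targets_per_gene: Tuple[int, int] = (5, 12)
    ca125_base: float = 30.0
    ca125_slope: float = 8.0               # log-linear: ln CA125 = ln base + slope * f
    ca125_sd: float = 0.25
    include_coverage: bool = True
    patients: Optional[Tuple[PatientSpec, ...]] = None   # override the default layout
    artifacts: Optional[Tuple[ArtifactSpec, ...]] = None

    def validate(self) -> None:
        if self.n_patients < 1 or not (0 <= self.n_good <= self.n_patients):
            raise ValueError("invalid patient counts")
        if min(self.plasma_depth, self.tissue_depth, self.germline_depth) <= 0:
            raise ValueError("depths must be positive")
        for d in (self.good_decay, self.poor_decay):
            if not (0 < d <= 1):
                raise ValueError("decay multipliers must lie in (0, 1]")
        if self.n_timepoints < 2:
            raise ValueError("need at least pretreatment plus one later timepoint")
        lo, hi = self.artifact_vaf_range
        if not (0 < lo <= hi < 1):
            raise ValueError("artifact VAF range must lie in (0, 1)")


@dataclass
class Truth:
    """Generator ground truth, consistent with the bundle by construction."""

    patients: pd.DataFrame          # patient_id, responder, pfi_months, f_plasma0, f_tissue
    clones: pd.DataFrame            # patient_id, key, gene, cellular_fraction, decay, truncal
    artifacts: pd.DataFrame         # key, gene, vaf, patient_id (one row per planting)
    sample_fractions: pd.DataFrame  # sample_id, tumor_fraction
    copy_states: pd.DataFrame       # patient_id, gene, copies


@dataclass
class CohortBundle:
    cohort: Cohort
    truth: Truth

    def write(self, outdir) -> None:
        """Emit the bundle in the standard flat formats."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cio.write_variant_calls(self.cohort.variants, outdir / "variants.tsv")
        cio.write_clinical(self.cohort.samples, self.cohort.outcomes, outdir / "clinical.csv")
        cio.write_coverage_table(self.cohort.coverage, outdir / "coverage.tsv")
        if self.cohort.cadd is not None:
            self.cohort.cadd.to_csv(outdir / "cadd.tsv", sep="\t", index=False)
        for name in ("patients", "clones", "artifacts", "sample_fractions", "copy_states"):
            getattr(self.truth, name).to_csv(outdir / f"truth_{name}.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# deterministic layout

def panel_gene_list(n: int) -> List[str]:
    named = ["TP53", *CHROMATIN_GENES,
             *sorted(set(ACTIONABLE_MUTATION_GENES.values())),
             *sorted(set(ACTIONABLE_AMP_GENES.values()))]
    fillers = [f"GENE{i:04d}" for i in range(1, n - len(named) + 1)]
    return (named + fillers)[:n]


def _gene_locus(genes: List[str]) -> Dict[str, Tuple[str, int]]:
    return {g: (str(i % 22 + 1), 1_000_000 + 10_000 * i) for i, g in enumerate(genes)}


_BASES = [("A", "T"), ("C", "T"), ("G", "A"), ("T", "C"), ("G", "T"), ("C", "G")]


def default_layout(config: SimulationConfig) -> Tuple[Tuple[PatientSpec, ...], Tuple[ArtifactSpec, ...]]:
    """Build the fixed cohort structure (independent of the sampling seed)."""
    rng = np.random.default_rng(_LAYOUT_SEED)
    genes = panel_gene_list(config.panel_genes)
    locus = _gene_locus(genes)
    filler = [g for g in genes if g.startswith("GENE")]

    n_mut = {"good": [6, 7, 8, 9, 10, 12], "poor": [18, 22, 26, 30, 34, 40]}
    patients: List[PatientSpec] = []
    filler_cursor = 0
    for idx in range(config.n_patients):
        pid = f"P{idx + 1:02d}"
        good = idx < config.n_good
        resp = "good" if good else "poor"
        pfi = float([14, 16, 18, 20, 24, 30][idx % 6]) if good else float([3, 4, 5, 8, 10, 12][idx % 6])
        f0 = float(rng.uniform(0.2, 0.35))
        f_tissue = float(rng.uniform(0.3, 0.7))
        total = n_mut[resp][idx % 6]

        clones: List[CloneSpec] = [CloneSpec(
            "TP53", locus["TP53"][0], locus["TP53"][1] + idx, *_BASES[idx % 6],
            cellular_fraction=1.0,
            decay=config.good_decay if good else config.poor_decay,
            truncal=True,
        )]
        sub_genes: List[str] = []
        if pid in ACTIONABLE_MUTATION_GENES:
            sub_genes.append(ACTIONABLE_MUTATION_GENES[pid])
        if not good:
            sub_genes += [CHROMATIN_GENES[(2 * idx) % 7], CHROMATIN_GENES[(2 * idx + 1) % 7]]
        while len(sub_genes) < total - 1:
            sub_genes.append(filler[filler_cursor % len(filler)])
            filler_cursor += 1
        n_sub = len(sub_genes)
        n_persistent = int(round(config.poor_persistent_fraction * n_sub)) if not good else 0
        for j, gene in enumerate(sub_genes):
            if good:
                cf, decay = float(rng.uniform(0.12, 0.9)), config.good_decay
            else:
                cf = float(rng.uniform(0.05, 0.6))
                # chromatin/actionable subclones persist first: the resistant population
                decay = 1.0 if j < n_persistent else config.poor_decay
            chrom, base = locus[gene]
            ref, alt = _BASES[(idx + j) % 6]
            clones.append(CloneSpec(gene, chrom, base + idx, ref, alt, cf, decay))

        events: List[Tuple[str, int]] = []
        if pid in ACTIONABLE_AMP_GENES:
            events.append((ACTIONABLE_AMP_GENES[pid], 8))
        events.append((filler[(137 * (idx + 1)) % len(filler)], 8))
        if idx % 3 == 0:
            events.append((filler[(211 * (idx + 1)) % len(filler)], 0))  # homozygous loss
        # keep events unique by gene
        seen, uniq = set(), []
        for g, c in events:
            if g not in seen:
                uniq.append((g, c))
                seen.add(g)
        patients.append(PatientSpec(pid, resp, pfi, f0, f_tissue, tuple(clones), tuple(uniq)))

    artifacts: List[ArtifactSpec] = []
    ids = [p.patient_id for p in patients]
    for a in range(config.n_artifacts):
        gene = filler[(31 * (a + 3)) % len(filler)]
        chrom, base = locus[gene]
        carriers = tuple(ids[(a + k) % len(ids)] for k in range(config.artifact_patients_each))
        vaf = float(rng.uniform(*config.artifact_vaf_range))
        ref, alt = _BASES[a % 6]
        artifacts.append(ArtifactSpec(chrom, base + 999, ref, alt, gene, vaf, carriers))
    return tuple(patients), tuple(artifacts)


# ---------------------------------------------------------------------------
# sampling

def _timepoints(config: SimulationConfig, responder: str) -> List[Tuple[int, str]]:
    days = [-7, 21, 63, 126, 250, 360]
    while len(days) < config.n_timepoints:
        days.append(days[-1] + 110)
    days = days[:config.n_timepoints]
    out = []
    for i, d in enumerate(days):
        if d < 0:
            phase = "pretreatment"
        elif d <= CYCLE_DAYS * (N_CYCLES - 1):
            phase = "on_treatment"
        elif i < len(days) - 1:
            phase = "post_treatment" if d <= 200 else "follow_up"
        else:
            phase = "progression" if responder == "poor" else "follow_up"
        out.append((d, phase))
    return out


def _clone_factor(clone: CloneSpec, day: int, phase: str, responder: str,
                  config: SimulationConfig) -> float:
    factor = clone.decay ** cycles_completed(day)
    if clone.truncal and responder == "poor" and phase == "progression":
        factor = max(factor, config.progression_rebound)
    return factor


def simulate_cohort(config: SimulationConfig = SimulationConfig(), seed: int = 0) -> CohortBundle:
    """Draw one synthetic cohort bundle under the configured study design."""
    config.validate()
    patients, artifacts = (config.patients, config.artifacts)
    if patients is None:
        patients, default_arts = default_layout(config)
        artifacts = default_arts if config.artifacts is None else config.artifacts
    artifacts = artifacts or ()
    rng = np.random.default_rng(np.random.SeedSequence(int(seed) & 0x7FFFFFFF))

    genes = panel_gene_list(config.panel_genes)
    sample_rows, variant_rows, fraction_rows = [], [], []
    artifact_by_patient: Dict[str, List[ArtifactSpec]] = {}
    for art in artifacts:
        for pid in art.patients:
            artifact_by_patient.setdefault(pid, []).append(art)

    for spec in patients:
        pid = spec.patient_id
        timepoints = _timepoints(config, spec.responder)
        samples = [(f"{pid}-BC", "germline", -14, "pretreatment", config.germline_depth),
                   (f"{pid}-T1", "tissue", -10, "pretreatment", config.tissue_depth)]
        samples += [(f"{pid}-PL{i + 1}", "plasma", day, phase, config.plasma_depth)
                    for i, (day, phase) in enumerate(timepoints)]

        for sid, material, day, phase, depth in samples:
            if material == "plasma":
                # without a truncal clone the tumor fraction has no decay model
                # and stays at its pretreatment value
                truncal = next((c for c in spec.clones if c.truncal), None)
                t_factor = (_clone_factor(truncal, day, phase, spec.responder, config)
                            if truncal else 1.0)
                f_sample = spec.f_plasma0 * t_factor
            elif material == "tissue":
                f_sample = spec.f_tissue
            else:
                f_sample = 0.0
            ca125 = np.nan
            if material == "plasma":
                ca125 = float(np.round(np.exp(
                    np.log(config.ca125_base) + config.ca125_slope * f_sample
                    + rng.normal(0.0, config.ca125_sd)), 1))
            sample_rows.append((pid, sid, material, day, phase, ca125))
            fraction_rows.append((sid, f_sample))

            sites: List[Tuple[str, int, str, str, str, float]] = []
            for c in spec.clones:
                if material == "germline":
                    ev = config.germline_error
                else:
                    f_mat = spec.f_plasma0 if material == "plasma" else spec.f_tissue
                    ev = 0.5 * f_mat * c.cellular_fraction * _clone_factor(
                        c, day if material == "plasma" else -7, phase, spec.responder, config)
                sites.append((c.chrom, c.pos, c.ref, c.alt, c.gene, min(ev, 0.999)))
            for art in artifact_by_patient.get(pid, []):
                ev = config.germline_error if material == "germline" else art.vaf
                sites.append((art.chrom, art.pos, art.ref, art.alt, art.gene, ev))
            if sites:
                probs = np.array([s[5] for s in sites])
                alts = rng.binomial(depth, probs)
                for (chrom, pos, ref, alt, gene, _), ac in zip(sites, alts):
                    if ac > 0:
                        variant_rows.append((pid, sid, chrom, pos, ref, alt,
                                             int(ac), depth, gene, np.nan, ""))

    samples_df = pd.DataFrame(sample_rows, columns=SAMPLE_COLUMNS)
    variants_df = pd.DataFrame(variant_rows, columns=[
        "patient_id", "sample_id", "chrom", "pos", "ref", "alt",
        "alt_count", "depth", "gene", "cadd", "consequence"])

    # CADD annotation: true somatics in [15, 40); artifacts scored 25 so that
    # the cross-patient rule, not the CADD rule, is what removes them.
    cadd_rng = np.random.default_rng(_LAYOUT_SEED + 1)
    cadd_rows = []
    for spec in patients:
        for c in spec.clones:
            cadd_rows.append((c.chrom, c.pos, c.ref, c.alt, float(np.round(cadd_rng.uniform(15, 40), 1))))
    for art in artifacts:
        cadd_rows.append((art.chrom, art.pos, art.ref, art.alt, 25.0))
    cadd_df = pd.DataFrame(cadd_rows, columns=["chrom", "pos", "ref", "alt", "cadd"]).drop_duplicates(
        subset=["chrom", "pos", "ref", "alt"])
    variants_df = cio.annotate_cadd(variants_df, cadd_df) if len(variants_df) else variants_df

    coverage_df = (_simulate_coverage(patients, samples_df, dict(fraction_rows), genes, config, rng)
                   if config.include_coverage else pd.DataFrame(columns=COVERAGE_COLUMNS))

    outcomes = pd.DataFrame({
        "patient_id": [p.patient_id for p in patients],
        "pfi_months": [p.pfi_months for p in patients],
    })
    outcomes["responder_truth"] = [derive_responder(x) for x in outcomes["pfi_months"]]

    cohort = Cohort(variants=variants_df, samples=samples_df, coverage=coverage_df,
                    outcomes=outcomes, cadd=cadd_df)
    truth = Truth(
        patients=pd.DataFrame([(p.patient_id, p.responder, p.pfi_months, p.f_plasma0, p.f_tissue)
                               for p in patients],
                              columns=["patient_id", "responder", "pfi_months", "f_plasma0", "f_tissue"]),
        clones=pd.DataFrame([(p.patient_id, c.key, c.gene, c.cellular_fraction, c.decay, c.truncal)
                             for p in patients for c in p.clones],
                            columns=["patient_id", "key", "gene", "cellular_fraction", "decay", "truncal"]),
        artifacts=pd.DataFrame([(a.key, a.gene, a.vaf, pid)
                                for a in artifacts for pid in a.patients],
                               columns=["key", "gene", "vaf", "patient_id"]),
        sample_fractions=pd.DataFrame(fraction_rows, columns=["sample_id", "tumor_fraction"]),
        copy_states=pd.DataFrame([(p.patient_id, g, c) for p in patients for g, c in p.cna_events],
                                 columns=["patient_id", "gene", "copies"]),
    )
    bundle = CohortBundle(cohort=cohort, truth=truth)
    audit_truth(bundle)
    return bundle


def _simulate_coverage(patients, samples_df, fractions, genes, config, rng) -> pd.DataFrame:
    nt_rng = np.random.default_rng(_LAYOUT_SEED + 2)
    lo, hi = config.targets_per_gene
    n_targets = nt_rng.integers(lo, hi + 1, size=len(genes))
    gene_of_target = np.repeat(np.arange(len(genes)), n_targets)
    target_idx = np.concatenate([np.arange(n) for n in n_targets])
    copies_by_patient = {p.patient_id: dict(p.cna_events) for p in patients}
    base_depth = {"plasma": config.plasma_depth, "tissue": config.tissue_depth,
                  "germline": config.germline_depth}
    gene_arr = np.array(genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    target_names = np.array([f"t{j:02d}" for j in range(int(n_targets.max()))])

    means, sample_ids = [], []
    for row in samples_df.itertuples(index=False):
        f = 0.0 if row.material == "germline" else fractions[row.sample_id]
        c = np.full(len(genes), 2.0)
        for g, cc in copies_by_patient.get(row.patient_id, {}).items():
            c[gene_index[g]] = cc
        scale = (f * c + 2.0 * (1.0 - f)) / 2.0
        means.append(base_depth[row.material] * scale[gene_of_target])
        sample_ids.append(row.sample_id)
    mean = np.concatenate(means)
    r = config.coverage_dispersion
    depth = rng.negative_binomial(r, r / (r + mean))
    n_t = len(gene_of_target)
    return pd.DataFrame({
        "sample_id": np.repeat(np.array(sample_ids), n_t),
        "gene": np.tile(gene_arr[gene_of_target], len(sample_ids)),
        "target": np.tile(target_names[target_idx], len(sample_ids)),
        "depth": depth,
    })


def audit_truth(bundle: CohortBundle) -> None:
    """Assert the truth tables are consistent with the generated bundle."""
    v, t = bundle.cohort.variants, bundle.truth
    if len(v) and ((v["alt_count"] > v["depth"]).any() or (v["alt_count"] < 0).any()):
        raise AssertionError("sampled counts exceed depths")
    planted = set(t.clones["key"]) | set(t.artifacts["key"])
    if len(v):
        observed = {variant_key(c, p, r, a)
                    for c, p, r, a in zip(v["chrom"], v["pos"], v["ref"], v["alt"])}
        stray = observed - planted
        if stray:
            raise AssertionError(f"observed variants not in truth tables: {sorted(stray)[:5]}")
    dup = t.clones.duplicated(subset=["patient_id", "key"])
    if dup.any():
        raise AssertionError("duplicate clone keys within a patient")
    counts = t.artifacts.groupby("key")["patient_id"].nunique()
    if len(counts) and (counts < 2).any():
        raise AssertionError("artifact planted in fewer than 2 patients")
    known = set(bundle.cohort.samples["sample_id"])
    if set(t.sample_fractions["sample_id"]) != known:
        raise AssertionError("sample_fractions does not cover the samples")


# ---------------------------------------------------------------------------
# deterministic worked-example fixtures

def _fixture_frames(samples, variants, cadd_rows, outcomes, coverage=None):
    samples_df = pd.DataFrame(samples, columns=SAMPLE_COLUMNS)
    variants_df = pd.DataFrame(variants, columns=[
        "patient_id", "sample_id", "chrom", "pos", "ref", "alt",
        "alt_count", "depth", "gene", "cadd", "consequence"])
    cadd_df = pd.DataFrame(cadd_rows, columns=["chrom", "pos", "ref", "alt", "cadd"])
    variants_df = cio.annotate_cadd(variants_df, cadd_df)
    outcomes_df = pd.DataFrame(outcomes, columns=["patient_id", "pfi_months"])
    outcomes_df["responder_truth"] = [derive_responder(x) for x in outcomes_df["pfi_months"]]
    coverage_df = coverage if coverage is not None else pd.DataFrame(columns=COVERAGE_COLUMNS)
    return Cohort(variants=variants_df, samples=samples_df, coverage=coverage_df,
                  outcomes=outcomes_df, cadd=cadd_df)


def emit_fixture_eoc429() -> CohortBundle:
    """Good responder with eight tracked mutations plus one decoy per filter rule.

    TP53 declines from 34.6% (346/1000) pretreatment to 0.4% (4/1000) after
    the last chemotherapy cycle; NF1 is at 34% before and 5.4% after primary
    debulking surgery.  Decoys: germline evidence (10/200 alt reads in the
    blood control), CADD 12, a cross-patient artifact shared with a second
    patient, and a variant never reaching 1% VAF.
    """
    P = "EOC429"
    samples = [
        (P, f"{P}-BC", "germline", -14, "pretreatment", np.nan),
        (P, f"{P}-T1", "tissue", -10, "pretreatment", np.nan),
        (P, f"{P}-PL1", "plasma", -7, "pretreatment", 600.0),
        (P, f"{P}-PL2", "plasma", 42, "on_treatment", 50.0),
        (P, f"{P}-PL3", "plasma", 140, "post_treatment", 12.0),
        ("EOC000", "EOC000-BC", "germline", -14, "pretreatment", np.nan),
        ("EOC000", "EOC000-PL1", "plasma", -7, "pretreatment", np.nan),
    ]
    # gene, chrom, pos, ref, alt, tissue alt/200, plasma alts /1000, CADD
    true_somatics = [
        ("TP53",   "17", 7577538, "C", "T", 90, (346, 30, 4), 32.0),
        ("NF1",    "17", 29588751, "C", "T", 80, (340, 54, 0), 35.0),
        ("PDK1",   "2", 173420000, "G", "A", 30, (60, 8, 0), None),   # unscored indel-like case
        ("ARID1A", "1", 27100000, "C", "T", 40, (80, 10, 0), 28.0),
        ("CSMD3",  "8", 113200000, "G", "T", 25, (50, 6, 0), 24.0),
        ("FAT3",   "11", 92100000, "A", "G", 20, (40, 5, 0), 22.0),
        ("MECOM",  "3", 168800000, "T", "C", 15, (30, 4, 0), 26.0),
        ("BRCA1",  "17", 41245000, "G", "A", 22, (45, 5, 0), 30.0),
    ]
    variants, cadd_rows = [], []
    plasma_ids = [f"{P}-PL1", f"{P}-PL2", f"{P}-PL3"]
    for gene, chrom, pos, ref, alt, tis, plas, cadd in true_somatics:
        variants.append((P, f"{P}-T1", chrom, pos, ref, alt, tis, 200, gene, np.nan, ""))
        for sid, ac in zip(plasma_ids, plas):
            if ac > 0:
                variants.append((P, sid, chrom, pos, ref, alt, ac, 1000, gene, np.nan, ""))
        if cadd is not None:
            cadd_rows.append((chrom, pos, ref, alt, cadd))

    # decoys: each violates exactly one filter rule
    variants += [
        (P, f"{P}-BC", "19", 9060000, "T", "C", 10, 200, "MUC16", np.nan, ""),     # germline evidence
        (P, f"{P}-PL1", "19", 9060000, "T", "C", 60, 1000, "MUC16", np.nan, ""),
        (P, f"{P}-PL1", "2", 179400000, "C", "A", 50, 1000, "TTN", np.nan, ""),    # CADD 12
        (P, f"{P}-T1", "2", 179400000, "C", "A", 12, 200, "TTN", np.nan, ""),
        (P, f"{P}-PL1", "1", 152280000, "G", "T", 15, 1000, "FLG", np.nan, ""),    # artifact
        ("EOC000", "EOC000-PL1", "1", 152280000, "G", "T", 15, 1000, "FLG", np.nan, ""),
        (P, f"{P}-PL1", "1", 228400000, "C", "G", 8, 1000, "OBSCN", np.nan, ""),   # below 1%
    ]
    cadd_rows += [
        ("19", 9060000, "T", "C", 30.0),
        ("2", 179400000, "C", "A", 12.0),
        ("1", 152280000, "G", "T", 25.0),
        ("1", 228400000, "C", "G", 25.0),
    ]
    cohort = _fixture_frames(samples, variants, cadd_rows,
                             [(P, 16.0), ("EOC000", np.nan)])
    truth = Truth(
        patients=pd.DataFrame([(P, "good", 16.0, 0.692, 0.45)],
                              columns=["patient_id", "responder", "pfi_months", "f_plasma0", "f_tissue"]),
        clones=pd.DataFrame([(P, variant_key(c, p, r, a), g, np.nan, np.nan, g == "TP53")
                             for g, c, p, r, a, *_ in true_somatics],
                            columns=["patient_id", "key", "gene", "cellular_fraction", "decay", "truncal"]),
        artifacts=pd.DataFrame([(variant_key("1", 152280000, "G", "T"), "FLG", 0.015, pid)
                                for pid in (P, "EOC000")],
                               columns=["key", "gene", "vaf", "patient_id"]),
        sample_fractions=pd.DataFrame(
            [(s[1], {"EOC429-PL1": 0.692, "EOC429-PL2": 0.06, "EOC429-PL3": 0.008,
                     "EOC429-T1": 0.45}.get(s[1], 0.0)) for s in samples],
            columns=["sample_id", "tumor_fraction"]),
        copy_states=pd.DataFrame(columns=["patient_id", "gene", "copies"]),
    )
    return CohortBundle(cohort=cohort, truth=truth)


def emit_fixture_eoc736() -> CohortBundle:
    """Poor responder with persistent TP53 and an 8-copy ERBB2 amplification.

    Coverage encodes ERBB2/CDK12 at 8 copies with tumor fraction 0.4 in the
    pretreatment plasma (expected log2 ratio log2(2.2) ~ 1.14) against four
    flat normals; RARA is amplified in plasma only.  TP53 VAF stays
    detectable throughout treatment (20% -> 9% at primary treatment end,
    24% at progression).
    """
    P = "EOC736"
    samples = [
        (P, f"{P}-BC", "germline", -14, "pretreatment", np.nan),
        (P, f"{P}-T1", "tissue", -12, "pretreatment", np.nan),
        (P, f"{P}-PL1", "plasma", -7, "pretreatment", 640.0),
        (P, f"{P}-PL2", "plasma", 42, "on_treatment", 300.0),
        (P, f"{P}-PL3", "plasma", 140, "post_treatment", 193.0),
        (P, f"{P}-PL4", "plasma", 290, "progression", 840.0),
    ]
    normals = [f"N{i}" for i in range(1, 5)]
    for n in normals:
        samples.append((f"EOC{n}", f"EOC{n}-BC", "germline", -14, "pretreatment", np.nan))

    persistent = ["KMT2D", "SMARCA4", "KDM5A", "SUZ12", "CSMD1", "LRP1B",
                  "PCLO", "RYR2", "USH2A", "DNAH5", "MUC4"]
    decaying = ["PTPRD", "GRIN2A", "TRRAP"]
    variants, cadd_rows = [], []

    def add(gene, chrom, pos, ref, alt, tis, plas, cadd):
        variants.append((P, f"{P}-T1", chrom, pos, ref, alt, tis, 200, gene, np.nan, ""))
        for sid, ac in zip([f"{P}-PL1", f"{P}-PL2", f"{P}-PL3", f"{P}-PL4"], plas):
            if ac > 0:
                variants.append((P, sid, chrom, pos, ref, alt, ac, 1000, gene, np.nan, ""))
        cadd_rows.append((chrom, pos, ref, alt, cadd))

    add("TP53", "17", 7577100, "G", "A", 80, (200, 120, 90, 240), 33.0)
    for j, gene in enumerate(persistent):
        base = 20 + 5 * j  # 20..70 /1000, roughly constant through treatment
        add(gene, str(j % 22 + 1), 2_000_000 + 1000 * j, "C", "T", max(4, base // 5),
            (base, base + 2, base - 2, base + 4), 24.0 + j % 8)
    for j, gene in enumerate(decaying):
        add(gene, str(10 + j), 3_000_000 + 1000 * j, "G", "A", 12,
            (60, 20, 5, 6), 26.0)

    amp_plasma = {"ERBB2": 2.2, "CDK12": 2.2, "RARA": 2.2}
    amp_tissue = {"ERBB2": 2.5, "CDK12": 2.5}  # f_tissue = 0.5, copies = 8
    cna_genes = [("ERBB2", 8), ("CDK12", 6), ("RARA", 4)] + [(f"BG{i:02d}", 4) for i in range(1, 38)]
    cov_rows = []
    for gi, (gene, nt) in enumerate(cna_genes):
        for j in range(nt):
            jitter = 1.0 + (((gi * 7 + j * 3) % 11) - 5) / 1000.0  # deterministic +-0.5%
            cov_rows.append((f"{P}-PL1", gene, f"t{j:02d}",
                             int(round(1000 * amp_plasma.get(gene, 1.0) * jitter))))
            cov_rows.append((f"{P}-T1", gene, f"t{j:02d}",
                             int(round(200 * amp_tissue.get(gene, 1.0) * jitter))))
            for k, n in enumerate(normals):
                njit = 1.0 + (((gi * 5 + j * 2 + k * 3) % 9) - 4) / 1000.0
                cov_rows.append((f"EOC{n}-BC", gene, f"t{j:02d}", int(round(200 * njit))))
    coverage = pd.DataFrame(cov_rows, columns=COVERAGE_COLUMNS)

    outcomes = [(P, 5.0)] + [(f"EOC{n}", np.nan) for n in normals]
    cohort = _fixture_frames(samples, variants, cadd_rows, outcomes, coverage)
    truth = Truth(
        patients=pd.DataFrame([(P, "poor", 5.0, 0.4, 0.5)],
                              columns=["patient_id", "responder", "pfi_months", "f_plasma0", "f_tissue"]),
        clones=pd.DataFrame(
            [(P, variant_key(r[2], r[3], r[4], r[5]), r[8], np.nan, np.nan, r[8] == "TP53")
             for r in variants if r[1] == f"{P}-T1"],
            columns=["patient_id", "key", "gene", "cellular_fraction", "decay", "truncal"]),
        artifacts=pd.DataFrame(columns=["key", "gene", "vaf", "patient_id"]),
        sample_fractions=pd.DataFrame(
            [(s[1], {"EOC736-PL1": 0.4, "EOC736-PL2": 0.24, "EOC736-PL3": 0.18,
                     "EOC736-PL4": 0.48, "EOC736-T1": 0.5}.get(s[1], 0.0)) for s in samples],
            columns=["sample_id", "tumor_fraction"]),
        copy_states=pd.DataFrame([(P, "ERBB2", 8), (P, "CDK12", 8)],
                                 columns=["patient_id", "gene", "copies"]),
    )
    return CohortBundle(cohort=cohort, truth=truth)
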