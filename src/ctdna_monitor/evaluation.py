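"""Seed-swept evaluation harnesses for the synthetic study conditions.

These drive the full pipeline over replicate synthetic cohorts and report
recovery metrics: tumor-fraction error against generator truth, responder
label recovery, CNA caller calibration (null call rate, planted-
amplification detection).  Used by the acceptance machinery and by
calibration-minded users.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .cna import CNAConfig, call_cohort
from .filters import FilterConfig, run_filter_chain
from .monitor import MonitorConfig, monitor_cohort
from .simulate import CohortBundle, PatientSpec, SimulationConfig, simulate_cohort


@dataclass
class RecoveryReport:
    mae: float                    # mean |estimated - true| fraction, truth >= 0.05
    n_fraction_points: int
    recovery: List[int]           # correctly labelled patients per seed (of 12)
    n_patients: int
    group_p: List[float]          # good-vs-poor Mann-Whitney p per seed

    @property
    def median_recovery(self) -> float:
        return float(np.median(self.recovery))

    @property
    def median_group_p(self) -> float:
        return float(np.median(self.group_p))


def tumor_fraction_and_responder_recovery(
    n_seeds: int = 100,
    base_seed: int = 0,
    min_truth_fraction: float = 0.05,
    config: Optional[SimulationConfig] = None,
) -> RecoveryReport:
    """Simulate ``n_seeds`` cohorts and score burden and responder recovery.

    The monitor runs with the heterozygous fraction model, matching the
    generator's allele dosage of 0.5.  Coverage simulation is skipped: the
    quantities scored here involve only the variant tables.
    """
    config = config or SimulationConfig(include_coverage=False)
    mon_config = MonitorConfig(fraction_model="het")
    errors, recovery, group_p = [], [], []
    n_patients = 0
    for i in range(n_seeds):
        bundle = simulate_cohort(config, seed=base_seed + i)
        res = run_filter_chain(bundle.cohort, FilterConfig())
        mon = monitor_cohort(res.tracked, bundle.cohort, mon_config)

        merged = mon.burden.merge(bundle.truth.sample_fractions, on="sample_id")
        sel = merged[merged["tumor_fraction"] >= min_truth_fraction].dropna(
            subset=["ctdna_fraction"])
        errors.append((sel["ctdna_fraction"] - sel["tumor_fraction"]).abs().to_numpy())

        calls = mon.responder_calls
        n_patients = len(calls)
        recovery.append(int((calls["predicted"] == calls["truth"]).sum()))
        if mon.group_p is not None:
            group_p.append(mon.group_p)
    all_err = np.concatenate(errors) if errors else np.array([])
    return RecoveryReport(
        mae=float(all_err.mean()) if len(all_err) else float("nan"),
        n_fraction_points=int(len(all_err)),
        recovery=recovery,
        n_patients=n_patients,
        group_p=group_p,
    )


def null_cna_calibration(seed: int = 0, sample_id: str = "P01-PL1") -> Dict[str, float]:
    """Call one tumor-bearing plasma sample of a default synthetic cohort
    against its 12 germline normals; genes without a planted event are null."""
    bundle = simulate_cohort(SimulationConfig(), seed=seed)
    cohort = bundle.cohort
    normals = cohort.samples.loc[cohort.samples["material"] == "germline", "sample_id"]
    calls = call_cohort(cohort.coverage, normals, [sample_id], CNAConfig(seed=seed))
    patient = sample_id.split("-")[0]
    events = set(bundle.truth.copy_states.query("patient_id == @patient")["gene"])
    null_calls = calls[~calls["gene"].isin(events)]
    rate = float((null_calls["call"] != "neutral").mean())
    return {"null_call_rate": rate, "n_null_genes": int(len(null_calls))}


def planted_amp_bundle(fraction: float, seed: int, n_genes: int = 40,
                       copies: int = 8) -> CohortBundle:
    """Minimal panel with one ``copies``-copy ERBB2 sample at the given tumor
    fraction plus three clone-free patients supplying germline normals.
    ERBB2 gets the panel-typical eight targets."""
    patients = (
        PatientSpec("AMP", "poor", 5.0, fraction, fraction, clones=(),
                    cna_events=(("ERBB2", copies),)),
    ) + tuple(PatientSpec(f"NRM{i}", "good", 20.0, 0.0, 0.0, clones=()) for i in range(3))
    config = SimulationConfig(panel_genes=n_genes, n_timepoints=2,
                              targets_per_gene=(8, 8), patients=patients, artifacts=())
    return simulate_cohort(config, seed=seed)


def planted_amp_detection_rate(fraction: float = 0.2, n_seeds: int = 100,
                               base_seed: int = 0) -> float:
    """Fraction of seeds in which the planted 8-copy amplification is called."""
    called = 0
    for i in range(n_seeds):
        seed = base_seed + i
        bundle = planted_amp_bundle(fraction, seed)
        cohort = bundle.cohort
        normals = cohort.samples.loc[cohort.samples["material"] == "germline", "sample_id"]
        calls = call_cohort(cohort.coverage, normals, ["AMP-PL1"], CNAConfig(seed=seed))
        called += int(calls.set_index("gene").loc["ERBB2", "call"] == "amp")
    return called / n_seeds
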