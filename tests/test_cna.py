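"""Panel CNA caller: purity model, normalization, bootstrap calibration."""

import numpy as np
import pandas as pd
import pytest

from ctdna_monitor import (
    CNAConfig,
    call_cohort,
    call_gene_cna,
    call_sample,
    cna_burden_correlation,
    cna_concordance,
    expected_log2,
    invert_expected_log2,
    normalize_coverage,
)
from ctdna_monitor.records import COVERAGE_COLUMNS


def _cov(rows):
    return pd.DataFrame(rows, columns=COVERAGE_COLUMNS)


def _flat_panel(samples, genes, depth=200, n_targets=6, scale=None):
    rows = []
    for s in samples:
        for g in genes:
            for t in range(n_targets):
                d = depth * (scale or {}).get((s, g), 1.0)
                rows.append((s, g, f"t{t}", int(d)))
    return _cov(rows)


class TestExpectedLog2:
    @pytest.mark.parametrize("f", [0.0, 0.3, 1.0])
    def test_two_copies_is_neutral(self, f):
        assert expected_log2(2, f) == 0.0

    def test_pure_tumor_doubling(self):
        assert expected_log2(4, 1.0) == 1.0

    def test_mixture_closed_form(self):
        assert expected_log2(8, 0.6) == pytest.approx(np.log2(2.8))
        assert expected_log2(8, 0.4) == pytest.approx(1.1375035, abs=1e-6)

    def test_strictly_increasing_in_copies(self):
        for f in (0.1, 0.5, 1.0):
            vals = [expected_log2(c, f) for c in range(6)]
            assert all(b > a for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("copies, f", [(8, 0.4), (1, 0.7), (0, 0.3)])
    def test_inversion_roundtrip(self, copies, f):
        assert invert_expected_log2(expected_log2(copies, f), f) == pytest.approx(copies)


class TestNormalization:
    def test_flat_sample_has_unit_relative_coverage(self):
        cov = _flat_panel(["N1", "N2", "N3", "S1"], ["G1", "G2"])
        targets, pon = normalize_coverage(cov, ["N1", "N2", "N3"])
        s1 = targets[targets["sample_id"] == "S1"]
        assert np.allclose(s1["rel"], 1.0)
        assert np.allclose(pon.reference["ref_median"], 1.0)

    def test_doubled_gene_has_relative_coverage_two(self):
        cov = _flat_panel(["N1", "N2", "N3", "S1"], [f"G{i}" for i in range(9)],
                          scale={("S1", "G0"): 2.0})
        targets, _ = normalize_coverage(cov, ["N1", "N2", "N3"])
        g0 = targets[(targets["sample_id"] == "S1") & (targets["gene"] == "G0")]
        assert np.allclose(g0["rel"], 2.0)

    def test_fewer_than_three_normals_rejected(self):
        cov = _flat_panel(["N1", "N2", "S1"], ["G1"])
        with pytest.raises(ValueError, match="3 normal"):
            normalize_coverage(cov, ["N1", "N2"])

    def test_zero_median_depth_rejected(self):
        cov = _flat_panel(["N1", "N2", "N3", "S1"], ["G1"], depth=0)
        with pytest.raises(ValueError, match="median"):
            normalize_coverage(cov, ["N1", "N2", "N3"])

    def test_gene_absent_from_normals_excluded_with_warning(self):
        cov = _flat_panel(["N1", "N2", "N3", "S1"], ["G1"])
        extra = _flat_panel(["S1"], ["ONLY_S1"])
        with pytest.warns(UserWarning, match="ONLY_S1"):
            targets, pon = normalize_coverage(pd.concat([cov, extra]), ["N1", "N2", "N3"])
        assert "ONLY_S1" not in set(targets["gene"]) and "ONLY_S1" not in pon.genes()


class TestCalling:
    def test_identical_depths_give_neutral_zero(self):
        call = call_gene_cna(np.ones(6), 1.0, 0.01, "S1", "G1")
        assert call.log2_ratio == 0.0 and call.call == "neutral"
        assert call.boot_ci == (0.0, 0.0)

    def test_bootstrap_interval_contains_point_estimate(self, eoc736):
        cohort = eoc736.cohort
        normals = cohort.samples.loc[cohort.samples["material"] == "germline", "sample_id"]
        calls = call_cohort(cohort.coverage, normals, ["EOC736-PL1"])
        assert ((calls["ci_low"] <= calls["log2_ratio"] + 1e-12)
                & (calls["log2_ratio"] <= calls["ci_high"] + 1e-12)).all()

    def test_planted_eoc736_erbb2_amplification(self, eoc736):
        cohort = eoc736.cohort
        normals = cohort.samples.loc[cohort.samples["material"] == "germline", "sample_id"]
        calls = call_cohort(cohort.coverage, normals, ["EOC736-PL1"],
                            tumor_fractions={"EOC736-PL1": 0.4})
        erbb2 = calls.set_index("gene").loc["ERBB2"]
        assert erbb2["call"] == "amp"
        assert erbb2["log2_ratio"] == pytest.approx(1.1375, abs=0.02)
        assert erbb2["est_copies"] == pytest.approx(8.0, abs=0.3)

    def test_bootstrap_deterministic_per_seed_sample_gene(self):
        rng = np.random.default_rng(0)
        rel = rng.normal(1.6, 0.1, 8)
        a = call_gene_cna(rel, 1.0, 0.02, "S1", "ERBB2", CNAConfig(seed=5))
        b = call_gene_cna(rel, 1.0, 0.02, "S1", "ERBB2", CNAConfig(seed=5))
        c = call_gene_cna(rel, 1.0, 0.02, "S1", "ERBB2", CNAConfig(seed=6))
        assert a.boot_ci == b.boot_ci and a.boot_ci != c.boot_ci

    def test_bootstrap_size_stability_on_planted_amp(self, eoc736):
        cohort = eoc736.cohort
        normals = cohort.samples.loc[cohort.samples["material"] == "germline", "sample_id"]
        cis = {}
        for n_boot in (200, 1000):
            targets, pon = normalize_coverage(cohort.coverage, normals)
            ref = pon.reference.set_index("gene").loc["ERBB2"]
            rel = targets.query("sample_id == 'EOC736-PL1' and gene == 'ERBB2'")["rel"].to_numpy()
            cis[n_boot] = call_gene_cna(rel, ref["ref_median"], ref["ref_mad"],
                                        "EOC736-PL1", "ERBB2",
                                        CNAConfig(n_boot=n_boot, seed=1)).boot_ci
        assert abs(cis[200][0] - cis[1000][0]) < 0.05
        assert abs(cis[200][1] - cis[1000][1]) < 0.05

    def test_few_targets_flagged_low_confidence(self):
        call = call_gene_cna(np.array([1.0, 1.1]), 1.0, 0.05, "S", "G", CNAConfig())
        assert call.low_confidence


class TestCalibration:
    def test_null_call_rate_within_tolerance(self, sim_bundle):
        """A pretreatment plasma sample against the 12 germline normals:
        genes without a planted event must be called neutral >= 90% of the time."""
        cohort = sim_bundle.cohort
        normals = cohort.samples.loc[cohort.samples["material"] == "germline", "sample_id"]
        calls = call_cohort(cohort.coverage, normals, ["P01-PL1"], CNAConfig(seed=0))
        events = set(sim_bundle.truth.copy_states.query("patient_id == 'P01'")["gene"])
        null_calls = calls[~calls["gene"].isin(events)]
        assert len(null_calls) >= 490
        assert (null_calls["call"] != "neutral").mean() <= 0.10

    def test_detection_power_monotone_in_tumor_fraction(self):
        rates = []
        for f in (0.05, 0.1, 0.2, 0.4, 0.6):
            called = 0
            for seed in range(8):
                bundle = _planted_amp_bundle(f, seed)
                cohort = bundle.cohort
                normals = cohort.samples.loc[cohort.samples["material"] == "germline", "sample_id"]
                calls = call_cohort(cohort.coverage, normals, ["AMP-PL1"], CNAConfig(seed=seed))
                called += int(calls.set_index("gene").loc["ERBB2", "call"] == "amp")
            rates.append(called / 8)
        assert all(b >= a for a, b in zip(rates, rates[1:]))
        assert rates[-1] == 1.0


from ctdna_monitor.evaluation import planted_amp_bundle as _planted_amp_bundle  # noqa: E402


class TestConcordanceAndBurden:
    def _calls(self, rows):
        return pd.DataFrame(rows, columns=["sample_id", "gene", "call"])

    def test_identical_calls_fully_concordant(self):
        tis = self._calls([("T1", "A", "amp"), ("T1", "B", "del")])
        pla = self._calls([("PL1", "A", "amp"), ("PL1", "B", "del")])
        per, med = cna_concordance(pla, tis, {"PL1": 0.5}, {"PL1": "P", "T1": "P"})
        assert med == 1.0

    def test_partial_agreement_ratio(self):
        tis = self._calls([("T1", "A", "amp"), ("T1", "B", "del"), ("T1", "C", "amp")])
        pla = self._calls([("PL1", "A", "amp"), ("PL1", "B", "del"), ("PL1", "C", "neutral")])
        per, med = cna_concordance(pla, tis, {"PL1": 0.5}, {"PL1": "P", "T1": "P"})
        assert med == pytest.approx(2 / 3)

    def test_low_tumor_content_sample_excluded(self):
        tis = self._calls([("T1", "A", "amp")])
        pla = self._calls([("PL1", "A", "amp")])
        per, med = cna_concordance(pla, tis, {"PL1": 0.1}, {"PL1": "P", "T1": "P"})
        assert len(per) == 0 and np.isnan(med)

    def test_burden_correlation_rises_with_fraction(self):
        """Across samples spanning low to high tumor fraction, the number of
        detectable planted amplifications tracks the fraction."""
        coefs = []
        for seed in range(5):
            rows, fractions = [], {}
            for i, f in enumerate((0.02, 0.1, 0.25, 0.45, 0.65)):
                bundle = _planted_amp_bundle(f, seed + 10 * i)
                cov = bundle.cohort.coverage
                sid = f"S{i}"
                sub = cov[cov["sample_id"] == "AMP-PL1"].assign(sample_id=sid)
                normals = cov[cov["sample_id"].str.startswith("NRM") & cov["sample_id"].str.endswith("BC")]
                calls = call_cohort(pd.concat([sub, normals]), normals["sample_id"].unique(),
                                    [sid], CNAConfig(seed=seed))
                rows.append(calls)
                fractions[sid] = f
            coefs.append(cna_burden_correlation(pd.concat(rows), fractions)["pearson"])
        assert np.median(coefs) > 0.7

    def test_constant_counts_undefined(self):
        calls = self._calls([("S1", "A", "neutral"), ("S2", "A", "neutral"), ("S3", "A", "neutral")])
        with pytest.warns(UserWarning):
            out = cna_burden_correlation(calls, {"S1": 0.1, "S2": 0.2, "S3": 0.3})
        assert np.isnan(out["pearson"])
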