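"""Longitudinal monitoring: trajectories, decrease tests, burden, response.

For each tracked somatic variant we assemble the ordered time series of
allelic counts across a patient's plasma samples and test, per on/post-
treatment sample, whether its VAF decreased relative to the earliest
pretreatment plasma sample.  The test is the one-sided Fisher exact test
on the 2x2 table of (alt, ref) read counts, alternative "VAF dropped";
conditioned on the margins this is the upper hypergeometric tail of the
pretreatment alt count.

The per-patient response statistic is the largest, over on/post-treatment
samples, proportion of significantly decreased variants (alpha = 0.01).
Because the proportion from few evaluable variants is unstable, a
count-corrected version is reported: the 95% Jeffreys lower bound of the
maximizing k/n.  The responder rule predicts a good responder when the
patient has few tracked mutations or a large corrected decrease
proportion; groups are compared with an exact one-sided Mann-Whitney U.

Tumor burden per plasma sample is tracked by the truncal TP53 VAF (chosen
as the TP53 variant with maximal pretreatment-tissue VAF), the median VAF
over tracked variants, and a ctDNA-fraction transform of the TP53 VAF:
``direct`` f = V (the TP53 VAF itself is the burden proxy), ``het``
f = min(1, 2V) (heterozygous variant, diploid locus), ``loh``
f = 2V/(1+V) (variant hemizygous after loss of the wild-type allele).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .records import Cohort, add_key_column

ON_POST_PHASES = ("on_treatment", "post_treatment", "follow_up", "progression")
FRACTION_MODELS = ("direct", "het", "loh")


@dataclass(frozen=True)
class MonitorConfig:
    alpha: float = 0.01
    fraction_model: str = "direct"
    correction: str = "jeffreys_lower"   # or "none"
    default_depth: int = 1000            # depth imputed for absent variant records
    classify_max_mutations: int = 10     # c_n: "few mutations" bound
    classify_min_decrease: float = 0.5   # c_d: corrected-proportion bound

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.fraction_model not in FRACTION_MODELS:
            raise ValueError(f"unknown fraction model {self.fraction_model!r}")
        if self.correction not in ("none", "jeffreys_lower"):
            raise ValueError(f"unknown correction {self.correction!r}")


# ---------------------------------------------------------------------------
# decrease test

def fisher_decrease_test(pre: Tuple[int, int], post: Tuple[int, int]) -> float:
    """One-sided Fisher exact p for "post VAF < pre VAF".

    ``pre``/``post`` are (alt_count, depth).  Zero depth on either side is
    undefined and returns NaN.  Equivalent to
    ``fisher_exact([[a1, d1-a1], [a2, d2-a2]], alternative="greater")``.
    """
    (a1, d1), (a2, d2) = pre, post
    if d1 <= 0 or d2 <= 0:
        return float("nan")
    if not (0 <= a1 <= d1 and 0 <= a2 <= d2):
        raise ValueError("alt counts must lie within depths")
    return float(stats.hypergeom.sf(a1 - 1, d1 + d2, a1 + a2, d1))


def decrease_pvalues(a1, d1, a2, d2) -> np.ndarray:
    """Vectorized :func:`fisher_decrease_test` on count arrays."""
    a1, d1, a2, d2 = (np.asarray(x, dtype=float) for x in (a1, d1, a2, d2))
    valid = (d1 > 0) & (d2 > 0)
    p = np.full(np.broadcast(a1, d1, a2, d2).shape, np.nan)
    if valid.any():
        p[valid] = stats.hypergeom.sf(a1[valid] - 1, (d1 + d2)[valid], (a1 + a2)[valid], d1[valid])
    return p


def jeffreys_lower(k: int, n: int, level: float = 0.95) -> float:
    """Lower bound of the Jeffreys binomial interval (Beta(k+1/2, n-k+1/2)).

    By the standard convention the lower bound is 0 when k = 0, which also
    keeps the corrected proportion <= the raw one everywhere.
    """
    if n <= 0:
        return float("nan")
    if k == 0:
        return 0.0
    return float(stats.beta.ppf((1 - level) / 2, k + 0.5, n - k + 0.5))


# ---------------------------------------------------------------------------
# trajectories

def build_trajectories(tracked: pd.DataFrame, cohort: Cohort,
                       config: MonitorConfig = MonitorConfig()) -> pd.DataFrame:
    """Complete per-variant plasma time series.

    Every tracked (patient, variant) gets one point per plasma sample of the
    patient; samples where the variant was not reported contribute
    alt_count = 0 with the sample's panel-wide median observed depth (the
    panel default when nothing was observed), flagged ``imputed``.
    """
    if tracked.empty:
        return pd.DataFrame(columns=["patient_id", "key", "gene", "sample_id",
                                     "timepoint_days", "phase", "alt_count", "depth",
                                     "vaf", "imputed"])
    t = tracked if "key" in tracked.columns else add_key_column(tracked)
    plasma = cohort.samples[cohort.samples["material"] == "plasma"]
    variants = t[["patient_id", "key", "gene"]].drop_duplicates()
    grid = variants.merge(
        plasma[["patient_id", "sample_id", "timepoint_days", "phase"]], on="patient_id"
    )
    obs = t[["patient_id", "key", "sample_id", "alt_count", "depth"]].drop_duplicates(
        subset=["patient_id", "key", "sample_id"]
    )
    pts = grid.merge(obs, on=["patient_id", "key", "sample_id"], how="left")

    median_depth = (
        add_key_column(cohort.variants).groupby("sample_id")["depth"].median().to_dict()
    )
    pts["imputed"] = pts["alt_count"].isna()
    fallback = pts["sample_id"].map(median_depth).fillna(config.default_depth)
    pts["depth"] = pts["depth"].fillna(fallback).astype(int)
    pts["alt_count"] = pts["alt_count"].fillna(0).astype(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        pts["vaf"] = np.where(pts["depth"] > 0, pts["alt_count"] / pts["depth"], np.nan)
    return pts.sort_values(
        ["patient_id", "key", "timepoint_days", "sample_id"]
    ).reset_index(drop=True)


def reference_sample(points: pd.DataFrame, patient_id: str) -> Optional[str]:
    """Earliest pretreatment plasma sample (ties by sample_id)."""
    pre = points[(points["patient_id"] == patient_id) & (points["phase"] == "pretreatment")]
    if pre.empty:
        return None
    pre = pre.sort_values(["timepoint_days", "sample_id"])
    return pre["sample_id"].iloc[0]


def decrease_tests(points: pd.DataFrame, config: MonitorConfig = MonitorConfig()) -> pd.DataFrame:
    """Per (patient, variant, on/post-treatment sample) decrease p-values."""
    out = []
    for patient_id, grp in points.groupby("patient_id", sort=True):
        ref = reference_sample(points, patient_id)
        if ref is None:
            warnings.warn(f"{patient_id}: no pretreatment plasma; decrease tests skipped")
            continue
        refs = grp[grp["sample_id"] == ref].set_index("key")
        post = grp[grp["phase"].isin(ON_POST_PHASES)].copy()
        if post.empty:
            continue
        post["pre_alt"] = post["key"].map(refs["alt_count"])
        post["pre_depth"] = post["key"].map(refs["depth"])
        post["decrease_p"] = decrease_pvalues(
            post["pre_alt"], post["pre_depth"], post["alt_count"], post["depth"]
        )
        post["decreased"] = post["decrease_p"] < config.alpha
        post["reference_sample"] = ref
        out.append(post)
    if not out:
        return pd.DataFrame(columns=list(points.columns) + [
            "pre_alt", "pre_depth", "decrease_p", "decreased", "reference_sample"])
    return pd.concat(out, ignore_index=True)


@dataclass
class PatientDecrease:
    patient_id: str
    per_sample: pd.DataFrame       # sample_id, timepoint_days, k, n, proportion
    raw: Optional[float]           # max over samples of k/n
    corrected: Optional[float]     # Jeffreys 95% lower bound of the maximizing k/n
    best_sample: Optional[str]


def decrease_proportion(tests: pd.DataFrame, patient_id: str,
                        config: MonitorConfig = MonitorConfig()) -> PatientDecrease:
    """Largest per-sample proportion of significantly decreased variants.

    Evaluable variants are those with a defined p (both depths > 0);
    duplicated sample records and variant ordering do not affect the result.
    """
    t = tests[tests["patient_id"] == patient_id].drop_duplicates(
        subset=["key", "sample_id"]
    )
    rows = []
    for (sample_id, day), grp in t.groupby(["sample_id", "timepoint_days"], sort=True):
        evaluable = grp["decrease_p"].notna()
        n = int(evaluable.sum())
        k = int((grp.loc[evaluable, "decrease_p"] < config.alpha).sum())
        rows.append({"sample_id": sample_id, "timepoint_days": day, "k": k, "n": n,
                     "proportion": k / n if n else np.nan})
    per_sample = pd.DataFrame(rows, columns=["sample_id", "timepoint_days", "k", "n", "proportion"])
    usable = per_sample.dropna(subset=["proportion"])
    if usable.empty:
        warnings.warn(f"{patient_id}: no evaluable variants; decrease proportion undefined")
        return PatientDecrease(patient_id, per_sample, None, None, None)
    best = usable.sort_values(
        ["proportion", "timepoint_days", "sample_id"], ascending=[False, True, True]
    ).iloc[0]
    raw = float(best["proportion"])
    corrected = (
        jeffreys_lower(int(best["k"]), int(best["n"]))
        if config.correction == "jeffreys_lower" else raw
    )
    return PatientDecrease(patient_id, per_sample, raw, corrected, str(best["sample_id"]))


def classify_responder(n_mutations: int, corrected: Optional[float],
                       config: MonitorConfig = MonitorConfig()) -> Optional[str]:
    """Good iff few tracked mutations OR a large corrected decrease proportion."""
    if corrected is None or (isinstance(corrected, float) and np.isnan(corrected)):
        if n_mutations <= config.classify_max_mutations:
            return "good"
        return None
    if n_mutations <= config.classify_max_mutations or corrected >= config.classify_min_decrease:
        return "good"
    return "poor"


def compare_responder_groups(good: np.ndarray, poor: np.ndarray) -> float:
    """One-sided Mann-Whitney U p-value for "good > poor" on a feature.

    Exact for small untied samples; midrank tie correction otherwise.  Both
    groups must be non-empty; identical pooled values give p = 0.5.
    """
    good = np.asarray(good, dtype=float)
    poor = np.asarray(poor, dtype=float)
    if len(good) == 0 or len(poor) == 0:
        raise ValueError("both responder groups must be non-empty")
    pooled = np.concatenate([good, poor])
    if np.all(pooled == pooled[0]):
        return 0.5
    ties = len(np.unique(pooled)) < len(pooled)
    small = len(good) + len(poor) <= 20
    method = "exact" if (small and not ties) else "asymptotic"
    res = stats.mannwhitneyu(good, poor, alternative="greater", method=method,
                             use_continuity=False)
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# tumor burden

def estimate_tumor_fraction(tp53_vaf: float, model: str = "direct") -> float:
    """ctDNA fraction from the truncal TP53 VAF under the chosen dosage model."""
    if np.isnan(tp53_vaf):
        return float("nan")
    if not 0 <= tp53_vaf <= 1:
        raise ValueError("VAF must lie in [0, 1]")
    if model == "direct":
        return float(tp53_vaf)
    if model == "het":
        return float(min(1.0, 2.0 * tp53_vaf))
    if model == "loh":
        return float(2.0 * tp53_vaf / (1.0 + tp53_vaf))
    raise ValueError(f"unknown fraction model {model!r}")


def select_truncal_tp53(tracked: pd.DataFrame, cohort: Cohort, patient_id: str) -> Optional[str]:
    """TP53 variant with maximal VAF in the earliest pretreatment tissue.

    Falls back to pretreatment plasma when no pretreatment tissue exists;
    ties break by genomic position then allele, ascending.
    """
    t = tracked if "key" in tracked.columns else add_key_column(tracked)
    tp53 = t[(t["patient_id"] == patient_id) & (t["gene"] == "TP53")]
    if tp53.empty:
        warnings.warn(f"{patient_id}: no tracked TP53 variant; tumor fraction missing")
        return None
    keys = sorted(tp53["key"].unique())
    if len(keys) == 1:
        return keys[0]
    samples = cohort.samples[cohort.samples["patient_id"] == patient_id]
    for material in ("tissue", "plasma"):
        pre = samples[(samples["material"] == material) & (samples["phase"] == "pretreatment")]
        if pre.empty:
            if material == "tissue":
                warnings.warn(f"{patient_id}: no pretreatment tissue; using pretreatment plasma")
            continue
        sid = pre.sort_values(["timepoint_days", "sample_id"])["sample_id"].iloc[0]
        obs = tp53[tp53["sample_id"] == sid]
        if obs.empty:
            continue
        obs = obs.sort_values(["vaf", "chrom", "pos", "ref", "alt"],
                              ascending=[False, True, True, True, True])
        return obs["key"].iloc[0]
    return keys[0]


def burden_track(points: pd.DataFrame, tracked: pd.DataFrame, cohort: Cohort,
                 patient_id: str, config: MonitorConfig = MonitorConfig()) -> pd.DataFrame:
    """Per-plasma-sample TP53 VAF, median VAF, ctDNA fraction and CA-125."""
    tp53_key = select_truncal_tp53(tracked, cohort, patient_id)
    pts = points[points["patient_id"] == patient_id]
    plasma = cohort.plasma_samples(patient_id)
    rows = []
    for s in plasma.itertuples(index=False):
        here = pts[pts["sample_id"] == s.sample_id]
        tp53_vaf = float("nan")
        if tp53_key is not None:
            sel = here[here["key"] == tp53_key]
            if len(sel):
                tp53_vaf = float(sel["vaf"].iloc[0])
        median_vaf = float(here["vaf"].median()) if len(here) else float("nan")
        rows.append({
            "patient_id": patient_id, "sample_id": s.sample_id,
            "timepoint_days": s.timepoint_days, "phase": s.phase,
            "tp53_vaf": tp53_vaf, "median_vaf": median_vaf,
            "ctdna_fraction": estimate_tumor_fraction(tp53_vaf, config.fraction_model),
            "ca125": s.ca125,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# concordance and correlation

def plasma_tissue_concordance(tracked: pd.DataFrame, cohort: Cohort,
                              direction: str = "tissue_recall",
                              min_vaf: float = 0.01) -> Tuple[pd.Series, float]:
    """Per-patient overlap of variants detected in plasma vs tumor tissue.

    A variant counts as detected in a material when any sample of that
    material shows it at >= ``min_vaf``.  Directions: ``tissue_recall``
    |P & T| / |T| (default), ``plasma_recall`` |P & T| / |P|, ``jaccard``.
    Returns (per-patient series, cohort median).
    """
    if direction not in ("tissue_recall", "plasma_recall", "jaccard"):
        raise ValueError(f"unknown direction {direction!r}")
    t = tracked if "key" in tracked.columns else add_key_column(tracked)
    t = t.merge(cohort.samples[["sample_id", "material"]], on="sample_id", how="left")
    detected = t[t["vaf"] >= min_vaf]
    result = {}
    for patient_id, grp in detected.groupby("patient_id"):
        has_tissue = (
            cohort.samples[(cohort.samples["patient_id"] == patient_id)
                           & (cohort.samples["material"] == "tissue")].shape[0] > 0
        )
        plasma = set(grp.loc[grp["material"] == "plasma", "key"])
        tissue = set(grp.loc[grp["material"] == "tissue", "key"])
        if not has_tissue or not tissue:
            result[patient_id] = np.nan
            continue
        inter = len(plasma & tissue)
        if direction == "tissue_recall":
            result[patient_id] = inter / len(tissue)
        elif direction == "plasma_recall":
            result[patient_id] = inter / len(plasma) if plasma else np.nan
        else:
            union = len(plasma | tissue)
            result[patient_id] = inter / union if union else np.nan
    series = pd.Series(result, dtype=float).sort_index()
    return series, float(series.median())


def correlate_series(x, y, method: str = "pearson") -> float:
    """Correlation on complete pairs; NaN (flagged) below 3 pairs or zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        warnings.warn("fewer than 3 complete pairs; correlation undefined")
        return float("nan")
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero variance; correlation undefined")
        return float("nan")
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    raise ValueError(f"unknown correlation method {method!r}")


# ---------------------------------------------------------------------------
# cohort driver

@dataclass
class MonitorResult:
    """Cohort monitoring output with a printable summary."""

    trajectories: pd.DataFrame
    tests: pd.DataFrame
    responder_calls: pd.DataFrame
    burden: pd.DataFrame
    concordance: pd.Series
    concordance_median: float
    group_p: Optional[float] = None
    decreases: Dict[str, PatientDecrease] = field(default_factory=dict)

    def summary(self) -> str:
        lines = ["Longitudinal ctDNA monitoring summary",
                 "=" * 42,
                 self.responder_calls.to_string(index=False, float_format=lambda v: f"{v:.3f}")]
        lines.append(f"median plasma/tissue concordance: {self.concordance_median:.2f}")
        if self.group_p is not None:
            lines.append(f"good vs poor corrected-decrease Mann-Whitney p: {self.group_p:.4g}")
        return "\n".join(lines)


def monitor_cohort(tracked: pd.DataFrame, cohort: Cohort,
                   config: MonitorConfig = MonitorConfig()) -> MonitorResult:
    """Run trajectory building, decrease testing, burden and classification."""
    points = build_trajectories(tracked, cohort, config)
    tests = decrease_tests(points, config)
    truth = dict(zip(cohort.outcomes["patient_id"], cohort.outcomes["responder_truth"]))

    calls, burdens, decreases = [], [], {}
    patients = sorted(set(tracked["patient_id"])) if len(tracked) else []
    for patient_id in patients:
        dec = decrease_proportion(tests, patient_id, config)
        decreases[patient_id] = dec
        keys = add_key_column(tracked) if "key" not in tracked.columns else tracked
        n_mut = keys[keys["patient_id"] == patient_id]["key"].nunique()
        corrected = dec.corrected if dec.corrected is not None else float("nan")
        calls.append({
            "patient_id": patient_id, "n_mutations": n_mut,
            "max_decrease_proportion_raw": dec.raw if dec.raw is not None else float("nan"),
            "max_decrease_proportion_corrected": corrected,
            "predicted": classify_responder(n_mut, dec.corrected, config),
            "truth": truth.get(patient_id),
        })
        burdens.append(burden_track(points, tracked, cohort, patient_id, config))

    responder_calls = pd.DataFrame(calls, columns=[
        "patient_id", "n_mutations", "max_decrease_proportion_raw",
        "max_decrease_proportion_corrected", "predicted", "truth"])
    burden = pd.concat(burdens, ignore_index=True) if burdens else pd.DataFrame()
    concordance, conc_median = (
        plasma_tissue_concordance(tracked, cohort) if len(tracked)
        else (pd.Series(dtype=float), float("nan"))
    )
    group_p = None
    with_truth = responder_calls.dropna(subset=["max_decrease_proportion_corrected"])
    with_truth = with_truth[with_truth["truth"].isin(["good", "poor"])]
    good = with_truth.loc[with_truth["truth"] == "good", "max_decrease_proportion_corrected"]
    poor = with_truth.loc[with_truth["truth"] == "poor", "max_decrease_proportion_corrected"]
    if len(good) >= 2 and len(poor) >= 2:
        group_p = compare_responder_groups(good.to_numpy(), poor.to_numpy())
    return MonitorResult(points, tests, responder_calls, burden,
                         concordance, conc_median, group_p, decreases)
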