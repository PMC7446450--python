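"""Gene-level copy-number calling from targeted-panel depth of coverage.

The caller compares a sample against a panel of normals:

1. each target's depth is divided by the sample's median target depth
   (library-size normalization);
2. a gene's relative coverage is the median over its targets;
3. the normals define a per-gene reference median and MAD;
4. the gene log2 ratio is log2(sample relative / normals median), with a
   percentile bootstrap over the gene's targets for an interval.

A gene is called amplified when the bootstrap interval lies above 0 and
the log2 ratio reaches the amplification threshold (0.58, i.e. 3 copies
at purity 1), deleted symmetrically at -0.41 (1.5 copies), else neutral.
Under a tumor fraction f the expected ratio for c copies is
log2((f*c + 2(1-f))/2), which is inverted for a purity-adjusted copy
estimate.  No GC/mappability correction is applied (hook:
``normalize_coverage``'s per-target table is the place to add one).

Bootstrap randomness is a deterministic stream per (seed, sample, gene).
"""

from __future__ import annotations

import math
import warnings
import zlib
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

from .monitor import correlate_series


@dataclass(frozen=True)
class CNAConfig:
    amp_log2: float = 0.58
    del_log2: float = -0.41
    n_boot: int = 1000
    min_targets: int = 3
    tumor_content_min_for_concordance: float = 0.30
    seed: int = 0

    def __post_init__(self):
        if self.amp_log2 <= 0 or self.del_log2 >= 0:
            raise ValueError("amp_log2 must be > 0 and del_log2 < 0")
        if self.n_boot < 100:
            raise ValueError("n_boot must be >= 100")


@dataclass(frozen=True)
class GeneCNACall:
    sample_id: str
    gene: str
    log2_ratio: float
    z: float
    boot_ci: Tuple[float, float]
    call: str                      # amp | del | neutral
    est_copies: Optional[float] = None
    low_confidence: bool = False   # fewer than min_targets targets


@dataclass
class PanelOfNormals:
    """Per-gene reference: median and MAD of relative coverage over normals."""

    reference: pd.DataFrame        # gene, ref_median, ref_mad, n_targets
    normal_samples: Tuple[str, ...]

    def genes(self) -> List[str]:
        return list(self.reference["gene"])


def expected_log2(copies: float, tumor_fraction: float) -> float:
    """Expected coverage log2 ratio of a c-copy gene at tumor fraction f."""
    if copies < 0 or not (0 <= tumor_fraction <= 1):
        raise ValueError("copies must be >= 0 and tumor fraction in [0, 1]")
    with np.errstate(divide="ignore"):  # homozygous loss in pure tumor: -inf
        return float(np.log2((tumor_fraction * copies + 2 * (1 - tumor_fraction)) / 2))


def invert_expected_log2(log2_ratio: float, tumor_fraction: float) -> float:
    """Purity-adjusted copy estimate: inverse of :func:`expected_log2`."""
    if tumor_fraction <= 0:
        return float("nan")
    return float((2 * 2 ** log2_ratio - 2 * (1 - tumor_fraction)) / tumor_fraction)


def _normalize_targets(coverage: pd.DataFrame) -> pd.DataFrame:
    """Per-target depths divided by each sample's median target depth."""
    out = coverage.copy()
    med = out.groupby("sample_id")["depth"].median()
    if (med <= 0).any():
        bad = sorted(med[med <= 0].index)
        raise ValueError(f"zero median target depth in samples: {bad}")
    out["rel"] = out["depth"] / out["sample_id"].map(med)
    return out


def normalize_coverage(coverage: pd.DataFrame, normal_samples: Iterable[str]):
    """Build the per-target relative-coverage table and the normals reference.

    Returns ``(targets, pon)`` where ``targets`` carries a ``rel`` column and
    ``pon`` is the :class:`PanelOfNormals`.  Requires >= 3 normal samples;
    genes absent from the normals are excluded with a warning.
    """
    normal_samples = tuple(sorted(set(normal_samples)))
    if len(normal_samples) < 3:
        raise ValueError("panel of normals requires >= 3 normal samples")
    targets = _normalize_targets(coverage)
    normals = targets[targets["sample_id"].isin(normal_samples)]
    gene_rel = normals.groupby(["sample_id", "gene"])["rel"].median().reset_index()
    ref = gene_rel.groupby("gene")["rel"].agg(
        ref_median="median",
        ref_mad=lambda v: float(np.median(np.abs(v - np.median(v)))),
    ).reset_index()
    nt = targets.groupby("gene")["target"].nunique().rename("n_targets")
    ref = ref.merge(nt, on="gene")
    missing = set(targets["gene"]) - set(ref["gene"])
    if missing:
        warnings.warn(f"genes absent from normals are excluded: {sorted(missing)}")
        targets = targets[targets["gene"].isin(set(ref["gene"]))]
    return targets, PanelOfNormals(ref.sort_values("gene").reset_index(drop=True), normal_samples)


def _boot_rng(seed: int, sample_id: str, gene: str) -> np.random.Generator:
    """Deterministic bootstrap stream derived from (seed, sample, gene)."""
    ss = np.random.SeedSequence(
        entropy=int(seed) & 0x7FFFFFFF,
        spawn_key=(zlib.crc32(sample_id.encode()), zlib.crc32(gene.encode())),
    )
    return np.random.default_rng(ss)


def call_gene_cna(rel_targets: np.ndarray, ref_median: float, ref_mad: float,
                  sample_id: str, gene: str, config: CNAConfig = CNAConfig(),
                  tumor_fraction: Optional[float] = None) -> GeneCNACall:
    """Call one gene in one sample against the normals reference."""
    rel_targets = np.asarray(rel_targets, dtype=float)
    nt = len(rel_targets)
    gene_rel = float(np.median(rel_targets))
    log2_ratio = float(np.log2(gene_rel / ref_median))
    scale = 1.4826 * ref_mad
    diff = gene_rel - ref_median
    z = float(diff / scale) if scale > 0 else (0.0 if diff == 0 else math.copysign(math.inf, diff))

    rng = _boot_rng(config.seed, sample_id, gene)
    idx = rng.integers(0, nt, size=(config.n_boot, nt))
    boot = np.log2(np.median(rel_targets[idx], axis=1) / ref_median)
    lo, hi = np.percentile(boot, [2.5, 97.5])

    if lo > 0 and log2_ratio >= config.amp_log2:
        call = "amp"
    elif hi < 0 and log2_ratio <= config.del_log2:
        call = "del"
    else:
        call = "neutral"
    est = invert_expected_log2(log2_ratio, tumor_fraction) if tumor_fraction else None
    return GeneCNACall(sample_id, gene, log2_ratio, z, (float(lo), float(hi)),
                       call, est, low_confidence=nt < config.min_targets)


def call_sample(targets: pd.DataFrame, pon: PanelOfNormals, sample_id: str,
                config: CNAConfig = CNAConfig(),
                tumor_fraction: Optional[float] = None) -> pd.DataFrame:
    """Call every gene of one sample; returns the flat calls table."""
    ref = pon.reference.set_index("gene")
    here = targets[targets["sample_id"] == sample_id]
    rows = []
    for gene, grp in here.groupby("gene", sort=True):
        call = call_gene_cna(
            grp.sort_values("target")["rel"].to_numpy(),
            float(ref.loc[gene, "ref_median"]), float(ref.loc[gene, "ref_mad"]),
            sample_id, gene, config, tumor_fraction,
        )
        rows.append({
            "sample_id": sample_id, "gene": gene, "log2_ratio": call.log2_ratio,
            "z": call.z, "ci_low": call.boot_ci[0], "ci_high": call.boot_ci[1],
            "call": call.call, "est_copies": call.est_copies,
            "low_confidence": call.low_confidence,
        })
    return pd.DataFrame(rows)


def call_cohort(coverage: pd.DataFrame, normal_samples: Iterable[str],
                sample_ids: Iterable[str], config: CNAConfig = CNAConfig(),
                tumor_fractions: Optional[Dict[str, float]] = None) -> pd.DataFrame:
    """Normalize once and call a batch of samples."""
    targets, pon = normalize_coverage(coverage, normal_samples)
    frames = []
    for sid in sorted(set(sample_ids)):
        tf = (tumor_fractions or {}).get(sid)
        frames.append(call_sample(targets, pon, sid, config, tf))
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def cna_concordance(plasma_calls: pd.DataFrame, tissue_calls: pd.DataFrame,
                    sample_fractions: Dict[str, float],
                    sample_patients: Dict[str, str],
                    config: CNAConfig = CNAConfig()) -> Tuple[pd.Series, float]:
    """Directional agreement of non-neutral calls, plasma vs tissue.

    Only plasma samples whose ctDNA fraction exceeds the tumor-content
    threshold qualify; concordance for a patient is |non-neutral calls
    agreeing in direction| / |non-neutral tissue calls|.  Returns the
    per-patient series and the cohort median over qualifying patients.
    """
    thr = config.tumor_content_min_for_concordance
    qualifying = {s for s, f in sample_fractions.items() if f is not None and f > thr}
    result = {}
    patients = sorted({sample_patients[s] for s in set(tissue_calls["sample_id"])
                       if s in sample_patients})
    for patient in patients:
        tis = tissue_calls[tissue_calls["sample_id"].map(sample_patients) == patient]
        tis = tis[tis["call"] != "neutral"]
        pla = plasma_calls[
            (plasma_calls["sample_id"].map(sample_patients) == patient)
            & plasma_calls["sample_id"].isin(qualifying)
        ]
        if pla.empty:
            continue  # no qualifying plasma sample: patient excluded, reported
        if tis.empty:
            result[patient] = np.nan
            continue
        pla_dir = pla[pla["call"] != "neutral"].groupby("gene")["call"].agg(
            lambda c: c.mode().iloc[0])
        tis_dir = tis.groupby("gene")["call"].agg(lambda c: c.mode().iloc[0])
        agree = sum(1 for g, d in tis_dir.items() if pla_dir.get(g) == d)
        result[patient] = agree / len(tis_dir)
    series = pd.Series(result, dtype=float).sort_index()
    return series, float(series.median()) if len(series) else float("nan")


def cna_burden_correlation(calls: pd.DataFrame, sample_fractions: Dict[str, float]) -> Dict[str, float]:
    """Correlate per-sample non-neutral call counts with ctDNA fraction.

    Reports both Pearson (default metric) and Spearman.
    """
    counts = calls[calls["call"] != "neutral"].groupby("sample_id").size()
    samples = sorted(set(calls["sample_id"]))
    x = np.array([sample_fractions.get(s, np.nan) for s in samples], dtype=float)
    y = np.array([counts.get(s, 0) for s in samples], dtype=float)
    return {
        "pearson": correlate_series(x, y, "pearson"),
        "spearman": correlate_series(x, y, "spearman"),
        "n": int(np.sum(~np.isnan(x))),
    }
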