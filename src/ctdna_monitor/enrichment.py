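"""Gene-set over-representation for persistently mutated genes.

Genes whose mutation VAF did *not* significantly decrease by the end of
treatment (the candidate chemoresistance drivers) are selected per patient
scope and tested for over-representation against user-supplied GMT gene
sets with the upper hypergeometric tail, conditioning on the panel gene
list as the background.  P-values across the set battery are adjusted
with Benjamini-Hochberg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Set

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .monitor import ON_POST_PHASES


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    overlap: int
    set_size: int
    n_selected: int
    background_size: int
    p: float
    q: float = float("nan")


def select_nondecreasing_genes(tests: pd.DataFrame, scope: Iterable[str],
                               alpha: float = 0.01, mode: str = "last") -> Set[str]:
    """Genes harboring a variant whose VAF did not significantly decrease.

    ``tests`` is the decrease-test table from
    :func:`ctdna_monitor.monitor.decrease_tests`.  A gene qualifies when,
    for >= 1 patient in ``scope``, >= 1 of its tracked variants has an
    evaluable decrease p >= alpha at the anchor sample: the patient's last
    on/post-treatment plasma sample (``mode="last"``, default) or any
    such sample (``mode="all"``).
    """
    scope = sorted(set(scope))
    if not scope:
        raise ValueError("patient scope must be non-empty")
    if mode not in ("last", "all"):
        raise ValueError(f"unknown mode {mode!r}")
    t = tests[tests["patient_id"].isin(scope) & tests["phase"].isin(ON_POST_PHASES)]
    t = t[t["decrease_p"].notna()]
    if t.empty:
        return set()
    if mode == "last":
        last = t.groupby("patient_id")["timepoint_days"].transform("max")
        t = t[t["timepoint_days"] == last]
    stable = t[t["decrease_p"] >= alpha]
    return set(stable["gene"]) - {""}


def ora_hypergeometric(selected: Set[str], gene_set: Set[str],
                       background: Set[str], set_name: str = "") -> EnrichmentResult:
    """Upper hypergeometric tail P(X >= overlap) for one gene set.

    The gene set is intersected with the background before testing;
    ``selected`` must be a subset of the background.
    """
    if not background:
        raise ValueError("background gene list must be non-empty")
    selected = set(selected)
    if not selected <= set(background):
        raise ValueError("selected genes must be a subset of the background")
    effective = set(gene_set) & set(background)
    if not effective:
        warnings.warn(f"gene set {set_name!r} is disjoint from the background")
        return EnrichmentResult(set_name, 0, 0, len(selected), len(background), 1.0)
    overlap = len(selected & effective)
    p = float(stats.hypergeom.sf(overlap - 1, len(background), len(effective), len(selected)))
    return EnrichmentResult(set_name, overlap, len(effective), len(selected),
                            len(background), min(p, 1.0))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(list(pvalues), dtype=float)
    if len(p) == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_enrichment(selected: Set[str], gene_sets: Dict[str, Set[str]],
                   background: Set[str]) -> pd.DataFrame:
    """Test a battery of gene sets and BH-adjust across them."""
    results: List[EnrichmentResult] = [
        ora_hypergeometric(selected, genes, background, name)
        for name, genes in sorted(gene_sets.items())
    ]
    q = bh_adjust([r.p for r in results]) if results else []
    rows = [
        {"set_name": r.set_name, "overlap": r.overlap, "set_size": r.set_size,
         "n_selected": r.n_selected, "background_size": r.background_size,
         "p": r.p, "q": qi}
        for r, qi in zip(results, q)
    ]
    return pd.DataFrame(rows, columns=["set_name", "overlap", "set_size", "n_selected",
                                       "background_size", "p", "q"])
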