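"""Plots for burden tracks and variant trajectories.

Matplotlib is imported lazily so the analysis pipeline has no hard
display dependency at import time.
"""

from __future__ import annotations

import pandas as pd


def plot_burden_track(burden: pd.DataFrame, ax=None):
    """TP53 VAF (orange) and median VAF (blue) over time for one patient,
    with CA-125 on a secondary axis when present."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    b = burden.sort_values("timepoint_days")
    ax.plot(b["timepoint_days"], 100 * b["tp53_vaf"], "o-", color="tab:orange", label="TP53 VAF")
    ax.plot(b["timepoint_days"], 100 * b["median_vaf"], "s-", color="tab:blue", label="median VAF")
    ax.set_xlabel("days from treatment start")
    ax.set_ylabel("VAF (%)")
    patient = b["patient_id"].iloc[0] if len(b) else ""
    ax.set_title(f"{patient} tumor burden")
    if b["ca125"].notna().any():
        ax2 = ax.twinx()
        ax2.plot(b["timepoint_days"], b["ca125"], "^--", color="tab:gray", alpha=0.6, label="CA-125")
        ax2.set_ylabel("CA-125 (IU/mL)")
    ax.legend(loc="upper right", fontsize=8)
    return ax


def plot_trajectories(points: pd.DataFrame, patient_id: str, ax=None, normalize: bool = False):
    """Per-variant VAF time series for one patient.

    With ``normalize`` each trajectory is scaled to its own maximum to show
    relative changes regardless of level.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    pts = points[points["patient_id"] == patient_id]
    for key, grp in pts.groupby("key"):
        grp = grp.sort_values("timepoint_days")
        y = grp["vaf"]
        if normalize and y.max() > 0:
            y = y / y.max()
        label = grp["gene"].iloc[0] or key
        ax.plot(grp["timepoint_days"], y, "o-", alpha=0.7, label=label)
    ax.set_xlabel("days from treatment start")
    ax.set_ylabel("relative VAF" if normalize else "VAF")
    ax.set_title(f"{patient_id} variant trajectories")
    if pts["key"].nunique() <= 12:
        ax.legend(fontsize=7)
    return ax
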