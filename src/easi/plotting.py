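"""Optional matplotlib convenience plots (not an acceptance surface)."""

from __future__ import annotations

from .model import Trajectory
from .population import EnsembleSummary

__all__ = ["plot_trajectory", "plot_ensemble"]


def plot_trajectory(t: Trajectory, ax=None):
    """Life-course panel: exposure, activity and impact (left axis, fractions)
    against FEV1 in liters (right axis)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    f = t.frame
    e_max = f["exposure_packs_day"].max()
    e_norm = f["exposure_packs_day"] / e_max if e_max > 0 else f["exposure_packs_day"]
    ax.plot(f["age"], e_norm, color="tab:blue", label="Exposure (fraction of max)")
    ax.plot(f["age"], f["activity"], color="tab:red", label="Activity")
    ax.plot(f["age"], f["impact"], color="tab:green", label="Impact")
    ax.set_xlabel("age (years)")
    ax.set_ylabel("fraction of maximum")
    ax.set_ylim(-0.02, 1.02)
    ax2 = ax.twinx()
    ax2.plot(f["age"], f["fev1_L"], color="tab:cyan", label="FEV1 (L)")
    ax2.set_ylabel("FEV1 (L)")
    ax.legend(loc="center left", fontsize=8)
    return ax


def plot_ensemble(summary: EnsembleSummary, ax=None):
    """Cohort mean FEV1 with a +/-1 SD band by age."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    b = summary.by_age
    ax.plot(b["age"], b["mean_fev1_L"], color="tab:blue", label="mean FEV1")
    ax.fill_between(
        b["age"],
        b["mean_fev1_L"] - b["sd_fev1_L"],
        b["mean_fev1_L"] + b["sd_fev1_L"],
        alpha=0.3,
        color="tab:blue",
        label="+/- 1 SD",
    )
    ax.set_xlabel("age (years)")
    ax.set_ylabel("FEV1 (L)")
    ax.legend()
    return ax
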