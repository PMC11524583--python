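"""Headless-safe plotting: predicted-vs-observed PS scatter and TEER time courses."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .records import IvivcResult, TeerValue

__all__ = ["plot_ivivc_scatter", "plot_teer_timecourse"]


def plot_ivivc_scatter(results: Sequence[IvivcResult], path: str | Path) -> Path:
    """Log–log scatter of predicted vs observed PS with identity and
    0.5×/2× guide lines, one panel per model."""
    if not results:
        raise ValueError("nothing to plot")
    models = sorted({r.model_id for r in results})
    fig, axes = plt.subplots(1, len(models), figsize=(5 * len(models), 4.5), squeeze=False)
    for ax, model in zip(axes[0], models):
        sub = [r for r in results if r.model_id == model]
        obs = np.array([r.ps_obs for r in sub])
        pre = np.array([r.ps_pre for r in sub])
        ok = np.array([r.within_2fold for r in sub])
        lo = min(obs.min(), pre.min()) / 3
        hi = max(obs.max(), pre.max()) * 3
        grid = np.array([lo, hi])
        ax.plot(grid, grid, "k-", lw=1)
        ax.plot(grid, 2 * grid, "k--", lw=0.8)
        ax.plot(grid, 0.5 * grid, "k--", lw=0.8)
        ax.scatter(obs[ok], pre[ok], c="tab:blue", label="within 2-fold")
        if (~ok).any():
            ax.scatter(obs[~ok], pre[~ok], c="tab:red", label="outside")
        ax.set_xscale("log")
        ax.set_yscale("log")
        ax.set_xlabel("observed PS (µL/min/g)")
        ax.set_ylabel("predicted PS (µL/min/g)")
        ax.set_title(model)
        ax.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_teer_timecourse(values: Sequence[TeerValue], path: str | Path) -> Path:
    """Mean ± SEM corrected TEER per model across culture days."""
    if not values:
        raise ValueError("nothing to plot")
    fig, ax = plt.subplots(figsize=(6, 4))
    models = sorted({v.model_id for v in values})
    for model in models:
        sub = sorted((v for v in values if v.model_id == model), key=lambda v: v.day)
        days = [v.day for v in sub]
        means = [v.teer_mean for v in sub]
        sems = [v.teer_sem for v in sub]
        ax.errorbar(days, means, yerr=sems, marker="o", capsize=3, label=model)
    ax.set_xlabel("culture day")
    ax.set_ylabel("TEER (Ω·cm²)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
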