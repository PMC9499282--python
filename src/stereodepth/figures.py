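"""Figure-style outputs and the end-to-end simulation pipeline."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .analysis import DEFAULT_N_BOOT, fit_conditions, summarize
from .observer import ExperimentDesign, exp1_design, simulate_trials
from .stimulus import ARCMIN_PER_DEG


def plot_psychometric(summary: pd.DataFrame, path: str | Path,
                      measure: str = "natural") -> Path:
    """Proportion (natural or confident) versus eccentricity, one panel
    per duration-by-configuration condition, CRDS and ACRDS overlaid
    with bootstrap confidence limits."""
    durations = sorted(summary["duration_ms"].unique())
    configs = sorted(summary["configuration"].unique())
    fig, axes = plt.subplots(len(durations), len(configs), squeeze=False,
                             figsize=(4.2 * len(configs), 3.4 * len(durations)),
                             sharey=True)
    colors = {"correlated": "tab:blue", "anticorrelated": "tab:pink"}
    markers = {"correlated": "s", "anticorrelated": "o"}
    for i, dur in enumerate(durations):
        for j, cfg in enumerate(configs):
            ax = axes[i][j]
            panel = summary[(summary["duration_ms"] == dur)
                            & (summary["configuration"] == cfg)]
            for corr, grp in panel.groupby("correlation"):
                grp = grp.sort_values("eccentricity_arcmin")
                x = grp["eccentricity_arcmin"] / ARCMIN_PER_DEG
                y = grp[f"proportion_{measure}"]
                yerr = np.vstack([y - grp[f"ci_low_{measure}"],
                                  grp[f"ci_high_{measure}"] - y])
                ax.errorbar(x, y, yerr=yerr, color=colors[corr],
                            marker=markers[corr], capsize=3, label=corr)
            ax.axhline(0.5, ls=":", color="grey")
            ax.set_ylim(0.0, 1.05)
            ax.set_title(f"{cfg}, {dur:.0f} ms")
            ax.set_xlabel("eccentricity (deg)")
            if j == 0:
                ax.set_ylabel(f"proportion {measure}")
    axes[0][0].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def run_pipeline(
    design: ExperimentDesign | None = None,
    seed: int = 0,
    outdir: str | Path = "results",
    n_boot: int = DEFAULT_N_BOOT,
) -> dict[str, Path]:
    """Simulate an experiment, analyse it, and write figure-style outputs.

    Deterministic: the seed drives the observer simulation and the
    bootstrap, so repeated runs produce byte-identical CSVs.  Writes
    ``trials.csv``, ``summary.csv``, ``fits.csv`` and two PNG panels
    (depth judgments and confidence), returning their paths.
    """
    if design is None:
        design = exp1_design()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(seed)
    rng_sim, rng_boot = (np.random.default_rng(s) for s in root.spawn(2))
    trials = simulate_trials(design, rng=rng_sim)
    summary = summarize(trials, n_boot=n_boot, rng=rng_boot)
    fits = fit_conditions(trials)
    paths = {
        "trials": outdir / "trials.csv",
        "summary": outdir / "summary.csv",
        "fits": outdir / "fits.csv",
        "figure_natural": outdir / "proportion_natural.png",
        "figure_confident": outdir / "proportion_confident.png",
    }
    trials.to_csv(paths["trials"], index=False)
    summary.to_csv(paths["summary"], index=False, float_format="%.10g")
    fits.to_csv(paths["fits"], index=False, float_format="%.10g")
    plot_psychometric(summary, paths["figure_natural"], measure="natural")
    plot_psychometric(summary, paths["figure_confident"], measure="confident")
    return paths
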