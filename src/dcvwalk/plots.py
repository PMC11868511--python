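"""Matplotlib figures for the analysis reports.

Advisory visual output only: every quantitative result lives in the CSV/JSON
artifacts, never in the pixels.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .distributions import bb_mean_variance, bb_pmf, fpt_frame_probs
from .params import ModelParams

__all__ = [
    "displacement_histogram_figure",
    "moments_figure",
    "fpt_histogram_figure",
]


def displacement_histogram_figure(samples, params: ModelParams | None):
    """Step-count histograms per lag, with the beta-binomial overlay."""
    fig, axes = plt.subplots(
        1, max(len(samples), 1), figsize=(5 * max(len(samples), 1), 4),
        squeeze=False,
    )
    for ax, sample in zip(axes[0], samples):
        n = sample.n_trials
        support = np.arange(n + 1)
        freq = np.bincount(sample.k_values, minlength=n + 1) / max(len(sample), 1)
        ax.bar(support, freq, width=1.0, color="#9ecae1", label="data")
        if params is not None:
            ax.plot(
                support, bb_pmf(support, n, params), "k.", ms=4,
                label=f"beta-binomial ({params.alpha:.2f}, {params.beta:.2f})",
            )
        ax.set_xlabel("displacement (steps)")
        ax.set_ylabel("frequency")
        ax.set_title(f"t = {sample.t_seconds} s (n = {len(sample)})")
        ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    return fig


def moments_figure(stats, params: ModelParams | None):
    """Mean and variance of displacement versus lag, with theory curves."""
    fig, (ax_m, ax_v) = plt.subplots(1, 2, figsize=(10, 4))
    ax_m.plot(stats.lags_s, stats.mean_um, "o", color="#3182bd", label="data")
    ax_v.plot(stats.lags_s, stats.var_um2, "o", color="#3182bd", label="data")
    if params is not None and len(stats.lags_s):
        tt = np.linspace(min(stats.lags_s), max(stats.lags_s), 80)
        theory = [
            bb_mean_variance(round(t / params.step_time_s) * params.step_time_s, params)
            for t in tt
        ]
        ax_m.plot(tt, [m for m, _ in theory], "k-", label="model")
        ax_v.plot(tt, [v for _, v in theory], "k-", label="model")
    ax_m.set_xlabel("t (s)")
    ax_m.set_ylabel("mean displacement (µm)")
    ax_v.set_xlabel("t (s)")
    ax_v.set_ylabel("var displacement (µm²)")
    for ax in (ax_m, ax_v):
        ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    return fig


def fpt_histogram_figure(fpt_by_threshold: dict, params: ModelParams | None,
                         frame_interval_s: float):
    """First-passage-time histograms per threshold with the BNB overlay."""
    n_panels = max(len(fpt_by_threshold), 1)
    fig, axes = plt.subplots(1, n_panels, figsize=(5 * n_panels, 4), squeeze=False)
    for ax, (threshold, times) in zip(axes[0], fpt_by_threshold.items()):
        times = np.asarray(times)
        if times.size == 0:
            continue
        frames = np.rint(times / frame_interval_s).astype(int)
        m_max = frames.max()
        edges = (np.arange(m_max + 1) + 0.5) * frame_interval_s
        ax.hist(times, bins=edges, density=True, color="#a1d99b", label="data")
        if params is not None:
            spf = round(frame_interval_s / params.step_time_s)
            k = params.k_steps(threshold)
            probs = fpt_frame_probs(k, int(m_max), params, steps_per_frame=spf)
            tt = np.arange(1, m_max + 1) * frame_interval_s
            ax.plot(tt, probs / frame_interval_s, "k-", label="beta-neg-binomial")
        ax.set_xlabel("first passage time (s)")
        ax.set_ylabel("density")
        ax.set_title(f"L = {threshold} µm (n = {times.size})")
        ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    return fig
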