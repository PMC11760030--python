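"""Plot helpers: Bland–Altman panels, identity regression, cycle traces."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .agreement import _match_tables, bland_altman


def bland_altman_plot(ref, cand, ax=None, label: str = ""):
    """Difference-vs-mean scatter with bias and 95% limit lines."""
    ref = np.asarray(ref, float)
    cand = np.asarray(cand, float)
    if ax is None:
        _, ax = plt.subplots()
    bias, lo, hi = bland_altman(ref, cand)
    ax.scatter((ref + cand) / 2.0, cand - ref, s=12, alpha=0.7)
    ax.axhline(bias, color="black", lw=1.2)
    for y in (lo, hi):
        ax.axhline(y, color="red", ls="--", lw=1.0)
    ax.set_xlabel(f"mean of methods {label}")
    ax.set_ylabel("candidate − reference")
    return ax


def regression_plot(ref, cand, ax=None, label: str = ""):
    """Scatter with identity line and the fitted regression line."""
    from .agreement import fit_identity_regression

    ref = np.asarray(ref, float)
    cand = np.asarray(cand, float)
    if ax is None:
        _, ax = plt.subplots()
    slope, intercept, r = fit_identity_regression(ref, cand)
    ax.scatter(ref, cand, s=12, alpha=0.7)
    lim = np.array([ref.min(), ref.max()])
    ax.plot(lim, lim, color="black", lw=1.0, label="identity")
    ax.plot(lim, slope * lim + intercept, color="tab:red", lw=1.0,
            label=f"fit (slope {slope:.3f}, r {r:.3f})")
    ax.set_xlabel(f"reference {label}")
    ax.set_ylabel("candidate")
    ax.legend(fontsize=7)
    return ax


def agreement_figure(ref_params, cand_params, mode, tol_s, path: str | Path):
    """One Bland–Altman panel per temporal parameter, written to ``path``."""
    matched = _match_tables(ref_params, cand_params, tol_s)
    params = [
        p for p in ("stride_time", "step_time", "stance_time",
                    "swing_time", "double_support_time", "cadence")
        if f"{p}_ref" in matched.columns
    ]
    fig, axes = plt.subplots(2, 3, figsize=(12, 7))
    for ax, param in zip(axes.ravel(), params):
        pairs = matched[["subject_ref", f"{param}_ref", f"{param}_cand"]].dropna()
        if mode == "participants_mean":
            pairs = pairs.groupby("subject_ref").mean()
        try:
            bland_altman_plot(
                pairs[f"{param}_ref"], pairs[f"{param}_cand"], ax=ax, label=param
            )
        except ValueError:
            ax.set_visible(False)
            continue
        ax.set_title(param.replace("_", " "))
    fig.suptitle(f"Bland–Altman, {mode}")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path


def cycle_angle_figure(traces: np.ndarray, path: str | Path, title: str = ""):
    """Ensemble mean ± SD of cycle-normalised angle traces (0–100%)."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    pct = np.linspace(0, 100, traces.shape[1])
    mean = traces.mean(axis=0)
    sd = traces.std(axis=0)
    ax.plot(pct, mean, color="tab:red")
    ax.fill_between(pct, mean - sd, mean + sd, alpha=0.3, color="tab:red")
    ax.set_xlabel("gait cycle (%)")
    ax.set_ylabel("angle (deg)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path
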