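"""Deterministic figure generation from experiment result bundles."""

from __future__ import annotations

import warnings
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_figures"]


def _plot_paths(ax, paths, color, label=None):
    for i, p in enumerate(paths):
        ax.plot(p[:, 0], p[:, 1], color=color, lw=0.8,
                label=label if i == 0 else None)
    ax.set_aspect("equal")


def _conditt_figure(results):
    fig, axes = plt.subplots(2, 4, figsize=(13, 7))
    panels = [
        ("nf", "free condition"),
        ("first_exposure", "first exposure"),
        ("in_field_direct", "in field (circle-trained)"),
        ("in_field_transfer", "in field (reach-trained)"),
        ("after_direct", "after-effect (circle-trained)"),
        ("after_transfer", "after-effect (reach-trained)"),
    ]
    reach = results["paths"].get("reach", {})
    ax = axes[0, 0]
    for phase, color in (("early", "gold"), ("late", "c"), ("after", "m")):
        if phase in reach:
            _plot_paths(ax, reach[phase], color, label=phase)
    ax.set_title("reaching movements")
    ax.legend(fontsize=7)
    for (key, title), ax in zip(panels, axes.flat[1:]):
        _plot_paths(ax, results["paths"][key], "tab:blue")
        ax.set_title(f"{title}\nratio {results['ratios'][key]:.2f}", fontsize=9)
    axes.flat[-1].axis("off")
    fig.tight_layout()
    return fig


def _thoroughman_figure(results):
    ks = sorted(results["correlation_curves"])
    fig, axes = plt.subplots(2, len(ks) + 1, figsize=(4 * (len(ks) + 1), 7))
    ax = axes[0, 0]
    for k in ks:
        ax.plot(results["correlation_curves"][k], label=f"VF{k}")
    ax.axhline(0.9, ls="--", c="k", lw=0.7)
    ax.set_xlabel("field trial")
    ax.set_ylabel("velocity correlation (20-trial avg)")
    ax.legend()
    axes[1, 0].axis("off")
    for j, k in enumerate(ks):
        p = results["paths"][k]
        _plot_paths(axes[0, j + 1], p["before"], "gold")
        _plot_paths(axes[0, j + 1], p["after"], "tab:blue")
        axes[0, j + 1].set_title(f"VF{k}: before/after")
        _plot_paths(axes[1, j + 1], p["after"], "tab:blue")
        _plot_paths(axes[1, j + 1], p["aftereffect"], "m")
        axes[1, j + 1].set_title(f"VF{k}: after-effects")
    fig.tight_layout()
    return fig


def _ellipse_points(K, scale=2e-4):
    th = np.linspace(0, 2 * np.pi, 100)
    circ = np.stack([np.cos(th), np.sin(th)])
    Ks = 0.5 * (K + K.T)
    return (Ks @ circ) * scale


def _kadiallah_figure(results):
    fig, axes = plt.subplots(1, 3, figsize=(13, 4.5))
    for d, color in ((0, "tab:blue"), (1, "tab:red")):
        _plot_paths(axes[0], results["early_paths"][d], color)
        _plot_paths(axes[1], results["late_paths"][d], color)
    axes[0].set_title("initial trials in the divergent field")
    axes[1].set_title("after 300 trials")
    ax = axes[2]
    for d, color in ((0, "tab:blue"), (1, "tab:red")):
        for key, ls in (("stiffness_before", "--"), ("stiffness_after", "-")):
            pts = _ellipse_points(results[key][d].K)
            ax.plot(pts[0], pts[1], color=color, ls=ls)
    ax.set_aspect("equal")
    ax.set_title("endpoint stiffness ellipses (dashed: before)")
    fig.tight_layout()
    return fig


def plot_figures(results: dict, outdir: str | Path) -> list:
    """Write the figures for one experiment's results bundle.

    The bundle's contents determine which layout is produced.  Missing
    phases produce a partial figure with a warning; an empty bundle is an
    error.
    """
    if not results:
        raise ValueError("empty results bundle")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    try:
        if "ratios" in results:
            fig = _conditt_figure(results)
            path = outdir / "movement_generalization.png"
        elif "correlation_curves" in results:
            fig = _thoroughman_figure(results)
            path = outdir / "granularity.png"
        elif "stiffness_after" in results:
            fig = _kadiallah_figure(results)
            path = outdir / "impedance_learning.png"
        else:
            raise KeyError("unrecognized bundle contents")
    except KeyError as exc:
        warnings.warn(f"incomplete bundle, partial figure skipped: {exc}")
        return written
    fig.savefig(path, dpi=150)
    plt.close(fig)
    written.append(path)
    return written
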