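"""Figure helpers for the comparison analyses (headless-safe)."""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .compare import SensitivityDistribution


def plot_sensitivity_distributions(dists: list[SensitivityDistribution],
                                   path: str | Path, level: int = 90) -> Path:
    """Overlaid histograms of pooled VF sensitivities with CI boundary lines."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for dist in dists:
        ax.hist(dist.values, bins=40, density=True, alpha=0.45,
                label=f"{dist.group} ({dist.technique})")
        lo, hi = dist.boundaries[level]
        for b in (lo, hi):
            ax.axvline(b, linestyle="--", linewidth=0.8)
    ax.set_xlabel("VF sensitivity (dB)")
    ax.set_ylabel("density")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_qq(points: np.ndarray, path: str | Path,
            xlabel: str = "pRF quantiles (dB)",
            ylabel: str = "MP quantiles (dB)") -> Path:
    """Quantile-quantile plot with the identity reference line."""
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(points[:, 0], points[:, 1], "o", ms=3)
    lims = [min(points.min(), 0), max(points.max(), 0)]
    ax.plot(lims, lims, "k--", linewidth=0.8)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_scatter_fits(x: np.ndarray, y: np.ndarray, result: dict,
                      path: str | Path) -> Path:
    """Scatter of the two sensitivity estimates with the linear and
    polynomial least-squares fits from :func:`linear_vs_polynomial`."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(x, y, ".", ms=2, alpha=0.4)
    xx = np.linspace(x.min(), x.max(), 200)
    ax.plot(xx, np.polyval(np.polyfit(x, y, 1), xx),
            label=f"linear R={result['R_lin']:.2f}")
    ax.plot(xx, np.polyval(np.polyfit(x, y, result["degree"]), xx),
            label=f"poly(deg {result['degree']}) R={result['R_poly']:.2f}")
    ax.set_xlabel("pRF sensitivity (dB)")
    ax.set_ylabel("MP sensitivity (dB)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
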