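"""Small plotting helpers: loading scatters and scree plots."""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402


def loading_scatter(x, y, path, xlabel: str = "phenotypic PC1 loading",
                    ylabel: str = "genetic PC1 loading",
                    highlight: np.ndarray | None = None) -> None:
    """Scatter of two per-trait vectors (loadings, age sensitivities, ...)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    colors = np.where(highlight, "crimson", "steelblue") if highlight is not None else "steelblue"
    ax.scatter(x, y, s=18, c=colors, alpha=0.8, edgecolors="none")
    lo = min(x.min(), y.min())
    hi = max(x.max(), y.max())
    pad = 0.05 * (hi - lo if hi > lo else 1.0)
    ax.plot([lo - pad, hi + pad], [lo - pad, hi + pad], ls=":", c="grey", lw=1)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(Path(path), dpi=150)
    plt.close(fig)


def scree_plot(eigenvalues, path, null_p95=None) -> None:
    """Observed eigenvalues by rank, optionally with a parallel-analysis null."""
    ev = np.asarray(eigenvalues, float)
    ranks = np.arange(1, len(ev) + 1)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(ranks, ev, "o-", ms=4, label="observed")
    if null_p95 is not None:
        ax.plot(ranks, np.asarray(null_p95, float), "s--", ms=3,
                c="grey", label="null 95th percentile")
        ax.legend(frameon=False)
    ax.set_xlabel("component")
    ax.set_ylabel("eigenvalue")
    fig.tight_layout()
    fig.savefig(Path(path), dpi=150)
    plt.close(fig)
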