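"""Optional figures: chromosome dosage bars and the validation scatter."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


def plot_chromosome_ratios(summary: pd.DataFrame, path: str | Path) -> None:
    """Bar plot of the per-chromosome A/B mean-expression ratio."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = summary.sort_index()
    fig, ax = plt.subplots(figsize=(8, 3.5))
    ax.bar(df.index.astype(str), df["ratio"], color="#4878b0")
    ax.axhline(1.0, color="grey", lw=0.8)
    ax.axhline(1.5, color="firebrick", lw=0.8, ls="--", label="3:2 dosage")
    ax.set_xlabel("chromosome")
    ax.set_ylabel("A/B mean expression ratio")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_validation_scatter(
    expected: np.ndarray, observed: np.ndarray, path: str | Path
) -> None:
    """Expected (map) vs observed (qPCR) ratios with a 95% normal ellipse."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Ellipse
    from scipy import stats

    x = np.asarray(expected, dtype=float)
    y = np.asarray(observed, dtype=float)
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(x, y, color="#4878b0", zorder=3)
    # 95% bivariate-normal ellipse from the sample covariance
    cov = np.cov(x, y)
    evals, evecs = np.linalg.eigh(cov)
    chi2 = stats.chi2.ppf(0.95, df=2)
    width = 2.0 * np.sqrt(chi2 * evals[-1])  # principal axis
    height = 2.0 * np.sqrt(chi2 * evals[0])
    angle = float(np.degrees(np.arctan2(evecs[1, -1], evecs[0, -1])))
    ax.add_patch(
        Ellipse(
            (x.mean(), y.mean()), width=width, height=height, angle=angle,
            facecolor="none", edgecolor="grey", ls="--",
        )
    )
    r = stats.pearsonr(x, y)
    ax.set_xlabel("expected ratio (integrated map)")
    ax.set_ylabel("observed ratio (qPCR)")
    ax.set_title(f"r = {r.statistic:.2f}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
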