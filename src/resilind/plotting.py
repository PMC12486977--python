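"""Plot helpers: MDS scatter, LD decay, Manhattan and QQ plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def mds_plot(mds: pd.DataFrame, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    for breed, grp in mds.groupby("breed"):
        ax.scatter(grp["dim1"], grp["dim2"], s=6, alpha=0.6, label=str(breed))
    ax.set_xlabel("MDS dimension 1")
    ax.set_ylabel("MDS dimension 2")
    ax.legend(title="breed", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def ld_decay_plot(decay: pd.DataFrame, path: str | Path, label: str = "pooled") -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    mid = (decay["bin_start_bp"] + decay["bin_end_bp"]) / 2e3
    ax.plot(mid, decay["mean_r2"], marker="o", ms=3, label=label)
    ax.set_xlabel("distance (kb)")
    ax.set_ylabel(r"mean $r^2$")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def manhattan_plot(annotated: pd.DataFrame, path: str | Path) -> None:
    pcol = "p" if "p" in annotated.columns else "p_pooled"
    fig, ax = plt.subplots(figsize=(8, 3.2))
    for k, (chrom, grp) in enumerate(annotated.groupby("chrom", sort=False)):
        ax.scatter(grp["cum_pos"], -np.log10(grp[pcol]), s=4,
                   color="steelblue" if k % 2 == 0 else "darkorange")
    n = int(annotated[pcol].notna().sum())
    ax.axhline(-np.log10(0.05 / max(n, 1)), color="red", lw=0.8, ls="--")
    ax.axhline(-np.log10(5e-5), color="grey", lw=0.8, ls=":")
    ax.set_xlabel("genome position")
    ax.set_ylabel(r"$-\log_{10} p$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def qq_plot(pvalues: np.ndarray, path: str | Path) -> None:
    p = np.sort(pvalues[np.isfinite(pvalues)])
    exp = -np.log10((np.arange(1, p.size + 1) - 0.5) / p.size)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(exp, -np.log10(p), ".", ms=3)
    lim = max(exp.max(), -np.log10(p).max()) * 1.05
    ax.plot([0, lim], [0, lim], "k--", lw=0.8)
    ax.set_xlabel(r"expected $-\log_{10} p$")
    ax.set_ylabel(r"observed $-\log_{10} p$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
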