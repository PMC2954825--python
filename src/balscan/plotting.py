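"""Plot helpers: SFS panels and MFI boxplots (matplotlib)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .sfs import Spectrum

__all__ = ["plot_sfs", "plot_mfi_boxes"]


def plot_sfs(spectra: dict[str, Spectrum], ax=None, folded: bool = False):
    """Bar panels of projected spectra, one series per labelled region."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    width = 0.8 / max(len(spectra), 1)
    for k, (label, sp) in enumerate(spectra.items()):
        if folded:
            x = np.arange(1, sp.n // 2 + 1)
            y = sp.folded[1:]
        else:
            x = np.arange(1, sp.n)
            y = sp.unfolded[1 : sp.n]
        total = y.sum()
        ax.bar(x + k * width, y / total if total else y, width=width, label=label)
    ax.set_xlabel("minor-allele count" if folded else "derived-allele count")
    ax.set_ylabel("fraction of sites")
    ax.legend()
    return ax


def plot_mfi_boxes(records: pd.DataFrame, ax=None):
    """Standardized-MFI boxplots per experiment x genotype."""
    df = records.copy()
    df["standardized"] = df["hla_mfi"] / df["cd19_mfi"]
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    groups, labels = [], []
    for (e, g), sub in df.groupby(["experiment", "genotype"]):
        groups.append(sub["standardized"].to_numpy())
        labels.append(f"exp{e}\n{g}")
    ax.boxplot(groups, tick_labels=labels, showmeans=True)
    ax.set_ylabel("standardized HLA-ABC MFI")
    return ax
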