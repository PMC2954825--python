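"""Haplogroup partitioning, diagnostic SNPs, and rho-statistic dating.

Long-term balancing selection that maintains two allelic classes leaves two
deeply diverged haplotype clades at intermediate frequency.  This module
partitions haplotypes into two groups by agglomerative clustering on
pairwise Hamming distance, finds the diagnostic variants that separate the
groups, and dates the most recent common ancestor with the rho statistic
(mean mutational distance of haplotypes to an ancestral root haplotype),
calibrated by outgroup fixed differences at a known divergence time.

Rooting: the ancestral allele vector (outgroup-polarized) defines the root
haplotype — a deterministic substitute for network-based root inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "HaplogroupPartition",
    "TmrcaEstimate",
    "partition_haplogroups",
    "diagnostic_snps",
    "haplogroup_frequencies",
    "rho_tmrca",
]


@dataclass
class HaplogroupPartition:
    """Two-group haplotype labelling with support diagnostics."""

    labels: list[str]                   # per-haplotype group, "A" or "B"
    haplotype_ids: list[str]
    method: str = "complete-linkage Hamming"
    low_support: bool = False           # star-like data: groups not separated
    separation: float = float("nan")    # between-group / within-group distance

    def group_indices(self, group: str) -> np.ndarray:
        return np.asarray([i for i, g in enumerate(self.labels) if g == group])


@dataclass
class TmrcaEstimate:
    """Rho-statistic age estimate with its calibration inputs.

    ``rho`` is the mean number of mutational steps from a haplotype to the
    root; ``sigma`` the standard error of rho; ``mu_locus_per_year`` the
    locus mutation rate calibrated as FD / (2 * divergence_time), counting
    both lineages of the outgroup comparison.
    """

    rho: float
    sigma: float
    mu_locus_per_year: float
    age_years: float
    sigma_years: float
    calibration: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if min(self.rho, self.sigma, self.mu_locus_per_year, self.age_years) < 0:
            raise ValueError("rho-statistic quantities must be non-negative")


def _hamming_condensed(matrix: np.ndarray, missing="N") -> np.ndarray:
    """Pairwise Hamming distances (counts), missing entries skipped."""
    mat = np.asarray(matrix)
    if mat.dtype.kind in "iuf":
        return pdist(mat.astype(float), metric="hamming") * mat.shape[1]
    # string matrix with missing codes: pairwise called comparison
    n = mat.shape[0]
    out = []
    for i in range(n):
        for j in range(i + 1, n):
            both = (mat[i] != missing) & (mat[j] != missing)
            out.append(float((mat[i, both] != mat[j, both]).sum()))
    return np.asarray(out)


def partition_haplogroups(matrix: np.ndarray, k: int = 2) -> HaplogroupPartition:
    """Cut a complete-linkage Hamming dendrogram into ``k`` groups.

    Complete linkage resists chaining through recombinant intermediates.
    The partition is deterministic for a fixed row order (scipy's tie-break
    follows input ordering).  When the between-group separation does not
    exceed the within-group diameter the partition is flagged
    ``low_support`` (star-like data with no deep structure).
    """
    mat = np.asarray(matrix)
    if mat.shape[0] < 2:
        raise ValueError("need at least two haplotypes")
    dist = _hamming_condensed(mat)
    if np.all(dist == 0):
        raise ValueError("all haplotypes identical: no partition exists")
    z = linkage(dist, method="complete")
    assignment = cut_tree(z, n_clusters=k).ravel()
    # name groups by first appearance so labels are order-stable
    seen: dict[int, str] = {}
    names = iter("ABCDEFGH")
    labels = []
    for a in assignment:
        if a not in seen:
            seen[a] = next(names)
        labels.append(seen[a])
    sq = squareform(dist)
    within = []
    between = []
    for i in range(mat.shape[0]):
        for j in range(i + 1, mat.shape[0]):
            (within if labels[i] == labels[j] else between).append(sq[i, j])
    diam = max(within) if within else 0.0
    sep = (min(between) / diam) if (between and diam > 0) else float("inf")
    return HaplogroupPartition(
        labels=labels,
        haplotype_ids=[str(i) for i in range(mat.shape[0])],
        low_support=bool(sep <= 1.0),
        separation=float(sep),
    )


def diagnostic_snps(
    matrix: np.ndarray,
    partition: HaplogroupPartition,
    *,
    max_mismatch: int = 1,
    positions: np.ndarray | None = None,
) -> pd.DataFrame:
    """Sites whose alleles separate the two haplogroups.

    A site is *diagnostic* when every group-A haplotype carries one allele
    and every group-B haplotype the other; *nearly diagnostic* when at most
    ``max_mismatch`` haplotypes cross over.  Output is symmetric under a
    group-label swap.
    """
    mat = np.asarray(matrix)
    ia = partition.group_indices("A")
    ib = partition.group_indices("B")
    if len(ia) == 0 or len(ib) == 0:
        raise ValueError("partition must contain two non-empty groups")
    pos = positions if positions is not None else np.arange(mat.shape[1])
    rows = []
    for j in range(mat.shape[1]):
        col = mat[:, j]
        vals = np.unique(col)
        vals = vals[vals != "N"] if col.dtype.kind == "U" else vals
        if len(vals) != 2:
            continue
        a_is_0 = col[ia] == vals[0]
        b_is_1 = col[ib] == vals[1]
        mism1 = int((~a_is_0).sum() + (~b_is_1).sum())
        mism2 = int(a_is_0.sum() + b_is_1.sum())  # swapped allele orientation
        mism = min(mism1, mism2)
        if mism == 0:
            rows.append({"position": pos[j], "status": "diagnostic", "mismatches": 0})
        elif mism <= max_mismatch:
            rows.append(
                {"position": pos[j], "status": "nearly_diagnostic", "mismatches": mism}
            )
    return pd.DataFrame(rows, columns=["position", "status", "mismatches"])


def haplogroup_frequencies(
    partition: HaplogroupPartition,
    populations: list[str] | None = None,
) -> pd.DataFrame:
    """Pooled and per-population haplogroup frequencies.

    ``populations`` gives one label per haplotype (row order); populations
    with no haplotypes are absent from the output rather than reported as
    0/0.
    """
    groups = sorted(set(partition.labels))
    rows = []
    n = len(partition.labels)
    rows.append(
        {"population": "pooled", "n": n}
        | {g: partition.labels.count(g) / n for g in groups}
    )
    if populations is not None:
        if len(populations) != n:
            raise ValueError("one population label per haplotype required")
        for p in dict.fromkeys(populations):
            idx = [i for i, q in enumerate(populations) if q == p]
            rows.append(
                {"population": p, "n": len(idx)}
                | {
                    g: sum(partition.labels[i] == g for i in idx) / len(idx)
                    for g in groups
                }
            )
    return pd.DataFrame(rows)


def rho_tmrca(
    matrix: np.ndarray,
    ancestral: np.ndarray,
    calibration: dict,
) -> TmrcaEstimate:
    """Rho-statistic TMRCA calibrated by outgroup divergence.

    ``matrix`` holds the haplotypes at polarized segregating sites and
    ``ancestral`` the ancestral allele at each of those sites; the
    ancestral vector is the root.  rho is the mean Hamming distance of
    haplotypes to the root, and sigma the standard rho-statistic error
    ``sqrt(sum_sites (d_i / n)^2)`` where ``d_i`` is the number of
    haplotypes carrying the derived allele at site i (each segregating
    site is one inferred mutation on the genealogy, shared by its ``d_i``
    descendants).

    Calibration: ``mu_locus_per_year = FD / (2 * divergence_time_years)``
    — the outgroup comparison spans both lineages, hence the factor 2 —
    and ``age = rho / mu``.
    """
    fd = calibration["FD"]
    t_div = calibration["divergence_time_years"]
    if fd <= 0:
        raise ValueError("cannot calibrate: FD must be > 0")
    mat = np.asarray(matrix)
    anc = np.asarray(ancestral)
    if mat.ndim != 2 or mat.shape[1] != anc.shape[0]:
        raise ValueError("ancestral vector must match matrix columns")
    if anc.shape[0] < 1:
        raise ValueError("need at least one polarized site")
    n = mat.shape[0]
    derived = mat != anc[None, :]
    if mat.dtype.kind == "U":
        derived &= mat != "N"
    rho = float(derived.sum(axis=1).mean())
    d = derived.sum(axis=0).astype(float)
    sigma = float(np.sqrt(np.sum((d / n) ** 2)))
    mu = fd / (2.0 * t_div)
    return TmrcaEstimate(
        rho=rho,
        sigma=sigma,
        mu_locus_per_year=mu,
        age_years=rho / mu,
        sigma_years=sigma / mu,
        calibration={"divergence_time_years": t_div, "FD": fd},
    )
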