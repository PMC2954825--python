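"""Site-frequency spectra with hypergeometric projection.

Samples with missing data have a different number of called chromosomes at
every site.  To compare spectra across sites (and against simulations) each
site is projected down to a common chromosome count ``n`` by hypergeometric
downsampling: the probability that a site with ``d`` copies of the derived
allele among ``m`` called chromosomes shows ``j`` copies in a subsample of
``n`` is ``C(d, j) C(m-d, n-j) / C(m, n)``.  Spectra here are *expected*
spectra: each site contributes its full weight vector rather than a single
sampled outcome, which keeps the construction deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = ["Spectrum", "projection_weights", "project_spectrum", "fold_spectrum"]


@dataclass
class Spectrum:
    """Projected site-frequency spectrum.

    ``unfolded[j]`` is the expected number of sites with derived-allele
    count ``j`` (index 0..n; entries 0 and n are always zero, their mass is
    tracked in ``discarded_mass``).  ``folded[k]`` covers minor counts
    ``1..floor(n/2)`` (index 0 unused).  ``site_freqs`` holds one expected
    folded minor count per contributing site, the per-site statistic the
    rank test consumes.
    """

    n: int
    unfolded: np.ndarray
    folded: np.ndarray
    discarded_mass: float = 0.0
    site_freqs: list[float] = field(default_factory=list)
    n_sites: int = 0

    @property
    def total_mass(self) -> float:
        return float(self.unfolded.sum() + self.discarded_mass)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (j, expected unfolded count, folded count)."""
        rows = []
        for j in range(1, self.n):
            rows.append(
                {
                    "j": j,
                    "unfolded": float(self.unfolded[j]),
                    "folded": float(self.folded[j]) if j <= self.n // 2 else np.nan,
                }
            )
        return pd.DataFrame(rows)


def projection_weights(d: int, m: int, n: int) -> np.ndarray:
    """Hypergeometric projection weights over j = 0..n.

    weight(j) = C(d, j) C(m-d, n-j) / C(m, n); the vector sums to one.
    ``n > m`` is an error: such a site must be dropped or the target
    lowered.
    """
    if not 0 <= d <= m:
        raise ValueError(f"need 0 <= d <= m, got d={d}, m={m}")
    if n > m:
        raise ValueError(f"projection target n={n} exceeds called chromosomes m={m}")
    j = np.arange(n + 1)
    w = hypergeom.pmf(j, m, d, n)
    return w


def project_spectrum(
    variants: pd.DataFrame,
    n: int,
    population: str | None = None,
    *,
    folded_only_unpolarized: bool = True,
) -> Spectrum:
    """Project a variant table to an expected SFS at sample size ``n``.

    Polarized sites contribute hypergeometric weight to the unfolded
    spectrum over ``j = 1..n-1``; mass landing on ``j = 0`` or ``j = n``
    (the site looks monomorphic in the subsample) accumulates in
    ``discarded_mass``.  Unpolarized sites cannot enter the unfolded
    spectrum but still carry folded information through their minor-allele
    counts; they are added to the folded spectrum directly (and to
    ``site_freqs``).

    ``population`` selects the per-population count columns ``d_<pop>`` /
    ``m_<pop>``; ``None`` uses the pooled counts.  Sites with ``m < n`` are
    skipped (reported via ``n_sites`` which counts contributing sites).
    """
    if population is None:
        d_col, m_col, c_col = "d", "m", "c"
    else:
        d_col, m_col, c_col = f"d_{population}", f"m_{population}", f"c_{population}"
        if d_col not in variants.columns:
            raise KeyError(f"population {population!r} absent from variant table")

    unfolded = np.zeros(n + 1)
    half = n // 2
    folded = np.zeros(half + 1)
    discarded = 0.0
    site_freqs: list[float] = []
    n_sites = 0

    for _, row in variants.iterrows():
        m = int(row[m_col])
        if m < n or m == 0:
            continue
        unpol = bool(row["unpolarized"])
        if unpol and not folded_only_unpolarized:
            continue
        count = int(row[c_col]) if unpol else int(row[d_col])
        if unpol and count == 0:
            continue  # population monomorphic at this site
        w = projection_weights(count, m, n)
        if not unpol:
            if w[1:n].sum() == 0 and count in (0, m):
                # site monomorphic in this population: no contribution
                continue
            unfolded[1:n] += w[1:n]
            discarded += float(w[0] + w[n])
            wf = _fold_weights(w, n)
            folded[1:] += wf[1:]
            exp_minor = float(np.dot(np.arange(half + 1), wf))
        else:
            if count == 0 or count == m:
                continue
            # fold first: minor count in the subsample
            wf = _fold_weights(w, n)
            folded[1:] += wf[1:]
            exp_minor = float(np.dot(np.arange(half + 1), wf))
        site_freqs.append(exp_minor)
        n_sites += 1

    return Spectrum(
        n=n,
        unfolded=unfolded,
        folded=folded,
        discarded_mass=discarded,
        site_freqs=site_freqs,
        n_sites=n_sites,
    )


def _fold_weights(w: np.ndarray, n: int) -> np.ndarray:
    """Reflect a length-(n+1) weight vector onto minor counts 0..floor(n/2)."""
    half = n // 2
    wf = np.zeros(half + 1)
    for j in range(n + 1):
        k = min(j, n - j)
        wf[k] += w[j]
    return wf


def fold_spectrum(spectrum: Spectrum) -> np.ndarray:
    """Fold an unfolded spectrum: folded[k] = unfolded[k] + unfolded[n-k].

    The midpoint ``k = n/2`` (n even) is not double counted.  Returns the
    folded counts over minor count 0..floor(n/2).
    """
    n = spectrum.n
    half = n // 2
    out = np.zeros(half + 1)
    for j in range(n + 1):
        out[min(j, n - j)] += spectrum.unfolded[j]
    return out
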