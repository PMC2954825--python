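"""Neutrality tests: Tajima's D, the folded-SFS rank test, and HKA.

Three complementary signals of long-term balancing selection are covered:

* **Tajima's D** — the normalized difference between the mean-pairwise
  (``theta_pi``) and Watterson (``theta_w``) estimators of the scaled
  mutation rate; positive values indicate genealogies with long internal
  branches, i.e. an excess of intermediate-frequency variants.
* **MWUhigh** — a one-sided Mann-Whitney rank test asking whether the
  folded site frequencies of a test region are shifted toward intermediate
  values relative to neutral control regions.  Significant only for an
  *excess* of intermediate-frequency alleles.
* **HKA** — the classic two-locus polymorphism/divergence contrast: under
  neutrality the ratio of within-species polymorphism to outgroup
  divergence is shared across loci; an excess of polymorphism at the test
  locus signals balancing selection.

Because sites within a locus share a genealogy, analytic p-values that
assume independent observations are anticonservative; empirical p-values
from coalescent simulation are the primary significance measure, with the
analytic values reported as secondary diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb, sqrt

import numpy as np
from scipy.stats import chi2, norm, rankdata
from scipy.optimize import brentq

__all__ = [
    "NeutralityResult",
    "ThetaEstimates",
    "theta_estimates",
    "pairwise_diversity",
    "tajimas_d",
    "mwu_high",
    "hka_test",
    "HkaFit",
    "empirical_p",
]

EXACT_ENUMERATION_LIMIT = 12  # combined sample size for exact MWU p


@dataclass
class NeutralityResult:
    """A statistic with its simulation-based and analytic p-values."""

    statistic: str
    value: float
    p_sim: float | None = None
    p_analytic: float | None = None
    n_sims: int = 0
    population: str = ""
    region: str = ""
    inputs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.p_sim is not None:
            if not (0.0 < self.p_sim <= 1.0):
                raise ValueError("empirical p must lie in (0, 1]")
            if self.n_sims <= 0:
                raise ValueError("n_sims must be positive when p_sim is present")

    def display_p(self) -> str:
        """Render p_sim; values below the simulation resolution print as a bound."""
        if self.p_sim is None:
            return "NA"
        floor = 1.0 / (self.n_sims + 1)
        if self.p_sim <= floor:
            return f"< 1/{self.n_sims}"
        return f"{self.p_sim:.3f}"


# ---------------------------------------------------------------------------
# Theta estimators and Tajima's D


def _harmonic(n: int, power: int = 1) -> float:
    return float(sum(1.0 / i**power for i in range(1, n)))


@dataclass(frozen=True)
class ThetaEstimates:
    theta_w: float
    theta_pi: float
    n: int
    S: int

    def __post_init__(self) -> None:
        if self.theta_w < 0 or self.theta_pi < 0:
            raise ValueError("theta estimates must be non-negative")


def pairwise_diversity(matrix: np.ndarray, missing: str = "N") -> float:
    """Mean number of pairwise differences between haplotype rows.

    Missing entries are handled pairwise: a site enters a pair's comparison
    only when both haplotypes are called there, and the pair's difference
    count is rescaled by the fraction of co-called sites so that every pair
    contributes on the full-locus scale.
    """
    mat = np.asarray(matrix)
    n = mat.shape[0]
    if n < 2:
        raise ValueError("need at least two haplotypes")
    if mat.dtype.kind in "if":
        called = ~np.isnan(mat.astype(float))
    else:
        called = mat != missing
    total = 0.0
    n_sites = mat.shape[1]
    for i, j in combinations(range(n), 2):
        both = called[i] & called[j]
        nb = int(both.sum())
        if nb == 0:
            continue
        diff = int((mat[i, both] != mat[j, both]).sum())
        total += diff * (n_sites / nb)
    return total / comb(n, 2)


def theta_estimates(
    S: int | None = None,
    n: int | None = None,
    theta_pi: float | None = None,
    matrix: np.ndarray | None = None,
) -> ThetaEstimates:
    """Watterson and pairwise estimators of the scaled mutation rate.

    Either supply ``matrix`` (haplotypes x segregating sites; S and
    theta_pi are computed from it) or the summary triplet ``(S, n,
    theta_pi)``.  Both estimators are per locus.
    """
    if matrix is not None:
        mat = np.asarray(matrix)
        n = mat.shape[0]
        if mat.dtype.kind in "if":
            seg = [
                len(np.unique(col[~np.isnan(col.astype(float))])) > 1 for col in mat.T
            ]
        else:
            seg = [len(np.unique(col[col != "N"])) > 1 for col in mat.T]
        S = int(np.sum(seg))
        theta_pi = pairwise_diversity(mat) if S else 0.0
    if S is None or n is None or theta_pi is None:
        raise ValueError("supply matrix or (S, n, theta_pi)")
    if n < 2:
        raise ValueError("need n >= 2 chromosomes")
    return ThetaEstimates(theta_w=S / _harmonic(n), theta_pi=theta_pi, n=n, S=S)


def tajimas_d(S: int, theta_pi: float, n: int) -> float:
    """Tajima's D with the 1989 normalizing constants.

    D = (theta_pi - S/a1) / sqrt(e1*S + e2*S*(S-1)).  ``S = 0`` leaves the
    statistic undefined and raises; callers should report a null result.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if S <= 0:
        raise ValueError("Tajima's D undefined for S = 0")
    a1 = _harmonic(n)
    a2 = _harmonic(n, 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    var = e1 * S + e2 * S * (S - 1)
    return (theta_pi - S / a1) / sqrt(var)


# ---------------------------------------------------------------------------
# MWUhigh


def _u_statistic(test: np.ndarray, control: np.ndarray) -> float:
    """Mann-Whitney U for the test group, midranks for ties."""
    pooled = np.concatenate([test, control])
    ranks = rankdata(pooled)
    r1 = ranks[: len(test)].sum()
    return float(r1 - len(test) * (len(test) + 1) / 2.0)


def mwu_high(
    test_freqs,
    control_freqs,
    *,
    method: str = "auto",
) -> tuple[float, float]:
    """One-sided Mann-Whitney U: are test frequencies shifted high?

    ``test_freqs`` and ``control_freqs`` are per-site folded frequencies
    (expected minor counts under projection).  The alternative is that the
    test region's values are stochastically larger, i.e. an excess of
    intermediate-frequency variants.  Ties take midranks.

    p is exact (complete enumeration of group assignments) when the
    combined size is at most 12, otherwise a normal approximation with tie
    correction and continuity correction.  Returns ``(U, p_one_sided)``.
    """
    test = np.asarray(list(test_freqs), dtype=float)
    control = np.asarray(list(control_freqs), dtype=float)
    if test.size == 0 or control.size == 0:
        raise ValueError("both frequency lists must be non-empty")
    u_obs = _u_statistic(test, control)
    n1, n2 = len(test), len(control)
    total = n1 + n2
    if method == "exact" or (method == "auto" and total <= EXACT_ENUMERATION_LIMIT):
        pooled = np.concatenate([test, control])
        ranks = rankdata(pooled)
        count = 0
        n_arr = 0
        offset = n1 * (n1 + 1) / 2.0
        for idx in combinations(range(total), n1):
            u = ranks[list(idx)].sum() - offset
            n_arr += 1
            if u >= u_obs - 1e-12:
                count += 1
        return u_obs, count / n_arr
    # normal approximation with tie correction
    pooled = np.concatenate([test, control])
    _, t = np.unique(pooled, return_counts=True)
    tie_term = float((t**3 - t).sum())
    mean = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((total + 1) - tie_term / (total * (total - 1)))
    if var <= 0:
        return u_obs, 1.0  # all values tied: no evidence of a shift
    z = (u_obs - mean - 0.5) / sqrt(var)
    return u_obs, float(norm.sf(z))


# ---------------------------------------------------------------------------
# HKA


@dataclass
class HkaFit:
    """Fitted two-locus HKA system and goodness-of-fit decomposition."""

    x2: float
    theta: tuple[float, float]
    T_hat: float
    expected: dict
    variance: dict
    observed: dict
    p_analytic: float

    def components(self) -> dict:
        return {
            k: (self.observed[k] - self.expected[k]) ** 2 / self.variance[k]
            for k in self.observed
        }


def _hka_solve(s1: float, d1: float, s2: float, d2: float, n1: int, n2: int):
    """Solve the HKA moment equations for (theta1, theta2, T).

    System (time in 2N generations, single outgroup sequence):
        S1 + S2 = theta1*a1(n1) + theta2*a1(n2)
        D1 + D2 = (theta1 + theta2) * (T + 1)
        S1 + D1 = theta1 * (a1(n1) + T + 1)
    Parameterized by u = T + 1; theta1(u) and theta2(u) follow, and u is
    found by a bracketed root solve of the divergence equation.
    """
    A, B = _harmonic(n1), _harmonic(n2)
    ss, ds = s1 + s2, d1 + d2
    if ss <= 0 or ds <= 0:
        raise ValueError("degenerate totals: need polymorphism and divergence")

    def theta_of(u: float):
        th1 = (s1 + d1) / (A + u)
        th2 = (ss - th1 * A) / B
        return th1, th2

    def f(u: float) -> float:
        th1, th2 = theta_of(u)
        return (th1 + th2) * u - ds

    lo, hi = 1e-9, 1.0
    while f(hi) < 0 and hi < 1e9:
        hi *= 2.0
    u = brentq(f, lo, hi)
    th1, th2 = theta_of(u)
    if th1 <= 0 or th2 <= 0:
        raise ValueError("HKA moment fit produced non-positive theta")
    return th1, th2, u - 1.0


def hka_test(
    test,
    controls,
    n_test: int,
    n_controls: int | None = None,
    *,
    n_sims: int = 0,
    seed: int | None = None,
) -> HkaFit | tuple[HkaFit, "NeutralityResult"]:
    """Two-locus HKA: test locus vs (pooled) controls.

    ``test`` and ``controls`` carry ``.S`` and ``.FD`` (fixed differences
    with the outgroup, used as the divergence observation).  Expectations
    and variances follow the classic formulation: E[S] = theta*a1(n),
    Var[S] = E[S] + theta^2*b2(n); E[D] = theta*(T+1),
    Var[D] = E[D] + theta^2 (time in units of 2N generations, equal-sized
    ancestral population, one outgroup sequence).

    X^2 sums the four standardized squared deviations.  The analytic p uses
    chi^2 with 1 degree of freedom (4 observations, 3 fitted parameters).
    With ``n_sims > 0`` a parametric bootstrap at the fitted parameters
    supplies the empirical p (each replicate is refitted), returned as a
    :class:`NeutralityResult` alongside the fit.
    """
    if n_controls is None:
        n_controls = n_test
    s1, d1 = float(test.S), float(test.FD)
    s2, d2 = float(controls.S), float(controls.FD)
    fit = _hka_fit(s1, d1, s2, d2, n_test, n_controls)
    if n_sims <= 0:
        return fit
    rng = np.random.default_rng(seed)
    draws = _hka_null_draws(fit, n_test, n_controls, n_sims, rng)
    p = empirical_p(fit.x2, draws, tail="upper")
    res = NeutralityResult(
        statistic="HKA",
        value=fit.x2,
        p_sim=p,
        p_analytic=fit.p_analytic,
        n_sims=len(draws),
        inputs={"S": s1, "FD": d1, "S_controls": s2, "FD_controls": d2},
    )
    return fit, res


def _hka_fit(s1, d1, s2, d2, n1, n2) -> HkaFit:
    th1, th2, T = _hka_solve(s1, d1, s2, d2, n1, n2)
    A, B = _harmonic(n1), _harmonic(n2)
    b2_1, b2_2 = _harmonic(n1, 2), _harmonic(n2, 2)
    expected = {
        "S1": th1 * A,
        "S2": th2 * B,
        "D1": th1 * (T + 1.0),
        "D2": th2 * (T + 1.0),
    }
    variance = {
        "S1": th1 * A + th1**2 * b2_1,
        "S2": th2 * B + th2**2 * b2_2,
        "D1": th1 * (T + 1.0) + th1**2,
        "D2": th2 * (T + 1.0) + th2**2,
    }
    observed = {"S1": s1, "S2": s2, "D1": d1, "D2": d2}
    x2 = sum((observed[k] - expected[k]) ** 2 / variance[k] for k in observed)
    return HkaFit(
        x2=x2,
        theta=(th1, th2),
        T_hat=T,
        expected=expected,
        variance=variance,
        observed=observed,
        p_analytic=float(chi2.sf(x2, df=1)),
    )


def _coalescent_total_length(n: int, rng: np.random.Generator) -> float:
    """Total branch length of a constant-size coalescent tree, 2N units."""
    total = 0.0
    for k in range(n, 1, -1):
        total += k * rng.exponential(1.0 / comb(k, 2))
    return total


def _hka_null_draws(fit: HkaFit, n1: int, n2: int, n_sims: int, rng) -> np.ndarray:
    th = fit.theta
    T = fit.T_hat
    draws = []
    for _ in range(n_sims):
        sim = {}
        for locus, (theta, n) in enumerate(zip(th, (n1, n2)), start=1):
            L = _coalescent_total_length(n, rng)
            sim[f"S{locus}"] = rng.poisson(theta / 2.0 * L)
            sim[f"D{locus}"] = rng.poisson(theta * (T + rng.exponential(1.0)))
        try:
            f = _hka_fit(sim["S1"], sim["D1"], sim["S2"], sim["D2"], n1, n2)
        except ValueError:
            continue  # degenerate replicate (no polymorphism or divergence)
        draws.append(f.x2)
    return np.asarray(draws)


# ---------------------------------------------------------------------------
# Empirical p-values


def empirical_p(observed: float, null_draws, tail: str = "upper") -> float:
    """Add-one empirical p-value against simulated null draws.

    upper: (1 + #{draw >= obs}) / (1 + N).  The add-one rule keeps p > 0;
    results below 1/N should be displayed as "< 1/N".
    """
    draws = np.asarray(null_draws, dtype=float)
    if draws.size == 0:
        raise ValueError("null_draws must be non-empty")
    n = draws.size
    p_up = (1 + int((draws >= observed).sum())) / (1 + n)
    p_lo = (1 + int((draws <= observed).sum())) / (1 + n)
    if tail == "upper":
        return p_up
    if tail == "lower":
        return p_lo
    if tail == "two-sided":
        return min(1.0, 2.0 * min(p_up, p_lo))
    raise ValueError(f"unknown tail {tail!r}")
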