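"""End-to-end balancing-selection scan with simulation-calibrated p-values.

:class:`NeutralityScan` is the model object: it holds a test-locus
haplotype alignment, a panel of neutral control alignments, the aligned
outgroup sequences, and a demographic null model.  ``fit`` runs the full
pipeline — variant tabulation, QC, polarization, SFS projection, the three
neutrality tests, and coalescent-simulation p-values conditioned on the
observed numbers of segregating sites — and returns a
:class:`ScanResults` with a Table-style summary (per population: S,
Tajima's D and its p, the folded-SFS rank-test p, and the HKA p).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import (
    DivergenceSummary,
    HaplotypeAlignment,
    QcRules,
    apply_qc_filters,
    count_segregating_and_fixed,
    polarize_sites,
    read_haplotypes,
    read_outgroup,
    variants_from_alignment,
)
from .coalescent import (
    DemographicModel,
    SimulationConfig,
    default_ooa_model,
    place_mutations_fixed_S,
    simulate_genealogies,
)
from .neutrality import (
    NeutralityResult,
    empirical_p,
    hka_test,
    mwu_high,
    pairwise_diversity,
    tajimas_d,
)
from .sfs import project_spectrum
from .synth import POPULATION_DEME_MAP

__all__ = ["NeutralityScan", "ScanResults"]


@dataclass
class ScanResults:
    """Fitted scan statistics with their simulation provenance."""

    table: pd.DataFrame
    results: list[NeutralityResult]
    n_sims: int
    seed: int | None
    projection_n: int

    def summary(self) -> str:
        lines = [
            "Balancing-selection scan (simulation-calibrated neutrality tests)",
            f"  simulations per test: {self.n_sims}; "
            f"SFS projected to {self.projection_n} chromosomes",
            "",
        ]
        show = self.table.copy()
        for col in ("TajD", "HKA_X2"):
            if col in show:
                show[col] = show[col].map(lambda v: f"{v:.2f}" if pd.notna(v) else "NA")
        for col in ("p_TajD", "p_MWU", "p_HKA"):
            if col in show:
                floor = 1.0 / (self.n_sims + 1)
                show[col] = show[col].map(
                    lambda v: "NA"
                    if pd.isna(v)
                    else (f"< 1/{self.n_sims}" if v <= floor else f"{v:.3f}")
                )
        lines.append(show.to_string(index=False))
        return "\n".join(lines)


class NeutralityScan:
    """Scan one locus against neutral controls under a demographic null.

    Parameters
    ----------
    alignment, outgroup
        Test-locus phased haplotypes and the aligned outgroup sequence.
    controls, control_outgroups
        Neutral control alignments with their outgroup sequences.
    model
        Demographic null (default: the three-population out-of-Africa
        model).
    projection_n
        Common chromosome count for SFS projection (default 15).
    deme_map
        Study population -> model deme for the simulation null.
    qc_rules
        Variant QC applied to test and control tables.
    """

    def __init__(
        self,
        alignment: HaplotypeAlignment,
        outgroup: str,
        controls: list[HaplotypeAlignment],
        control_outgroups: list[str],
        *,
        model: DemographicModel | None = None,
        projection_n: int = 15,
        deme_map: dict | None = None,
        qc_rules: QcRules = QcRules(),
    ):
        if len(controls) != len(control_outgroups):
            raise ValueError("one outgroup sequence per control alignment required")
        if not controls:
            raise ValueError("at least one control region is required")
        self.alignment = alignment
        self.outgroup = outgroup
        self.controls = controls
        self.control_outgroups = control_outgroups
        self.model = model or default_ooa_model()
        self.projection_n = projection_n
        self.deme_map = dict(deme_map or POPULATION_DEME_MAP)
        self.qc_rules = qc_rules

        self.variants, self.qc_report = apply_qc_filters(
            variants_from_alignment(alignment), alignment, qc_rules
        )
        self.variants = polarize_sites(self.variants, outgroup)
        self.control_variants = []
        for ctl, og in zip(controls, control_outgroups):
            v, _ = apply_qc_filters(variants_from_alignment(ctl), ctl, qc_rules)
            self.control_variants.append(polarize_sites(v, og))

        self.divergence = count_segregating_and_fixed(alignment, outgroup)
        ctl_s = ctl_fd = 0
        for ctl, og in zip(controls, control_outgroups):
            d = count_segregating_and_fixed(ctl, og)
            ctl_s += d.S
            ctl_fd += d.FD
        self.control_divergence = DivergenceSummary(ctl_s, ctl_fd, region="controls")

    @classmethod
    def from_files(
        cls,
        test_haplotypes: str | Path,
        popmap: str | Path,
        outgroup: str | Path,
        control_haplotypes: list[str | Path],
        control_outgroups: list[str | Path],
        **kwargs,
    ) -> "NeutralityScan":
        aln = read_haplotypes(test_haplotypes, popmap)
        og = read_outgroup(outgroup, expected_length=aln.n_positions)
        ctls, ogs = [], []
        for c_path, o_path in zip(control_haplotypes, control_outgroups):
            c = read_haplotypes(c_path, popmap)
            ctls.append(c)
            ogs.append(read_outgroup(o_path, expected_length=c.n_positions))
        return cls(aln, og, ctls, ogs, **kwargs)

    # -- population-level observables -------------------------------------

    def _pop_matrix(self, population: str) -> np.ndarray:
        rows = self.alignment.haplotypes_of(population)
        cols = np.searchsorted(self.alignment.positions, self.variants["position"])
        return self.alignment.alleles[np.ix_(rows, cols)]

    def pop_segregating(self, population: str) -> int:
        c = self.variants[f"c_{population}"]
        m = self.variants[f"m_{population}"]
        return int(((c > 0) & (c < m)).sum())

    def observed_mwu(self, population: str) -> tuple[float, float, list, list]:
        """Observed rank statistic: projected folded frequencies of the
        test locus vs the pooled control sites."""
        n = self.projection_n
        test = project_spectrum(self.variants, n, population).site_freqs
        ctl: list[float] = []
        for v in self.control_variants:
            ctl.extend(project_spectrum(v, n, population).site_freqs)
        test_f = [x / n for x in test]
        ctl_f = [x / n for x in ctl]
        if not test_f or not ctl_f:
            return np.nan, np.nan, test_f, ctl_f
        u, p = mwu_high(test_f, ctl_f)
        return u, p, test_f, ctl_f

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        n_sims: int = 10_000,
        seed: int | None = None,
        populations: list[str] | None = None,
    ) -> ScanResults:
        """Run the tests with ``n_sims`` coalescent replicates per population.

        Simulations sample the population's deme under the demographic
        null, conditioned on the observed number of segregating sites; the
        control panel is re-simulated per replicate (each control locus
        conditioned on its observed per-population site count) so the rank
        test's null respects the shared-genealogy correlation of sites
        within a locus.
        """
        pops = populations or self.alignment.populations
        rng = np.random.default_rng(seed)
        rows = []
        results: list[NeutralityResult] = []
        for pop in pops:
            rows.append(self._fit_population(pop, n_sims, rng, results))
        table = pd.DataFrame(rows)
        return ScanResults(
            table=table,
            results=results,
            n_sims=n_sims,
            seed=seed,
            projection_n=self.projection_n,
        )

    def _sim_config(self, population: str, n_chrom: int, s_cond: int, L: float):
        deme = self.deme_map.get(population, population)
        if deme not in self.model.labels:
            raise KeyError(f"population {population!r} has no deme in the null model")
        return SimulationConfig(
            n_per_pop={deme: n_chrom},
            L=L,
            rho_per_bp=1e-6,
            S_condition=s_cond,
        )

    def _fit_population(self, pop, n_sims, rng, results) -> dict:
        m_chrom = len(self.alignment.haplotypes_of(pop))
        s_obs = self.pop_segregating(pop)
        mat = self._pop_matrix(pop)
        row: dict = {"population": pop, "S": s_obs}

        taj_obs = np.nan
        if s_obs > 0:
            pi = pairwise_diversity(mat)
            taj_obs = tajimas_d(s_obs, pi, m_chrom)
        row["TajD"] = taj_obs

        u_obs, p_mwu_analytic, test_f, _ = self.observed_mwu(pop)
        row["MWU_U"] = u_obs

        ctl_counts = [
            int(((v[f"c_{pop}"] > 0) & (v[f"c_{pop}"] < v[f"m_{pop}"])).sum())
            for v in self.control_variants
        ]

        taj_draws = np.full(n_sims, np.nan)
        u_draws = np.full(n_sims, np.nan)
        cfg_test = self._sim_config(pop, m_chrom, s_obs, float(self.alignment.n_positions))
        for r in range(n_sims):
            trees = simulate_genealogies(cfg_test, self.model, rng)
            rep = place_mutations_fixed_S(trees, s_obs, rng)
            if s_obs > 0:
                d = rep.derived_counts()
                pi_sim = (
                    2.0 * (d * (m_chrom - d)).sum() / (m_chrom * (m_chrom - 1))
                )
                taj_draws[r] = tajimas_d(s_obs, pi_sim, m_chrom)
            test_sim = rep.folded_counts() / m_chrom
            ctl_sim: list[float] = []
            for s_c in ctl_counts:
                if s_c == 0:
                    continue
                ct = simulate_genealogies(
                    self._sim_config(pop, m_chrom, s_c, 2000.0), self.model, rng
                )
                crep = place_mutations_fixed_S(ct, s_c, rng)
                ctl_sim.extend(crep.folded_counts() / m_chrom)
            if len(test_sim) and len(ctl_sim):
                u_draws[r], _ = mwu_high(test_sim, ctl_sim)

        p_taj = p_u = np.nan
        if not np.isfinite(u_obs):
            u_draws[:] = np.nan
        if s_obs > 0 and np.isfinite(taj_draws).any():
            p_taj = empirical_p(taj_obs, taj_draws[np.isfinite(taj_draws)])
            results.append(
                NeutralityResult(
                    "TajD", taj_obs, p_sim=p_taj,
                    n_sims=int(np.isfinite(taj_draws).sum()), population=pop,
                    inputs={"S": s_obs, "n": m_chrom},
                )
            )
        if np.isfinite(u_draws).any():
            p_u = empirical_p(u_obs, u_draws[np.isfinite(u_draws)])
            results.append(
                NeutralityResult(
                    "MWUhigh", u_obs, p_sim=p_u, p_analytic=p_mwu_analytic,
                    n_sims=int(np.isfinite(u_draws).sum()), population=pop,
                    inputs={"n_test_sites": len(test_f)},
                )
            )
        row["p_TajD"] = p_taj
        row["p_MWU"] = p_u

        # HKA: test locus vs pooled controls, parametric-bootstrap p
        row["HKA_X2"] = np.nan
        row["p_HKA"] = np.nan
        try:
            fit, res = hka_test(
                self.divergence,
                self.control_divergence,
                n_test=m_chrom,
                n_sims=max(n_sims, 1),
                seed=int(rng.integers(2**31)),
            )
            res.population = pop
            results.append(res)
            row["HKA_X2"] = fit.x2
            row["p_HKA"] = res.p_sim
        except ValueError:
            pass
        return row
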