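"""Seeded generators for every pipeline input.

All generators are pure functions of (spec, seed): a fixed seed gives
byte-identical outputs.  Each fixture carries a truth record sufficient to
score the downstream estimators (clade labels, diagnostic sites, split
age, allelic ratios, group effects).

The balancing-selection fixture emulates the genetic signature of two
long-maintained allelic classes *structurally*: the two haplotype clades
are simulated as two demes exchanging no migrants until their joining time
``T_b``, after which a (small) ancestral deme closes the genealogy.  This
reproduces what the neutrality tests consume — deep divergence between
clades at intermediate frequency, hence an excess of intermediate-
frequency variants — without a forward selection simulation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .coalescent import (
    DemographicModel,
    MassMigration,
    MigrationRateChange,
    Population,
    PopulationParametersChange,
    SimulationConfig,
    SimReplicate,
    default_ooa_model,
    place_mutations_theta,
    simulate_genealogies,
)
from .splice import DonorModel, GeneModel

__all__ = [
    "FixtureSpec",
    "LocusFixture",
    "gen_locus_fixture",
    "gen_control_panel",
    "gen_qpcr_fixture",
    "gen_mfi_fixture",
    "gen_gene_model_fixture",
    "toy_donor_pwm",
    "DEFAULT_POPULATIONS",
    "POPULATION_DEME_MAP",
]

DEFAULT_POPULATIONS = ("Yoruba", "Luhya", "Palestinian", "Gujarati", "Han", "Toscani")

# The demographic null has three demes; the six study populations map onto
# them (Middle Eastern and South Asian samples scanned against the European
# deme by default; override via FixtureSpec.deme_map).
POPULATION_DEME_MAP = {
    "Yoruba": "AF",
    "Luhya": "AF",
    "Han": "AS",
    "Toscani": "EU",
    "Palestinian": "EU",
    "Gujarati": "EU",
}

BASES = np.array(list("ACGT"))


@dataclass
class FixtureSpec:
    """Study-condition parameters of a sequence fixture.

    Defaults mirror the study design: 30 diploids from each of six
    populations over an 8,794-bp locus, chimpanzee outgroup at 6 Mya, and
    in balancing mode two clades split ~1.4 Myr ago held near frequency
    0.5.  ``mu_per_bp`` (2e-8 per generation) and the balancing-mode
    reference size (1e4 diploids) are conventional human point values.
    """

    mode: str = "balancing"
    populations: tuple = DEFAULT_POPULATIONS
    n_diploids: int = 30
    locus_length: int = 8794
    clade_split_years: float = 1.4e6
    clade_freq: float = 0.5
    mu_per_bp: float = 2e-8
    n_ref: float = 1e4
    ancestral_size_factor: float = 0.05
    generation_years: float = 25.0
    divergence_time_years: float = 6.0e6
    rho_per_bp: float = 1e-6
    deme_map: dict = field(default_factory=lambda: dict(POPULATION_DEME_MAP))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("neutral", "balancing"):
            raise ValueError("mode must be 'neutral' or 'balancing'")
        if not 0.0 < self.clade_freq < 1.0:
            raise ValueError("clade frequency must lie in (0, 1)")
        if self.locus_length <= 0:
            raise ValueError("locus length must be positive")
        n_hap = 2 * self.n_diploids
        n_a = round(self.clade_freq * n_hap)
        if self.mode == "balancing" and (n_a == 0 or n_a == n_hap):
            raise ValueError(
                f"clade frequency {self.clade_freq} infeasible for {n_hap} haplotypes"
            )

    @property
    def theta_locus(self) -> float:
        return 4.0 * self.n_ref * self.mu_per_bp * self.locus_length


@dataclass
class LocusFixture:
    """An in-memory sequence fixture plus its truth record."""

    haplotype_ids: list[str]
    sequences: list[str]
    outgroup: str
    populations: dict[str, str]         # sample -> population
    truth: dict
    matrix: np.ndarray                  # 0/1 derived matrix (rows match ids)
    positions: np.ndarray               # 1-based locus coordinates of SNPs

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        hap_fa = outdir / "haplotypes.fa"
        with hap_fa.open("w") as fh:
            for hid, seq in zip(self.haplotype_ids, self.sequences):
                fh.write(f">{hid}\n{seq}\n")
        out_fa = outdir / "outgroup.fa"
        out_fa.write_text(f">outgroup\n{self.outgroup}\n")
        popmap = outdir / "popmap.tsv"
        with popmap.open("w") as fh:
            for s, p in self.populations.items():
                fh.write(f"{s}\t{p}\n")
        truth = outdir / "truth.json"
        truth.write_text(json.dumps(self.truth, sort_keys=True, indent=1))
        return {
            "haplotypes": hap_fa,
            "outgroup": out_fa,
            "popmap": popmap,
            "truth": truth,
        }


def _balancing_model(spec: FixtureSpec) -> DemographicModel:
    t_b = spec.clade_split_years / spec.generation_years  # generations
    return DemographicModel(
        populations=[
            Population("cladeA", spec.n_ref * spec.clade_freq),
            Population("cladeB", spec.n_ref * (1.0 - spec.clade_freq)),
        ],
        events=[
            MassMigration(t_b, source="cladeB", dest="cladeA"),
            PopulationParametersChange(
                t_b, "cladeA", size=spec.n_ref * spec.ancestral_size_factor
            ),
        ],
        reference_size=spec.n_ref,
    )


def _sample_layout(spec: FixtureSpec, rng: np.random.Generator):
    """Per-deme chromosome counts plus the study-population label and clade
    of every sampled haplotype, in engine row order."""
    n_hap = 2 * spec.n_diploids
    if spec.mode == "balancing":
        n_a = round(spec.clade_freq * n_hap)
        n_per_pop = {
            "cladeA": n_a * len(spec.populations),
            "cladeB": (n_hap - n_a) * len(spec.populations),
        }
        pop_labels = [p for p in spec.populations for _ in range(n_a)] + [
            p for p in spec.populations for _ in range(n_hap - n_a)
        ]
        clades = ["A"] * (n_a * len(spec.populations)) + ["B"] * (
            (n_hap - n_a) * len(spec.populations)
        )
        return n_per_pop, pop_labels, clades
    demes = ["AF", "EU", "AS"]
    n_per_pop = {d: 0 for d in demes}
    pop_labels_by_deme: dict[str, list[str]] = {d: [] for d in demes}
    for p in spec.populations:
        d = spec.deme_map.get(p, "AF")  # unmapped study populations scan African deme
        n_per_pop[d] += n_hap
        pop_labels_by_deme[d].extend([p] * n_hap)
    pop_labels = [lbl for d in demes for lbl in pop_labels_by_deme[d]]
    return n_per_pop, pop_labels, [""] * len(pop_labels)


def simulate_locus(spec: FixtureSpec, rng: np.random.Generator):
    """Simulate a replicate for the spec; returns (replicate, pop labels,
    clade labels, model)."""
    if spec.mode == "balancing":
        model = _balancing_model(spec)
    else:
        model = default_ooa_model()
    n_per_pop, pop_labels, clades = _sample_layout(spec, rng)
    config = SimulationConfig(
        n_per_pop=n_per_pop,
        L=float(spec.locus_length),
        rho_per_bp=spec.rho_per_bp,
    )
    theta = 4.0 * model.reference_size * spec.mu_per_bp * spec.locus_length
    trees = simulate_genealogies(config, model, rng)
    rep = place_mutations_theta(trees, theta, rng)
    # outgroup stem: both lineages to the outgroup ancestor, less the part
    # of the tree already below the sample MRCA
    t_div = spec.divergence_time_years / spec.generation_years
    t_div_coal = t_div / (2.0 * model.reference_size)
    stem = max(2.0 * t_div_coal - rep.tmrca, 0.0)
    rep.FD = int(rng.poisson(rep.mutation_rate * stem))
    rep.outgroup_scale = stem
    return rep, pop_labels, clades, model


def _diagnostic_sites(matrix: np.ndarray, clades: list[str]) -> list[int]:
    ia = [i for i, c in enumerate(clades) if c == "A"]
    ib = [i for i, c in enumerate(clades) if c == "B"]
    out = []
    for j in range(matrix.shape[1]):
        da, db = matrix[ia, j].sum(), matrix[ib, j].sum()
        if (da == len(ia) and db == 0) or (da == 0 and db == len(ib)):
            out.append(j)
    return out


def gen_locus_fixture(spec: FixtureSpec) -> LocusFixture:
    """Generate a sequence fixture (haplotypes, outgroup, popmap, truth).

    Neutral mode simulates the out-of-Africa demographic null; balancing
    mode the two-clade structure.  Segregating sites and fixed differences
    are realized onto concrete nucleotide sequences at distinct integer
    positions; the outgroup carries the ancestral allele at polymorphic
    sites and a divergent base at fixed-difference sites.
    """
    rng = np.random.default_rng(spec.seed)
    rep, pop_labels, clades, model = simulate_locus(spec, rng)
    L, S, FD = spec.locus_length, rep.S, rep.FD
    if S + FD > L:
        raise ValueError("locus too short for the simulated site count")

    all_pos = rng.choice(L, size=S + FD, replace=False) + 1
    poly_pos = np.sort(all_pos[:S])
    fd_pos = np.sort(all_pos[S:])
    ancestral = rng.choice(BASES, size=L)
    derived = np.array(
        [rng.choice([b for b in "ACGT" if b != ancestral[p - 1]]) for p in poly_pos]
    )
    out_seq = ancestral.copy()
    for p in fd_pos:
        out_seq[p - 1] = rng.choice([b for b in "ACGT" if b != ancestral[p - 1]])

    # pair haplotypes into diploids within populations (clades intermix)
    order: list[int] = []
    hap_ids: list[str] = []
    sample_pop: dict[str, str] = {}
    for p in spec.populations:
        rows = [i for i, q in enumerate(pop_labels) if q == p]
        rows = [rows[k] for k in rng.permutation(len(rows))]
        for d in range(len(rows) // 2):
            sample = f"{p}{d + 1:02d}"
            sample_pop[sample] = p
            for phase in (1, 2):
                order.append(rows[2 * d + phase - 1])
                hap_ids.append(f"{sample}.{phase}")

    sequences = []
    matrix = np.zeros((len(order), S), dtype=np.uint8)
    for out_row, src_row in enumerate(order):
        seq = ancestral.copy()
        carried = rep.matrix[src_row] == 1
        matrix[out_row] = rep.matrix[src_row]
        for k in np.flatnonzero(carried):
            seq[poly_pos[k] - 1] = derived[k]
        sequences.append("".join(seq))

    clade_of = {hap_ids[i]: clades[order[i]] for i in range(len(order))}
    diag = _diagnostic_sites(matrix, [clades[i] for i in order])
    truth = {
        "mode": spec.mode,
        "seed": spec.seed,
        "S": int(S),
        "FD": int(FD),
        "theta_locus": 4.0 * model.reference_size * spec.mu_per_bp * spec.locus_length,
        "mu_locus_per_year": spec.mu_per_bp * spec.locus_length / spec.generation_years,
        "tmrca_years": rep.tmrca * 2.0 * model.reference_size * spec.generation_years,
        "clade_split_years": spec.clade_split_years if spec.mode == "balancing" else None,
        "clade_of": clade_of if spec.mode == "balancing" else None,
        "diagnostic_positions": [int(poly_pos[j]) for j in diag],
        "divergence_time_years": spec.divergence_time_years,
    }
    return LocusFixture(
        haplotype_ids=hap_ids,
        sequences=sequences,
        outgroup="".join(out_seq),
        populations=sample_pop,
        truth=truth,
        matrix=matrix,
        positions=poly_pos,
    )


def gen_control_panel(
    count: int = 47,
    spec: FixtureSpec | None = None,
    *,
    control_length: int = 2000,
    seed: int = 0,
) -> list[LocusFixture]:
    """A panel of independent neutral control loci (default 47).

    Controls share the spec's sample layout but are shorter unlinked
    regions; each gets its own logged child seed.
    """
    base = spec or FixtureSpec(mode="neutral")
    seeds = np.random.SeedSequence(seed).generate_state(count) % (2**31)
    panel = []
    for k in range(count):
        sub = FixtureSpec(
            mode="neutral",
            populations=base.populations,
            n_diploids=base.n_diploids,
            locus_length=control_length,
            mu_per_bp=base.mu_per_bp,
            generation_years=base.generation_years,
            divergence_time_years=base.divergence_time_years,
            rho_per_bp=base.rho_per_bp,
            deme_map=dict(base.deme_map),
            seed=int(seeds[k]),
        )
        panel.append(gen_locus_fixture(sub))
    return panel


# ---------------------------------------------------------------------------
# qPCR plates


def gen_qpcr_fixture(
    true_ratio: float = 0.3,
    ct_sd: float = 0.1,
    n_standards: int = 5,
    seed: int = 0,
    *,
    n_replicates: int = 3,
    treatment: str = "untreated",
) -> tuple[pd.DataFrame, dict]:
    """A synthetic TaqMan plate: standards, an unknown, and a gDNA control.

    Standards sit at mix fractions spread over (0.1, 0.9); the unknown cDNA
    sample has B:A ratio ``true_ratio``; the heterozygous genomic-DNA
    control has equal template (ratio 1).  Channel Cts follow
    ``Ct_A - Ct_B = log2(ratio)`` plus Gaussian noise of sd ``ct_sd``.
    """
    if true_ratio <= 0:
        raise ValueError("true ratio must be positive")
    if n_standards < 3:
        raise ValueError("need at least three standard fractions")
    rng = np.random.default_rng(seed)
    fractions = np.linspace(0.1, 0.9, n_standards)
    rows = []

    def add(sample, role, fraction, ratio):
        base = 24.0 + rng.normal(0, 0.5)
        for rep_i in range(1, n_replicates + 1):
            ct_b = base + rng.normal(0, ct_sd)
            ct_a = base + np.log2(ratio) + rng.normal(0, ct_sd)
            rows.append(
                {
                    "sample": sample,
                    "assay": "diagSNP1",
                    "role": role,
                    "fraction": fraction,
                    "ct_a": ct_a,
                    "ct_b": ct_b,
                    "replicate": rep_i,
                    "treatment": treatment,
                }
            )

    for i, f in enumerate(fractions, start=1):
        add(f"std{i}", "standard", f, f / (1.0 - f))
    add("unknown1", "unknown", np.nan, true_ratio)
    add("gdna1", "gdna-control", np.nan, 1.0)
    truth = {"true_ratio": true_ratio, "ct_sd": ct_sd, "seed": seed}
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# Flow-cytometry tables


def gen_mfi_fixture(
    genotype_effect: float = 0.2,
    experiment_effect: float = 0.3,
    n_per_cell: int = 6,
    outlier_rate: float = 0.0,
    seed: int = 0,
    *,
    sigma: float = 0.15,
    n_experiments: int = 2,
) -> tuple[pd.DataFrame, dict]:
    """Synthetic MFI records over experiments x genotypes.

    Standardized (HLA/CD19) values are log-normal with sd ``sigma`` on the
    log scale; the BB genotype's mean is reduced by ``genotype_effect``
    (AB by half of it), and each successive experiment scales the mean by
    ``1 + experiment_effect``.  Outliers are injected by multiplying a
    value by 4 or 1/4 at rate ``outlier_rate``.
    """
    if not 0.0 <= outlier_rate < 1.0:
        raise ValueError("outlier rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    rows = []
    base = 1.2
    for e in range(1, n_experiments + 1):
        exp_scale = (1.0 + experiment_effect) ** (e - 1)
        for gt, g_scale in (
            ("AA", 1.0),
            ("AB", 1.0 - genotype_effect / 2.0),
            ("BB", 1.0 - genotype_effect),
        ):
            for i in range(n_per_cell):
                cd19 = float(np.exp(rng.normal(np.log(200.0), 0.2)))
                std = float(
                    base * exp_scale * g_scale * np.exp(rng.normal(0.0, sigma))
                )
                if outlier_rate > 0 and rng.random() < outlier_rate:
                    std *= float(rng.choice([0.25, 4.0]))
                rows.append(
                    {
                        "sample": f"e{e}_{gt}_{i + 1}",
                        "genotype": gt,
                        "experiment": e,
                        "hla_mfi": std * cd19,
                        "cd19_mfi": cd19,
                    }
                )
    truth = {
        "genotype_effect": genotype_effect,
        "experiment_effect": experiment_effect,
        "sigma": sigma,
        "seed": seed,
    }
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# Toy gene model


def toy_donor_pwm() -> DonorModel:
    """A donor PWM with a strong GT consensus and an allele-sensitive +3.

    Column order ACGT over positions -3..+6.  Built so that an A-to-G change
    at +3 costs ~4.5 log2-odds units, mirroring how a single intronic
    substitution in a real donor site can hand splicing to a cryptic donor.
    """
    pwm = np.array(
        [
            [0.35, 0.35, 0.20, 0.10],   # -3
            [0.60, 0.10, 0.15, 0.15],   # -2
            [0.10, 0.05, 0.80, 0.05],   # -1
            [0.001, 0.001, 0.997, 0.001],  # +1 (G)
            [0.001, 0.001, 0.001, 0.997],  # +2 (T)
            [0.90, 0.03, 0.04, 0.03],   # +3 (allele-sensitive)
            [0.70, 0.10, 0.10, 0.10],   # +4
            [0.10, 0.05, 0.80, 0.05],   # +5
            [0.20, 0.15, 0.15, 0.50],   # +6
        ]
    )
    return DonorModel(kind="pwm", pwm=pwm)


def gen_gene_model_fixture() -> GeneModel:
    """A five-exon toy gene reproducing the allele-dependent splice fate.

    Allele A keeps the strong canonical donor of the variable intron and
    yields a full-length protein.  Allele B (A->G at intron position +3)
    weakens the canonical donor below the cryptic donor 56 nt downstream,
    so the upstream exon is extended by 56 nt; the extension carries an
    in-frame TAG well over 50 nt upstream of the final exon-exon junction,
    making the transcript an NMD target.
    """
    e1 = "ATG" + "GCT" * 19                       # 60 nt, CDS starts here
    e2 = "GAA" * 20                               # 60
    e3 = "GTT" * 22 + "CAG"                       # 69, donor exon
    e4 = "GAC" * 20                               # 60
    e5 = "GGT" * 10 + "TAA" + "GCT" * 29          # 120, canonical stop inside
    i_plain = "GTAAGT" + "T" * 50 + "TTCAG"       # 61 nt, not scored
    # variable intron: canonical donor GT(A/G)AGT, in-frame TAG at +7..+9,
    # cryptic donor ending 56 nt into the intron
    filler = ("CCT" * 15)[:44]
    i_var = "GTAAGT" + "TAG" + filler + "AAG" + "GTAAGA" + "T" * 58
    assert len(i_var) == 120 and i_var[53:62] == "AAGGTAAGA"

    seq = e1 + i_plain + e2 + i_plain + e3 + i_var + e4 + i_plain + e5
    e1_s = 1
    e2_s = e1_s + len(e1) + len(i_plain)
    e3_s = e2_s + len(e2) + len(i_plain)
    i3_s = e3_s + len(e3)                          # first intronic base
    e4_s = i3_s + len(i_var)
    e5_s = e4_s + len(e4) + len(i_plain)
    exons = [
        (e1_s, e1_s + len(e1) - 1),
        (e2_s, e2_s + len(e2) - 1),
        (e3_s, e3_s + len(e3) - 1),
        (e4_s, e4_s + len(e4) - 1),
        (e5_s, e5_s + len(e5) - 1),
    ]
    canonical_end = exons[2][1]
    return GeneModel(
        seq=seq,
        exons=exons,
        cds_start=1,
        variable_intron=2,
        donor_candidates=[canonical_end, canonical_end + 56],
        snp_pos=i3_s + 2,                          # +3 of the variable intron
        allele_a="A",
        allele_b="G",
        donor_model=toy_donor_pwm(),
        min_donor_score=6.0,
    )
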