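"""Hudson-style coalescent engine with demography and fixed-S conditioning.

A backward-in-time simulator of sample genealogies under a multi-population
demographic model with migration, population splits, size changes,
exponential growth, and uniform recombination (ancestral recombination
graph with segment tracking).  Mutations are laid on branches under the
infinite-sites model, either at a fixed total count (conditioning on the
number of informative sites, as in simulation-calibrated neutrality tests)
or at a scaled rate theta.  An outgroup stem branch of configurable length
converts the same mutation process into fixed differences, and
:func:`calibrate_divergence` tunes that length to a target
SNPs-per-fixed-difference ratio.

Units
-----
Time is measured in units of ``2 * N_ref`` generations (a pair of lineages
in a population of size ``N_ref`` coalesces at rate 1), population sizes
are diploid individuals, and event times in the demographic model are
plain generations ago.  ``theta = 4 * N_ref * mu_locus``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from math import comb, exp, inf, log
from typing import Callable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "Population",
    "MassMigration",
    "PopulationParametersChange",
    "MigrationRateChange",
    "DemographicModel",
    "SimulationConfig",
    "SimReplicate",
    "default_ooa_model",
    "constant_model",
    "simulate_genealogies",
    "place_mutations_fixed_S",
    "place_mutations_theta",
    "add_outgroup_divergence",
    "simulate_replicate",
    "calibrate_divergence",
    "null_distribution",
    "write_ms",
    "parse_ms",
]


# ---------------------------------------------------------------------------
# Demographic model


@dataclass(frozen=True)
class Population:
    """A deme: diploid size at the present and forward-time growth rate
    (per generation).  Backward in time an exponentially growing deme
    shrinks."""

    label: str
    size: float
    growth_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError(f"population {self.label}: size must be > 0")


@dataclass(frozen=True)
class MassMigration:
    """At ``time`` (generations ago) move lineages from ``source`` into
    ``dest`` with probability ``proportion`` — proportion 1 is a population
    split viewed backward (a join)."""

    time: float
    source: str
    dest: str
    proportion: float = 1.0
    kind: str = field(default="mass_migration", init=False)


@dataclass(frozen=True)
class PopulationParametersChange:
    time: float
    population: str
    size: float | None = None
    growth_rate: float | None = None
    kind: str = field(default="population_parameters_change", init=False)


@dataclass(frozen=True)
class MigrationRateChange:
    """Set a backward migration rate (per generation).  ``source=None``
    resets every pair to ``rate``."""

    time: float
    rate: float
    source: str | None = None
    dest: str | None = None
    kind: str = field(default="migration_rate_change", init=False)


Event = MassMigration | PopulationParametersChange | MigrationRateChange


@dataclass
class DemographicModel:
    """Populations, time-sorted demographic events, and migration matrix.

    ``migration[a][b]`` is the backward rate (per generation) at which a
    lineage currently in ``a`` traces its ancestry to ``b``.
    ``reference_size`` sets the coalescent time scale (2 * N_ref
    generations per unit).
    """

    populations: list[Population]
    events: list[Event] = field(default_factory=list)
    migration: dict[str, dict[str, float]] = field(default_factory=dict)
    reference_size: float = 1e4

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.time)
        labels = [p.label for p in self.populations]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate population labels")
        self._check_single_root()

    @property
    def labels(self) -> list[str]:
        return [p.label for p in self.populations]

    def _check_single_root(self) -> None:
        """After all joins, lineages must be able to meet in one deme (or be
        connected by migration)."""
        alive = set(self.labels)
        final_mig = {a: dict(self.migration.get(a, {})) for a in alive}
        for ev in self.events:
            if isinstance(ev, MassMigration) and ev.proportion >= 1.0:
                alive.discard(ev.source)
            elif isinstance(ev, MigrationRateChange):
                if ev.source is None:
                    final_mig = {
                        a: {b: ev.rate for b in self.labels if b != a} for a in self.labels
                    }
                else:
                    final_mig.setdefault(ev.source, {})[ev.dest] = ev.rate
        if len(alive) > 1:
            connected = any(
                final_mig.get(a, {}).get(b, 0.0) > 0
                for a in alive
                for b in alive
                if a != b
            )
            if not connected:
                raise ValueError(
                    "demography leaves multiple isolated root populations; "
                    "lineages could never fully coalesce"
                )

    # -- config round trip -------------------------------------------------

    def to_dict(self) -> dict:
        evs = []
        for e in self.events:
            d = {"kind": e.kind}
            d.update({k: v for k, v in e.__dict__.items() if k != "kind"})
            evs.append(d)
        return {
            "reference_size": self.reference_size,
            "populations": [
                {"label": p.label, "size": p.size, "growth_rate": p.growth_rate}
                for p in self.populations
            ],
            "migration": self.migration,
            "events": evs,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "DemographicModel":
        kinds = {
            "mass_migration": MassMigration,
            "population_parameters_change": PopulationParametersChange,
            "migration_rate_change": MigrationRateChange,
        }
        events = []
        for e in d.get("events", []):
            e = dict(e)
            kind = e.pop("kind")
            events.append(kinds[kind](**e))
        return cls(
            populations=[Population(**p) for p in d["populations"]],
            events=events,
            migration={a: dict(v) for a, v in d.get("migration", {}).items()},
            reference_size=d.get("reference_size", 1e4),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "DemographicModel":
        return cls.from_dict(yaml.safe_load(text))


# Published point estimates of the three-population out-of-Africa scenario
# (African / European / East Asian), generation time 25 years.
OOA_PARAMS = {
    "N_A": 7300.0,        # ancestral
    "N_AF": 12300.0,      # African, constant since T_AF
    "N_B": 2100.0,        # out-of-Africa bottleneck deme
    "N_EU0": 1000.0,      # European at the EU/AS split
    "r_EU": 0.004,        # per-generation growth
    "N_AS0": 510.0,       # East Asian at the split
    "r_AS": 0.0055,
    "m_AF_B": 25e-5,      # symmetric backward migration, per generation
    "m_AF_EU": 3e-5,
    "m_AF_AS": 1.9e-5,
    "m_EU_AS": 9.6e-5,
    "T_AF": 8800.0,       # generations ago (220 kya)
    "T_B": 5600.0,        # 140 kya
    "T_EU_AS": 848.0,     # 21.2 kya
}


def default_ooa_model() -> DemographicModel:
    """Three-population out-of-Africa demographic null.

    African (AF), European (EU), and East Asian (AS) demes with the
    published point estimates: an ancestral population of 7,300 grows to
    12,300 at 220 kya; the out-of-Africa bottleneck deme (2,100) splits off
    at 140 kya; Europe and East Asia split at 21.2 kya and grow
    exponentially to the present, with continuous migration throughout.
    Fully overridable by constructing a model by hand or editing the YAML
    round trip.
    """
    p = OOA_PARAMS
    n_eu = p["N_EU0"] * exp(p["r_EU"] * p["T_EU_AS"])
    n_as = p["N_AS0"] * exp(p["r_AS"] * p["T_EU_AS"])
    populations = [
        Population("AF", p["N_AF"]),
        Population("EU", n_eu, growth_rate=p["r_EU"]),
        Population("AS", n_as, growth_rate=p["r_AS"]),
    ]
    migration = {
        "AF": {"EU": p["m_AF_EU"], "AS": p["m_AF_AS"]},
        "EU": {"AF": p["m_AF_EU"], "AS": p["m_EU_AS"]},
        "AS": {"AF": p["m_AF_AS"], "EU": p["m_EU_AS"]},
    }
    t_split, t_b, t_af = p["T_EU_AS"], p["T_B"], p["T_AF"]
    events: list[Event] = [
        # EU/AS merge into the bottleneck deme B (carried by the EU slot)
        MassMigration(t_split, source="AS", dest="EU"),
        PopulationParametersChange(t_split, "EU", size=p["N_B"], growth_rate=0.0),
        MigrationRateChange(t_split, 0.0),
        MigrationRateChange(t_split, p["m_AF_B"], source="AF", dest="EU"),
        MigrationRateChange(t_split, p["m_AF_B"], source="EU", dest="AF"),
        # B merges into AF
        MassMigration(t_b, source="EU", dest="AF"),
        MigrationRateChange(t_b, 0.0),
        # ancestral size change
        PopulationParametersChange(t_af, "AF", size=p["N_A"]),
    ]
    return DemographicModel(
        populations=populations,
        events=events,
        migration=migration,
        reference_size=p["N_A"],
    )


def constant_model(size: float = 1e4, label: str = "pop") -> DemographicModel:
    """Single constant-size panmictic population."""
    return DemographicModel(
        populations=[Population(label, size)], reference_size=size
    )


# ---------------------------------------------------------------------------
# Simulation configuration and replicate containers


@dataclass
class SimulationConfig:
    """Knobs of a simulation run.

    ``rho_per_bp`` is the population-scaled recombination rate 4*N*r per
    base pair (the value quoted in simulation contexts); set
    ``rho_is_scaled=False`` to give the per-generation rate instead, which
    is then scaled by the model's reference size.  ``S_condition`` fixes
    the number of segregating sites per replicate (0 disables mutations;
    ``None`` uses ``theta``).  ``informative_mode`` chooses what the fixed
    count conditions on: segregating sites only (``"S"``) or segregating
    sites plus fixed differences jointly (``"S+FD"``).
    """

    n_per_pop: dict[str, int]
    L: float = 8794.0
    rho_per_bp: float = 1e-6
    rho_is_scaled: bool = True
    S_condition: int | None = None
    theta: float | None = None
    outgroup_scale: float = 0.0
    informative_mode: str = "S"
    n_reps: int = 1

    def __post_init__(self) -> None:
        if sum(self.n_per_pop.values()) < 2:
            raise ValueError("need at least 2 sampled chromosomes in total")
        if self.L <= 0:
            raise ValueError("locus length must be positive")
        if self.S_condition is not None and self.S_condition < 0:
            raise ValueError("S_condition must be >= 0")
        if self.informative_mode not in ("S", "S+FD"):
            raise ValueError("informative_mode must be 'S' or 'S+FD'")


@dataclass
class GenealogyRecord:
    """Branch pieces of one simulated ancestral recombination graph.

    Each piece is a (duration x genomic-span) weighted branch segment with
    the bitmask of sample leaves beneath it; mutation placement draws
    pieces with probability proportional to weight.
    """

    n: int
    sample_pops: list[str]
    weights: np.ndarray            # dt * span per piece
    masks: list[int]               # leaf bitmask per piece
    intervals: list[tuple[float, float]]
    tmrca: float
    total_length: float            # span-weighted, 2N units
    n_recombinations: int = 0

    @property
    def full_mask(self) -> int:
        return (1 << self.n) - 1


@dataclass
class SimReplicate:
    """A simulated haplotype 0/1 matrix with outgroup divergence counts."""

    matrix: np.ndarray             # (n, S) uint8, 1 = derived
    positions: np.ndarray          # in (0, 1], scaled to locus length
    sample_pops: list[str]
    tmrca: float
    total_length: float
    mutation_rate: float           # per unit time per locus (theta/2 or S/L_tree)
    S: int
    FD: int = 0
    outgroup_scale: float = 0.0
    seed: int | None = None

    def derived_counts(self, population: str | None = None) -> np.ndarray:
        if population is None:
            return self.matrix.sum(axis=0)
        rows = [i for i, p in enumerate(self.sample_pops) if p == population]
        return self.matrix[rows].sum(axis=0)

    def folded_counts(self, population: str | None = None) -> np.ndarray:
        d = self.derived_counts(population)
        if population is None:
            n = self.matrix.shape[0]
        else:
            n = sum(1 for p in self.sample_pops if p == population)
        return np.minimum(d, n - d)


# ---------------------------------------------------------------------------
# Core simulation


class _Lineage:
    __slots__ = ("segments", "birth", "pop")

    def __init__(self, segments, birth, pop):
        self.segments = segments  # list of (left, right, mask), sorted
        self.birth = birth
        self.pop = pop

    @property
    def extent(self):
        return self.segments[0][0], self.segments[-1][1]


def _merge_segments(segs_a, segs_b, full_mask):
    """Union two sorted segment lists; drop portions whose mask reaches the
    full sample (local MRCA found)."""
    bounds = sorted(
        {x for l, r, _ in segs_a for x in (l, r)}
        | {x for l, r, _ in segs_b for x in (l, r)}
    )
    out = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        mid = (lo + hi) / 2.0
        mask = 0
        for l, r, m in segs_a:
            if l <= mid < r:
                mask |= m
                break
        for l, r, m in segs_b:
            if l <= mid < r:
                mask |= m
                break
        if mask == 0 or mask == full_mask:
            continue
        if out and out[-1][1] == lo and out[-1][2] == mask:
            out[-1] = (out[-1][0], hi, mask)
        else:
            out.append((lo, hi, mask))
    return out


def _record_pieces(rec_w, rec_m, rec_i, lineage, t):
    dt = t - lineage.birth
    if dt <= 0:
        return
    for l, r, m in lineage.segments:
        rec_w.append(dt * (r - l))
        rec_m.append(m)
        rec_i.append((l, r))


def simulate_genealogies(
    config: SimulationConfig,
    model: DemographicModel,
    seed: int | np.random.Generator | None = None,
) -> GenealogyRecord:
    """Simulate one ancestral recombination graph under the model.

    With ``rho_per_bp = 0`` the result is a single tree.  Returns the
    branch pieces needed for mutation placement together with the TMRCA
    (time of the last coalescence) and span-weighted total branch length,
    in units of 2 * N_ref generations.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_ref = model.reference_size
    labels = model.labels
    for lbl in config.n_per_pop:
        if lbl not in labels:
            raise KeyError(f"sampled population {lbl!r} not in model")

    if config.rho_is_scaled:
        r2_total = config.rho_per_bp * config.L / 2.0
    else:
        r2_total = 2.0 * n_ref * config.rho_per_bp * config.L

    # population state: relative size nu at time t_set, scaled growth alpha
    nu = {p.label: p.size / n_ref for p in model.populations}
    alpha = {p.label: p.growth_rate * 2.0 * n_ref for p in model.populations}
    t_set = {lbl: 0.0 for lbl in labels}
    mig = {a: {b: 0.0 for b in labels if b != a} for a in labels}
    for a, row in model.migration.items():
        for b, rate in row.items():
            mig[a][b] = rate * 2.0 * n_ref  # scaled per 2N generations

    # sample leaves
    sample_pops: list[str] = []
    pops: dict[str, list[_Lineage]] = {lbl: [] for lbl in labels}
    leaf = 0
    for lbl in labels:
        for _ in range(config.n_per_pop.get(lbl, 0)):
            pops[lbl].append(_Lineage([(0.0, 1.0, 1 << leaf)], 0.0, lbl))
            sample_pops.append(lbl)
            leaf += 1
    n = leaf
    full_mask = (1 << n) - 1

    events = list(model.events)
    ev_idx = 0
    t = 0.0
    rec_w: list[float] = []
    rec_m: list[int] = []
    rec_i: list[tuple[float, float]] = []
    tmrca = 0.0
    n_recomb = 0

    def n_active() -> int:
        return sum(len(v) for v in pops.values())

    while n_active() > 0:
        if n_active() == 1:
            # a lone lineage can only carry full-mask material, which is
            # dropped at creation; reaching here means a bookkeeping error
            raise RuntimeError("single uncoalesced lineage remained")
        # candidate waiting times
        best_w = inf
        best_action: tuple | None = None
        for lbl in labels:
            k = len(pops[lbl])
            if k >= 2:
                ck = comb(k, 2)
                a = alpha[lbl]
                nu_now = nu[lbl] * (exp(-a * (t - t_set[lbl])) if a else 1.0)
                e = rng.exponential(1.0)
                if a == 0.0:
                    w = e * nu_now / ck
                else:
                    arg = 1.0 + a * e * nu_now / ck
                    w = log(arg) / a if arg > 0 else inf
                if w < best_w:
                    best_w, best_action = w, ("coal", lbl)
            if k >= 1:
                m_tot = sum(mig[lbl].values())
                if m_tot > 0:
                    w = rng.exponential(1.0 / (k * m_tot))
                    if w < best_w:
                        best_w, best_action = w, ("mig", lbl)
        if r2_total > 0:
            ext = [
                (lbl, i, lin.extent[1] - lin.extent[0])
                for lbl in labels
                for i, lin in enumerate(pops[lbl])
            ]
            tot_ext = sum(x[2] for x in ext)
            if tot_ext > 0:
                w = rng.exponential(1.0 / (r2_total * tot_ext))
                if w < best_w:
                    best_w, best_action = w, ("rec", ext, tot_ext)

        # demographic event preempts?
        if ev_idx < len(events):
            ev_time = events[ev_idx].time / (2.0 * n_ref)
            if ev_time <= t + best_w:
                # advance clock and apply the event
                ev = events[ev_idx]
                ev_idx += 1
                t = ev_time
                if isinstance(ev, MassMigration):
                    movers = []
                    for lin in list(pops[ev.source]):
                        if ev.proportion >= 1.0 or rng.random() < ev.proportion:
                            pops[ev.source].remove(lin)
                            lin.pop = ev.dest
                            movers.append(lin)
                    pops[ev.dest].extend(movers)
                elif isinstance(ev, PopulationParametersChange):
                    lbl = ev.population
                    a = alpha[lbl]
                    nu_now = nu[lbl] * (exp(-a * (t - t_set[lbl])) if a else 1.0)
                    nu[lbl] = (ev.size / n_ref) if ev.size is not None else nu_now
                    if ev.growth_rate is not None:
                        alpha[lbl] = ev.growth_rate * 2.0 * n_ref
                    t_set[lbl] = t
                else:  # MigrationRateChange
                    if ev.source is None:
                        for a_ in labels:
                            for b_ in mig[a_]:
                                mig[a_][b_] = ev.rate * 2.0 * n_ref
                    else:
                        mig[ev.source][ev.dest] = ev.rate * 2.0 * n_ref
                continue

        if best_action is None or best_w is inf:
            raise RuntimeError(
                "no possible event and no pending demography: stuck genealogy"
            )
        t += best_w
        kind = best_action[0]
        if kind == "coal":
            lbl = best_action[1]
            group = pops[lbl]
            i, j = (int(x) for x in rng.choice(len(group), size=2, replace=False))
            a_lin, b_lin = group[i], group[j]
            for idx_rm in sorted((i, j), reverse=True):
                group.pop(idx_rm)
            _record_pieces(rec_w, rec_m, rec_i, a_lin, t)
            _record_pieces(rec_w, rec_m, rec_i, b_lin, t)
            merged = _merge_segments(a_lin.segments, b_lin.segments, full_mask)
            tmrca = t
            if merged:
                group.append(_Lineage(merged, t, lbl))
        elif kind == "mig":
            lbl = best_action[1]
            rates = mig[lbl]
            dests, vals = zip(*[(d, v) for d, v in rates.items() if v > 0])
            probs = np.asarray(vals) / sum(vals)
            dest = dests[int(rng.choice(len(dests), p=probs))]
            lin = pops[lbl].pop(int(rng.integers(len(pops[lbl]))))
            lin.pop = dest
            pops[dest].append(lin)
        else:  # recombination
            _, ext, tot_ext = best_action
            probs = np.asarray([x[2] for x in ext]) / tot_ext
            lbl, idx, _span = ext[int(rng.choice(len(ext), p=probs))]
            lin = pops[lbl].pop(idx)
            lo, hi = lin.extent
            x = rng.uniform(lo, hi)
            left = [(l, min(r, x), m) for l, r, m in lin.segments if l < x]
            right = [(max(l, x), r, m) for l, r, m in lin.segments if r > x]
            left = [(l, r, m) for l, r, m in left if r > l]
            right = [(l, r, m) for l, r, m in right if r > l]
            if left and right:
                _record_pieces(rec_w, rec_m, rec_i, lin, t)
                pops[lbl].append(_Lineage(left, t, lbl))
                pops[lbl].append(_Lineage(right, t, lbl))
                n_recomb += 1
            else:
                pops[lbl].append(lin)  # split outside ancestral material

    weights = np.asarray(rec_w)
    return GenealogyRecord(
        n=n,
        sample_pops=sample_pops,
        weights=weights,
        masks=rec_m,
        intervals=rec_i,
        tmrca=tmrca,
        total_length=float(weights.sum()),
        n_recombinations=n_recomb,
    )


# ---------------------------------------------------------------------------
# Mutation placement


def _mask_to_column(mask: int, n: int) -> np.ndarray:
    col = np.zeros(n, dtype=np.uint8)
    i = 0
    while mask:
        if mask & 1:
            col[i] = 1
        mask >>= 1
        i += 1
    return col


def place_mutations_fixed_S(
    trees: GenealogyRecord,
    S: int,
    seed: int | np.random.Generator | None = None,
) -> SimReplicate:
    """Place exactly S infinite-sites mutations, branch-length weighted.

    Each mutation picks a branch piece with probability proportional to its
    (duration x span) weight and a uniform position within the piece's
    genomic interval; carriers are the leaves beneath the branch.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if S < 0:
        raise ValueError("S must be >= 0")
    if trees.total_length <= 0 and S > 0:
        raise ValueError("zero total branch length")
    n = trees.n
    if S == 0:
        matrix = np.zeros((n, 0), dtype=np.uint8)
        positions = np.asarray([])
    else:
        probs = trees.weights / trees.total_length
        picks = rng.choice(len(probs), size=S, p=probs)
        positions = np.empty(S)
        cols = np.empty((S, n), dtype=np.uint8)
        for k, piece in enumerate(picks):
            l, r = trees.intervals[piece]
            positions[k] = rng.uniform(l, r)
            cols[k] = _mask_to_column(trees.masks[piece], n)
        order = np.argsort(positions)
        positions = positions[order]
        matrix = cols[order].T
    return SimReplicate(
        matrix=matrix,
        positions=positions,
        sample_pops=trees.sample_pops,
        tmrca=trees.tmrca,
        total_length=trees.total_length,
        mutation_rate=(S / trees.total_length) if trees.total_length > 0 else 0.0,
        S=S,
    )


def place_mutations_theta(
    trees: GenealogyRecord,
    theta: float,
    seed: int | np.random.Generator | None = None,
) -> SimReplicate:
    """Poisson mutations at scaled rate theta = 4*N_ref*mu_locus."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    s = int(rng.poisson(theta / 2.0 * trees.total_length))
    rep = place_mutations_fixed_S(trees, s, rng)
    rep.mutation_rate = theta / 2.0
    return rep


def add_outgroup_divergence(
    replicate: SimReplicate,
    outgroup_scale: float,
    seed: int | np.random.Generator | None = None,
) -> SimReplicate:
    """Accumulate fixed differences on an outgroup stem branch.

    ``outgroup_scale`` is the stem length in units of 2*N_ref generations
    (the total unshared branch separating the sample's ancestor from the
    outgroup).  Mutations arise at the replicate's per-locus rate, so FD ~
    Poisson(rate * scale) and doubling the scale doubles the expectation.
    Under infinite sites the FD positions never overlap polymorphic sites.
    """
    if outgroup_scale < 0:
        raise ValueError("outgroup scale must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fd = int(rng.poisson(replicate.mutation_rate * outgroup_scale))
    replicate.FD = fd
    replicate.outgroup_scale = outgroup_scale
    return replicate


def simulate_replicate(
    config: SimulationConfig,
    model: DemographicModel,
    seed: int | np.random.Generator | None = None,
) -> SimReplicate:
    """One full replicate: genealogy, mutations, outgroup divergence.

    Honors ``S_condition`` / ``theta`` and the ``informative_mode``: under
    ``"S+FD"`` the fixed count is split between polymorphisms and fixed
    differences in proportion to tree length vs stem length.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    trees = simulate_genealogies(config, model, rng)
    if config.S_condition is not None:
        if config.informative_mode == "S+FD" and config.outgroup_scale > 0:
            w_tree = trees.total_length
            p_poly = w_tree / (w_tree + config.outgroup_scale)
            s = int(rng.binomial(config.S_condition, p_poly))
            rep = place_mutations_fixed_S(trees, s, rng)
            rep.FD = config.S_condition - s
            rep.outgroup_scale = config.outgroup_scale
            return rep
        rep = place_mutations_fixed_S(trees, config.S_condition, rng)
    elif config.theta is not None:
        rep = place_mutations_theta(trees, config.theta, rng)
    else:
        rep = place_mutations_fixed_S(trees, 0, rng)
    if config.outgroup_scale > 0:
        add_outgroup_divergence(rep, config.outgroup_scale, rng)
    return rep


# ---------------------------------------------------------------------------
# Divergence calibration and null distributions


def calibrate_divergence(
    config: SimulationConfig,
    model: DemographicModel,
    target_ratio: float,
    *,
    batch_size: int = 200,
    rel_tol: float = 0.05,
    max_iter: int = 12,
    seed: int | None = None,
) -> float:
    """Find the outgroup stem length hitting a target S/FD ratio.

    Iteratively simulates batches, measures E[S]/E[FD] at the current
    scale, and adjusts the scale multiplicatively (the expectation is
    linear in the scale) until the simulated ratio is within ``rel_tol`` of
    ``target_ratio``.
    """
    if target_ratio <= 0:
        raise ValueError("target ratio must be positive")
    rng = np.random.default_rng(seed)
    # initial guess from the mutation-rate identity E[FD] = scale * E[rate]
    rates, s_vals = [], []
    for _ in range(batch_size):
        rep = simulate_replicate(replace(config, outgroup_scale=0.0), model, rng)
        rates.append(rep.mutation_rate)
        s_vals.append(rep.S)
    mean_rate = float(np.mean(rates))
    mean_s = float(np.mean(s_vals))
    if mean_rate <= 0 or mean_s <= 0:
        raise RuntimeError("cannot calibrate: no polymorphism simulated")
    scale = mean_s / (target_ratio * mean_rate)
    for it in range(max_iter):
        # grow the batch as the scale stabilizes so the stopping rule is
        # driven by bias, not Monte-Carlo noise
        batch = batch_size * min(2**it, 8)
        s_tot = fd_tot = 0
        cfg = replace(config, outgroup_scale=scale)
        for _ in range(batch):
            rep = simulate_replicate(cfg, model, rng)
            s_tot += rep.S
            fd_tot += rep.FD
        if fd_tot == 0:
            scale *= 2.0
            continue
        ratio = s_tot / fd_tot
        if abs(ratio - target_ratio) / target_ratio <= rel_tol:
            return scale
        scale *= ratio / target_ratio  # simulated ratio is inverse in scale
    raise RuntimeError(
        f"divergence calibration did not converge after {max_iter} iterations"
    )


def null_distribution(
    stat_fns: Mapping[str, Callable[[SimReplicate], float]],
    config: SimulationConfig,
    model: DemographicModel,
    n_reps: int | None = None,
    seed: int | None = None,
):
    """Stream per-replicate statistics into a draws table.

    Returns a dict of name -> numpy array of ``n_reps`` draws.  Replicates
    for which a statistic is undefined contribute NaN.  Identical seeds
    give identical draw vectors.
    """
    import pandas as pd

    n_reps = n_reps if n_reps is not None else config.n_reps
    rng = np.random.default_rng(seed)
    out = {name: np.empty(n_reps) for name in stat_fns}
    for r in range(n_reps):
        rep = simulate_replicate(config, model, rng)
        for name, fn in stat_fns.items():
            try:
                out[name][r] = fn(rep)
            except (ValueError, ZeroDivisionError):
                out[name][r] = np.nan
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# ms-compatible text I/O


def write_ms(replicates: Sequence[SimReplicate], out=None) -> str:
    """Serialize replicates in ms-style text blocks."""
    buf = io.StringIO()
    n = replicates[0].matrix.shape[0] if replicates else 0
    buf.write(f"balscan {n} {len(replicates)}\n\n")
    for rep in replicates:
        buf.write("//\n")
        buf.write(f"segsites: {rep.S}\n")
        if rep.S:
            buf.write("positions: " + " ".join(f"{p:.5f}" for p in rep.positions) + "\n")
            for row in rep.matrix:
                buf.write("".join(str(int(x)) for x in row) + "\n")
        buf.write("\n")
    text = buf.getvalue()
    if out is not None:
        out.write(text)
    return text


def parse_ms(text: str) -> list[SimReplicate]:
    """Parse ms-style text back into replicates (positions and matrices)."""
    reps = []
    blocks = text.split("//")[1:]
    for block in blocks:
        lines = [ln for ln in block.strip().splitlines() if ln.strip()]
        if not lines:
            continue
        seg = int(lines[0].split(":")[1])
        if seg == 0:
            matrix = np.zeros((0, 0), dtype=np.uint8)
            positions = np.asarray([])
            rows: list[str] = []
        else:
            positions = np.asarray([float(x) for x in lines[1].split(":")[1].split()])
            rows = lines[2:]
            matrix = np.asarray(
                [[int(c) for c in row] for row in rows], dtype=np.uint8
            )
        reps.append(
            SimReplicate(
                matrix=matrix,
                positions=positions,
                sample_pops=["pop"] * matrix.shape[0],
                tmrca=float("nan"),
                total_length=float("nan"),
                mutation_rate=float("nan"),
                S=seg,
            )
        )
    return reps
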