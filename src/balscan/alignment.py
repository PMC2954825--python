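"""Phased haplotype alignments: data model, I/O, QC, polarization, counting.

The central container is :class:`HaplotypeAlignment`, a rectangular matrix of
nucleotide codes with one row per phased haplotype.  Variant sites are
summarised into a pandas DataFrame (one row per segregating site) that the
spectrum and neutrality-test layers consume.

Coordinate convention: locus coordinates are 1-based and inclusive
throughout; matrix columns are indexed by ``positions`` which must be
strictly increasing.  Missing data is encoded as ``N`` (gaps in the outgroup
are treated the same way).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

VALID_BASES = frozenset("ACGT")
MISSING = "N"

__all__ = [
    "HaplotypeAlignment",
    "DivergenceSummary",
    "QcRules",
    "SnpFixedRatio",
    "read_haplotypes",
    "read_outgroup",
    "variants_from_alignment",
    "apply_qc_filters",
    "polarize_sites",
    "count_segregating_and_fixed",
    "snp_fixed_ratio",
    "pairwise_r2",
    "hardy_weinberg",
]


class RaggedAlignmentError(ValueError):
    """Raised when input records do not share a common length."""


class UnphasedGenotypeError(ValueError):
    """Raised when a VCF genotype is not phased ('|')."""


@dataclass
class HaplotypeAlignment:
    """Phased allele matrix over haplotypes x aligned positions.

    Parameters
    ----------
    haplotype_ids
        One identifier per row, conventionally ``SAMPLE.1`` / ``SAMPLE.2``.
    alleles
        ``(n_haplotypes, n_positions)`` array of single characters in
        ``{A, C, G, T, N}``.
    positions
        1-based locus coordinates, strictly increasing, one per column.
    population_of
        Haplotype id -> population label; every haplotype must be present.
    region_mask
        Per-position region class, ``"coding"`` or ``"noncoding"``.
    amplicon_spans
        ``(start, end)`` 1-based inclusive sequenced-segment coordinates.
    """

    haplotype_ids: list[str]
    alleles: np.ndarray
    positions: np.ndarray
    population_of: dict[str, str]
    region_mask: np.ndarray | None = None
    amplicon_spans: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype="U1")
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.alleles.ndim != 2:
            raise RaggedAlignmentError("allele matrix must be 2-D (ragged input?)")
        n_hap, n_pos = self.alleles.shape
        if len(self.haplotype_ids) != n_hap:
            raise ValueError("haplotype_ids length does not match matrix rows")
        if len(self.positions) != n_pos:
            raise ValueError("positions length does not match matrix columns")
        if n_pos > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        missing_pop = [h for h in self.haplotype_ids if h not in self.population_of]
        if missing_pop:
            raise KeyError(f"samples missing from popmap: {missing_pop[:5]}")
        if self.region_mask is None:
            self.region_mask = np.full(n_pos, "noncoding", dtype="U9")
        else:
            self.region_mask = np.asarray(self.region_mask, dtype="U9")
            if len(self.region_mask) != n_pos:
                raise ValueError("region_mask length does not match positions")
        lo = int(self.positions[0]) if n_pos else 1
        hi = int(self.positions[-1]) if n_pos else 1
        for start, end in self.amplicon_spans:
            if start > end:
                raise ValueError(f"amplicon span reversed: ({start}, {end})")
            if n_pos and (end < lo or start > hi) and not (start <= lo and end >= hi):
                # spans may extend past sequenced edges but must touch the locus
                raise ValueError(f"amplicon span ({start}, {end}) outside locus")

    # -- basic accessors ---------------------------------------------------

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_positions(self) -> int:
        return self.alleles.shape[1]

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for h in self.haplotype_ids:
            seen.setdefault(self.population_of[h], None)
        return list(seen)

    def haplotypes_of(self, population: str) -> np.ndarray:
        """Row indices belonging to ``population``."""
        idx = [
            i
            for i, h in enumerate(self.haplotype_ids)
            if self.population_of[h] == population
        ]
        return np.asarray(idx, dtype=int)

    def column(self, position: int) -> np.ndarray:
        j = int(np.searchsorted(self.positions, position))
        if j >= self.n_positions or self.positions[j] != position:
            raise KeyError(f"position {position} not in alignment")
        return self.alleles[:, j]


@dataclass(frozen=True)
class DivergenceSummary:
    """Counts of within-species polymorphism and outgroup fixed differences."""

    S: int
    FD: int
    region: str = "all"

    def __post_init__(self) -> None:
        if self.S < 0 or self.FD < 0:
            raise ValueError("S and FD must be non-negative")


@dataclass(frozen=True)
class QcRules:
    """Variant-filtering rules.

    ``edge_bp``: variants whose 1-based offset from either end of a
    containing amplicon falls in ``1..edge_bp`` are removed (sequencing
    quality degrades at amplicon edges).  ``min_quality`` applies only when
    per-variant quality scores are supplied.  Singletons and triallelic
    sites are flagged for manual review, never silently dropped, unless
    ``strict_triallelic`` is set.
    """

    edge_bp: int = 50
    min_quality: float = 99.0
    strict_triallelic: bool = False


class SnpFixedRatio(float):
    """SNPs-per-fixed-difference ratio.

    Floats truncate ``S/FD`` in binary; the exact rational is retained in
    ``.exact`` so that ``ratio.exact * FD == S`` holds identically.  The
    conventional display rounds to one decimal (``.display``).
    """

    exact: Fraction

    def __new__(cls, s: int, fd: int) -> "SnpFixedRatio":
        if fd <= 0:
            raise ZeroDivisionError("undefined ratio: FD must be > 0")
        obj = super().__new__(cls, s / fd)
        obj.exact = Fraction(int(s), int(fd))
        return obj

    @property
    def display(self) -> float:
        return round(float(self), 1)


# ---------------------------------------------------------------------------
# I/O


def _read_popmap(popmap: str | Path | pd.DataFrame) -> dict[str, str]:
    if isinstance(popmap, pd.DataFrame):
        df = popmap
    else:
        df = pd.read_csv(popmap, sep="\t", header=None, comment="#")
    if df.shape[1] < 2:
        raise ValueError("popmap must have columns: sample, population")
    first = str(df.iloc[0, 0]).lower()
    if first in {"sample", "sample_id"}:
        df = df.iloc[1:]
    return {str(s): str(p) for s, p in zip(df.iloc[:, 0], df.iloc[:, 1])}


def _sample_of(hap_id: str) -> str:
    return hap_id.rsplit(".", 1)[0] if "." in hap_id else hap_id


def read_haplotypes(
    path: str | Path,
    popmap: str | Path | pd.DataFrame,
    *,
    amplicon_spans: Sequence[tuple[int, int]] | None = None,
    region_mask: np.ndarray | None = None,
) -> HaplotypeAlignment:
    """Read phased haplotypes from multi-FASTA or a phased VCF.

    FASTA records must be equal length with ids ``SAMPLE.1`` / ``SAMPLE.2``;
    positions are assigned 1..L.  VCF input must carry fully phased
    genotypes (``|`` separator); each diploid contributes two haplotype
    rows and the matrix spans the variant positions only.
    """
    path = Path(path)
    sample_pops = _read_popmap(popmap)
    if path.suffix in {".vcf"} or path.name.endswith(".vcf.gz"):
        return _read_vcf(path, sample_pops, amplicon_spans, region_mask)
    return _read_fasta(path, sample_pops, amplicon_spans, region_mask)


def _attach_pops(hap_ids: list[str], sample_pops: Mapping[str, str]) -> dict[str, str]:
    pop_of = {}
    for h in hap_ids:
        s = _sample_of(h)
        if s not in sample_pops:
            raise KeyError(f"sample {s!r} missing from popmap")
        pop_of[h] = sample_pops[s]
    return pop_of


def _read_fasta(path, sample_pops, amplicon_spans, region_mask) -> HaplotypeAlignment:
    ids, rows = [], []
    length = None
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("-", MISSING)
        if length is None:
            length = len(seq)
        elif len(seq) != length:
            raise RaggedAlignmentError(
                f"ragged alignment: record {rec.id} length {len(seq)} != {length}"
            )
        ids.append(rec.id)
        rows.append(list(seq))
    if not rows:
        raise ValueError(f"no FASTA records in {path}")
    alleles = np.asarray(rows, dtype="U1")
    bad = ~np.isin(alleles, list(VALID_BASES | {MISSING}))
    if bad.any():
        alleles = np.where(bad, MISSING, alleles)
    return HaplotypeAlignment(
        haplotype_ids=ids,
        alleles=alleles,
        positions=np.arange(1, length + 1),
        population_of=_attach_pops(ids, sample_pops),
        region_mask=region_mask,
        amplicon_spans=list(amplicon_spans or []),
    )


def _read_vcf(path, sample_pops, amplicon_spans, region_mask) -> HaplotypeAlignment:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    hap_ids = [f"{s}.{k}" for s in samples for k in (1, 2)]
    positions, cols = [], []
    for var in vcf:
        alleles = [var.REF] + list(var.ALT)
        col = []
        for g in var.genotypes:
            a0, a1, phased = g[0], g[1], g[-1]
            if not phased:
                raise UnphasedGenotypeError(
                    f"unphased genotype at {var.CHROM}:{var.POS}"
                )
            for a in (a0, a1):
                col.append(MISSING if a < 0 else alleles[a][0].upper())
        positions.append(var.POS)
        cols.append(col)
    alleles_mat = (
        np.asarray(cols, dtype="U1").T
        if cols
        else np.empty((len(hap_ids), 0), dtype="U1")
    )
    return HaplotypeAlignment(
        haplotype_ids=hap_ids,
        alleles=alleles_mat,
        positions=np.asarray(positions, dtype=np.int64),
        population_of=_attach_pops(hap_ids, sample_pops),
        region_mask=region_mask,
        amplicon_spans=list(amplicon_spans or []),
    )


def read_amplicons(path: str | Path) -> list[tuple[int, int]]:
    """Read amplicon spans from a two-column TSV (start, end; 1-based)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    first = str(df.iloc[0, 0]).lower()
    if first in {"start", "begin"}:
        df = df.iloc[1:]
    return [(int(s), int(e)) for s, e in zip(df.iloc[:, 0], df.iloc[:, 1])]


def read_outgroup(path: str | Path, expected_length: int | None = None) -> str:
    """Read the single aligned outgroup sequence (FASTA, same coordinates)."""
    recs = list(SeqIO.parse(str(path), "fasta"))
    if len(recs) != 1:
        raise ValueError(f"expected exactly one outgroup record, got {len(recs)}")
    seq = str(recs[0].seq).upper()
    if expected_length is not None and len(seq) != expected_length:
        raise RaggedAlignmentError(
            f"outgroup length {len(seq)} != locus length {expected_length}"
        )
    return seq


# ---------------------------------------------------------------------------
# Variant table construction


def variants_from_alignment(aln: HaplotypeAlignment) -> pd.DataFrame:
    """Tabulate segregating sites.

    Returns one row per polymorphic position with columns: ``position``,
    ``major``, ``minor``, ``n_alleles``, ``region``, per-population minor
    counts ``c_<pop>`` and called chromosomes ``m_<pop>``, pooled ``c`` and
    ``m``, review flags (``flag_singleton``, ``flag_triallelic``), and
    placeholders for ancestral annotation (filled by
    :func:`polarize_sites`).
    """
    pops = aln.populations
    pop_rows = {p: aln.haplotypes_of(p) for p in pops}
    records = []
    for j in range(aln.n_positions):
        col = aln.alleles[:, j]
        called = col != MISSING
        bases, counts = np.unique(col[called], return_counts=True)
        if len(bases) < 2:
            continue
        order = np.argsort(counts)[::-1]
        bases, counts = bases[order], counts[order]
        major, minor = str(bases[0]), str(bases[1])
        rec: dict = {
            "position": int(aln.positions[j]),
            "major": major,
            "minor": minor,
            "n_alleles": len(bases),
            "region": str(aln.region_mask[j]),
            "c": int(counts[1]),
            "m": int(called.sum()),
            "ancestral": "",
            "unpolarized": True,
            "flag_singleton": int(counts[1]) == 1,
            "flag_triallelic": len(bases) > 2,
            "flag_edge": False,
            "flag_low_quality": False,
            "flag_uncovered": False,
        }
        for p in pops:
            sub = col[pop_rows[p]]
            sub_called = sub != MISSING
            rec[f"c_{p}"] = int((sub == minor).sum())
            rec[f"m_{p}"] = int(sub_called.sum())
            rec[f"d_{p}"] = np.nan  # derived count, filled after polarization
        rec["d"] = np.nan
        records.append(rec)
    cols = [
        "position", "major", "minor", "n_alleles", "region", "c", "m", "d",
        "ancestral", "unpolarized", "flag_singleton", "flag_triallelic",
        "flag_edge", "flag_low_quality", "flag_uncovered",
    ] + [f"{k}_{p}" for p in pops for k in ("c", "m", "d")]
    df = pd.DataFrame.from_records(records)
    if df.empty:
        return pd.DataFrame(columns=cols)
    return df[cols]


# ---------------------------------------------------------------------------
# QC filtering


def _edge_offsets(position: int, spans: Iterable[tuple[int, int]]):
    """Smallest 1-based offsets of ``position`` from the ends of containing
    amplicons, or ``None`` when no amplicon covers the position."""
    best = None
    for start, end in spans:
        if start <= position <= end:
            off = min(position - start + 1, end - position + 1)
            best = off if best is None else min(best, off)
    return best


def apply_qc_filters(
    variants: pd.DataFrame,
    alignment: HaplotypeAlignment,
    rules: QcRules = QcRules(),
    quality: Mapping[int, float] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Apply amplicon-edge and quality filters; flag sites needing review.

    Variants whose 1-based offset from either boundary of a containing
    amplicon is within ``1..edge_bp`` are removed.  When per-variant
    ``quality`` scores (position -> score) are supplied, sub-threshold
    variants are removed.  Singletons and triallelic sites are retained but
    flagged (they were manually reviewed, not discarded, in the original
    protocol); ``strict_triallelic`` drops triallelic sites.  A variant
    outside every amplicon is flagged ``uncovered`` and retained.

    Returns the filtered table and a per-rule count report.  The operation
    is idempotent.
    """
    df = variants.copy()
    report = {
        "input": len(df),
        "removed_edge": 0,
        "removed_low_quality": 0,
        "removed_triallelic": 0,
        "flagged_singleton": 0,
        "flagged_triallelic": 0,
        "flagged_uncovered": 0,
    }
    if df.empty:
        report["retained"] = 0
        return df, report
    keep = np.ones(len(df), dtype=bool)
    spans = alignment.amplicon_spans
    for i, pos in enumerate(df["position"].to_numpy()):
        if spans:
            off = _edge_offsets(int(pos), spans)
            if off is None:
                df.iloc[i, df.columns.get_loc("flag_uncovered")] = True
            elif off <= rules.edge_bp:
                df.iloc[i, df.columns.get_loc("flag_edge")] = True
                keep[i] = False
        if quality is not None and int(pos) in quality:
            if quality[int(pos)] < rules.min_quality:
                df.iloc[i, df.columns.get_loc("flag_low_quality")] = True
                keep[i] = False
    report["removed_edge"] = int((df["flag_edge"] & ~keep).sum())
    report["removed_low_quality"] = int(df["flag_low_quality"].sum())
    if rules.strict_triallelic:
        tri = df["flag_triallelic"].to_numpy(dtype=bool)
        report["removed_triallelic"] = int((tri & keep).sum())
        keep &= ~tri
    out = df.loc[keep].reset_index(drop=True)
    report["flagged_singleton"] = int(out["flag_singleton"].sum())
    report["flagged_triallelic"] = int(out["flag_triallelic"].sum())
    report["flagged_uncovered"] = int(out["flag_uncovered"].sum())
    report["retained"] = len(out)
    return out, report


# ---------------------------------------------------------------------------
# Polarization and counting


def polarize_sites(variants: pd.DataFrame, outgroup: str, positions_offset: int = 0) -> pd.DataFrame:
    """Annotate ancestral alleles by outgroup comparison.

    The ancestral state is the outgroup base when it matches one of the two
    segregating alleles; otherwise (mismatch, gap, or N) the site stays
    unpolarized.  Only annotation changes: the set of sites, their minor
    counts, and S are untouched.  Derived counts ``d`` / ``d_<pop>`` are
    filled for polarized sites.
    """
    df = variants.copy()
    if df.empty:
        return df
    pops = [c[2:] for c in df.columns if c.startswith("c_")]
    anc, unpol = [], []
    d_pooled = []
    d_pop: dict[str, list] = {p: [] for p in pops}
    for _, row in df.iterrows():
        idx = int(row["position"]) - 1 - positions_offset
        out_base = outgroup[idx] if 0 <= idx < len(outgroup) else MISSING
        out_base = out_base.upper()
        major, minor = row["major"], row["minor"]
        if out_base in (major, minor):
            anc.append(out_base)
            unpol.append(False)
            derived = minor if out_base == major else major
            if derived == minor:
                d_pooled.append(row["c"])
                for p in pops:
                    d_pop[p].append(row[f"c_{p}"])
            else:
                d_pooled.append(row["m"] - row["c"])
                for p in pops:
                    d_pop[p].append(row[f"m_{p}"] - row[f"c_{p}"])
        else:
            anc.append("")
            unpol.append(True)
            d_pooled.append(np.nan)
            for p in pops:
                d_pop[p].append(np.nan)
    df["ancestral"] = anc
    df["unpolarized"] = unpol
    df["d"] = d_pooled
    for p in pops:
        df[f"d_{p}"] = d_pop[p]
    return df


def count_segregating_and_fixed(
    aln: HaplotypeAlignment,
    outgroup: str,
    region: str | None = None,
) -> DivergenceSummary:
    """Count segregating sites (S) and fixed differences vs outgroup (FD).

    A site is in S when polymorphic within the ingroup; in FD when the
    ingroup is monomorphic and its allele differs from the (called)
    outgroup base.  The two sets are mutually exclusive by definition.
    Outgroup gaps/N never contribute to FD.
    """
    if len(outgroup) != aln.n_positions:
        raise ValueError("outgroup must be aligned to the same positions")
    s = fd = 0
    for j in range(aln.n_positions):
        if region is not None and aln.region_mask[j] != region:
            continue
        col = aln.alleles[:, j]
        called = col[col != MISSING]
        if called.size == 0:
            continue
        bases = np.unique(called)
        if len(bases) > 1:
            s += 1
        else:
            out_base = outgroup[j].upper()
            if out_base in VALID_BASES and out_base != bases[0]:
                fd += 1
    return DivergenceSummary(S=s, FD=fd, region=region or "all")


def snp_fixed_ratio(S: int, FD: int) -> SnpFixedRatio:
    """SNPs per fixed difference; exact rational kept on ``.exact``."""
    return SnpFixedRatio(S, FD)


# ---------------------------------------------------------------------------
# Linkage disequilibrium


def pairwise_r2(
    aln: HaplotypeAlignment,
    site_pairs: Sequence[tuple[int, int]],
) -> pd.DataFrame:
    """Squared allelic correlation r^2 for the given position pairs.

    Haplotypes missing at either site are dropped pairwise.  Monomorphic
    (after missing-data removal) or non-biallelic sites yield ``NaN`` with a
    note.
    """
    rows = []
    for pos_a, pos_b in site_pairs:
        col_a, col_b = aln.column(pos_a), aln.column(pos_b)
        ok = (col_a != MISSING) & (col_b != MISSING)
        a, b = col_a[ok], col_b[ok]
        note, r2 = "", np.nan
        ua, ub = np.unique(a), np.unique(b)
        if len(ua) != 2 or len(ub) != 2:
            note = "monomorphic or not biallelic"
        else:
            x = (a == ua[0]).astype(float)
            y = (b == ub[0]).astype(float)
            denom = x.std() * y.std()
            if denom == 0:
                note = "degenerate"
            else:
                r2 = float(np.corrcoef(x, y)[0, 1] ** 2)
        rows.append({"pos_a": pos_a, "pos_b": pos_b, "r2": r2, "note": note})
    return pd.DataFrame(rows)


def hardy_weinberg(p: float) -> tuple[float, float, float]:
    """Hardy-Weinberg genotype proportions (p^2, 2pq, q^2) at frequency p."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("allele frequency must lie in [0, 1]")
    q = 1.0 - p
    return (p * p, 2.0 * p * q, q * q)
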