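"""Donor splice-site scoring, allele-aware transcript assembly, and NMD.

A 5' (donor) splice site is scored over the 9-mer spanning positions -3..+6
(last 3 exonic, first 6 intronic bases).  Two scorer kinds are supported:

* ``pwm`` — a position weight matrix on log2-odds scale against a
  background composition (self-contained, used by the synthetic fixtures);
* ``maxent-table`` — the published 5' maximum-entropy model, driven by its
  7-mer probability table (``me2x5``); the score is
  ``log2(consensus_odds(+1, +2) * table[rest-of-9-mer])``, matching the
  reference scoring pipeline for 5' sites.  The table is an external asset
  (it ships with the published scorer); point
  :meth:`DonorModel.from_maxent_tables` at it.

An allele that weakens the canonical donor can hand splicing to a cryptic
donor downstream, extending the exon; if the extension carries an in-frame
stop sufficiently upstream of the final exon-exon junction, the transcript
is a nonsense-mediated-decay (NMD) target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log2
from pathlib import Path

import numpy as np
from Bio.Seq import Seq

__all__ = [
    "DonorModel",
    "GeneModel",
    "TranscriptFate",
    "ScoredDonor",
    "score_donor",
    "select_donor",
    "splice_and_translate",
    "classify_nmd",
    "translate_longest_orf",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}

# Consensus-position frequencies of the published 5' maximum-entropy
# scorer: the +1/+2 (GT) positions are scored by first-order odds, the
# remaining seven positions by the joint maximum-entropy table.
MAXENT_BGD = {"A": 0.27, "C": 0.23, "G": 0.23, "T": 0.27}
MAXENT_CONS1 = {"A": 0.004, "C": 0.0032, "G": 0.9896, "T": 0.0022}
MAXENT_CONS2 = {"A": 0.0034, "C": 0.0039, "G": 0.0042, "T": 0.9884}


@dataclass
class DonorModel:
    """Donor (5' splice site) strength model over -3..+6 9-mers."""

    kind: str                                # "pwm" | "maxent-table"
    pwm: np.ndarray | None = None            # (9, 4) probabilities, ACGT columns
    background: np.ndarray | None = None     # (4,) composition for the PWM
    me2x5: np.ndarray | None = None          # 4**7 table, 7-mer base-4 index

    def __post_init__(self) -> None:
        if self.kind == "pwm":
            self.pwm = np.asarray(self.pwm, dtype=float)
            if self.pwm.shape != (9, 4):
                raise ValueError("PWM must be 9 x 4 (positions -3..+6, ACGT)")
            if self.background is None:
                self.background = np.full(4, 0.25)
            self.background = np.asarray(self.background, dtype=float)
        elif self.kind == "maxent-table":
            if self.me2x5 is None or len(self.me2x5) != 4**7:
                raise ValueError("maxent-table model needs the 4^7-entry me2x5 table")
            self.me2x5 = np.asarray(self.me2x5, dtype=float)
        else:
            raise ValueError(f"unknown donor model kind {self.kind!r}")

    @classmethod
    def from_maxent_tables(cls, path: str | Path) -> "DonorModel":
        """Load the published 5' maximum-entropy table (``me2x5`` file, one
        probability per line, 7-mers in base-4 A<C<G<T order)."""
        values = [
            float(line.split()[0])
            for line in Path(path).read_text().splitlines()
            if line.strip()
        ]
        return cls(kind="maxent-table", me2x5=np.asarray(values))

    @classmethod
    def uniform_pwm(cls) -> "DonorModel":
        """PWM equal to background everywhere: every 9-mer scores 0."""
        return cls(kind="pwm", pwm=np.full((9, 4), 0.25))


def _check_9mer(seq9: str) -> str:
    s = seq9.upper()
    if len(s) != 9 or any(b not in _BASE_INDEX for b in s):
        raise ValueError(f"donor site must be a 9-mer over ACGT, got {seq9!r}")
    return s


def score_donor(seq9: str, model: DonorModel) -> float:
    """Log2-odds donor strength of a 9-mer (-3..+6)."""
    s = _check_9mer(seq9)
    if model.kind == "pwm":
        total = 0.0
        for i, b in enumerate(s):
            j = _BASE_INDEX[b]
            total += log2(model.pwm[i, j] / model.background[j])
        return total
    # maxent-table: consensus odds at +1/+2 times joint table on the rest
    s4, s5 = s[3], s[4]
    consensus = (MAXENT_CONS1[s4] / MAXENT_BGD[s4]) * (
        MAXENT_CONS2[s5] / MAXENT_BGD[s5]
    )
    rest = s[:3] + s[5:]
    idx = 0
    for b in rest:
        idx = idx * 4 + _BASE_INDEX[b]
    return log2(consensus * float(model.me2x5[idx]))


@dataclass(frozen=True)
class ScoredDonor:
    """A donor candidate: genomic position of its last exonic base."""

    exon_end: int
    score: float
    canonical: bool = False


def select_donor(candidates: list[ScoredDonor], min_score: float) -> ScoredDonor:
    """Choose the active donor.

    The highest-scoring candidate at or above ``min_score`` wins, with ties
    broken upstream (smaller exon end).  When no candidate clears the
    threshold, splicing falls through to the next candidate downstream of
    the canonical donor (cryptic activation); with no downstream candidate
    the best-scoring one is used as a last resort.
    """
    if not candidates:
        raise ValueError("no donor candidates")
    eligible = [c for c in candidates if c.score >= min_score]
    if eligible:
        best = max(eligible, key=lambda c: (c.score, -c.exon_end))
        return best
    canonical = next((c for c in candidates if c.canonical), candidates[0])
    downstream = [c for c in candidates if c.exon_end > canonical.exon_end]
    if downstream:
        return min(downstream, key=lambda c: c.exon_end)
    return max(candidates, key=lambda c: (c.score, -c.exon_end))


@dataclass
class GeneModel:
    """A toy gene with one allele-sensitive intron.

    Coordinates are 1-based inclusive on ``seq``.  ``exons`` are ordered and
    non-overlapping; ``cds_start`` lies within an exon.  The intron after
    exon ``variable_intron`` (0-based exon index) carries the canonical
    donor plus any cryptic candidates, each given by the genomic position
    of the last exonic base it would produce; a SNP at ``snp_pos``
    switches between alleles A and B.
    """

    seq: str
    exons: list[tuple[int, int]]
    cds_start: int
    variable_intron: int
    donor_candidates: list[int]           # alternative exon-end positions
    snp_pos: int
    allele_a: str
    allele_b: str
    donor_model: DonorModel = field(default_factory=DonorModel.uniform_pwm)
    min_donor_score: float = 0.0

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        last = 0
        for s, e in self.exons:
            if s > e or s <= last:
                raise ValueError("exons must be ordered and non-overlapping")
            last = e
        if not any(s <= self.cds_start <= e for s, e in self.exons):
            raise ValueError("CDS start must lie within an exon")
        if not 0 <= self.variable_intron < len(self.exons) - 1:
            raise ValueError("variable intron index out of range")

    def donor_9mer(self, exon_end: int, allele: str) -> str:
        """9-mer around the donor with the allele substituted."""
        seq = self.with_allele(allele)
        return seq[exon_end - 3 : exon_end + 6]

    def with_allele(self, allele: str) -> str:
        base = {"A": self.allele_a, "B": self.allele_b}[allele]
        i = self.snp_pos - 1
        return self.seq[:i] + base + self.seq[i + 1 :]


@dataclass
class TranscriptFate:
    """Spliced mRNA with its translational outcome."""

    mrna: str
    junctions: list[int]        # 0-based mRNA offsets just after each junction
    protein: str
    protein_length: int
    stop_offset: int | None     # 0-based offset of the stop codon's first base
    ptc: bool                   # stop upstream of the last exon
    nmd: bool = False
    non_stop: bool = False
    chosen_donor: ScoredDonor | None = None

    def __post_init__(self) -> None:
        if self.nmd and not self.ptc:
            raise ValueError("NMD flag requires a premature termination codon")


def splice_and_translate(gene: GeneModel, allele: str, rule_nt: int = 50) -> TranscriptFate:
    """Assemble the allele's mRNA, translate, and classify NMD.

    The variable intron's donor candidates are scored on the allele's
    sequence and resolved by :func:`select_donor`; the chosen donor sets
    the end of the upstream exon (a downstream cryptic donor extends it).
    Translation runs from the CDS start to the first stop; a missing stop
    is flagged ``non_stop``.
    """
    if allele not in ("A", "B"):
        raise ValueError("allele must be 'A' or 'B'")
    seq = gene.with_allele(allele)
    scored = [
        ScoredDonor(
            exon_end=pos,
            score=score_donor(gene.donor_9mer(pos, allele), gene.donor_model),
            canonical=(i == 0),
        )
        for i, pos in enumerate(gene.donor_candidates)
    ]
    chosen = select_donor(scored, gene.min_donor_score)

    exons = list(gene.exons)
    s, _e = exons[gene.variable_intron]
    exons[gene.variable_intron] = (s, chosen.exon_end)

    mrna_parts = [seq[s - 1 : e] for s, e in exons]
    mrna = "".join(mrna_parts)
    junctions = [int(x) for x in np.cumsum([len(p) for p in mrna_parts])[:-1]]

    # CDS start in mRNA coordinates
    offset = 0
    cds_off = None
    for (s, e), part in zip(exons, mrna_parts):
        if s <= gene.cds_start <= e:
            cds_off = offset + (gene.cds_start - s)
            break
        offset += len(part)
    if cds_off is None:
        raise ValueError("CDS start not contained in the spliced transcript")

    coding = mrna[cds_off:]
    coding = coding[: len(coding) - len(coding) % 3]
    aa = str(Seq(coding).translate())
    stop_idx = aa.find("*")
    if stop_idx == -1:
        fate = TranscriptFate(
            mrna=mrna,
            junctions=junctions,
            protein=aa,
            protein_length=len(aa),
            stop_offset=None,
            ptc=False,
            non_stop=True,
            chosen_donor=chosen,
        )
        return fate
    protein = aa[:stop_idx]
    stop_offset = cds_off + 3 * stop_idx
    last_exon_start = junctions[-1] if junctions else 0
    ptc = (stop_offset + 3) <= last_exon_start
    fate = TranscriptFate(
        mrna=mrna,
        junctions=junctions,
        protein=protein,
        protein_length=len(protein),
        stop_offset=stop_offset,
        ptc=ptc,
        chosen_donor=chosen,
    )
    fate.nmd = classify_nmd(fate, rule_nt=rule_nt)
    return fate


def translate_longest_orf(mrna: str) -> str:
    """Protein of the longest ATG-initiated open reading frame.

    Scans all three forward frames for ATG..stop spans and translates the
    longest one (the main ORF of an mRNA).  An ORF reaching the transcript
    end without a stop is included (non-stop transcripts).
    """
    seq = mrna.upper().replace("U", "T")
    best = ""
    for frame in range(3):
        i = frame
        while i + 3 <= len(seq):
            if seq[i : i + 3] == "ATG":
                coding = seq[i:]
                coding = coding[: len(coding) - len(coding) % 3]
                aa = str(Seq(coding).translate())
                stop = aa.find("*")
                protein = aa if stop == -1 else aa[:stop]
                if len(protein) > len(best):
                    best = protein
                # skip past this ORF to avoid quadratic rescans of its
                # internal ATGs yielding only shorter proteins
                i += 3 * max(len(protein), 1)
            else:
                i += 3
    return best


def classify_nmd(fate: TranscriptFate, rule_nt: int = 50) -> bool:
    """Apply the junction rule: NMD when the stop codon lies at least
    ``rule_nt`` nucleotides upstream of the final exon-exon junction.

    The distance is measured from the 3' end of the stop codon to the
    junction; a stop in the last exon is never an NMD target.
    """
    if fate.stop_offset is None or not fate.junctions:
        return False
    stop_end = fate.stop_offset + 3
    upstream = fate.junctions[-1] - stop_end
    return fate.ptc and upstream >= rule_nt
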