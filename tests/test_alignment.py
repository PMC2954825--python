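"""Alignment I/O, QC filtering, polarization, and counting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from balscan.alignment import (
    QcRules,
    RaggedAlignmentError,
    apply_qc_filters,
    count_segregating_and_fixed,
    hardy_weinberg,
    pairwise_r2,
    polarize_sites,
    read_haplotypes,
    snp_fixed_ratio,
    variants_from_alignment,
)
from conftest import make_alignment


# ---------------------------------------------------------------------------
# I/O


def write_popmap(tmp_path, samples):
    p = tmp_path / "popmap.tsv"
    p.write_text("".join(f"{s}\t{pop}\n" for s, pop in samples))
    return p


def test_fasta_reading_builds_matrix_with_populations(tmp_path):
    fa = tmp_path / "h.fa"
    fa.write_text(">s1.1\nACGT\n>s1.2\nACGA\n>s2.1\nACGT\n>s2.2\nTCGT\n")
    pm = write_popmap(tmp_path, [("s1", "popA"), ("s2", "popB")])
    aln = read_haplotypes(fa, pm)
    assert aln.alleles.shape == (4, 4)
    assert aln.populations == ["popA", "popB"]
    assert aln.population_of["s2.1"] == "popB"


def test_ragged_fasta_is_an_error(tmp_path):
    fa = tmp_path / "h.fa"
    fa.write_text(">s1.1\nACGT\n>s1.2\nACG\n")
    pm = write_popmap(tmp_path, [("s1", "popA")])
    with pytest.raises(RaggedAlignmentError, match="ragged"):
        read_haplotypes(fa, pm)


VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "##contig=<ID=chr5>\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ti1\ti2\ti3\n"
)


def test_phased_vcf_gives_two_haplotypes_per_diploid(tmp_path):
    vcf = tmp_path / "h.vcf"
    vcf.write_text(
        VCF_HEADER
        + "chr5\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0|1\t1|1\t0|0\n"
        + "chr5\t200\t.\tC\tT\t.\tPASS\t.\tGT\t1|0\t0|0\t0|1\n"
    )
    pm = write_popmap(tmp_path, [("i1", "p"), ("i2", "p"), ("i3", "q")])
    aln = read_haplotypes(vcf, pm)
    assert aln.n_haplotypes == 6
    assert list(aln.positions) == [100, 200]
    assert aln.column(100).tolist() == ["A", "G", "G", "G", "A", "A"]


def test_unphased_genotype_rejected(tmp_path):
    vcf = tmp_path / "h.vcf"
    vcf.write_text(VCF_HEADER + "chr5\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\t1|1\t0|0\n")
    pm = write_popmap(tmp_path, [("i1", "p"), ("i2", "p"), ("i3", "q")])
    with pytest.raises(Exception, match="[Uu]nphased"):
        read_haplotypes(vcf, pm)


def test_sample_missing_from_popmap(tmp_path):
    fa = tmp_path / "h.fa"
    fa.write_text(">s1.1\nACGT\n>s1.2\nACGT\n>s9.1\nACGT\n")
    pm = write_popmap(tmp_path, [("s1", "popA")])
    with pytest.raises(KeyError, match="s9"):
        read_haplotypes(fa, pm)


# ---------------------------------------------------------------------------
# QC filtering


def edge_case_alignment(variant_offsets, amp=(1, 200), length=200):
    """Alignment polymorphic exactly at the given 1-based offsets."""
    base = ["A"] * length
    rows = []
    for r in range(4):
        row = list(base)
        if r >= 2:
            for off in variant_offsets:
                row[off - 1] = "G"
        rows.append("".join(row))
    return make_alignment(rows, amplicons=[amp])


@pytest.mark.parametrize(
    "offset,kept",
    [(50, False), (51, True), (150, True), (151, False)],  # 1..50 edge both ends
)
def test_edge_rule_boundaries(offset, kept):
    aln = edge_case_alignment([offset])
    variants = variants_from_alignment(aln)
    out, report = apply_qc_filters(variants, aln)
    assert (len(out) == 1) == kept
    assert report["removed_edge"] == (0 if kept else 1)


def test_five_variants_one_in_each_edge_leaves_three():
    # 30 in the left edge, 170 in the right edge (offset 31), three interior
    aln = edge_case_alignment([30, 100, 110, 120, 170])
    out, report = apply_qc_filters(variants_from_alignment(aln), aln)
    assert len(out) == 3
    assert set(out["position"]) == {100, 110, 120}
    assert report["removed_edge"] == 2


def test_uncovered_variant_flagged_and_retained():
    aln = edge_case_alignment([100], amp=(1, 60))
    out, _ = apply_qc_filters(variants_from_alignment(aln), aln)
    assert len(out) == 1
    assert bool(out.iloc[0]["flag_uncovered"])


def test_quality_filter_and_flags():
    aln = edge_case_alignment([100, 120])
    variants = variants_from_alignment(aln)
    out, report = apply_qc_filters(
        variants, aln, QcRules(), quality={100: 95.0, 120: 99.0}
    )
    assert list(out["position"]) == [120]
    assert report["removed_low_quality"] == 1


def test_filtering_is_idempotent(toy_alignment):
    v = variants_from_alignment(toy_alignment)
    once, _ = apply_qc_filters(v, toy_alignment)
    twice, _ = apply_qc_filters(once, toy_alignment)
    pd.testing.assert_frame_equal(once, twice)


# ---------------------------------------------------------------------------
# Polarization and S / FD


def test_polarize_simple_match(toy_alignment):
    # outgroup equals first haplotype: all three sites polarizable
    out = polarize_sites(variants_from_alignment(toy_alignment), "AAAACAAAGA")
    assert not out["unpolarized"].any()
    site2 = out[out["position"] == 2].iloc[0]
    assert site2["ancestral"] == "A"
    assert site2["d"] == 3  # G is derived, carried by 3 haplotypes


def test_polarize_mismatch_leaves_unpolarized(toy_alignment):
    # outgroup C at position 2 matches neither A nor G
    out = polarize_sites(variants_from_alignment(toy_alignment), "ACAACAAAGA")
    assert bool(out[out["position"] == 2].iloc[0]["unpolarized"])


def test_polarize_ten_site_toy_eight_of_ten():
    # 10 polymorphic sites; outgroup mismatches at sites 3 and 7 (1-based)
    rows = ["ACACACACAC", "GTGTGTGTGT"]
    aln = make_alignment([rows[0]] * 2 + [rows[1]] * 2)
    outgroup = "ACTCACCCAC"  # T at 3 and C at 7 match neither allele
    variants = variants_from_alignment(aln)
    assert len(variants) == 10
    out = polarize_sites(variants, outgroup)
    assert int(out["unpolarized"].sum()) == 2
    assert set(out.loc[out["unpolarized"], "position"]) == {3, 7}


def test_polarization_changes_only_annotation(toy_alignment):
    v = variants_from_alignment(toy_alignment)
    out = polarize_sites(v, "AAAACAAAGA")
    assert list(out["position"]) == list(v["position"])
    assert list(out["c"]) == list(v["c"])


def test_s_and_fd_counting(toy_alignment):
    og_same = "AAAACAAAGA"
    d = count_segregating_and_fixed(toy_alignment, og_same)
    assert (d.S, d.FD) == (3, 0)
    # outgroup differs at monomorphic sites 1 and 10, and at polymorphic site 2
    og = "TAAACAAAGC"
    d2 = count_segregating_and_fixed(toy_alignment, og)
    assert (d2.S, d2.FD) == (3, 2)  # polymorphic site never counted as FD


def test_identical_ingroup_and_outgroup():
    aln = make_alignment(["ACGT"] * 3)
    d = count_segregating_and_fixed(aln, "ACGT")
    assert (d.S, d.FD) == (0, 0)


@given(
    st.lists(
        st.tuples(st.integers(0, 3), st.integers(0, 3), st.integers(0, 3)),
        min_size=1,
        max_size=30,
    )
)
def test_s_fd_mutually_exclusive(cols):
    """No site can be both segregating and a fixed difference."""
    bases = "ACGT"
    rows = ["".join(bases[c[0]] for c in cols), "".join(bases[c[1]] for c in cols)]
    outgroup = "".join(bases[c[2]] for c in cols)
    aln = make_alignment(rows)
    d = count_segregating_and_fixed(aln, outgroup)
    n_seg = sum(1 for c in cols if c[0] != c[1])
    n_fd = sum(1 for c in cols if c[0] == c[1] and c[2] != c[0])
    assert (d.S, d.FD) == (n_seg, n_fd)


# ---------------------------------------------------------------------------
# Ratios, r2, HWE


@pytest.mark.parametrize(
    "s,fd,display",
    [(22, 10, 2.2), (287, 352, 0.8), (45, 7, 6.4), (0, 5, 0.0)],
)
def test_snp_fixed_ratio_display(s, fd, display):
    assert snp_fixed_ratio(s, fd).display == display


def test_snp_fixed_ratio_two_decimals_controls():
    assert round(float(snp_fixed_ratio(287, 352)), 2) == 0.82


def test_snp_fixed_ratio_undefined():
    with pytest.raises(ZeroDivisionError):
        snp_fixed_ratio(5, 0)


@given(st.integers(0, 500), st.integers(1, 400))
def test_ratio_exactness(s, fd):
    assert snp_fixed_ratio(s, fd).exact * fd == s


def test_r2_perfect_and_zero():
    aln = make_alignment(["AAGG", "AAGG", "GGAA", "GGAA"])
    out = pairwise_r2(aln, [(1, 2)])
    assert out.iloc[0]["r2"] == pytest.approx(1.0)
    # balanced independent design
    aln2 = make_alignment(["AA", "AG", "GA", "GG"])
    out2 = pairwise_r2(aln2, [(1, 2)])
    assert out2.iloc[0]["r2"] == pytest.approx(0.0, abs=1e-12)


def test_r2_hand_computed_six_haplotypes():
    # site1 alleles: A A A G G G ; site2: A A G A G G
    # 2x2 table: pA=0.5, pB=0.5, pAB (A,A) = 2/6 -> D = 1/3 - 1/4 = 1/12
    # r2 = D^2 / (pA qA pB qB) = (1/144) / (1/16) = 1/9
    aln = make_alignment(["AA", "AA", "AG", "GA", "GG", "GG"])
    out = pairwise_r2(aln, [(1, 2)])
    assert out.iloc[0]["r2"] == pytest.approx(1.0 / 9.0)


def test_r2_monomorphic_reported():
    aln = make_alignment(["AA", "AG", "AA", "AG"])
    out = pairwise_r2(aln, [(1, 2)])
    assert np.isnan(out.iloc[0]["r2"])
    assert "monomorphic" in out.iloc[0]["note"]


def test_hardy_weinberg_quarter():
    aa, ab, bb = hardy_weinberg(0.5)
    assert aa == pytest.approx(0.25)
    assert ab == pytest.approx(0.5)


def test_read_amplicons_tsv(tmp_path):
    from balscan.alignment import read_amplicons

    p = tmp_path / "amps.tsv"
    p.write_text("start\tend\n1\t400\n350\t800\n")
    assert read_amplicons(p) == [(1, 400), (350, 800)]
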