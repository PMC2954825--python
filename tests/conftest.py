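import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from balscan.alignment import HaplotypeAlignment


def make_alignment(rows, populations=None, amplicons=(), region=None):
    """Build a small HaplotypeAlignment from sequence strings."""
    n = len(rows)
    ids = [f"s{i // 2 + 1}.{i % 2 + 1}" for i in range(n)]
    if populations is None:
        populations = ["pop1"] * n
    pop_of = {ids[i]: populations[i] for i in range(n)}
    mat = np.array([list(r) for r in rows], dtype="U1")
    return HaplotypeAlignment(
        haplotype_ids=ids,
        alleles=mat,
        positions=np.arange(1, mat.shape[1] + 1),
        population_of=pop_of,
        region_mask=region,
        amplicon_spans=list(amplicons),
    )


@pytest.fixture
def toy_alignment():
    # 4 haplotypes, 10 positions; sites 2, 5, 8 polymorphic (1-based)
    return make_alignment(
        [
            "AAAACAAAGA",
            "AGAACAAAGA",
            "AGAATAAATA",
            "AGAATAAATA",
        ],
        populations=["pop1", "pop1", "pop2", "pop2"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
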