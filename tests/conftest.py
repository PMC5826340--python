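import numpy as np
import pytest

from finrep.germline import GeneSegment, GermlineSet
from finrep.simulate import (
    SimulationConfig,
    make_germline,
    simulate_repertoire,
)


@pytest.fixture(scope="session")
def small_germline():
    """An 8 V x 4 D x 3 J synthetic IgM germline set."""
    return make_germline(8, 4, 3, seed=11)


@pytest.fixture(scope="session")
def paired_germlines():
    """Full-scale IgM (32x6x5) and IgT (32x3x2) germline sets."""
    return {
        "IgM": make_germline(32, 6, 5, seed=1, isotype="IgM"),
        "IgT": make_germline(32, 3, 2, seed=2, isotype="IgT"),
    }


@pytest.fixture(scope="session")
def noise_free_repertoire(paired_germlines):
    """500 noise-free reads (60% IgM) with their truth records."""
    config = SimulationConfig(seed=7, n_reads=500, isotype_mix=0.6)
    pairs, truths = simulate_repertoire(paired_germlines, config)
    return pairs, truths


@pytest.fixture
def toy_vj_germline():
    """A hand-built minimal germline whose anchors are obvious.

    V = ATG AAA TGC (2nd-CYS at offset 6), J = TGG GGC CAA GGC (WGxG at 0).
    """
    v = GeneSegment(id="V1.1", segment_class="V", sequence="ATGAAATGC",
                    anchor_offset=6)
    j = GeneSegment(id="Jm1", segment_class="J", sequence="TGGGGCCAAGGC",
                    anchor_offset=0)
    d = GeneSegment(id="Dm1", segment_class="D", sequence="GCAAGAGA")
    return GermlineSet(isotype="IgM", v_segments=[v], d_segments=[d],
                       j_segments=[j])


def brute_force_sw(a: str, b: str, match=2, mismatch=-3, gap_open=-5,
                   gap_extend=-2) -> float:
    """Independent full-matrix affine-gap Smith-Waterman (test oracle).

    gap_open is the score of the first gapped base, gap_extend of each
    additional one.
    """
    n, m = len(a), len(b)
    NEG = -1e18
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)
    F = np.full((n + 1, m + 1), NEG)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if (a[i - 1] == b[j - 1] and a[i - 1] != "N") else mismatch
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best
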