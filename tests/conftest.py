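import numpy as np
import pytest

from rpimer.encode import RamachandranCodebook, RamachandranRegion
from rpimer.synth import MotifSpec, SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def tiling_codebook():
    """Seven-code codebook whose first six regions tile the torus exactly."""
    regions = []
    codes = "abcdefg"
    phi_edges = [(-180, -60), (-60, 60), (60, 180)]
    psi_edges = [(-180, 0), (0, 180)]
    i = 0
    for plo, phi in phi_edges:
        for slo, shi in psi_edges:
            regions.append(RamachandranRegion(codes[i], plo, phi, slo, shi))
            i += 1
    return RamachandranCodebook(regions=tuple(regions), codes=tuple(codes),
                                fallback_code="g")


@pytest.fixture(scope="session")
def small_dataset():
    """Tiny planted-motif corpus shared by pipeline-level tests."""
    cfg = SynthConfig(
        n_pos=20, n_neg=20,
        rna_length=(50, 80), protein_length=(60, 90),
        motifs=(MotifSpec("ACGUG", "rna_seq", p_pos=1.0, p_neg=0.0),),
        seed=11,
    )
    return generate_dataset(cfg)


def naive_kmer_counts(corpus, k_min, k_max):
    """Independent oracle: nested-loop substring counter.

    For every string, every start position and every k, extract the
    substring and tally it; no sliding-window reuse, no indexing.
    """
    counts = {}
    for s in corpus:
        for start in range(len(s)):
            for k in range(k_min, k_max + 1):
                if start + k <= len(s):
                    sub = s[start:start + k]
                    counts[sub] = counts.get(sub, 0) + 1
    return counts
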