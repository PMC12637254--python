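"""Shared fixtures: a tiny hand-built atlas and a small simulated benchmark."""

import numpy as np
import pytest

from amp2bgc.atlas import atlas_from_profiles
from amp2bgc.profiles import BGCProfile
from amp2bgc.simulate import SimConfig, make_benchmark


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def tiny_atlas():
    """Four distinct 80-nt references, one entry with two member genomes."""
    r = np.random.default_rng(42)
    seqs = {f"g{i}": _random_seq(r, 80) for i in range(1, 5)}
    seqs["g5"] = seqs["g4"]  # duplicate marker -> multiplicity 2
    profiles = {
        "g1": BGCProfile.from_array([1, 0, 2, 0, 0, 0, 1, 0]),
        "g2": BGCProfile.from_array([0, 0, 5, 0, 1, 0, 0, 0]),
        "g3": BGCProfile.from_array([0, 1, 0, 0, 2, 0, 1, 1]),
        "g4": BGCProfile.from_array([3, 0, 0, 1, 0, 0, 0, 0]),
        "g5": BGCProfile.from_array([4, 0, 0, 1, 0, 0, 0, 0]),
    }
    return atlas_from_profiles(seqs, profiles)


@pytest.fixture(scope="session")
def bench40():
    """Small end-to-end benchmark shared across slower tests."""
    return make_benchmark(SimConfig(n_tips=40, seed=7, holdout_fraction=0.25))
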