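import numpy as np
import pytest

from genostruct.phylo import Phylogeny
from genostruct.pipeline import SimBundle, reference_maps, simulate
from genostruct.simgen import SimConfig


def small_config(seed: int = 3, **overrides) -> SimConfig:
    base = dict(
        seed=seed,
        chrom_lengths={"chr2": 500_000, "chrX": 500_000},
        n_genes=40,
        n_trnas=24,
        n_trna_clusters=6,
        n_satellites=6,
        n_ancestral_tes=20,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def phylo() -> Phylogeny:
    return Phylogeny()


@pytest.fixture(scope="session")
def small_bundle() -> SimBundle:
    """A 2 x 500 kb five-genome simulation shared across module tests."""
    return simulate(small_config())


@pytest.fixture(scope="session")
def small_maps(small_bundle):
    return reference_maps(small_bundle)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def random_seq(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
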