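import numpy as np
import pytest

import rootweb as rw
from rootweb.alignment import warm_up


@pytest.fixture(scope="session", autouse=True)
def _warm_jit():
    """Compile the alignment kernel once so tests measure logic, not JIT."""
    warm_up()


@pytest.fixture(scope="session")
def small_world():
    """A small but complete synthetic survey reused across integration tests."""
    spec = rw.CommunitySpec(
        n_plants=4,
        n_fungi_per_ecotype={"ectomycorrhizal": 3, "arbuscular": 1,
                             "endophyte": 2, "other": 2},
        n_root_samples=10,
        n_soil_samples=4,
        depth_range=(120, 160),
        rbcl_depth=10,
        seed=11,
    )
    truth = rw.generate_community(spec)
    sim = rw.simulate_reads(truth)
    return spec, truth, sim


@pytest.fixture(scope="session")
def clean_world():
    """Error-free, chimera-free world: every read equals its template."""
    spec = rw.CommunitySpec(
        n_plants=3,
        n_fungi_per_ecotype={"ectomycorrhizal": 2, "arbuscular": 1,
                             "endophyte": 2, "other": 1},
        n_root_samples=6,
        n_soil_samples=3,
        depth_range=(110, 130),
        rbcl_depth=8,
        error_rate=0.0,
        chimera_rate=0.0,
        seed=5,
    )
    truth = rw.generate_community(spec)
    sim = rw.simulate_reads(truth)
    return spec, truth, sim


def rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def mutate(seq: str, rng: np.random.Generator, k: int) -> str:
    """Exactly k substitutions at distinct positions."""
    arr = list(seq)
    pos = rng.choice(len(arr), size=k, replace=False)
    for p in pos:
        arr[p] = rng.choice([b for b in "ACGT" if b != arr[p]])
    return "".join(arr)
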