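import numpy as np
import pytest

from dendrysis import (
    EnsembleSpec,
    enumerate_branch_permutations,
    generate_dendrimer_ensemble,
    parse_dendrimer_sequence,
)

MH18_SEQ = "(KL)_8(*K*KL)_4(*K*LL)_2*K*LLLL"
MH47_SEQ = "(KL)_8(*K*LL)_4(*K*LL)_2*K*LLLL"
MH13_SEQ = "(KL)_8(*K*KL)_4(*K*LL)_2*K*K(C_16)K(C_16)"
DMH18_SEQ = "(kl)_8(*k*kl)_4(*k*ll)_2*k*llll"

# the full water-phase panel (all systems except MH47)
WATER_PANEL = {
    "MH18": MH18_SEQ,
    "DMH18": DMH18_SEQ,
    "MH18D1": "(kl)_8(*K*KL)_4(*K*LL)_2*K*LLLL",
    "MH18D2": "(KL)_8(*K*KL)_4(*K*LL)_2*K*llll",
    "MH18D3": "(KL)_8(*k*KL)_4(*k*LL)_2*k*LLLL",
    "MH18D4": "(kl)_8(*K*KL)_4(*k*ll)_2*K*LLLL",
    "MH13": MH13_SEQ,
    "DMH13": "(kl)_8(*k*kl)_4(*k*ll)_2*k*k(C_16)k(C_16)",
}


@pytest.fixture(scope="session")
def mh18():
    return parse_dendrimer_sequence(MH18_SEQ, "MH18")


@pytest.fixture(scope="session")
def mh47():
    return parse_dendrimer_sequence(MH47_SEQ, "MH47")


@pytest.fixture(scope="session")
def mh13():
    return parse_dendrimer_sequence(MH13_SEQ, "MH13")


@pytest.fixture(scope="session")
def toy_branch():
    """A single branching lysine with two identical KL arms."""
    return parse_dendrimer_sequence("(KL)_2*K*", "toy")


@pytest.fixture(scope="session")
def mh18_perms(mh18):
    return enumerate_branch_permutations(mh18)


@pytest.fixture(scope="session")
def mh18_ensemble(mh18):
    return generate_dendrimer_ensemble(
        EnsembleSpec(topology=mh18, n_frames=50, compactness=0.5, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
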