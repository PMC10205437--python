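import numpy as np
import pytest

from dais import FixtureSpec, Injection, make_case_pair, make_ring_ensemble


def random_cloud(rng, n, scale=4.0):
    return rng.normal(size=(n, 3)) * scale


@pytest.fixture(scope="session")
def ring_ensemble():
    """20-residue jittered ring, 20 frames."""
    return make_ring_ensemble(
        FixtureSpec(n_residues=20, n_frames=20, jitter_sd=0.05, seed=7)
    )


@pytest.fixture(scope="session")
def opening_pair():
    """Control/Case pair with a ring-opening injection on residues 5-10."""
    spec = FixtureSpec(
        n_residues=20,
        n_frames=40,
        jitter_sd=0.05,
        seed=11,
        injection=Injection(
            kind="ring_opening", residues=tuple(range(5, 11)), magnitude=5.0
        ),
    )
    return make_case_pair(spec)
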