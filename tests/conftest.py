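"""Shared fixtures: the default network point and small problem builders.

The default parameter point (f = 0.2, r = 0.02, beta = 20, w~ = 20, 20%
inhibitory) is the biologically plausible setting used throughout the
package; fixtures expose it at several sizes so tests can trade accuracy
for runtime.
"""

import numpy as np
import pytest

from assocmem import NetworkSpec, generate_sequence
from assocmem.loading import AssociationSet

F = 0.2
R = 0.02
BETA = 20.0
W_TILDE = 20.0
FRAC_INH = 0.2


def make_spec(n: int, beta: float = BETA, r: float = R, seed: int = 0) -> NetworkSpec:
    return NetworkSpec.homogeneous_network(
        n, frac_inh=FRAC_INH, f=F, r=r, beta_int=beta, w=W_TILDE / n, seed=seed
    )


def neuron_problem(spec: NetworkSpec) -> dict:
    p = spec.neurons[0]
    return dict(
        f=spec.f, r=spec.r, g=spec.g.astype(float),
        beta_syn=p.beta_syn, beta_int=p.beta_int,
        w_tilde=float(spec.w_tilde[0]), f_out=p.f, r_out=p.r,
    )


@pytest.fixture(scope="session")
def spec100():
    return make_spec(100)


@pytest.fixture(scope="session")
def spec200():
    return make_spec(200)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_assoc(spec100):
    seq = generate_sequence(spec100, 6, seed=42)
    return AssociationSet.from_sequence(seq, 0)
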