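"""Shared fixtures: small built chains and the benchmark scenario."""

import numpy as np
import pytest

from cisnonpro.model import Structure
from cisnonpro.pipeline import run_detect
from cisnonpro.synth import build_backbone, generate_case, standard_scenario


def make_chain(sequence="ASERATLKVD", cis_bond=None, chain_id="A",
               phi2=-90.0, b_factors=None, bond_overrides=None):
    """Build a beta-strand chain, optionally with one planted cis bond."""
    n = len(sequence)
    phi = [-120.0] * n
    psi = [130.0] * n
    omega = [180.0] * (n - 1)
    if cis_bond is not None:
        omega[cis_bond] = 0.0
        phi[cis_bond + 1] = phi2
    return build_backbone(sequence, phi, psi, omega, chain_id=chain_id,
                          b_factors=b_factors, bond_overrides=bond_overrides)


@pytest.fixture
def beta_chain():
    return make_chain()


@pytest.fixture
def cis_structure():
    """Single-chain structure with one cis-nonPro bond mid-chain."""
    return Structure("test", [make_chain(cis_bond=4)], resolution=1.5)


@pytest.fixture(scope="module")
def benchmark_case():
    """The 50-chain benchmark scenario: 12 clean plants + 12 decoys."""
    return generate_case(standard_scenario(seed=1))


@pytest.fixture(scope="module")
def benchmark_result(benchmark_case):
    return run_detect(benchmark_case.structures, benchmark_case.annotations)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
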