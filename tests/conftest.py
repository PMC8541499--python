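"""Shared fixtures: small synthetic ensembles with known ground truth."""

import numpy as np
import pytest

from confens.synthetic import (
    BackboneGeometry,
    ChainSpec,
    build_backbone,
    generate_gaussian_chain,
    generate_multistate_ensemble,
)


@pytest.fixture(scope="session")
def fjc_ensemble():
    """Freely-jointed chain: 100 bonds, 10^4 frames, fixed seed."""
    return generate_gaussian_chain(ChainSpec(101, 0.38, 10_000, seed=11))


@pytest.fixture(scope="session")
def helix_peptide():
    """15-residue ideal alpha-helix, single frame."""
    return build_backbone("A" * 15, BackboneGeometry.alpha_helix(15))


@pytest.fixture(scope="session")
def two_state_conformers():
    """Two well-separated low-symmetry conformers sharing a topology."""
    n = 15
    geo_a = BackboneGeometry(
        phi=(-57.0,) * 8 + (-75.0,) * 7, psi=(-47.0,) * 8 + (145.0,) * 7
    )
    geo_b = BackboneGeometry(
        phi=(-75.0,) * 8 + (-57.0,) * 7, psi=(145.0,) * 8 + (-47.0,) * 7
    )
    return build_backbone("A" * n, geo_a), build_backbone("A" * n, geo_b)


@pytest.fixture(scope="session")
def two_state_ensemble(two_state_conformers):
    """4000-frame 70/30 mixture with labels, 4 replicates."""
    ens, labels = generate_multistate_ensemble(
        list(two_state_conformers),
        (0.7, 0.3),
        noise_sd=0.03,
        n_frames=4000,
        n_replicates=4,
        seed=7,
        return_labels=True,
    )
    return ens, labels


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
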