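"""Shared fixtures: small grids and reusable phantom cases.

Expensive session-scoped fixtures (full 96³ phantoms, one registration)
are shared across test modules so the suite stays fast.
"""

from dataclasses import replace

import numpy as np
import pytest

from lafq.image_model import LabelMask, Volume3D
from lafq.phantom import PhantomSpec, _default_veins, generate_phantom
from lafq.registration import register, RegistrationSettings


def make_volume(voxels, spacing=(1, 1, 1), origin=(0, 0, 0)) -> Volume3D:
    return Volume3D(np.asarray(voxels, dtype=float), spacing, origin, np.eye(3))


def make_mask(voxels, spacing=(1, 1, 1), origin=(0, 0, 0)) -> LabelMask:
    return LabelMask(np.asarray(voxels).astype(bool), spacing, origin, np.eye(3))


def ball_mask(shape, center, radius, spacing=(1, 1, 1)) -> LabelMask:
    idx = np.indices(shape).reshape(3, -1).T
    keep = np.linalg.norm((idx - np.asarray(center, dtype=float)), axis=1) <= radius
    vox = np.zeros(shape, dtype=bool)
    vox[tuple(idx[keep].T)] = True
    return make_mask(vox, spacing=spacing)


def ablated_spec(seed=7, noise_sd=10.0, misalign=True, coverage=0.8) -> PhantomSpec:
    """Post-ablation-style phantom: rings on all four veins + diffuse load."""
    veins = {v: replace(vs, ring_coverage=coverage, ring_axial_mm=10.0)
             for v, vs in _default_veins().items()}
    return PhantomSpec(veins=veins, diffuse_fibrosis_mm3=1500.0,
                       noise_sd=noise_sd, misalign=misalign, seed=seed)


@pytest.fixture(scope="session")
def noiseless_case():
    return generate_phantom(ablated_spec(noise_sd=0.0, misalign=False))


@pytest.fixture(scope="session")
def misaligned_case():
    return generate_phantom(ablated_spec(seed=3))


@pytest.fixture(scope="session")
def registered(misaligned_case):
    """One shared rigid registration of the misaligned phantom pair."""
    transform, report = register(misaligned_case.lge, misaligned_case.angio,
                                 mode="rigid", settings=RegistrationSettings())
    return transform, report
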