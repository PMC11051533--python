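"""Shared fixtures: small analytic meshes and a cached end-to-end rehearsal."""

from __future__ import annotations

import numpy as np
import pytest
import trimesh

from kneemorph.mesh import TriangleMesh
from kneemorph.phantoms import PhantomSpec, generate_knee, generate_phantom


def icosphere(subdivisions: int = 3, radius: float = 10.0, name: str = "sphere") -> TriangleMesh:
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriangleMesh(np.asarray(ico.vertices), np.asarray(ico.faces), name)


@pytest.fixture(scope="session")
def sphere() -> TriangleMesh:
    return icosphere()


@pytest.fixture(scope="session")
def femur_phantom():
    """Default femur-like phantom (about 2k vertices) with analytic truth."""
    return generate_phantom(PhantomSpec(bone="femur_like"))


@pytest.fixture(scope="session")
def tibia_phantom():
    return generate_phantom(PhantomSpec(bone="tibia_like"))


@pytest.fixture(scope="session")
def base_knee():
    return generate_knee(subject="base", seed=1)


@pytest.fixture(scope="session")
def rehearsal():
    """One full synthetic end-to-end run shared by the expensive checks.

    Study conditions: six subjects deformed from a common base phantom
    (RMS 2 mm, smoothness 20 mm), three simulated observers with repeat
    noise 1.0 mm and observer noise 1.5 mm, fixed seed.
    """
    from kneemorph.pipeline import run_phantom_rehearsal

    return run_phantom_rehearsal(n_subjects=6, seed=1)
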