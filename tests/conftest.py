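"""Shared fixtures: small phantoms and analytic voxel solids.

Everything is generated at test time from seeds; sizes are kept small
(envelopes of a few hundred nm, 2-2.5 nm voxels) so the full suite runs on
one CPU in minutes.
"""

from __future__ import annotations

import numpy as np
import pytest

from cristamorph.phantom import PhantomSpec, generate_phantom
from cristamorph.segmentation import LabelVolume, extract_mesh
from cristamorph.volume import Volume

# standard small-phantom conditions used across the suite
SMALL = dict(voxel_size=2.5, slab_thickness_nm=200.0,
             envelope_semi_axes=(260.0, 260.0))
ENVELOPES = {"lamellar": (260.0, 260.0), "tubular": (260.0, 260.0),
             "transitional": (260.0, 260.0), "mixed": (260.0, 420.0)}


def small_spec(morphology: str, seed: int, **over) -> PhantomSpec:
    kw = dict(SMALL)
    kw["envelope_semi_axes"] = ENVELOPES[morphology]
    kw.update(over)
    return PhantomSpec(morphology_class=morphology, seed=seed, **kw)


@pytest.fixture(scope="session")
def lamellar_phantom():
    spec = small_spec("lamellar", seed=3)
    vol, cset, truth = generate_phantom(spec)
    return spec, vol, cset, truth


@pytest.fixture(scope="session")
def tubular_phantom():
    spec = small_spec("tubular", seed=5)
    vol, cset, truth = generate_phantom(spec)
    return spec, vol, cset, truth


def voxel_solid(shape: tuple[int, int, int], predicate) -> np.ndarray:
    zz, yy, xx = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    return predicate(zz, yy, xx)


def mesh_of(mask: np.ndarray, voxel: float = 1.0):
    (_k, mesh), = extract_mesh(LabelVolume(mask.astype(np.uint8), voxel))
    return mesh


@pytest.fixture(scope="session")
def ball_mesh():
    """Voxelized ball, radius 30 (units = voxels = nm at voxel 1)."""
    mask = voxel_solid((81, 81, 81),
                       lambda z, y, x: (z - 40) ** 2 + (y - 40) ** 2
                       + (x - 40) ** 2 <= 30 ** 2)
    return mesh_of(mask)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
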