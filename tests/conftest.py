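"""Shared fixtures: canonical profiles, integrator settings, tiny frames."""

import numpy as np
import pytest

from flipkin import (
    GeometrySpec,
    LangevinModel,
    MolecularFrame,
    ProfileSpec,
    generate_hydration_frames,
    make_pmf,
)


@pytest.fixture()
def double_well():
    """The ambient-condition double-well profile: stacked minimum at 0 deg
    (3 kT deep), base-triplet-like minimum at -100 deg (1.5 kT), 5 kT
    looping-out barrier near +70 deg."""
    spec = ProfileSpec(minima=((0.0, 3.0), (-100.0, 1.5)), barrier_height=5.0)
    return make_pmf(spec, 1.0)


@pytest.fixture()
def single_well():
    spec = ProfileSpec(minima=((0.0, 2.0),), barrier_height=4.0)
    return make_pmf(spec, 1.0)


@pytest.fixture()
def flat_profile():
    grid = -180.0 + 1.0 * np.arange(360)
    return make_flat(grid)


def make_flat(grid):
    from flipkin import FreeEnergyProfile

    return FreeEnergyProfile(
        grid=np.asarray(grid, dtype=float),
        values=np.zeros(len(grid)),
        energy_fn=lambda x: np.zeros_like(np.asarray(x, dtype=float)),
        force_fn=lambda x: np.zeros_like(np.asarray(x, dtype=float)),
    )


@pytest.fixture()
def fast_model():
    return LangevinModel(dt=1.0, n_steps=20_000, record_every=10, seed=1)


@pytest.fixture()
def lattice_frame():
    """One noise-free diamond-network frame with a centered point solute."""
    spec = GeometrySpec(solute_positions={"bulge": np.array([[1.293] * 3])})
    return generate_hydration_frames(spec, 1, seed=0, mode="lattice+noise")[0]


@pytest.fixture()
def tetra_frame():
    """Five atoms: a center and its four perfect-tetrahedron neighbors, in a
    box large enough that minimum image never wraps."""
    box = np.array([10.0, 10.0, 10.0])
    verts = np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
    ) / np.sqrt(3.0)
    pos = np.vstack([[5.0, 5.0, 5.0], 5.0 + 0.28 * verts])
    return MolecularFrame(solvent=pos, box=box)
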