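"""Hydration-shell observables: RDF, membership, OOO angles, q, occupancy."""

import numpy as np
import pytest

from flipkin import (
    GeometrySpec,
    MolecularFrame,
    generate_hydration_frames,
    minimum_image,
    ooo_angle_distribution,
    rdf,
    shell_average_q,
    shell_membership,
    shell_occupancy,
    tetrahedral_q,
)

TETRA_ANGLE = np.degrees(np.arccos(-1.0 / 3.0))   # 109.47 deg


def test_minimum_image():
    box = np.array([2.0, 2.0, 2.0])
    d = minimum_image(np.array([1.9, -1.9, 0.4]), box)
    assert d == pytest.approx([-0.1, 0.1, 0.4])


def test_q_perfect_tetrahedron_is_one(tetra_frame):
    assert tetrahedral_q(tetra_frame, 0, [1, 2, 3, 4]) == pytest.approx(
        1.0, abs=1e-12
    )


def test_q_square_planar_is_half():
    box = np.array([10.0, 10.0, 10.0])
    sq = np.array([[1, 0, 0], [0, 1, 0], [-1, 0, 0], [0, -1, 0]], dtype=float)
    pos = np.vstack([[5.0, 5.0, 5.0], 5.0 + 0.3 * sq])
    frame = MolecularFrame(solvent=pos, box=box)
    assert tetrahedral_q(frame, 0, [1, 2, 3, 4]) == pytest.approx(0.5,
                                                                 abs=1e-12)


def test_q_collinear_is_minus_three():
    """All four neighbors on the same ray: every pair cosine is 1, so
    q = 1 - (3/8) * 6 * (4/3)^2 = -3."""
    box = np.array([10.0, 10.0, 10.0])
    line = np.array([[1, 0, 0], [2, 0, 0], [3, 0, 0], [4, 0, 0]],
                    dtype=float)
    pos = np.vstack([[5.0, 5.0, 5.0], 5.0 + 0.2 * line])
    frame = MolecularFrame(solvent=pos, box=box)
    assert tetrahedral_q(frame, 0, [1, 2, 3, 4]) == pytest.approx(-3.0,
                                                                  abs=1e-12)


def test_q_validation(tetra_frame):
    with pytest.raises(ValueError, match="exactly 4"):
        tetrahedral_q(tetra_frame, 0, [1, 2, 3])
    with pytest.raises(ValueError, match="exactly 4"):
        tetrahedral_q(tetra_frame, 0, [1, 1, 2, 3])
    with pytest.raises(ValueError, match="own neighbor"):
        tetrahedral_q(tetra_frame, 0, [0, 1, 2, 3])


def test_q_uses_minimum_image_across_boundary():
    """A tetrahedron split across the periodic boundary must still give 1."""
    box = np.array([2.0, 2.0, 2.0])
    verts = np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
    ) / np.sqrt(3.0)
    pos = np.vstack([[0.0, 0.0, 0.0], 0.28 * verts])  # wraps into [0, box)
    frame = MolecularFrame(solvent=pos, box=box)
    assert tetrahedral_q(frame, 0, [1, 2, 3, 4]) == pytest.approx(1.0,
                                                                  abs=1e-12)


def test_shell_membership_hand_built():
    box = np.array([3.0, 3.0, 3.0])
    solv = np.array([[1.5, 1.5, 1.8], [1.5, 1.5, 2.4], [0.1, 1.5, 1.5]])
    frame = MolecularFrame(solvent=solv, box=box,
                           solute={"bulge": np.array([[1.5, 1.5, 1.5]])})
    sel = shell_membership(frame, "bulge", 0.35)
    assert list(sel.members) == [0]
    assert sel.n_waters == 1
    assert shell_membership(frame, "bulge", 0.0).n_waters == 0
    with pytest.raises(ValueError, match=">= 0"):
        shell_membership(frame, "bulge", -0.1)
    with pytest.raises(KeyError):
        frame.role_positions("phosphate")


def test_shell_membership_wraps_across_boundary():
    box = np.array([3.0, 3.0, 3.0])
    frame = MolecularFrame(solvent=np.array([[2.9, 1.5, 1.5]]), box=box,
                           solute={"bulge": np.array([[0.1, 1.5, 1.5]])})
    assert shell_membership(frame, "bulge", 0.3).n_waters == 1


def test_rdf_ideal_gas_is_flat():
    spec = GeometrySpec(box=(3.0, 3.0, 3.0), n_solvent=500,
                        solute_positions={"bulge": np.array([[1.5] * 3])})
    frames = generate_hydration_frames(spec, 100, seed=9, mode="ideal_gas")
    res = rdf(frames, "bulge", "solvent", dr=0.1)
    sel = res.r > 0.3   # small-r shells hold few counts
    assert np.abs(res.g[sel] - 1.0).mean() < 0.05


def test_rdf_lattice_first_minimum_between_shells(lattice_frame):
    """The diamond network has neighbor shells at 0.28 and 0.457 nm; the
    solvent-solvent RDF first minimum must fall between them."""
    spec = GeometrySpec(angular_noise=6.0)
    frames = generate_hydration_frames(spec, 4, seed=2, mode="lattice+noise")
    res = rdf(frames, "solvent", "solvent", dr=0.01)
    assert res.first_maximum == pytest.approx(0.28, abs=0.03)
    assert 0.28 < res.first_minimum < 0.457


def test_rdf_validation(lattice_frame):
    with pytest.raises(ValueError, match="no frames"):
        rdf([], "solvent")
    with pytest.raises(ValueError, match="half the smallest box"):
        rdf([lattice_frame], "solvent", r_max=2.0)


def test_ooo_angles_on_perfect_lattice(lattice_frame):
    shells = [shell_membership(lattice_frame, "bulge", 0.35)]
    assert shells[0].n_waters > 0
    stats = ooo_angle_distribution([lattice_frame], shells)
    # every OOO angle of a diamond network is the tetrahedral angle
    peak = stats.theta[np.argmax(stats.density)]
    assert peak == pytest.approx(TETRA_ANGLE, abs=2.0)
    width = stats.density > 0
    assert np.all(np.abs(stats.theta[width] - TETRA_ANGLE) < 3.0)
    # distribution integrates to one
    dtheta = stats.theta[1] - stats.theta[0]
    assert np.sum(stats.density) * dtheta == pytest.approx(1.0)
    assert stats.q_mean == pytest.approx(1.0, abs=1e-9)


def test_shell_average_q_decreases_with_noise():
    qs = []
    for sigma in (2.0, 25.0):
        spec = GeometrySpec(angular_noise=sigma,
                            solute_positions={"bulge": np.array([[1.293] * 3])})
        frames = generate_hydration_frames(spec, 4, seed=3,
                                           mode="lattice+noise")
        shells = [shell_membership(f, "bulge", 0.35) for f in frames]
        qs.append(shell_average_q(frames, shells).q_mean)
    assert qs[0] > 0.9
    assert qs[1] < qs[0] - 0.3


def test_ooo_validation(lattice_frame):
    shells = [shell_membership(lattice_frame, "bulge", 0.35)]
    with pytest.raises(ValueError, match="one shell selection per frame"):
        ooo_angle_distribution([lattice_frame], shells * 2)
    empty = [shell_membership(lattice_frame, "bulge", 0.0)]
    with pytest.raises(ValueError, match="no shell members"):
        ooo_angle_distribution([lattice_frame], empty)
    tiny = MolecularFrame(solvent=np.random.default_rng(0).uniform(0, 1, (3, 3)),
                          box=np.array([1.0, 1.0, 1.0]))
    from flipkin import ShellSelection
    with pytest.raises(ValueError, match="need at least"):
        ooo_angle_distribution([tiny], [ShellSelection(0.3, [0], 1)])


def test_shell_occupancy_statistics():
    box = np.array([3.0, 3.0, 3.0])
    frames = []
    for n in (2, 3, 3, 4):
        solv = 1.5 + 0.05 * np.arange(n)[:, None] * np.ones(3)
        frames.append(MolecularFrame(solvent=solv, box=box,
                                     solute={"bulge": np.array([[1.5] * 3])}))
    occ = shell_occupancy(frames, "bulge", 0.4)
    assert np.array_equal(occ.counts_per_frame, [2, 3, 3, 4])
    assert occ.mean == pytest.approx(3.0)
    assert occ.probability.sum() == pytest.approx(1.0)
    assert occ.probability[3] == pytest.approx(0.5)
    assert occ.sem == pytest.approx(np.std([2, 3, 3, 4], ddof=1) / 2.0)
    with pytest.raises(ValueError, match="no frames"):
        shell_occupancy([], "bulge", 0.4)
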