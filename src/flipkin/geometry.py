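"""Synthetic solvent-oxygen configurations with controlled structure.

Stands in for MD snapshots when exercising the hydration-shell analysis:
a diamond-cubic "water network" whose four-coordinated sites subtend the
tetrahedral angle exactly (mode ``lattice+noise``, with Gaussian positional
jitter parameterised by an angular noise scale), uniform Poisson placement
(mode ``ideal_gas``) whose shell occupancies are exactly Poisson, and a
pass-through ``fixture`` mode for hand-built coordinates.  All generators
are pure functions of (spec, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .hydration import MolecularFrame

__all__ = ["GeometrySpec", "generate_hydration_frames", "diamond_lattice"]

# O-O nearest-neighbor distance of water-like networks, nm; sets the
# default diamond-lattice constant a0 = 4 r_nn / sqrt(3)
R_NN = 0.28
A0 = 4.0 * R_NN / np.sqrt(3.0)
HARD_SPHERE = 0.15  # nm; closer approaches are rejected in lattice mode


@dataclass
class GeometrySpec:
    """Parameters of the synthetic solvent generators.

    box : orthorhombic box lengths (nm).  In lattice mode each length is
        divided into an integer number of unit cells near the water-like
        lattice constant, so the network is periodic.
    angular_noise : sigma in degrees; atoms are displaced by an isotropic
        Gaussian of standard deviation r_nn * sigma (radians), the arc
        length a neighbor direction swings through at that angular scale.
    n_solvent : molecule count for ideal_gas mode when ``density`` unset
        (lattice mode derives the count from the box).
    density : nm^-3; in ideal_gas mode each frame draws a Poisson count at
        this density, so shell occupancies are exactly Poisson.
    solute_positions : role -> (M, 3) positions embedded in every frame.
    """

    box: tuple = (2.586, 2.586, 2.586)
    angular_noise: float = 0.0
    n_solvent: int = 216
    density: float | None = None
    solute_positions: dict = field(default_factory=dict)

    def __post_init__(self):
        self.box = np.asarray(self.box, dtype=float)
        if np.any(self.box <= 0):
            raise ValueError("box lengths must be positive")
        if self.angular_noise < 0:
            raise ValueError("angular_noise must be >= 0")
        if self.density is not None and self.density <= 0:
            raise ValueError("density must be positive when given")


def diamond_lattice(box: np.ndarray) -> np.ndarray:
    """Positions of a diamond-cubic lattice filling ``box`` periodically.

    Every site has four nearest neighbors at the tetrahedral angle.  Cell
    counts round box/A0 per axis; a warning is issued if the implied
    spacings differ across axes (anisotropic strain distorts the angles).
    """
    n_cells = np.maximum(np.round(box / A0).astype(int), 1)
    a = box / n_cells
    if np.max(a) - np.min(a) > 1e-9 * np.max(a):
        warnings.warn("non-cubic cells: lattice angles deviate from 109.47 deg",
                      stacklevel=2)
    basis = np.array([
        [0.0, 0.0, 0.0], [0.0, 0.5, 0.5], [0.5, 0.0, 0.5], [0.5, 0.5, 0.0],
    ])
    basis = np.concatenate([basis, basis + 0.25])
    cells = np.stack(np.meshgrid(*[np.arange(n) for n in n_cells],
                                 indexing="ij"), axis=-1).reshape(-1, 3)
    pos = (cells[:, None, :] + basis[None, :, :]).reshape(-1, 3) * a
    return pos


def generate_hydration_frames(
    spec: GeometrySpec,
    n_frames: int,
    seed: int = 0,
    mode: str = "lattice+noise",
    coords=None,
) -> list[MolecularFrame]:
    """Generate ``n_frames`` solvent snapshots in the requested mode.

    - ``lattice+noise``: diamond network + Gaussian jitter (see
      GeometrySpec.angular_noise); rejects configurations whose nominal
      bond length falls below the hard-sphere tolerance.
    - ``ideal_gas``: uniform placement; Poisson-distributed count at
      ``spec.density`` if set, else exactly ``spec.n_solvent``.
    - ``fixture``: ``coords`` (one (N, 3) array, or a list of one per
      frame) are passed through unchanged.
    """
    rng = np.random.default_rng(seed)
    frames: list[MolecularFrame] = []

    if mode == "lattice+noise":
        base = diamond_lattice(spec.box)
        n_cells = np.maximum(np.round(spec.box / A0).astype(int), 1)
        bond = float(np.min(spec.box / n_cells) * np.sqrt(3.0) / 4.0)
        if bond < HARD_SPHERE:
            raise ValueError(
                f"lattice bond length {bond:.3f} nm below hard-sphere "
                f"tolerance {HARD_SPHERE} nm: box too dense"
            )
        sigma_disp = bond * np.radians(spec.angular_noise)
        for _ in range(n_frames):
            jitter = (sigma_disp * rng.standard_normal(base.shape)
                      if sigma_disp > 0 else 0.0)
            frames.append(MolecularFrame(solvent=base + jitter, box=spec.box,
                                         solute=dict(spec.solute_positions)))
    elif mode == "ideal_gas":
        vol = float(np.prod(spec.box))
        for _ in range(n_frames):
            n = (rng.poisson(spec.density * vol) if spec.density is not None
                 else spec.n_solvent)
            pts = rng.uniform(0.0, 1.0, size=(n, 3)) * spec.box
            frames.append(MolecularFrame(solvent=pts, box=spec.box,
                                         solute=dict(spec.solute_positions)))
    elif mode == "fixture":
        if coords is None:
            raise ValueError("fixture mode requires explicit coordinates")
        if isinstance(coords, np.ndarray) and coords.ndim == 2:
            coords = [coords] * n_frames
        if len(coords) != n_frames:
            raise ValueError("need one coordinate set per frame")
        for c in coords:
            frames.append(MolecularFrame(solvent=np.asarray(c, dtype=float),
                                         box=spec.box,
                                         solute=dict(spec.solute_positions)))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return frames
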