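"""Parametric free-energy profiles for a periodic torsional reaction coordinate.

The torsion angle psi monitors looping-out of an RNA bulge base from the
local helical plane.  Its free-energy landscape at ambient pressure has a
deep minimum at the stacked conformation, a shallower secondary minimum
attributed to transient base-triplet hydrogen bonding, and a barrier on the
path to the fully looped-out state.  Increasing pressure raises the
looping-out barrier and fills in the base-triplet minimum until it
disappears.  ``ProfileSpec``/``make_pmf`` encode that phenomenology as a
smooth periodic function (sum of von-Mises-shaped wells and a barrier hump)
with an analytic derivative, controlled by a single dimensionless
``pressure_knob`` in [0, 1].

Angles are degrees everywhere in the public API; energies default to kT.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = ["FreeEnergyProfile", "ProfileSpec", "make_pmf", "wrap_angle"]

DEG = np.pi / 180.0


def wrap_angle(psi):
    """Wrap angle(s) in degrees into the periodic domain [-180, 180)."""
    return (np.asarray(psi, dtype=float) + 180.0) % 360.0 - 180.0


def _width_to_kappa(width_deg: float) -> float:
    # exp(kappa*(cos d - 1)) ~ exp(-d^2 / (2 width^2)) for small d (radians)
    return (180.0 / (np.pi * width_deg)) ** 2


@dataclass
class FreeEnergyProfile:
    """Tabulated free energy F(psi) on a periodic angular grid.

    Parameters
    ----------
    grid : strictly increasing bin-center angles in degrees, inside
        [-180, 180).
    values : free energy at the grid points, in `unit`.  The minimum over
        unmasked grid points is zero by convention.
    unit : "kT" or "kcal/mol".
    kT : thermal energy expressed in `unit` (1.0 for kT units,
        ~0.596 kcal/mol at 300 K).
    mask : boolean array, True where F is defined.  Bins never visited by
        any sampling window stay masked and are not imputed.
    energy_fn, force_fn : optional analytic callables (degrees ->
        energy, energy/deg).  Present for synthetic profiles; when absent,
        interpolation falls back to a periodic spline.
    """

    grid: np.ndarray
    values: np.ndarray
    unit: str = "kT"
    kT: float = 1.0
    temperature: float = 300.0
    mask: np.ndarray | None = None
    energy_fn: Callable | None = field(default=None, repr=False, compare=False)
    force_fn: Callable | None = field(default=None, repr=False, compare=False)
    # (centers, amplitudes, kappas) of the von-Mises terms for analytic
    # profiles; lets integrators use a compiled force kernel
    analytic_terms: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.shape != self.values.shape:
            raise ValueError("grid and values must have the same shape")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def defined(self) -> np.ndarray:
        """Boolean array: True where F is defined."""
        if self.mask is None:
            return np.ones_like(self.grid, dtype=bool)
        return self.mask

    def energy(self, psi):
        """F at angle(s) psi (degrees), analytic if available else
        periodic linear interpolation on the grid."""
        if self.energy_fn is not None:
            return self.energy_fn(psi)
        return self._interp(psi)

    def force(self, psi):
        """dF/dpsi (energy per degree)."""
        if self.force_fn is not None:
            return self.force_fn(psi)
        # centered finite difference on the periodic interpolant
        h = 1e-3
        return (self._interp(np.asarray(psi) + h) - self._interp(np.asarray(psi) - h)) / (2 * h)

    def _interp(self, psi):
        if self.mask is not None and not self.mask.all():
            raise ValueError("cannot interpolate a profile with masked bins")
        psi = wrap_angle(psi)
        # periodic linear interpolation: extend grid by one wrapped point
        gx = np.concatenate([self.grid, [self.grid[0] + 360.0]])
        gy = np.concatenate([self.values, [self.values[0]]])
        shifted = np.where(psi < gx[0], psi + 360.0, psi)
        return np.interp(shifted, gx, gy)

    def to_beta(self) -> np.ndarray:
        """Dimensionless beta*F on the grid."""
        return self.values / self.kT


@dataclass
class ProfileSpec:
    """Specification of a synthetic two-minimum periodic profile.

    minima : sequence of (position_deg, depth_kT).  The first entry is the
        primary (stacked) minimum; any further entries are secondary
        (base-triplet-like) minima whose depth scales with
        ``1 - pressure_knob`` and therefore vanish at knob 1.
    barrier_height : height (kT) of the looping-out barrier at knob 0,
        measured from the bottom of the primary minimum to the top of the
        barrier hump; must exceed the primary depth.  The effective barrier
        grows monotonically with the knob,
        B(p) = B0 * (1 + 0.2 p + 0.8 p^8), mildly up to p ~ 0.8 and then
        sharply — a pressure-like evolution with a jump at the top of the
        range.
    pressure_knob : dimensionless in [0, 1].
    barrier_position : degrees; default 70 deg past the primary minimum,
        i.e. on the looping-out path, away from the secondary minimum.
    """

    minima: Sequence[tuple[float, float]]
    barrier_height: float
    pressure_knob: float = 0.0
    barrier_position: float | None = None
    well_width: float = 20.0
    barrier_width: float = 20.0

    def __post_init__(self):
        if not self.minima:
            raise ValueError("at least one minimum required")
        if not (0.0 <= self.pressure_knob <= 1.0):
            raise ValueError("pressure_knob must lie in [0, 1]")
        if self.barrier_height < 0:
            raise ValueError("barrier_height must be non-negative")
        for _, d in self.minima:
            if d <= 0:
                raise ValueError("well depths must be positive")
        if self.barrier_height <= self.minima[0][1]:
            raise ValueError(
                "barrier_height is measured from the primary minimum and must "
                "exceed the primary well depth"
            )
        if self.barrier_position is None:
            self.barrier_position = wrap_angle(self.minima[0][0] + 70.0).item()

    # -- effective, pressure-dependent parameters ---------------------------

    def effective_barrier(self) -> float:
        p = self.pressure_knob
        return self.barrier_height * (1.0 + 0.2 * p + 0.8 * p ** 8)

    def effective_depths(self) -> list[float]:
        p = self.pressure_knob
        return [d if i == 0 else d * (1.0 - p) for i, (_, d) in enumerate(self.minima)]

    # -- analytic energy and derivative -------------------------------------

    def _terms(self):
        kw = _width_to_kappa(self.well_width)
        kb = _width_to_kappa(self.barrier_width)
        depths = self.effective_depths()
        centers = [m[0] for m in self.minima] + [self.barrier_position]
        amps = [-d for d in depths] + [self.effective_barrier() - depths[0]]
        kappas = [kw] * len(self.minima) + [kb]
        return np.asarray(centers), np.asarray(amps), np.asarray(kappas)

    def energy(self, psi):
        """F(psi) in kT, un-normalized (no min-shift)."""
        c, a, k = self._terms()
        d = (np.asarray(psi, dtype=float)[..., None] - c) * DEG
        return np.sum(a * np.exp(k * (np.cos(d) - 1.0)), axis=-1)

    def force(self, psi):
        """dF/dpsi in kT per degree."""
        c, a, k = self._terms()
        d = (np.asarray(psi, dtype=float)[..., None] - c) * DEG
        return np.sum(-a * k * np.sin(d) * np.exp(k * (np.cos(d) - 1.0)), axis=-1) * DEG


def make_pmf(spec: ProfileSpec, grid_step: float = 1.0) -> FreeEnergyProfile:
    """Tabulate the analytic profile of `spec` on a periodic grid.

    The grid has points at -180 + j*grid_step; grid_step must divide 360
    evenly.  The returned profile is normalized so its minimum over the
    grid is exactly zero, and it carries analytic energy/force callables
    (with the same normalization offset) for use by the Langevin
    integrator.

    Raises
    ------
    ValueError
        if grid_step does not divide 360, or two specified minima are
        closer than grid_step (indistinguishable on the grid).
    """
    n = 360.0 / grid_step
    if abs(n - round(n)) > 1e-9:
        raise ValueError(f"grid_step {grid_step} does not divide 360 evenly")
    n = int(round(n))

    pos = [m[0] for m in spec.minima]
    for i in range(len(pos)):
        for j in range(i + 1, len(pos)):
            sep = abs(wrap_angle(pos[i] - pos[j]))
            if sep < grid_step:
                raise ValueError(
                    f"minima at {pos[i]} and {pos[j]} deg are only {sep:.3g} deg "
                    f"apart, closer than grid_step {grid_step}"
                )

    grid = -180.0 + grid_step * np.arange(n)
    raw = spec.energy(grid)
    offset = raw.min()
    values = raw - offset

    energy_fn = lambda psi, _s=spec, _o=offset: _s.energy(psi) - _o  # noqa: E731
    return FreeEnergyProfile(
        grid=grid,
        values=values,
        unit="kT",
        kT=1.0,
        energy_fn=energy_fn,
        force_fn=spec.force,
        analytic_terms=spec._terms(),
    )
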