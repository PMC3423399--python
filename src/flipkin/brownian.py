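"""Overdamped Langevin dynamics of the torsional reaction coordinate.

In the high-friction limit the angle psi diffuses on the free-energy
surface F(psi):

    dpsi/dt = -(D/kT) dF/dpsi + sqrt(2 D) eta(t),   <eta(t) eta(t')> = delta

integrated here with the Euler--Maruyama scheme.  The module provides the
raw simulator, a chained umbrella-window generator (each window restrained
by a harmonic bias and started from the end state of its predecessor, as
in a sequential sampling protocol), and a brute-force first-passage-time
ensemble that serves as the stochastic oracle for the Smoluchowski MFPT
quadrature.

Units: angles in degrees, D in deg^2/time, energies in kT by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .profiles import FreeEnergyProfile, wrap_angle
from .wham import UmbrellaWindow

__all__ = ["LangevinModel", "FptSamples", "simulate_langevin",
           "generate_umbrella_dataset", "simulate_fpt"]

try:  # optional compiled kernel for long single-walker runs
    import numba as _numba
except ImportError:  # pragma: no cover - numba is normally present
    _numba = None

if _numba is not None:
    @_numba.njit(cache=False)
    def _vm_walk(x0, n_steps, record_every, coef, noise,
                 centers, amps, kappas, bias_c, bias_k, out):
        deg = np.pi / 180.0
        x = x0
        r = 0
        for i in range(n_steps):
            f = 0.0
            for t in range(centers.shape[0]):
                d = (x - centers[t]) * deg
                f += -amps[t] * kappas[t] * np.sin(d) * np.exp(
                    kappas[t] * (np.cos(d) - 1.0))
            f *= deg
            if bias_k > 0.0:
                db = x - bias_c
                db = (db + 180.0) % 360.0 - 180.0
                f += bias_k * db
            x = x - coef * f + noise[i]
            if (i + 1) % record_every == 0:
                out[r] = (x + 180.0) % 360.0 - 180.0
                r += 1
        return x


@dataclass
class LangevinModel:
    """Integrator parameters for overdamped dynamics of the angle.

    diffusion_constant : D in deg^2 per unit time.
    kT : thermal energy, same units as the profile (1.0 for kT units).
    dt : time step; default chosen so the per-step noise sqrt(2 D dt)
        is 2 deg at D = 1.
    record_every : store every k-th step.
    """

    diffusion_constant: float = 1.0
    kT: float = 1.0
    dt: float = 2.0
    n_steps: int = 50_000
    record_every: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.diffusion_constant < 0:
            raise ValueError("diffusion_constant must be >= 0")
        if self.kT <= 0 or self.dt <= 0:
            raise ValueError("kT and dt must be positive")
        if self.n_steps < 0 or self.record_every < 1:
            raise ValueError("n_steps >= 0 and record_every >= 1 required")


@dataclass
class FptSamples:
    """First-passage-time ensemble from direct simulation."""

    times: np.ndarray
    n_censored: int
    dt: float

    @property
    def mean(self) -> float:
        return float(np.mean(self.times)) if self.times.size else np.nan

    @property
    def sem(self) -> float:
        if self.times.size < 2:
            return np.nan
        return float(np.std(self.times, ddof=1) / np.sqrt(self.times.size))

    @property
    def censored(self) -> bool:
        return self.n_censored > 0


def _total_force(profile, bias, x):
    """dF_total/dpsi at (possibly wrapped) angle x, in energy/deg."""
    f = profile.force(wrap_angle(x))
    if bias is not None:
        c, k = bias
        f = f + k * wrap_angle(x - c)
    return f


def simulate_langevin(
    profile: FreeEnergyProfile,
    model: LangevinModel,
    x0: float,
    bias: tuple[float, float] | None = None,
    n_walkers: int = 1,
    wrap: bool = True,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Euler--Maruyama trajectory of the angle on ``profile`` (+ optional
    harmonic bias ``(center, force_constant)``).

    Returns the recorded angles: shape (n_records,) for a single walker,
    (n_records, n_walkers) otherwise.  ``wrap=False`` returns the
    unwrapped coordinate (useful for mean-squared-displacement checks);
    forces are always evaluated on the wrapped angle, as the profile is
    periodic.

    A warning is emitted if the deterministic drift can exceed 5 deg per
    step anywhere on the profile; non-finite forces abort with the
    offending location.
    """
    D, kT, dt = model.diffusion_constant, model.kT, model.dt
    # drift-magnitude pre-check on a coarse scan of the landscape; the bias
    # is checked separately via the overdamped stability bound (its large
    # restoring force far from the center is never actually visited)
    scan = np.linspace(-180.0, 180.0, 721)
    fmax = np.max(np.abs(profile.force(scan)))
    if D * fmax * dt / kT > 5.0:
        warnings.warn(
            f"per-step drift can reach {D * fmax * dt / kT:.1f} deg (> 5); "
            "reduce dt for a faithful integration",
            stacklevel=2,
        )
    if bias is not None and D * dt * bias[1] / kT > 1.0:
        warnings.warn(
            "harmonic bias is stiff for this time step (D*dt*k/kT > 1); "
            "reduce dt or the force constant",
            stacklevel=2,
        )
    if rng is None:
        rng = np.random.default_rng(model.seed)

    amp_ = np.sqrt(2.0 * D * dt)
    if (
        _numba is not None
        and n_walkers == 1
        and wrap
        and profile.analytic_terms is not None
        and amp_ > 0
    ):
        centers, amps, kappas = (np.asarray(t, dtype=float)
                                 for t in profile.analytic_terms)
        noise = amp_ * rng.standard_normal(model.n_steps)
        out = np.empty(model.n_steps // model.record_every)
        bc, bk = (float(bias[0]), float(bias[1])) if bias else (0.0, 0.0)
        _vm_walk(float(x0), model.n_steps, model.record_every,
                 D * dt / kT, noise, centers, amps, kappas, bc, bk, out)
        return out

    x = np.full(n_walkers, float(x0))
    n_rec = model.n_steps // model.record_every
    out = np.empty((n_rec, n_walkers))
    amp = np.sqrt(2.0 * D * dt)
    coef = D * dt / kT
    r = 0
    for step in range(1, model.n_steps + 1):
        force = _total_force(profile, bias, x)
        if not np.all(np.isfinite(force)):
            bad = x[~np.isfinite(force)][0]
            raise FloatingPointError(f"non-finite force at psi = {bad:.3f} deg")
        x = x - coef * force
        if amp > 0:
            x = x + amp * rng.standard_normal(n_walkers)
        if step % model.record_every == 0:
            out[r] = wrap_angle(x) if wrap else x
            r += 1
    return out[:, 0] if n_walkers == 1 else out


def generate_umbrella_dataset(
    profile: FreeEnergyProfile,
    window_centers,
    force_constant: float,
    n_samples: int,
    equilibration_discard: int,
    model: LangevinModel,
) -> list[UmbrellaWindow]:
    """Chained umbrella windows on ``profile``.

    Each window i is restrained by w_i = 1/2 k (psi - psi_i)^2, run for
    (equilibration_discard + n_samples) * record_every steps, the first
    ``equilibration_discard`` recorded samples dropped.  Window i+1 starts
    from the final state of window i; window 0 starts at its bias center.
    Each window draws noise from a generator seeded by (model.seed, i), so
    the dataset is a pure function of (inputs, seed).

    Warns when neighbor spacing exceeds 3 sigma of the stiff-bias
    distribution sqrt(kT/k), the usual overlap rule of thumb.
    """
    centers = np.asarray(window_centers, dtype=float)
    if centers.size == 0:
        raise ValueError("window_centers is empty")
    if np.any(np.diff(centers) <= 0):
        raise ValueError("window_centers must be sorted and strictly increasing")
    if n_samples <= 0:
        raise ValueError("n_samples per window must be positive after the discard")
    if force_constant > 0:
        sigma = np.sqrt(model.kT / force_constant)
        if np.any(np.diff(centers) > 3.0 * sigma):
            warnings.warn(
                "window spacing exceeds 3*sqrt(kT/k): histograms may not overlap",
                stacklevel=2,
            )

    steps = (equilibration_discard + n_samples) * model.record_every
    win_model = LangevinModel(
        diffusion_constant=model.diffusion_constant,
        kT=model.kT,
        dt=model.dt,
        n_steps=steps,
        record_every=model.record_every,
        seed=model.seed,
    )
    windows: list[UmbrellaWindow] = []
    x0 = float(centers[0])
    for i, c in enumerate(centers):
        rng = np.random.default_rng([model.seed, i])
        traj = simulate_langevin(
            profile, win_model, x0, bias=(float(c), force_constant), rng=rng
        )
        x0 = float(traj[-1])
        windows.append(
            UmbrellaWindow(
                window_id=f"w{i:03d}",
                bias_center=float(c),
                force_constant=force_constant,
                samples=traj[equilibration_discard:],
                sampling_interval=model.dt * model.record_every,
            )
        )
    return windows


def simulate_fpt(
    profile: FreeEnergyProfile,
    model: LangevinModel,
    x0: float,
    reflecting: float,
    absorbing: float,
    n_trials: int,
    max_steps: int = 2_000_000,
) -> FptSamples:
    """Direct first-passage ensemble: walkers start at x0, reflect at
    ``reflecting`` and are absorbed at ``absorbing``.

    The interval is treated as a bounded, non-periodic segment.  Walkers
    still in flight after ``max_steps`` are counted as censored and
    excluded from the mean (the result's ``censored`` flag is then set).
    All in-flight positions stay inside [reflecting, absorbing].
    """
    a, b = float(reflecting), float(absorbing)
    mirrored = b < a
    if mirrored:
        # map x -> -x: reflecting at -a < absorbing at -b becomes standard
        return _simulate_fpt_std(_Mirrored(profile), model, -x0, -a, -b,
                                 n_trials, max_steps)
    return _simulate_fpt_std(profile, model, x0, a, b, n_trials, max_steps)


class _Mirrored:
    """View of a profile under psi -> -psi (forces flip sign)."""

    def __init__(self, profile):
        self._p = profile

    def force(self, x):
        return -self._p.force(-np.asarray(x))

    def energy(self, x):
        return self._p.energy(-np.asarray(x))


def _simulate_fpt_std(profile, model, x0, a, b, n_trials, max_steps):
    if not (a <= x0 <= b):
        raise ValueError("require reflecting <= x0 <= absorbing (or mirrored)")
    if x0 == b:
        return FptSamples(times=np.zeros(n_trials), n_censored=0, dt=model.dt)

    D, kT, dt = model.diffusion_constant, model.kT, model.dt
    rng = np.random.default_rng(model.seed)
    amp = np.sqrt(2.0 * D * dt)
    coef = D * dt / kT

    pos = np.full(n_trials, float(x0))
    alive = np.arange(n_trials)
    times = np.full(n_trials, np.nan)
    for step in range(1, max_steps + 1):
        force = profile.force(pos)
        if not np.all(np.isfinite(force)):
            bad = pos[~np.isfinite(force)][0]
            raise FloatingPointError(f"non-finite force at psi = {bad:.3f} deg")
        pos = pos - coef * force + amp * rng.standard_normal(pos.size)
        # reflecting wall at a (steps are small; one fold suffices, then clamp)
        below = pos < a
        if below.any():
            pos[below] = 2.0 * a - pos[below]
            np.clip(pos, a, None, out=pos)
        hit = pos >= b
        if hit.any():
            times[alive[hit]] = step * dt
            keep = ~hit
            pos, alive = pos[keep], alive[keep]
            if pos.size == 0:
                break
        np.clip(pos, a, b, out=pos)
    n_censored = pos.size
    if n_censored:
        warnings.warn(
            f"{n_censored}/{n_trials} trials not absorbed within {max_steps} "
            "steps; mean is censored",
            stacklevel=2,
        )
    return FptSamples(times=times[np.isfinite(times)], n_censored=n_censored, dt=dt)
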