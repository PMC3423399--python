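"""Mean first-passage time and effective rate on a 1D free-energy surface.

For overdamped diffusion of the angle psi on F(psi) (Smoluchowski picture),
the mean time to first reach an absorbing boundary b starting from x0, with
a reflecting boundary a, is the classical double integral

    tau(x0 -> b) = (1/D) int_{x0}^{b} dy e^{beta F(y)}
                              int_{a}^{y} dz e^{-beta F(z)}

and the effective flipping rate is k_eff = 1/tau.  The quadrature runs in
log space (cumulative log-sum-exp over trapezoid segments), so barriers of
tens of kT — the high-pressure regime — never overflow.  The interval
[a, b] is treated as bounded and non-periodic: the reflecting wall breaks
the periodicity of psi.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .profiles import FreeEnergyProfile
from .wham import profile_features

__all__ = ["FptProblem", "FptResult", "KramersEstimate", "mfpt",
           "select_boundaries", "pressure_series_mfpt", "kramers_estimate"]

_LOG_GUARD = 700.0  # exp argument beyond which plain-space math would overflow


@dataclass
class FptProblem:
    """A first-passage setup: profile, diffusion constant and boundaries.

    ``reflecting`` and ``absorbing`` must bracket ``start`` on a
    non-periodic interval; the profile must be defined (unmasked)
    throughout it.
    """

    profile: FreeEnergyProfile
    diffusion_constant: float
    start: float
    reflecting: float
    absorbing: float
    kT: float = 1.0

    def __post_init__(self):
        if self.diffusion_constant <= 0:
            raise ValueError("diffusion_constant must be positive")
        a, x0, b = self.reflecting, self.start, self.absorbing
        if not (min(a, b) <= x0 <= max(a, b)):
            raise ValueError("start must lie between the boundaries")
        if not (min(a, b) < max(a, b)):
            raise ValueError("boundaries must be distinct")


@dataclass
class FptResult:
    mfpt: float
    effective_rate: float
    quadrature_error: float   # relative change at the final grid refinement
    n_grid: int


def _energy_at(profile: FreeEnergyProfile, x: np.ndarray, lo: float, hi: float):
    """Profile energy at x, honouring masks: every tabulated bin whose
    center falls inside [lo, hi] must be defined."""
    defined = profile.defined
    inside = (profile.grid >= lo) & (profile.grid <= hi)
    if np.any(inside & ~defined):
        raise ValueError(
            "profile has masked (undefined) bins inside the passage interval"
        )
    if profile.energy_fn is not None:
        return profile.energy_fn(x)
    return np.interp(x, profile.grid[defined], profile.values[defined])


def _tau_on_grid(bF: np.ndarray, z: np.ndarray, i0: int, D: float) -> float:
    """Log-space trapezoid evaluation of the double integral.

    bF: beta*F on the grid z (z[0] = a, z[-1] = b), i0: index of x0.
    """
    if np.max(bF) - np.min(bF) > 2 * _LOG_GUARD:
        raise FloatingPointError("beta*F range exceeds the overflow guard")
    logdz = np.log(np.diff(z))
    # inner integral I(y) = int_a^y e^{-bF}, cumulative over segments
    seg_in = np.logaddexp(-bF[:-1], -bF[1:]) + logdz + np.log(0.5)
    logI = np.logaddexp.accumulate(seg_in)          # I at z[1:]
    # outer integrand e^{+bF(y)} I(y), defined at z[1:]; I(a) = 0
    logo = bF[1:] + logI
    # trapezoid over y from x0 to b; at y = z[i0] with i0 = 0 the integrand is 0
    if i0 == 0:
        lo_vals = np.concatenate([[-np.inf], logo])
        yy = z
    else:
        lo_vals = logo[i0 - 1:]
        yy = z[i0:]
    seg_out = np.logaddexp(lo_vals[:-1], lo_vals[1:]) + np.log(0.5 * np.diff(yy))
    from scipy.special import logsumexp
    log_tau = logsumexp(seg_out) - np.log(D)
    return float(np.exp(log_tau))


def mfpt(problem: FptProblem, rtol: float = 1e-3, n_start: int = 513,
         max_refine: int = 12) -> FptResult:
    """Evaluate the Smoluchowski MFPT double integral for ``problem``.

    The grid over [a, b] (with x0 as a grid point) is refined by doubling
    until tau changes by less than ``rtol`` relative; the last relative
    change is reported as the discretization-error estimate.
    """
    a, b, x0 = problem.reflecting, problem.absorbing, problem.start
    mirrored = b < a
    if mirrored:
        # map psi -> -psi to the standard orientation
        a, b, x0 = -a, -b, -x0
    if x0 == b:
        return FptResult(mfpt=0.0, effective_rate=np.inf,
                         quadrature_error=0.0, n_grid=0)

    D, kT = problem.diffusion_constant, problem.kT
    lo, hi = (min(-b, -a), max(-b, -a)) if mirrored else (a, b)

    def beta_F(x):
        xq = -x if mirrored else x
        return _energy_at(problem.profile, xq, lo, hi) / kT

    n = n_start
    tau_prev = None
    err = np.inf
    for _ in range(max_refine):
        frac = (x0 - a) / (b - a)
        n_lo = max(int(round(frac * n)), 1) if x0 > a else 0
        z = np.concatenate([
            np.linspace(a, x0, n_lo + 1)[:-1] if n_lo else [],
            np.linspace(x0, b, n - n_lo),
        ])
        i0 = n_lo
        tau = _tau_on_grid(beta_F(z), z, i0, D)
        if tau_prev is not None:
            err = abs(tau - tau_prev) / tau if tau > 0 else 0.0
            if err < rtol:
                tau_prev = tau
                break
        tau_prev = tau
        n = 2 * n - 1
    else:
        warnings.warn(
            f"MFPT quadrature not converged to rtol={rtol} "
            f"(last change {err:.2e})", stacklevel=2,
        )
        tau = tau_prev
    return FptResult(mfpt=tau, effective_rate=1.0 / tau,
                     quadrature_error=err if np.isfinite(err) else 0.0, n_grid=n)


def select_boundaries(
    profile: FreeEnergyProfile,
    flip_target: float = 120.0,
    reflect_offset: float = 3.0,
    diffusion_constant: float = 1.0,
    kT: float = 1.0,
    min_prominence: float = 0.0,
) -> FptProblem:
    """Choose (x0, a, b) for the looping-out passage on ``profile``.

    x0 is the position of the deepest minimum (leftmost on an exact tie,
    with a warning); b is the user-supplied looped-out target angle; the
    reflecting boundary a is the first grid point beyond x0, on the side
    away from b, where F rises to F(x0) + reflect_offset — or the domain
    edge on that side if it never does.
    """
    feats = profile_features(profile, min_prominence=min_prominence)
    if not feats.minima:
        raise ValueError("profile has no local minimum")
    depth = min(v for _, v in feats.minima)
    deepest = [p for p, v in feats.minima if v == depth]
    if len(deepest) > 1:
        warnings.warn("two equal-depth minima; choosing the leftmost",
                      stacklevel=2)
    x0 = min(deepest)
    b = float(flip_target)
    if b == x0:
        raise ValueError("flip_target coincides with the starting minimum")

    grid, vals, defined = profile.grid, profile.values, profile.defined
    F0 = float(profile.values[np.argmin(np.abs(grid - x0))])
    thresh = F0 + reflect_offset
    if b > x0:   # scan left of x0 for the reflecting wall
        sel = np.where((grid <= x0) & defined)[0][::-1]
        edge = grid[defined].min()
    else:        # mirrored geometry: scan right
        sel = np.where((grid >= x0) & defined)[0]
        edge = grid[defined].max()
    a = float(edge)
    for j in sel:
        if vals[j] >= thresh:
            a = float(grid[j])
            break
    if min(a, x0) <= b <= max(a, x0):
        raise ValueError("flip_target lies inside the well region [a, x0]")
    return FptProblem(profile=profile, diffusion_constant=diffusion_constant,
                      start=float(x0), reflecting=a, absorbing=b, kT=kT)


def pressure_series_mfpt(
    labeled_profiles,
    diffusion_constant: float = 1.0,
    flip_target: float = 120.0,
    reflect_offset: float = 3.0,
    kT: float = 1.0,
    min_prominence: float = 0.0,
) -> pd.DataFrame:
    """MFPT and effective rate for an ordered series of profiles.

    ``labeled_profiles``: iterable of (label, FreeEnergyProfile), e.g. one
    reconstructed PMF per pressure.  All rows share the diffusion constant
    and the boundary-selection rules, mirroring a pressure-series study.
    """
    rows = []
    for label, prof in labeled_profiles:
        prob = select_boundaries(prof, flip_target, reflect_offset,
                                 diffusion_constant, kT, min_prominence)
        res = mfpt(prob)
        rows.append({
            "label": label, "x0": prob.start, "reflecting": prob.reflecting,
            "absorbing": prob.absorbing, "tau": res.mfpt,
            "k_eff": res.effective_rate,
        })
    return pd.DataFrame(rows)


@dataclass
class KramersEstimate:
    rate: float
    barrier_height: float
    well_curvature: float
    barrier_curvature: float
    low_barrier: bool   # True when beta*dF < 2: harmonic approximation dubious


def kramers_estimate(
    profile: FreeEnergyProfile,
    diffusion_constant: float,
    x0: float,
    barrier_position: float,
    kT: float = 1.0,
) -> KramersEstimate:
    """High-barrier harmonic (Kramers) escape-rate approximation.

    k ~ (D / 2 pi kT) sqrt(F''(x0) |F''(x_b)|) exp(-dF/kT), with
    curvatures from a 3-point finite difference at the well bottom and
    barrier top.  Intended as an independent sanity check on the full
    MFPT quadrature, valid only for beta*dF >> 1.
    """
    h = max(float(np.min(np.diff(profile.grid))), 0.5)

    def curv(x):
        f = profile.energy(np.array([x - h, x, x + h]))
        return (f[0] - 2 * f[1] + f[2]) / h**2

    cw = float(curv(x0))
    cb = float(curv(barrier_position))
    if cw <= 0:
        raise ValueError(f"non-positive curvature {cw:.3g} at the well ({x0} deg)")
    if cb >= 0:
        raise ValueError(
            f"non-negative curvature {cb:.3g} at the barrier ({barrier_position} deg)"
        )
    dF = float(profile.energy(barrier_position) - profile.energy(x0))
    rate = (diffusion_constant / (2 * np.pi * kT)) * np.sqrt(cw * abs(cb)) \
        * np.exp(-dF / kT)
    return KramersEstimate(rate=float(rate), barrier_height=dF,
                           well_curvature=cw, barrier_curvature=cb,
                           low_barrier=dF / kT < 2.0)
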