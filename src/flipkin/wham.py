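"""Weighted histogram analysis method (WHAM) for periodic umbrella sampling.

Biased windows sample a torsional reaction coordinate under harmonic
restraints w_i(psi) = 1/2 k (psi - psi_i)^2.  The unbiased probability is
recovered by self-consistent iteration of

    P(psi_j)      = sum_i n_ij / sum_i N_i exp[-(w_i(psi_j) - f_i)/kT]
    exp(-f_i/kT)  = sum_j P(psi_j) exp(-w_i(psi_j)/kT) dpsi

until the per-window free-energy constants f_i stabilise.  The potential of
mean force follows as F = -kT ln P, shifted to zero at its minimum.

The bias is evaluated at bin centers and, by default, on the minimum-image
angular difference, so windows near +/-180 deg behave correctly; a
non-periodic mode is available for truncated-interval analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .profiles import FreeEnergyProfile, wrap_angle

__all__ = [
    "UmbrellaWindow",
    "WindowHistogramSet",
    "WhamSolution",
    "ProfileFeatures",
    "bin_windows",
    "wham_solve",
    "pmf_from_probability",
    "profile_features",
]


@dataclass
class UmbrellaWindow:
    """One umbrella window: harmonic bias plus the sampled angle series."""

    window_id: str
    bias_center: float          # degrees
    force_constant: float       # energy per deg^2 (same units as kT used later)
    samples: np.ndarray         # degrees, wrapped to [-180, 180)
    sampling_interval: float = 1.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.force_constant < 0:
            raise ValueError("force_constant must be >= 0")
        if self.samples.size and (
            self.samples.min() < -180.0 or self.samples.max() >= 180.0
        ):
            self.samples = wrap_angle(self.samples)

    def bias_energy(self, psi, periodic: bool = True):
        d = np.asarray(psi, dtype=float) - self.bias_center
        if periodic:
            d = wrap_angle(d)
        return 0.5 * self.force_constant * d * d


@dataclass
class WindowHistogramSet:
    """Per-window histograms n_ij on a shared periodic binning."""

    bin_edges: np.ndarray       # length n_bins + 1, spanning [-180, 180]
    counts: np.ndarray          # (n_windows, n_bins) integer matrix
    totals: np.ndarray          # per-window sample counts N_i

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


@dataclass
class WhamSolution:
    """Self-consistent WHAM output: unbiased P(psi) and window constants f_i."""

    bin_centers: np.ndarray
    bin_width: float
    probability: np.ndarray         # density; sum(P * dpsi) = 1 over unmasked
    window_free_energies: np.ndarray  # f_i, gauge f_1 = 0
    kT: float
    iterations: int
    final_delta_f: float
    converged: bool
    empty_bins: np.ndarray          # True where no window contributed counts


def bin_windows(windows: list[UmbrellaWindow], bin_width: float) -> WindowHistogramSet:
    """Histogram every window's samples on a shared periodic binning.

    bin_width must divide 360 evenly.  Samples are wrapped first, so an
    angle recorded at +180 deg lands in the same bin as one at -180 deg.
    """
    nb = 360.0 / bin_width
    if abs(nb - round(nb)) > 1e-9:
        raise ValueError(f"bin_width {bin_width} does not divide 360 evenly")
    nb = int(round(nb))
    if not windows:
        raise ValueError("no umbrella windows given")

    edges = -180.0 + bin_width * np.arange(nb + 1)
    counts = np.empty((len(windows), nb), dtype=np.int64)
    for i, w in enumerate(windows):
        if w.samples.size == 0:
            raise ValueError(f"window {w.window_id!r} has zero samples")
        h, _ = np.histogram(wrap_angle(w.samples), bins=edges)
        counts[i] = h
    totals = counts.sum(axis=1)
    return WindowHistogramSet(bin_edges=edges, counts=counts, totals=totals)


def wham_solve(
    histograms: WindowHistogramSet,
    windows: list[UmbrellaWindow],
    kT: float = 1.0,
    tol: float = 1e-8,
    max_iter: int = 100_000,
    periodic: bool = True,
    debug: bool = False,
) -> WhamSolution:
    """Iterate the WHAM equations to self-consistency.

    Biases are evaluated at bin centers; with ``periodic=True`` (default)
    the harmonic bias acts on the minimum-image angular difference.
    Convergence is declared when max_i |delta f_i| < tol (in energy units);
    a non-converged run is returned with ``converged=False`` rather than
    raised, so diagnostics stay available.
    """
    if len(windows) != histograms.counts.shape[0]:
        raise ValueError("window list does not match histogram set")
    centers = histograms.bin_centers
    dpsi = histograms.bin_width
    n = histograms.counts
    N = histograms.totals.astype(float)

    n_j = n.sum(axis=0).astype(float)
    empty = n_j == 0
    interior_gap = empty & np.roll(~empty, 1) & np.roll(~empty, -1)
    if interior_gap.any():
        warnings.warn(
            f"{interior_gap.sum()} empty bin(s) flanked by occupied bins: "
            "window overlap may be insufficient",
            stacklevel=2,
        )

    # c_ij = exp(-w_i(psi_j)/kT); underflow to 0 for far-away bins is benign
    with np.errstate(under="ignore"):
        w = np.stack([win.bias_energy(centers, periodic=periodic) for win in windows])
        c = np.exp(-w / kT)

    f = np.zeros(len(windows))
    P = np.zeros_like(n_j)
    occ = ~empty
    delta = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        with np.errstate(under="ignore", over="ignore"):
            g = np.exp(f / kT)                      # e^{f_i/kT}
            denom = (N * g) @ c                     # sum_i N_i e^{f_i/kT} c_ij
        P[:] = 0.0
        P[occ] = n_j[occ] / denom[occ]
        norm = np.sum(P * dpsi)
        if not np.isfinite(norm) or norm <= 0:
            raise RuntimeError(f"WHAM iteration {it} produced a non-finite distribution")
        P /= norm
        if debug:
            assert abs(np.sum(P * dpsi) - 1.0) < 1e-12
        with np.errstate(divide="ignore"):
            f_new = -kT * np.log(c @ (P * dpsi))
        if not np.all(np.isfinite(f_new)):
            raise RuntimeError(f"NaN/inf in window free energies at iteration {it}")
        f_new -= f_new[0]                           # gauge: f_1 = 0
        delta = float(np.max(np.abs(f_new - f)))
        f = f_new
        if delta < tol:
            break
    converged = delta < tol

    return WhamSolution(
        bin_centers=centers,
        bin_width=dpsi,
        probability=P,
        window_free_energies=f,
        kT=kT,
        iterations=it,
        final_delta_f=delta,
        converged=converged,
        empty_bins=empty,
    )


def pmf_from_probability(solution: WhamSolution) -> FreeEnergyProfile:
    """F(psi) = -kT ln P(psi), shifted so the minimum over defined bins is 0.

    Bins with zero probability are masked, never imputed.
    """
    P = solution.probability
    defined = P > 0
    if not defined.any():
        raise ValueError("all bins empty: no probability to convert")
    F = np.full_like(P, np.nan)
    F[defined] = -solution.kT * np.log(P[defined])
    F[defined] -= F[defined].min()
    return FreeEnergyProfile(
        grid=solution.bin_centers,
        values=np.where(defined, F, 0.0),
        unit="kT" if solution.kT == 1.0 else "energy",
        kT=solution.kT,
        mask=defined,
    )


@dataclass
class ProfileFeatures:
    """Local minima and inter-minimum barriers of a (periodic) profile."""

    minima: list  # of (position_deg, F_value)
    barriers: list = field(default_factory=list)
    # each barrier: (from_position, to_position, height) where height is
    # max F on the arc from->to (rightward, wrapping) minus F at the
    # shallower (higher-F) of the two minima


def _plateau_minima_periodic(v: np.ndarray) -> list[int]:
    """Indices of local minima under a 3-point test with plateau tie-break
    (leftmost index of each minimal run), on a periodic array."""
    n = len(v)
    if np.all(v == v[0]):
        return [0]
    minima = []
    for j in range(n):
        if v[j - 1] == v[j]:
            continue  # not leftmost of its run
        # scan forward past the plateau
        k = (j + 1) % n
        while v[k] == v[j]:
            k = (k + 1) % n
        if v[j - 1] > v[j] and v[k] > v[j]:
            minima.append(j)
    return sorted(minima)


def _plateau_minima_linear(v: np.ndarray) -> list[int]:
    """Interior local minima of a non-periodic segment (endpoints excluded)."""
    n = len(v)
    minima = []
    j = 1
    while j < n - 1:
        if v[j] < v[j - 1]:
            k = j
            while k + 1 < n and v[k + 1] == v[j]:
                k += 1
            if k + 1 < n and v[k + 1] > v[j]:
                minima.append(j)
            j = k + 1
        else:
            j += 1
    return minima


def profile_features(
    profile: FreeEnergyProfile, min_prominence: float = 0.0
) -> ProfileFeatures:
    """Locate local minima and the barriers between consecutive minima.

    Minima are found by a discrete 3-point test; plateaus report their
    leftmost index.  For each pair of consecutive minima (by position,
    wrapping around the periodic domain) the barrier is the maximum of F
    on the connecting rightward arc minus F at the shallower minimum, so
    for a double well both periodic arcs are reported.

    ``min_prominence`` (energy units) iteratively drops the least
    prominent minimum below the threshold — useful on noisy reconstructed
    profiles; the default keeps the bare 3-point rule.  The deepest
    minimum is never dropped.
    """
    defined = profile.defined
    if defined.sum() < 3:
        raise ValueError("need at least 3 unmasked bins")

    if defined.all():
        grid, v = profile.grid, profile.values
        idx = _plateau_minima_periodic(v)
        periodic = True
    else:
        # largest contiguous unmasked run, treated as a linear segment
        n = len(defined)
        ext = np.concatenate([defined, defined])
        best_start, best_len, run = 0, 0, 0
        for j in range(2 * n):
            if ext[j]:
                run += 1
                if run > best_len:
                    best_len, best_start = run, j - run + 1
            else:
                run = 0
        best_len = min(best_len, n)
        sel = (best_start + np.arange(best_len)) % n
        grid, v = profile.grid[sel], profile.values[sel]
        idx = _plateau_minima_linear(v)
        periodic = False
        if not idx:
            return ProfileFeatures(minima=[], barriers=[])

    def arc_max(i, j):
        """max of v on the (periodic) rightward arc from index i to j."""
        if periodic:
            if j > i:
                return v[i : j + 1].max()
            return max(v[i:].max(), v[: j + 1].max())
        lo, hi = min(i, j), max(i, j)
        return v[lo : hi + 1].max()

    # prominence filter: drop shallow minima, never the deepest
    idx = list(idx)
    while len(idx) > 1 and min_prominence > 0:
        deepest = min(range(len(idx)), key=lambda a: v[idx[a]])
        worst, worst_prom = None, np.inf
        for a_pos, m in enumerate(idx):
            if a_pos == deepest:
                continue       # the deepest minimum is never dropped
            left = idx[a_pos - 1]
            right = idx[(a_pos + 1) % len(idx)]
            prom = min(arc_max(left, m), arc_max(m, right)) - v[m]
            if prom < worst_prom:
                worst, worst_prom = a_pos, prom
        if worst_prom >= min_prominence:
            break
        idx.pop(worst)

    minima = [(float(grid[m]), float(v[m])) for m in idx]
    barriers = []
    if periodic:
        if len(idx) == 1:
            m = idx[0]
            barriers.append((minima[0][0], minima[0][0], float(v.max() - v[m])))
        else:
            for a_pos in range(len(idx)):
                m, m2 = idx[a_pos], idx[(a_pos + 1) % len(idx)]
                h = arc_max(m, m2) - max(v[m], v[m2])
                barriers.append((float(grid[m]), float(grid[m2]), float(h)))
    else:
        for a_pos in range(len(idx) - 1):
            m, m2 = idx[a_pos], idx[a_pos + 1]
            h = arc_max(m, m2) - max(v[m], v[m2])
            barriers.append((float(grid[m]), float(grid[m2]), float(h)))
        if len(idx) == 1:
            m = idx[0]
            barriers.append((minima[0][0], minima[0][0], float(v.max() - v[m])))
    return ProfileFeatures(minima=minima, barriers=barriers)
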