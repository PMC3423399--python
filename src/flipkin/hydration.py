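"""Hydration-shell structure analysis on solvent-oxygen coordinates.

Implements the water-structure observables used to interrogate how
pressure reorganises the solvation shell around a solute: solute--oxygen
radial distribution functions (whose first minimum defines the shell
cutoff r_c), shell membership and occupancy statistics N_w, the OOO-angle
distribution P(theta) of a central oxygen and its nearest neighbors, and
the tetrahedral order parameter

    q = 1 - (3/8) sum_{i<j} (cos theta_ikj + 1/3)^2

summed over the six pairs among a molecule's four nearest neighbors
(q = 1 for a perfect tetrahedron; isotropic neighbors average to 0).

Solvent is represented by oxygen positions only.  Distances use the
minimum-image convention in an orthorhombic box.  Shell membership only
restricts which central molecules enter an average; neighbor searches
always run over all solvent, since a shell-edge molecule's true nearest
neighbors may sit just outside the shell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MolecularFrame", "ShellSelection", "OrientationalStats", "OccupancyStats",
    "RdfResult", "minimum_image", "rdf", "shell_membership",
    "ooo_angle_distribution", "tetrahedral_q", "shell_average_q",
    "shell_occupancy",
]


def minimum_image(disp: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement vector(s) in an orthorhombic box."""
    return disp - box * np.round(disp / box)


@dataclass
class MolecularFrame:
    """One snapshot: solvent oxygen positions plus labeled solute atoms.

    Positions in nm; ``box`` holds the three orthorhombic box lengths.
    Positions are wrapped into [0, box) on construction.
    """

    solvent: np.ndarray                 # (N, 3)
    box: np.ndarray                     # (3,)
    solute: dict = field(default_factory=dict)   # role -> (M, 3) positions

    def __post_init__(self):
        self.box = np.asarray(self.box, dtype=float)
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive lengths")
        self.solvent = np.mod(np.asarray(self.solvent, dtype=float).reshape(-1, 3),
                              self.box)
        self.solute = {
            role: np.mod(np.asarray(pos, dtype=float).reshape(-1, 3), self.box)
            for role, pos in self.solute.items()
        }

    def role_positions(self, role: str) -> np.ndarray:
        if role == "solvent":
            return self.solvent
        if role not in self.solute:
            raise KeyError(f"role {role!r} not present in frame "
                           f"(have {sorted(self.solute)})")
        return self.solute[role]


@dataclass
class ShellSelection:
    """Hydration-shell membership of one frame at cutoff r_c."""

    cutoff: float
    members: np.ndarray     # solvent indices within r_c of any solute atom
    n_waters: int

    def __post_init__(self):
        self.members = np.asarray(self.members, dtype=int)
        self.n_waters = int(self.n_waters)


@dataclass
class OrientationalStats:
    """OOO-angle distribution and tetrahedral order of shell waters."""

    theta: np.ndarray                   # bin centers, degrees
    density: np.ndarray                 # P(theta); integral over degrees = 1
    q_values: np.ndarray | None = None  # per shell-member q
    q_mean: float | None = None
    q_sem: float | None = None


@dataclass
class OccupancyStats:
    """Distribution of shell occupancy N_w over frames."""

    n_values: np.ndarray    # integer support of the histogram
    probability: np.ndarray  # P(N_w), sums to 1
    mean: float
    sem: float
    counts_per_frame: np.ndarray


@dataclass
class RdfResult:
    r: np.ndarray
    g: np.ndarray
    first_minimum: float | None
    first_maximum: float | None


def _pair_distances(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """(len(a), len(b)) minimum-image distance matrix."""
    d = minimum_image(a[:, None, :] - b[None, :, :], box)
    return np.sqrt(np.sum(d * d, axis=-1))


def rdf(frames, center_role: str, target_role: str = "solvent",
        r_max: float | None = None, dr: float = 0.01,
        smooth_bins: int = 3) -> RdfResult:
    """Radial distribution function g(r) between two roles, averaged over
    frames, with a first-minimum estimate for shell-cutoff selection.

    Normalisation is the ideal-gas shell count at the target role's mean
    number density, so uncorrelated placement gives g = 1.  The first
    minimum is the first interior local minimum (3-point rule) after the
    first maximum of a lightly smoothed curve (moving average over
    ``smooth_bins`` bins).  ``r_max`` defaults to just under half the
    smallest box length and must stay below it.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("no frames given")
    half = min(float(f.box.min()) for f in frames) / 2.0
    if r_max is None:
        r_max = 0.999 * half
    if r_max >= half:
        raise ValueError("r_max must be below half the smallest box length")

    edges = np.arange(0.0, r_max + dr, dr)
    counts = np.zeros(len(edges) - 1)
    n_center_total = 0
    rho_sum = 0.0
    for f in frames:
        centers = f.role_positions(center_role)
        targets = f.role_positions(target_role)
        if centers.size == 0 or targets.size == 0:
            raise ValueError("empty role in frame")
        d = _pair_distances(centers, targets, f.box)
        if center_role == target_role:
            np.fill_diagonal(d, np.inf)   # exclude self-pairs
        h, _ = np.histogram(d.ravel(), bins=edges)
        counts += h
        n_center_total += len(centers)
        n_t = len(targets) - (1 if center_role == target_role else 0)
        rho_sum += n_t / float(np.prod(f.box))
    rho = rho_sum / len(frames)
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    g = counts / (n_center_total * rho * shell_vol)
    r = 0.5 * (edges[:-1] + edges[1:])

    # light smoothing before feature detection
    k = max(int(smooth_bins), 1)
    kernel = np.ones(k) / k
    gs = np.convolve(g, kernel, mode="same")
    first_max = first_min = None
    for j in range(1, len(gs) - 1):
        if first_max is None:
            if gs[j] > gs[j - 1] and gs[j] >= gs[j + 1] and gs[j] > 1.0:
                first_max = r[j]
        else:
            if gs[j] < gs[j - 1] and gs[j] <= gs[j + 1]:
                first_min = r[j]
                break
    return RdfResult(r=r, g=g, first_minimum=first_min, first_maximum=first_max)


def shell_membership(frame: MolecularFrame, solute_role: str,
                     r_c: float) -> ShellSelection:
    """Solvent molecules within r_c (minimum image) of ANY atom of the role.

    r_c = 0 is allowed and yields an empty shell.
    """
    if r_c < 0:
        raise ValueError("r_c must be >= 0")
    solute = frame.role_positions(solute_role)
    if solute.size == 0:
        raise ValueError(f"role {solute_role!r} has no atoms")
    if r_c == 0.0 or frame.solvent.size == 0:
        return ShellSelection(cutoff=r_c, members=np.empty(0, dtype=int),
                              n_waters=0)
    d = _pair_distances(frame.solvent, solute, frame.box).min(axis=1)
    members = np.where(d <= r_c)[0]
    return ShellSelection(cutoff=r_c, members=members, n_waters=len(members))


def _nearest_neighbors(frame: MolecularFrame, central: int,
                       k: int) -> np.ndarray:
    """Indices of the k nearest solvent neighbors of solvent molecule
    ``central`` (all solvent, minimum image; ties broken by index order)."""
    d = minimum_image(frame.solvent - frame.solvent[central], frame.box)
    dist = np.sqrt(np.sum(d * d, axis=1))
    dist[central] = np.inf
    order = np.argsort(dist, kind="stable")
    return order[:k]


def _pair_cosines(frame: MolecularFrame, central: int,
                  neighbors: np.ndarray) -> np.ndarray:
    """cos(theta) for every pair among ``neighbors``, angle at ``central``."""
    v = minimum_image(frame.solvent[neighbors] - frame.solvent[central],
                      frame.box)
    norms = np.linalg.norm(v, axis=1)
    if np.any(norms == 0):
        raise ValueError("degenerate zero-length bond vector")
    u = v / norms[:, None]
    cosm = u @ u.T
    iu = np.triu_indices(len(neighbors), k=1)
    return np.clip(cosm[iu], -1.0, 1.0)


def tetrahedral_q(frame: MolecularFrame, central: int,
                  neighbors) -> float:
    """Tetrahedral order parameter of solvent molecule ``central`` given
    exactly four distinct neighbor indices."""
    neighbors = np.asarray(neighbors, dtype=int)
    if len(neighbors) != 4 or len(set(neighbors.tolist())) != 4:
        raise ValueError("exactly 4 distinct neighbors required")
    if central in neighbors:
        raise ValueError("central molecule cannot be its own neighbor")
    c = _pair_cosines(frame, central, neighbors)
    return float(1.0 - (3.0 / 8.0) * np.sum((c + 1.0 / 3.0) ** 2))


def ooo_angle_distribution(frames, shells, n_neighbors: int = 4,
                           bin_width: float = 2.0) -> OrientationalStats:
    """P(theta) of OOO angles at shell-member central molecules.

    For each central (a shell member), the angles subtended by all pairs
    among its ``n_neighbors`` nearest solvent neighbors (searched over ALL
    solvent) are collected; the histogram over [0, 180] deg is normalised
    to unit integral.  When ``n_neighbors`` is 4, per-molecule q values
    are computed from the same pair cosines and the shell-average
    reported.
    """
    frames = list(frames)
    shells = list(shells)
    if len(frames) != len(shells):
        raise ValueError("one shell selection per frame required")
    angles = []
    qs = []
    for f, s in zip(frames, shells):
        if len(f.solvent) < n_neighbors + 1:
            raise ValueError(
                f"frame has {len(f.solvent)} solvent molecules; need at least "
                f"{n_neighbors + 1}"
            )
        for central in s.members:
            nb = _nearest_neighbors(f, int(central), n_neighbors)
            c = _pair_cosines(f, int(central), nb)
            angles.append(np.degrees(np.arccos(c)))
            if n_neighbors == 4:
                qs.append(1.0 - (3.0 / 8.0) * np.sum((c + 1.0 / 3.0) ** 2))
    if not angles:
        raise ValueError("no shell members in any frame")
    angles = np.concatenate(angles)
    nb_bins = int(round(180.0 / bin_width))
    hist, edges = np.histogram(angles, bins=nb_bins, range=(0.0, 180.0))
    density = hist / (hist.sum() * bin_width)
    theta = 0.5 * (edges[:-1] + edges[1:])
    q_values = np.asarray(qs) if qs else None
    q_mean = float(np.mean(q_values)) if q_values is not None else None
    q_sem = (float(np.std(q_values, ddof=1) / np.sqrt(len(q_values)))
             if q_values is not None and len(q_values) > 1 else None)
    return OrientationalStats(theta=theta, density=density,
                              q_values=q_values, q_mean=q_mean, q_sem=q_sem)


def shell_average_q(frames, shells) -> OrientationalStats:
    """Shell-restricted ensemble average of q.

    Every shell member of every frame contributes one q observation
    (equal weight per molecule-frame pair); only the averaging is
    restricted to the shell — neighbor searches run over all solvent.
    """
    stats = ooo_angle_distribution(frames, shells, n_neighbors=4)
    return stats


def shell_occupancy(frames, solute_role: str = "bulge",
                    r_c: float = 0.35) -> OccupancyStats:
    """Distribution P(N_w) and mean occupancy of the role's hydration shell."""
    frames = list(frames)
    if not frames:
        raise ValueError("no frames given")
    counts = np.array([
        shell_membership(f, solute_role, r_c).n_waters for f in frames
    ])
    nmax = int(counts.max())
    support = np.arange(nmax + 1)
    hist = np.bincount(counts, minlength=nmax + 1).astype(float)
    prob = hist / hist.sum()
    mean = float(counts.mean())
    sem = float(counts.std(ddof=1) / np.sqrt(len(counts))) if len(counts) > 1 else np.nan
    return OccupancyStats(n_values=support, probability=prob, mean=mean,
                          sem=sem, counts_per_frame=counts)
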