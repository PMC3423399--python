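"""Plain-text readers and writers for the pipeline's file formats.

All formats are line-oriented text with deterministic formatting, so a
rerun with the same seed produces byte-identical files:

- window metadata: TSV ``window_id  center_deg  force_constant  series_file``
- window series: two columns ``time  angle_deg``, '#' comments
  (GROMACS-pull-output-like dialect)
- PMF: TSV ``angle_deg  F  defined`` with unit/kT metadata in '#' headers
- coordinates: minimal fixed-column GRO and XYZ dialects (orthorhombic
  boxes, oxygen-only solvent as resname SOL / element O)
- role map: TSV ``role  start  end`` with 1-based inclusive atom indices

Malformed input raises ValueError naming the file, line number and
offending token.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .hydration import MolecularFrame
from .profiles import FreeEnergyProfile
from .wham import UmbrellaWindow

__all__ = [
    "write_windows", "read_windows", "write_series", "read_series",
    "write_pmf", "read_pmf", "write_gro", "read_gro", "write_xyz", "read_xyz",
    "read_role_map", "write_json_report", "read_json_report",
]


def _fail(path, lineno, token, why):
    raise ValueError(f"{path}:{lineno}: {why} (offending token: {token!r})")


# ---------------------------------------------------------------- windows

def write_series(path, times, angles) -> None:
    """Two-column time/angle series with a '#' header."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# time\tangle_deg\n")
        for t, a in zip(times, angles):
            fh.write(f"{t:.6f}\t{a:.6f}\n")


def read_series(path):
    """Read a two-column series; returns (times, angles) arrays."""
    path = Path(path)
    times, angles = [], []
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            s = line.strip()
            if not s or s.startswith(("#", "@")):
                continue
            parts = s.split()
            if len(parts) < 2:
                _fail(path, lineno, s, "expected two columns")
            try:
                times.append(float(parts[0]))
                angles.append(float(parts[1]))
            except ValueError:
                bad = parts[0] if not _is_float(parts[0]) else parts[1]
                _fail(path, lineno, bad, "not a number")
    return np.asarray(times), np.asarray(angles)


def _is_float(tok):
    try:
        float(tok)
        return True
    except ValueError:
        return False


def write_windows(directory, windows: list[UmbrellaWindow],
                  meta_name: str = "windows.tsv") -> Path:
    """Write window metadata TSV plus one series file per window; returns
    the metadata path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = directory / meta_name
    with meta.open("w") as fh:
        fh.write("window_id\tcenter_deg\tforce_constant\tseries_file\n")
        for w in windows:
            series = f"{w.window_id}.dat"
            fh.write(f"{w.window_id}\t{w.bias_center:.6f}\t"
                     f"{w.force_constant:.8g}\t{series}\n")
            t = w.sampling_interval * np.arange(len(w.samples))
            write_series(directory / series, t, w.samples)
    return meta


def read_windows(meta_path) -> list[UmbrellaWindow]:
    """Read a window metadata TSV (series paths resolved relative to it)."""
    meta_path = Path(meta_path)
    windows = []
    with meta_path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.split("\t")
            if parts[0] == "window_id":
                continue
            if len(parts) != 4:
                _fail(meta_path, lineno, s, "expected 4 tab-separated columns")
            wid, center, k, series = parts
            if not _is_float(center):
                _fail(meta_path, lineno, center, "center_deg not a number")
            if not _is_float(k):
                _fail(meta_path, lineno, k, "force_constant not a number")
            t, a = read_series(meta_path.parent / series)
            dt = float(t[1] - t[0]) if len(t) > 1 else 1.0
            windows.append(UmbrellaWindow(
                window_id=wid, bias_center=float(center),
                force_constant=float(k), samples=a, sampling_interval=dt))
    if not windows:
        raise ValueError(f"{meta_path}: no windows found")
    return windows


# ---------------------------------------------------------------- PMF

def write_pmf(path, profile: FreeEnergyProfile) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# unit: {profile.unit}\n")
        fh.write(f"# kT: {profile.kT:.8g}\n")
        fh.write(f"# temperature: {profile.temperature:.8g}\n")
        fh.write("angle_deg\tfree_energy\tdefined\n")
        for x, v, d in zip(profile.grid, profile.values, profile.defined):
            fh.write(f"{x:.6f}\t{v:.6f}\t{int(d)}\n")


def read_pmf(path) -> FreeEnergyProfile:
    path = Path(path)
    unit, kT, temp = "kT", 1.0, 300.0
    grid, vals, mask = [], [], []
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            s = line.strip()
            if not s:
                continue
            if s.startswith("#"):
                body = s[1:].strip()
                if body.startswith("unit:"):
                    unit = body.split(":", 1)[1].strip()
                elif body.startswith("kT:"):
                    kT = float(body.split(":", 1)[1])
                elif body.startswith("temperature:"):
                    temp = float(body.split(":", 1)[1])
                continue
            parts = s.split("\t")
            if parts[0] == "angle_deg":
                continue
            if len(parts) != 3:
                _fail(path, lineno, s, "expected 3 tab-separated columns")
            if not (_is_float(parts[0]) and _is_float(parts[1])):
                bad = parts[0] if not _is_float(parts[0]) else parts[1]
                _fail(path, lineno, bad, "not a number")
            grid.append(float(parts[0]))
            vals.append(float(parts[1]))
            mask.append(bool(int(parts[2])))
    if not grid:
        raise ValueError(f"{path}: no PMF rows found")
    return FreeEnergyProfile(grid=np.asarray(grid), values=np.asarray(vals),
                             unit=unit, kT=kT, temperature=temp,
                             mask=np.asarray(mask))


# ---------------------------------------------------------------- GRO / XYZ

def write_gro(path, frames, title: str = "flipkin frame") -> None:
    """Minimal fixed-column GRO writer (solute roles first, then solvent
    as SOL/OW); multiple frames are concatenated."""
    if isinstance(frames, MolecularFrame):
        frames = [frames]
    path = Path(path)
    with path.open("w") as fh:
        for f in frames:
            atoms = []
            for role in sorted(f.solute):
                rn = (role.upper()[:5] or "MOL")
                for p in f.solute[role]:
                    atoms.append((rn, "CA", p))
            for p in f.solvent:
                atoms.append(("SOL", "OW", p))
            fh.write(f"{title}\n{len(atoms):5d}\n")
            for i, (rn, an, p) in enumerate(atoms, 1):
                ri = i % 100000
                fh.write(f"{ri:5d}{rn:<5s}{an:>5s}{ri:5d}"
                         f"{p[0]:8.3f}{p[1]:8.3f}{p[2]:8.3f}\n")
            fh.write(f"{f.box[0]:10.4f}{f.box[1]:10.4f}{f.box[2]:10.4f}\n")


def read_gro(path, role_map=None) -> list[MolecularFrame]:
    """Read a (possibly multi-frame) minimal GRO file.

    Solvent is every atom whose residue name is SOL; other residue names
    become solute roles (lower-cased).  ``role_map`` — a list of
    (role, start, end) with 1-based inclusive indices, e.g. from
    ``read_role_map`` — overrides the residue-name assignment.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    frames = []
    i = 0
    while i < len(lines):
        if not lines[i].strip() and i == len(lines) - 1:
            break
        if i + 1 >= len(lines):
            _fail(path, i + 1, lines[i], "truncated frame: missing atom count")
        try:
            n = int(lines[i + 1].strip())
        except ValueError:
            _fail(path, i + 2, lines[i + 1].strip(), "atom count not an integer")
        if i + 2 + n >= len(lines) + 1 and len(lines) < i + 3 + n:
            _fail(path, len(lines), "<eof>", f"truncated frame: expected {n} atoms + box")
        resnames, coords = [], []
        for j in range(n):
            ln = lines[i + 2 + j]
            lineno = i + 3 + j
            if len(ln) < 44:
                _fail(path, lineno, ln, "atom line shorter than fixed columns")
            resnames.append(ln[5:10].strip())
            try:
                coords.append([float(ln[20:28]), float(ln[28:36]),
                               float(ln[36:44])])
            except ValueError:
                _fail(path, lineno, ln[20:44], "bad coordinate field")
        box_line = lines[i + 2 + n]
        try:
            box = [float(t) for t in box_line.split()[:3]]
        except (ValueError, IndexError):
            _fail(path, i + 3 + n, box_line, "bad box line")
        coords = np.asarray(coords)
        roles: dict[str, list[int]] = {}
        if role_map:
            assigned = np.zeros(n, dtype=bool)
            for role, start, end in role_map:
                idx = np.arange(start - 1, end)
                roles.setdefault(role, []).extend(idx.tolist())
                assigned[idx] = True
            solvent_idx = np.where(~assigned)[0]
        else:
            rn = np.asarray(resnames)
            solvent_idx = np.where(rn == "SOL")[0]
            for role in sorted(set(resnames) - {"SOL"}):
                roles[role.lower()] = np.where(rn == role)[0].tolist()
        frames.append(MolecularFrame(
            solvent=coords[solvent_idx], box=np.asarray(box),
            solute={r: coords[np.asarray(ix, dtype=int)]
                    for r, ix in roles.items()},
        ))
        i = i + 3 + n
    if not frames:
        raise ValueError(f"{path}: no frames found")
    return frames


def write_xyz(path, frames) -> None:
    """Minimal XYZ writer: oxygen-only solvent, box on the comment line,
    coordinates in nm to 4 decimals.  Solute atoms are labelled by role."""
    if isinstance(frames, MolecularFrame):
        frames = [frames]
    path = Path(path)
    with path.open("w") as fh:
        for f in frames:
            atoms = [("O", p) for p in f.solvent]
            for role in sorted(f.solute):
                atoms += [(role, p) for p in f.solute[role]]
            fh.write(f"{len(atoms)}\n")
            fh.write(f"box {f.box[0]:.4f} {f.box[1]:.4f} {f.box[2]:.4f} nm\n")
            for name, p in atoms:
                fh.write(f"{name} {p[0]:.4f} {p[1]:.4f} {p[2]:.4f}\n")


def read_xyz(path) -> list[MolecularFrame]:
    path = Path(path)
    lines = path.read_text().splitlines()
    frames = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            _fail(path, i + 1, lines[i].strip(), "atom count not an integer")
        if i + 1 >= len(lines):
            _fail(path, i + 1, "<eof>", "missing comment line")
        comment = lines[i + 1].split()
        if len(comment) < 4 or comment[0] != "box":
            _fail(path, i + 2, lines[i + 1], "comment line must carry 'box Lx Ly Lz'")
        box = [float(t) for t in comment[1:4]]
        if i + 2 + n > len(lines):
            _fail(path, len(lines), "<eof>", f"truncated frame: expected {n} atoms")
        solvent, roles = [], {}
        for j in range(n):
            parts = lines[i + 2 + j].split()
            if len(parts) < 4:
                _fail(path, i + 3 + j, lines[i + 2 + j], "expected 'name x y z'")
            try:
                p = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError:
                _fail(path, i + 3 + j, lines[i + 2 + j], "bad coordinate")
            if parts[0] == "O":
                solvent.append(p)
            else:
                roles.setdefault(parts[0], []).append(p)
        frames.append(MolecularFrame(
            solvent=np.asarray(solvent) if solvent else np.empty((0, 3)),
            box=np.asarray(box),
            solute={r: np.asarray(ps) for r, ps in roles.items()},
        ))
        i += 2 + n
    if not frames:
        raise ValueError(f"{path}: no frames found")
    return frames


def read_role_map(path):
    """Role map TSV: ``role  start  end`` (1-based inclusive atom indices)."""
    path = Path(path)
    entries = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            s = line.strip()
            if not s or s.startswith("#") or s.startswith("role\t"):
                continue
            parts = s.split("\t")
            if len(parts) != 3:
                _fail(path, lineno, s, "expected 3 tab-separated columns")
            role, start, end = parts
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                _fail(path, lineno, s, "indices must be integers")
            if start_i < 1 or end_i < start_i:
                _fail(path, lineno, s, "need 1 <= start <= end")
            entries.append((role, start_i, end_i))
    if not entries:
        raise ValueError(f"{path}: no role entries found")
    return entries


# ---------------------------------------------------------------- JSON

def write_json_report(path, report: dict) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True,
                                     default=_jsonable) + "\n")


def read_json_report(path) -> dict:
    return json.loads(Path(path).read_text())


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
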