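"""Snapshot file formats: plain-text lattice configurations and XYZ trajectories.

Lattice snapshot (``.lat``)::

    L 60
    J 3
    0 0 1
    0 1 2
    ...

with one ``i j s`` line per occupied site (0-based axial coordinates, species
``s`` in {1, 2}).  The reader and writer round-trip bit-exactly.

Continuous snapshots use XYZ with species as atom labels (``A`` = species 1,
``B`` = species 2); the comment line carries step, temperature, potential
energy and the box, and each atom line optionally appends the velocity.
"""

from __future__ import annotations

import os
from fractions import Fraction
from numbers import Rational

import numpy as np

from .lattice import LatticeConfiguration
from .md import ContinuousPotentialParams, MDSystem, WallSpec

__all__ = [
    "SnapshotParseError",
    "write_lattice",
    "read_lattice",
    "write_xyz",
    "read_xyz",
]


class SnapshotParseError(ValueError):
    """Malformed snapshot file; the message names the offending line."""


def _fmt_J(J) -> str:
    if isinstance(J, Rational):
        return str(Fraction(J))
    return repr(float(J))


def write_lattice(config: LatticeConfiguration, path, J=Fraction(3)) -> None:
    """Write a lattice snapshot; ``J`` is stored as run metadata."""
    with open(path, "w") as fh:
        fh.write(f"L {config.L}\n")
        fh.write(f"J {_fmt_J(J)}\n")
        for i, j, sp in config.occupied_sites():
            fh.write(f"{i} {j} {sp}\n")


def read_lattice(path):
    """Read a lattice snapshot; returns ``(configuration, J)``."""
    sites = []
    L = None
    J = None
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            try:
                if parts[0] == "L":
                    L = int(parts[1])
                elif parts[0] == "J":
                    J = Fraction(parts[1]) if "/" in parts[1] or "." not in parts[1] \
                        else float(parts[1])
                else:
                    i, j, s = int(parts[0]), int(parts[1]), int(parts[2])
                    if s not in (1, 2):
                        raise ValueError(f"species must be 1 or 2, got {s}")
                    sites.append((i, j, s))
            except (ValueError, IndexError) as exc:
                raise SnapshotParseError(
                    f"{path}: line {ln}: {exc}") from None
    if L is None:
        raise SnapshotParseError(f"{path}: missing 'L' header line")
    try:
        config = LatticeConfiguration.from_sites(L, sites)
    except ValueError as exc:
        raise SnapshotParseError(f"{path}: {exc}") from None
    return config, J


_LABELS = {1: "A", 2: "B"}
_SPECIES = {"A": 1, "B": 2}


def write_xyz(system: MDSystem, path, step: int = 0, append: bool = False,
              velocities: bool = True) -> None:
    """Append one XYZ frame; positions to 9 significant digits."""
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        fh.write(f"{system.N}\n")
        fh.write(
            f"step={step} T={system.T_target:.9g} "
            f"box={system.box[0]:.9g},{system.box[1]:.9g},{system.box[2]:.9g} "
            f"q={system.params.q:.9g} wall={system.wall.bottom}\n")
        for sp, p, v in zip(system.species, system.positions, system.velocities):
            line = f"{_LABELS[int(sp)]} {p[0]:.9g} {p[1]:.9g} {p[2]:.9g}"
            if velocities:
                line += f" {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}"
            fh.write(line + "\n")


def read_xyz(path, frame: int = -1) -> MDSystem:
    """Read one frame (default: the last) of an XYZ trajectory."""
    frames = []
    with open(path) as fh:
        lines = fh.readlines()
    ln = 0
    while ln < len(lines):
        if not lines[ln].strip():
            ln += 1
            continue
        try:
            n = int(lines[ln].strip())
        except ValueError:
            raise SnapshotParseError(
                f"{path}: line {ln + 1}: expected atom count") from None
        comment = lines[ln + 1].strip()
        meta = dict(tok.split("=", 1) for tok in comment.split() if "=" in tok)
        box = tuple(float(x) for x in meta.get("box", "0,0,0").split(","))
        q = float(meta.get("q", 1.0))
        T = float(meta.get("T", 0.1))
        wall = int(meta.get("wall", 0))
        species = np.empty(n, dtype=np.int8)
        pos = np.zeros((n, 3))
        vel = np.zeros((n, 3))
        for a in range(n):
            lno = ln + 2 + a
            parts = lines[lno].split()
            if parts[0] not in _SPECIES:
                raise SnapshotParseError(
                    f"{path}: line {lno + 1}: unknown atom label {parts[0]!r}")
            try:
                species[a] = _SPECIES[parts[0]]
                pos[a] = [float(x) for x in parts[1:4]]
                if len(parts) >= 7:
                    vel[a] = [float(x) for x in parts[4:7]]
            except (ValueError, IndexError) as exc:
                raise SnapshotParseError(f"{path}: line {lno + 1}: {exc}") from None
        frames.append((species, pos, vel, box, q, T, wall))
        ln += 2 + n
    if not frames:
        raise SnapshotParseError(f"{path}: no frames found")
    species, pos, vel, box, q, T, wall = frames[frame]
    return MDSystem(pos, vel, species, box, WallSpec(wall),
                    ContinuousPotentialParams(q=q), T_target=T)
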