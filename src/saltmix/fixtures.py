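"""Fixture generation: ideal phase configurations and random initial states."""

from __future__ import annotations

import numpy as np

from .catalog import CATALOG, _compatible_torus, tile_phase
from .lattice import LatticeConfiguration, TriangularLattice

__all__ = ["generate_fixture", "random_lattice", "place_motif",
           "RHOMBUS", "HEXAGON"]

#: 4-particle cluster: two edge-sharing elementary triangles.
RHOMBUS = ((0, 0), (1, 0), (0, 1), (1, 1))

#: 7-particle cluster: a site and its full first shell.
HEXAGON = ((0, 0), (1, 0), (0, 1), (-1, 1), (-1, 0), (0, -1), (1, -1))


def generate_fixture(phase_name: str, L: int = 60) -> LatticeConfiguration:
    """Ideal periodic configuration of a catalog phase on an ``L x L`` torus.

    ``L`` must be divisible by the phase's cell periods (L = 60 accommodates
    the whole catalog); the error message lists valid sizes otherwise.
    """
    if phase_name not in CATALOG:
        raise KeyError(f"unknown phase {phase_name!r}; catalog: {sorted(CATALOG)}")
    phase = CATALOG[phase_name]
    if not phase.has_cell:
        raise ValueError(
            f"phase {phase_name!r} has no finite-period unit cell and cannot "
            "be generated as a fixture")
    try:
        return tile_phase(phase_name, L)
    except ValueError:
        base = _compatible_torus(phase.hnf, 1)
        valid = [base * m for m in range(1, 61) if base * m >= 5][:6]
        raise ValueError(
            f"L={L} incompatible with phase {phase_name!r}; valid sizes "
            f"include {valid}") from None


def random_lattice(L: int, N1: int, N2: int, seed: int = 0) -> LatticeConfiguration:
    """Uniformly random non-overlapping placement of ``N1 + N2`` particles."""
    if N1 + N2 > L * L:
        raise ValueError("too many particles for the lattice")
    rng = np.random.default_rng(seed)
    sites = rng.choice(L * L, size=N1 + N2, replace=False)
    S = np.zeros(L * L, dtype=np.int8)
    S[sites[:N1]] = 1
    S[sites[N1:]] = -1
    return LatticeConfiguration(TriangularLattice(L), S.reshape(L, L))


def place_motif(L: int, motif, species: int = 1, origin=(0, 0),
                config: LatticeConfiguration | None = None) -> LatticeConfiguration:
    """Place a finite cluster motif (offsets) on an otherwise empty lattice."""
    cfg = config if config is not None else LatticeConfiguration.empty(L)
    oi, oj = origin
    for di, dj in motif:
        site = cfg.lattice.wrap((oi + di, oj + dj))
        if cfg.S[site] != 0:
            raise ValueError(f"site {site} already occupied")
        cfg.S[site] = 1 if species == 1 else -1
    return cfg
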