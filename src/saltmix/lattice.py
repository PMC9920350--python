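"""Triangular-lattice geometry and exact energetics of the binary SALR mixture.

The model lives on a periodic triangular lattice.  Each site carries a spin-1
occupancy variable ``S`` with ``S = +1`` for a particle of species 1, ``S = -1``
for species 2 and ``S = 0`` for an empty cell; single occupancy is therefore
built into the representation.  Like particles attract at nearest-neighbour
distance (``-J1``) and repel at distance ``2a`` (``+J2``); unlike particles do
the opposite.  The second-neighbour shell at distance ``sqrt(3) a`` does not
interact.  With ``J = J2/J1`` and ``J1`` as the energy unit the total energy is

    E = -(1/2) sum_first S(x) S(x') + (J/2) sum_third S(x) S(x')

in units of ``J1``, where the sums run over ordered pairs in the first and
third neighbour shells.  All energies are exact integers plus an integer
multiple of ``J``, and are kept in rational arithmetic whenever ``J`` is
rational.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from numbers import Rational
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "FIRST_SHELL",
    "SECOND_SHELL",
    "THIRD_SHELL",
    "TriangularLattice",
    "InteractionParams",
    "ChemicalPotentials",
    "LatticeConfiguration",
    "axial_to_xy",
    "neighbor_shells",
    "pair_energy",
    "interaction_sums",
    "total_energy",
    "grand_hamiltonian_density",
    "local_field",
    "insertion_energy_change",
]

#: Axial offsets of the six nearest neighbours (Euclidean distance 1).
FIRST_SHELL: tuple[tuple[int, int], ...] = (
    (1, 0), (0, 1), (-1, 1), (-1, 0), (0, -1), (1, -1),
)

#: Axial offsets of the six second-shell sites (distance sqrt(3); inert).
SECOND_SHELL: tuple[tuple[int, int], ...] = (
    (1, 1), (-1, 2), (-2, 1), (-1, -1), (1, -2), (2, -1),
)

#: Axial offsets of the six third-shell sites (Euclidean distance 2).
THIRD_SHELL: tuple[tuple[int, int], ...] = (
    (2, 0), (0, 2), (-2, 2), (-2, 0), (0, -2), (2, -2),
)

_SQRT3_2 = np.sqrt(3.0) / 2.0


def axial_to_xy(i, j):
    """Embed axial coordinates ``(i, j)`` as ``i*a1 + j*a2`` in the plane.

    ``a1 = (1, 0)`` and ``a2 = (1/2, sqrt(3)/2)``; lengths are in units of the
    lattice constant ``a``.
    """
    i = np.asarray(i, dtype=float)
    j = np.asarray(j, dtype=float)
    return i + 0.5 * j, _SQRT3_2 * j


def _coerce_coupling(J):
    """Return ``J`` as a Fraction when it is exactly representable."""
    if isinstance(J, Rational):
        return Fraction(J)
    if isinstance(J, float) and J.is_integer():
        return Fraction(int(J))
    return J


@dataclass(frozen=True)
class InteractionParams:
    """Lattice couplings: ``J1 = 1`` is the energy unit, ``J = J2/J1``.

    ``J`` may be any positive real; rational values (ints, Fractions, strings
    like ``"13/12"``) keep all energy algebra exact.
    """

    J: object = Fraction(3)

    def __post_init__(self):
        J = self.J
        if isinstance(J, str):
            J = Fraction(J)
        object.__setattr__(self, "J", _coerce_coupling(J))
        if not self.J > 0:
            raise ValueError(f"J = J2/J1 must be positive, got {self.J}")

    @property
    def regime(self) -> str:
        """Ground-state regime flag for the ratio ``J``."""
        J = self.J
        if J < Fraction(1, 2):
            return "no-microphase (J < 1/2)"
        if J < Fraction(13, 12):
            return "large-cluster (1/2 < J < 13/12)"
        if J < Fraction(7, 4):
            return "small-cluster (13/12 < J < 7/4)"
        return "periodic-cluster (J > 7/4)"


@dataclass(frozen=True)
class ChemicalPotentials:
    """Dimensionless chemical potentials ``mu_i* = mu_i / J1``."""

    mu1: object = Fraction(0)
    mu2: object = Fraction(0)

    def __post_init__(self):
        for name in ("mu1", "mu2"):
            v = getattr(self, name)
            if isinstance(v, str):
                v = Fraction(v)
            v = _coerce_coupling(v)
            if not np.isfinite(float(v)):
                raise ValueError(f"{name} must be finite, got {v}")
            object.__setattr__(self, name, v)

    def swapped(self) -> "ChemicalPotentials":
        return ChemicalPotentials(self.mu2, self.mu1)


class TriangularLattice:
    """Periodic triangular lattice of ``L x L`` sites in axial coordinates."""

    def __init__(self, L: int):
        L = int(L)
        if L < 5:
            raise ValueError(
                "L >= 5 required for unambiguous minimum-image neighbour shells"
            )
        self.L = L

    @property
    def n_sites(self) -> int:
        return self.L * self.L

    def wrap(self, site: tuple[int, int]) -> tuple[int, int]:
        i, j = site
        return (int(i) % self.L, int(j) % self.L)

    def neighbor_shells(self, site):
        """The 6 first-shell and 6 third-shell sites of ``site`` (wrapped)."""
        i, j = self.wrap(site)
        first = tuple(((i + di) % self.L, (j + dj) % self.L) for di, dj in FIRST_SHELL)
        third = tuple(((i + di) % self.L, (j + dj) % self.L) for di, dj in THIRD_SHELL)
        return first, third

    def __repr__(self):
        return f"TriangularLattice(L={self.L})"

    def __eq__(self, other):
        return isinstance(other, TriangularLattice) and other.L == self.L

    def __hash__(self):
        return hash(("TriangularLattice", self.L))


def neighbor_shells(lattice: TriangularLattice, site):
    """Module-level alias for :meth:`TriangularLattice.neighbor_shells`."""
    return lattice.neighbor_shells(site)


class LatticeConfiguration:
    """Occupancy field ``S`` in ``{+1, -1, 0}`` on a triangular lattice."""

    def __init__(self, lattice: TriangularLattice, S: np.ndarray | None = None):
        self.lattice = lattice
        if S is None:
            S = np.zeros((lattice.L, lattice.L), dtype=np.int8)
        else:
            S = np.asarray(S, dtype=np.int8)
            if S.shape != (lattice.L, lattice.L):
                raise ValueError(f"S must have shape {(lattice.L, lattice.L)}")
            if not np.isin(S, (-1, 0, 1)).all():
                raise ValueError("S entries must be in {+1, -1, 0}")
        self.S = S

    # -- constructors -------------------------------------------------------
    @classmethod
    def empty(cls, L: int) -> "LatticeConfiguration":
        return cls(TriangularLattice(L))

    @classmethod
    def from_sites(cls, L: int, sites: Iterable[tuple[int, int, int]]):
        """Build from ``(i, j, species)`` triples with species in {1, 2}."""
        cfg = cls.empty(L)
        for i, j, sp in sites:
            if sp not in (1, 2):
                raise ValueError(f"species must be 1 or 2, got {sp}")
            i, j = cfg.lattice.wrap((i, j))
            if cfg.S[i, j] != 0:
                raise ValueError(f"site ({i}, {j}) occupied twice")
            cfg.S[i, j] = 1 if sp == 1 else -1
        return cfg

    # -- basic queries ------------------------------------------------------
    @property
    def L(self) -> int:
        return self.lattice.L

    @property
    def N1(self) -> int:
        return int(np.count_nonzero(self.S == 1))

    @property
    def N2(self) -> int:
        return int(np.count_nonzero(self.S == -1))

    def occupied_sites(self) -> list[tuple[int, int, int]]:
        """Sorted ``(i, j, species)`` triples of occupied sites."""
        out = []
        for i, j in zip(*np.nonzero(self.S)):
            out.append((int(i), int(j), 1 if self.S[i, j] == 1 else 2))
        return sorted(out)

    def copy(self) -> "LatticeConfiguration":
        return LatticeConfiguration(self.lattice, self.S.copy())

    def translated(self, di: int, dj: int) -> "LatticeConfiguration":
        return LatticeConfiguration(self.lattice, np.roll(self.S, (di, dj), axis=(0, 1)))

    def species_swapped(self) -> "LatticeConfiguration":
        return LatticeConfiguration(self.lattice, -self.S)

    def __eq__(self, other):
        return (
            isinstance(other, LatticeConfiguration)
            and other.lattice == self.lattice
            and np.array_equal(other.S, self.S)
        )


def pair_energy(species_i: int, species_j: int, shell: str, params: InteractionParams):
    """Interaction of one pair, in ``J1`` units.

    Like pairs: ``-1`` (first shell), ``+J`` (third shell); unlike pairs flip
    both signs.  The second shell is inert and returns 0.
    """
    if species_i not in (1, 2) or species_j not in (1, 2):
        raise ValueError("species must be 1 or 2")
    like = species_i == species_j
    if shell == "first":
        return -1 if like else 1
    if shell == "third":
        return params.J if like else -params.J
    if shell == "second":
        return 0
    raise ValueError(f"unknown shell {shell!r}")


def interaction_sums(config: LatticeConfiguration) -> tuple[int, int]:
    """Exact integer pair sums ``(Q1, Q3)`` with ``Q = sum_pairs S(x) S(x')``.

    ``Q1`` runs over first-shell pairs and ``Q3`` over third-shell pairs, each
    pair counted once.  The total energy is ``-Q1 + J * Q3``.
    """
    S = config.S.astype(np.int64)
    q1 = 0
    q3 = 0
    # Half of each shell's offsets suffices to count every pair once.
    for di, dj in FIRST_SHELL[:3]:
        q1 += int(np.sum(S * np.roll(S, (-di, -dj), axis=(0, 1))))
    for di, dj in THIRD_SHELL[:3]:
        q3 += int(np.sum(S * np.roll(S, (-di, -dj), axis=(0, 1))))
    return q1, q3


def total_energy(config: LatticeConfiguration, params: InteractionParams):
    """Total configuration energy in ``J1`` units (exact for rational ``J``)."""
    q1, q3 = interaction_sums(config)
    return -q1 + params.J * q3


def grand_hamiltonian_density(
    config: LatticeConfiguration,
    params: InteractionParams,
    mu: ChemicalPotentials,
):
    """Per-site thermodynamic Hamiltonian ``h* = (E - mu1 N1 - mu2 N2) / L^2``."""
    H = total_energy(config, params) - mu.mu1 * config.N1 - mu.mu2 * config.N2
    area = config.lattice.n_sites
    if isinstance(H, Rational):
        return Fraction(H) / area
    return H / area


def local_field(config: LatticeConfiguration, site) -> tuple[int, int]:
    """``(Delta1, Delta2)``: sums of ``S`` over the first and third shells."""
    first, third = config.lattice.neighbor_shells(site)
    d1 = int(sum(config.S[p] for p in first))
    d2 = int(sum(config.S[p] for p in third))
    return d1, d2


def insertion_energy_change(
    config: LatticeConfiguration, site, species: int, params: InteractionParams
):
    """Energy change of inserting ``species`` at an empty ``site``.

    ``dE = -s (Delta1 - J Delta2)`` with ``s = +1`` for species 1 and ``-1``
    for species 2; equals ``total_energy(after) - total_energy(before)``
    exactly.
    """
    site = config.lattice.wrap(site)
    if config.S[site] != 0:
        raise ValueError(f"site {site} is occupied")
    if species not in (1, 2):
        raise ValueError("species must be 1 or 2")
    s = 1 if species == 1 else -1
    d1, d2 = local_field(config, site)
    return -s * (d1 - params.J * d2)
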