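"""Grand-canonical and canonical Metropolis Monte Carlo on the lattice model.

Moves follow the insertion/removal scheme: a site is drawn uniformly; if empty,
a species is drawn with probability 1/2 and inserted with acceptance
``min(1, exp[(u_i + mu_i*)/T*])``; if occupied by species ``i`` the particle is
removed with acceptance ``min(1, exp[-(u_i + mu_i*)/T*])``, where
``u_1 = -u_2 = Delta1 - J * Delta2`` is the local insertion energy gain.  One
MC step is ``L^2`` attempted moves.  The canonical variant conserves particle
numbers and moves particles to empty first-shell sites with plain Metropolis
acceptance on the energy change.

Annealing follows the protocol of starting from an empty (or random) lattice
at ``T* = 5`` and cooling through a fixed schedule to ``T* = 0.2``, with an
equilibration and a production period at every temperature.

Energy bookkeeping is exact: the kernels track the integer pair sums
``(Q1, Q3)`` so that ``E = -Q1 + J*Q3`` matches a from-scratch evaluation with
zero tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit

from .lattice import (
    FIRST_SHELL,
    THIRD_SHELL,
    ChemicalPotentials,
    InteractionParams,
    LatticeConfiguration,
    TriangularLattice,
    insertion_energy_change,
    local_field,
)

__all__ = [
    "DEFAULT_SCHEDULE",
    "GCMCParams",
    "CanonicalParams",
    "MCResult",
    "gcmc_move",
    "canonical_move",
    "anneal_gcmc",
    "anneal_canonical",
    "build_neighbor_tables",
]

#: Default annealing schedule: start hot at T* = 5.0, end at T* = 0.2.
DEFAULT_SCHEDULE: tuple[float, ...] = (5.0, 2.0, 1.0, 0.6, 0.35, 0.2)

_NB_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def build_neighbor_tables(L: int) -> tuple[np.ndarray, np.ndarray]:
    """Flat-index first- and third-shell neighbour tables, shape ``(L*L, 6)``."""
    if L in _NB_CACHE:
        return _NB_CACHE[L]
    TriangularLattice(L)  # validates L >= 5
    idx = np.arange(L * L).reshape(L, L)
    nb1 = np.empty((L * L, 6), dtype=np.int32)
    nb3 = np.empty((L * L, 6), dtype=np.int32)
    for a, (di, dj) in enumerate(FIRST_SHELL):
        nb1[:, a] = np.roll(idx, (-di, -dj), axis=(0, 1)).ravel()
    for a, (di, dj) in enumerate(THIRD_SHELL):
        nb3[:, a] = np.roll(idx, (-di, -dj), axis=(0, 1)).ravel()
    _NB_CACHE[L] = (nb1, nb3)
    return nb1, nb3


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

def _check_schedule(ts):
    ts = tuple(float(t) for t in ts)
    if not ts or any(t <= 0 for t in ts):
        raise ValueError("temperatures must be positive")
    if any(b >= a for a, b in zip(ts, ts[1:])):
        raise ValueError("temperature schedule must be strictly decreasing")
    return ts


@dataclass
class GCMCParams:
    """Run parameters for grand-canonical annealing at fixed ``(mu1*, mu2*)``."""

    mu: ChemicalPotentials
    T_schedule: Sequence[float] = DEFAULT_SCHEDULE
    equil_steps: int = 10**5
    prod_steps: int = 10**6
    L: int = 60
    seed: int = 0
    snapshot_interval: int = 10**3
    record_interval: int = 100

    def __post_init__(self):
        self.T_schedule = _check_schedule(self.T_schedule)
        for name in ("equil_steps", "prod_steps", "snapshot_interval",
                     "record_interval"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class CanonicalParams:
    """Run parameters for canonical (fixed ``N1, N2``) annealing."""

    N1: int
    N2: int
    T_schedule: Sequence[float] = DEFAULT_SCHEDULE
    equil_steps: int = 10**4
    prod_steps: int = 10**5
    L: int = 60
    seed: int = 0
    snapshot_interval: int = 10**3
    record_interval: int = 100

    def __post_init__(self):
        self.T_schedule = _check_schedule(self.T_schedule)
        if self.N1 < 0 or self.N2 < 0 or self.N1 + self.N2 > self.L**2:
            raise ValueError("need 0 <= N1 + N2 <= L^2")
        if self.N1 + self.N2 == 0:
            raise ValueError("canonical run needs at least one particle")


@dataclass
class MCResult:
    """Outcome of an annealing run.

    ``series`` rows are ``(step, T, N1, N2, energy)`` sampled every
    ``record_interval`` MC steps; ``snapshots`` are configurations stored
    during the production period of the final (lowest) temperature.
    """

    final: LatticeConfiguration
    series: "np.ndarray"
    snapshots: list[LatticeConfiguration]
    params: object
    interaction: InteractionParams

    def series_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.series, columns=["step", "T", "N1", "N2", "energy"])


# ---------------------------------------------------------------------------
# python-level single moves (reference implementation, used by tests)
# ---------------------------------------------------------------------------

def gcmc_move(config: LatticeConfiguration, interaction: InteractionParams,
              mu: ChemicalPotentials, T: float, rng: np.random.Generator
              ) -> bool:
    """One attempted grand-canonical insertion/removal move, in place."""
    if T <= 0:
        raise ValueError("T must be positive")
    L = config.L
    site = (int(rng.integers(L)), int(rng.integers(L)))
    s = int(config.S[site])
    J = float(interaction.J)
    d1, d2 = local_field(config, site)
    if s == 0:
        spin = 1 if rng.random() < 0.5 else -1
        u = spin * (d1 - J * d2)
        mu_i = float(mu.mu1 if spin == 1 else mu.mu2)
        arg = (u + mu_i) / T
        if arg >= 0 or rng.random() < np.exp(arg):
            config.S[site] = spin
            return True
        return False
    u = s * (d1 - J * d2)
    mu_i = float(mu.mu1 if s == 1 else mu.mu2)
    arg = -(u + mu_i) / T
    if arg >= 0 or rng.random() < np.exp(arg):
        config.S[site] = 0
        return True
    return False


def canonical_move(config: LatticeConfiguration, interaction: InteractionParams,
                   T: float, rng: np.random.Generator) -> bool:
    """One attempted displacement of a random particle to a random
    first-shell site (rejected if the target is occupied), in place."""
    occ = np.argwhere(config.S != 0)
    if len(occ) == 0:
        raise ValueError("no particles to move")
    i, j = occ[rng.integers(len(occ))]
    src = (int(i), int(j))
    di, dj = FIRST_SHELL[rng.integers(6)]
    dst = config.lattice.wrap((src[0] + di, src[1] + dj))
    if config.S[dst] != 0:
        return False
    spin = int(config.S[src])
    species = 1 if spin == 1 else 2
    dE_remove = -insertion_energy_change(
        _without(config, src), src, species, interaction)
    config.S[src] = 0
    dE_insert = insertion_energy_change(config, dst, species, interaction)
    dE = float(dE_remove + dE_insert)
    if dE <= 0 or rng.random() < np.exp(-dE / T):
        config.S[dst] = spin
        return True
    config.S[src] = spin
    return False


def _without(config: LatticeConfiguration, site) -> LatticeConfiguration:
    out = config.copy()
    out.S[site] = 0
    return out


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=False, inline="always")
def _next_u64(rng):
    """xorshift64* pseudo-random draw; ``rng`` is a one-element uint64 array."""
    x = rng[0]
    x ^= x >> np.uint64(12)
    x ^= x << np.uint64(25)
    x ^= x >> np.uint64(27)
    rng[0] = x
    return x * np.uint64(2685821657736338717)


_INV53 = 1.0 / (1 << 53)


def _gc_tables(J: float, mu1: float, mu2: float, T: float):
    """Acceptance probabilities indexed by (spin, Delta1 + 6, Delta2 + 6).

    ``p_ins[0]`` is for species 1 (spin +1), ``p_ins[1]`` for species 2.
    """
    d = np.arange(-6, 7, dtype=float)
    D1, D2 = np.meshgrid(d, d, indexing="ij")
    p_ins = np.empty((2, 13, 13))
    p_rem = np.empty((2, 13, 13))
    for row, (spin, mu_i) in enumerate(((1.0, mu1), (-1.0, mu2))):
        u = spin * (D1 - J * D2)
        p_ins[row] = np.minimum(1.0, np.exp(np.minimum((u + mu_i) / T, 0.0)))
        p_rem[row] = np.minimum(1.0, np.exp(np.minimum(-(u + mu_i) / T, 0.0)))
    return p_ins, p_rem


@njit(cache=False)
def _run_gc_chunk(S, nb, p_ins, p_rem, n_moves, state, rng):
    """state = int64[q1, q3, N1, N2]; nb = (L^2, 12) first+third neighbours."""
    n = S.shape[0]
    acc = 0
    for _ in range(n_moves):
        r = _next_u64(rng)
        site = int((r >> np.uint64(12)) % np.uint64(n))
        d1 = 0
        d2 = 0
        for a in range(6):
            d1 += S[nb[site, a]]
            d2 += S[nb[site, a + 6]]
        s = S[site]
        if s == 0:
            spin = 1 if (r & np.uint64(1)) == 0 else -1
            p = p_ins[0 if spin == 1 else 1, d1 + 6, d2 + 6]
            if p >= 1.0 or (_next_u64(rng) >> np.uint64(11)) * _INV53 < p:
                S[site] = spin
                state[0] += spin * d1
                state[1] += spin * d2
                state[2 if spin == 1 else 3] += 1
                acc += 1
        else:
            p = p_rem[0 if s == 1 else 1, d1 + 6, d2 + 6]
            if p >= 1.0 or (_next_u64(rng) >> np.uint64(11)) * _INV53 < p:
                S[site] = 0
                state[0] -= s * d1
                state[1] -= s * d2
                state[2 if s == 1 else 3] -= 1
                acc += 1
    return acc


@njit(cache=False)
def _run_canon_chunk(S, nb, part, J, T, n_moves, state, rng):
    """Displacement moves; ``part`` holds the flat site index per particle."""
    npart = part.shape[0]
    acc = 0
    for _ in range(n_moves):
        r = _next_u64(rng)
        idx = int((r >> np.uint64(12)) % np.uint64(npart))
        src = part[idx]
        dst = nb[src, int(r % np.uint64(6))]
        if S[dst] != 0:
            continue
        spin = S[src]
        d1o = 0
        d2o = 0
        for a in range(6):
            d1o += S[nb[src, a]]
            d2o += S[nb[src, a + 6]]
        S[src] = 0
        d1n = 0
        d2n = 0
        for a in range(6):
            d1n += S[nb[dst, a]]
            d2n += S[nb[dst, a + 6]]
        # dE = u_old - u_new with u = spin * (Delta1 - J*Delta2)
        dE = spin * ((d1o - d1n) - J * (d2o - d2n))
        if dE <= 0.0 or (_next_u64(rng) >> np.uint64(11)) * _INV53 < np.exp(-dE / T):
            S[dst] = spin
            part[idx] = dst
            state[0] += spin * (d1n - d1o)
            state[1] += spin * (d2n - d2o)
            acc += 1
        else:
            S[src] = spin
    return acc


# ---------------------------------------------------------------------------
# annealing drivers
# ---------------------------------------------------------------------------

def _initial_state(S_flat, nb1, nb3):
    q1 = 0
    q3 = 0
    for a in range(3):
        q1 += int(np.sum(S_flat * S_flat[nb1[:, a]]))
        q3 += int(np.sum(S_flat * S_flat[nb3[:, a]]))
    return np.array([q1, q3,
                     int(np.count_nonzero(S_flat == 1)),
                     int(np.count_nonzero(S_flat == -1))], dtype=np.int64)


def _anneal(S_flat, nb1, nb3, interaction, params, mu, grand: bool):
    L2 = S_flat.shape[0]
    J = float(interaction.J)
    rec = params.record_interval
    state = _initial_state(S_flat, nb1, nb3)
    nb = np.concatenate([nb1, nb3], axis=1)
    part = None
    if not grand:
        part = np.flatnonzero(S_flat != 0).astype(np.int32)
    rng = np.array([(params.seed % 2**31) * 2654435761 + 0x9E3779B9],
                   dtype=np.uint64)
    rows = []
    snapshots = []
    L = int(np.sqrt(L2))
    step = 0
    final_T = params.T_schedule[-1]
    for T in params.T_schedule:
        if grand:
            p_ins, p_rem = _gc_tables(J, float(mu.mu1), float(mu.mu2), T)
        for stage, n_steps in (("equil", params.equil_steps),
                               ("prod", params.prod_steps)):
            done = 0
            while done < n_steps:
                chunk = min(rec, n_steps - done)
                if grand:
                    _run_gc_chunk(S_flat, nb, p_ins, p_rem, chunk * L2,
                                  state, rng)
                else:
                    _run_canon_chunk(S_flat, nb, part, J, T, chunk * L2,
                                     state, rng)
                done += chunk
                step += chunk
                E = -state[0] + J * state[1]
                rows.append((step, T, int(state[2]), int(state[3]), E))
                if (stage == "prod" and T == final_T
                        and done % params.snapshot_interval == 0):
                    snapshots.append(LatticeConfiguration(
                        TriangularLattice(L), S_flat.reshape(L, L).copy()))
    final = LatticeConfiguration(TriangularLattice(L), S_flat.reshape(L, L).copy())
    return final, np.array(rows, dtype=float), snapshots


def anneal_gcmc(params: GCMCParams, interaction: InteractionParams) -> MCResult:
    """Grand-canonical annealing from an empty lattice through the schedule.

    Returns the final configuration, the ``(step, T, N1, N2, E)`` time series
    and the configurations stored during production at the final temperature.
    """
    nb1, nb3 = build_neighbor_tables(params.L)
    S = np.zeros(params.L * params.L, dtype=np.int8)
    final, series, snaps = _anneal(S, nb1, nb3, interaction, params,
                                   params.mu, grand=True)
    return MCResult(final, series, snaps, params, interaction)


def anneal_canonical(params: CanonicalParams, interaction: InteractionParams,
                     initial: LatticeConfiguration | None = None) -> MCResult:
    """Canonical annealing of ``N1 + N2`` particles through the schedule.

    Starts from ``initial`` or from a uniformly random non-overlapping
    placement; particle numbers are conserved exactly.
    """
    nb1, nb3 = build_neighbor_tables(params.L)
    if initial is not None:
        if initial.N1 != params.N1 or initial.N2 != params.N2:
            raise ValueError("initial configuration has wrong particle numbers")
        S = initial.S.ravel().astype(np.int8).copy()
    else:
        rng = np.random.default_rng(params.seed)
        sites = rng.choice(params.L**2, size=params.N1 + params.N2, replace=False)
        S = np.zeros(params.L * params.L, dtype=np.int8)
        S[sites[:params.N1]] = 1
        S[sites[params.N1:]] = -1
    final, series, snaps = _anneal(S, nb1, nb3, interaction, params, None,
                                   grand=False)
    return MCResult(final, series, snaps, params, interaction)
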