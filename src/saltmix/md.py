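"""Desk-scale molecular dynamics of the continuous binary mixture.

Like particles attract at contact and repel at long range through a screened
Coulomb tail; unlike particles do the opposite:

    V11(r) = 6 eps [ r^-12 - r^-6 + 0.3 e^(-r/2) / r ]
    V22(r) = V11(r) / q^2
    V12(r) = 6 eps [ r^-12 + r^-6 - 0.3 e^(-r/2) / r ] / q

with ``r`` in particle diameters, truncated (unshifted) at ``r = 6.75``.  The
charge-asymmetry ratio ``q`` scales the species-2 self-interaction by ``1/q^2``
and the cross-interaction by ``1/q``.  Particles live in a box periodic in
``x, y`` and bounded by walls in ``z``: a repulsive wall ``2 eps/(z-zw)^12``
and, for adsorption studies, an attractive wall ``4 eps (z^-12 - z^-6)``
acting on species 1 only or on both species.

Integration is velocity-Verlet (unit mass, default dt = 0.004) with forces
from an x-y cell list; temperature is imposed by periodic velocity rescaling,
optionally in z-zones during the initial stage of adsorption runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

__all__ = [
    "R_CUT",
    "ContinuousPotentialParams",
    "WallSpec",
    "MDSystem",
    "pair_potential",
    "pair_force",
    "wall_potential",
    "wall_force",
    "random_system",
    "step",
    "run_nve",
    "run_slit",
    "run_adsorption_scaled",
    "potential_energy",
    "kinetic_temperature",
    "largest_cluster_fraction",
]

#: Pair-interaction cutoff, in particle diameters.
R_CUT = 6.75

# wall modes
WALL_REPULSIVE = 0        # Eq.-6 wall on both species
WALL_ATTRACT_SP1 = 1      # attractive for species 1, repulsive for species 2
WALL_ATTRACT_BOTH = 2     # attractive for both species


@dataclass(frozen=True)
class ContinuousPotentialParams:
    """eps is the energy unit; q in (0, 1] is the charge-asymmetry ratio."""

    epsilon: float = 1.0
    q: float = 1.0
    r_cut: float = R_CUT

    def __post_init__(self):
        if not 0 < self.q <= 1:
            raise ValueError("q must be in (0, 1]")
        if self.r_cut <= 0 or self.epsilon <= 0:
            raise ValueError("epsilon and r_cut must be positive")


@dataclass(frozen=True)
class WallSpec:
    """Wall at z = 0 (``bottom``) and repulsive wall at z = Lz (``top``)."""

    bottom: int = WALL_REPULSIVE

    def __post_init__(self):
        if self.bottom not in (WALL_REPULSIVE, WALL_ATTRACT_SP1,
                               WALL_ATTRACT_BOTH):
            raise ValueError("unknown wall mode")


# ---------------------------------------------------------------------------
# potentials (python reference; the kernels inline the same formulas)
# ---------------------------------------------------------------------------

def _v_like(r, eps):
    return 6.0 * eps * (r**-12 - r**-6 + 0.3 * np.exp(-r / 2) / r)


def _v_unlike(r, eps):
    return 6.0 * eps * (r**-12 + r**-6 - 0.3 * np.exp(-r / 2) / r)


def pair_potential(r, species_i: int, species_j: int,
                   params: ContinuousPotentialParams = ContinuousPotentialParams()):
    """Pair energy in eps units; zero at and beyond the cutoff."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    if species_i not in (1, 2) or species_j not in (1, 2):
        raise ValueError("species must be 1 or 2")
    eps = params.epsilon
    if species_i == species_j:
        v = _v_like(r, eps)
        if species_i == 2:
            v = v / params.q**2
    else:
        v = _v_unlike(r, eps) / params.q
    return np.where(r < params.r_cut, v, 0.0)[()]


def pair_force(r, species_i: int, species_j: int,
               params: ContinuousPotentialParams = ContinuousPotentialParams()):
    """Radial force magnitude ``-dV/dr`` (positive = repulsive)."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    eps = params.epsilon
    yuk = 0.3 * np.exp(-r / 2) * (1.0 / (2 * r) + 1.0 / r**2)
    if species_i == species_j:
        dv = 6.0 * eps * (-12 * r**-13 + 6 * r**-7 - yuk)
        if species_i == 2:
            dv = dv / params.q**2
    else:
        dv = 6.0 * eps * (-12 * r**-13 - 6 * r**-7 + yuk) / params.q
    return np.where(r < params.r_cut, -dv, 0.0)[()]


def wall_potential(z, species: int, wall: WallSpec, Lz: float,
                   eps: float = 1.0):
    """Total wall energy of a particle at height ``z`` in the slab."""
    z = np.asarray(z, dtype=float)
    if np.any((z <= 0) | (z >= Lz)):
        raise ValueError("z must lie strictly inside (0, Lz)")
    top = 2.0 * eps / (z - Lz) ** 12
    if wall.bottom == WALL_REPULSIVE or (
            wall.bottom == WALL_ATTRACT_SP1 and species == 2):
        bottom = 2.0 * eps / z**12
    else:
        bottom = 4.0 * eps * (z**-12 - z**-6)
    return (top + bottom)[()]


def wall_force(z, species: int, wall: WallSpec, Lz: float, eps: float = 1.0):
    """z-component of the wall force."""
    z = np.asarray(z, dtype=float)
    f_top = 24.0 * eps / (z - Lz) ** 13
    if wall.bottom == WALL_REPULSIVE or (
            wall.bottom == WALL_ATTRACT_SP1 and species == 2):
        f_bot = 24.0 * eps / z**13
    else:
        f_bot = 4.0 * eps * (12 * z**-13 - 6 * z**-7)
    return (f_top + f_bot)[()]


# ---------------------------------------------------------------------------
# system container
# ---------------------------------------------------------------------------

@dataclass
class MDSystem:
    """Particle state in a box periodic in x, y and walled in z."""

    positions: np.ndarray      # (N, 3)
    velocities: np.ndarray     # (N, 3)
    species: np.ndarray        # (N,) in {1, 2}
    box: tuple[float, float, float]
    wall: WallSpec = field(default_factory=WallSpec)
    params: ContinuousPotentialParams = field(
        default_factory=ContinuousPotentialParams)
    T_target: float = 0.1
    dt: float = 0.004
    rescale_interval: int = 50
    time: float = 0.0

    def __post_init__(self):
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=np.float64)
        self.species = np.ascontiguousarray(self.species, dtype=np.int8)
        N = len(self.positions)
        if self.velocities.shape != (N, 3) or self.species.shape != (N,):
            raise ValueError("inconsistent array shapes")
        if not np.isin(self.species, (1, 2)).all():
            raise ValueError("species must be 1 or 2")
        Lz = self.box[2]
        if np.any((self.positions[:, 2] <= 0) | (self.positions[:, 2] >= Lz)):
            raise ValueError("all particles must satisfy 0 < z < Lz")

    @property
    def N(self) -> int:
        return len(self.positions)

    @property
    def N1(self) -> int:
        return int(np.count_nonzero(self.species == 1))

    @property
    def N2(self) -> int:
        return int(np.count_nonzero(self.species == 2))

    def copy(self) -> "MDSystem":
        return replace(self, positions=self.positions.copy(),
                       velocities=self.velocities.copy(),
                       species=self.species.copy())


def kinetic_temperature(system: MDSystem) -> float:
    """Instantaneous kinetic temperature (kB = 1, unit mass, 3 dof/particle)."""
    v2 = float(np.sum(system.velocities**2))
    return v2 / (3 * system.N)


def random_system(N1: int, N2: int, box, T: float, seed: int = 0,
                  q: float = 1.0, wall: WallSpec | None = None,
                  min_dist: float = 0.95, z_range=None) -> MDSystem:
    """Random non-overlapping initial configuration with Maxwell velocities."""
    rng = np.random.default_rng(seed)
    Lx, Ly, Lz = box
    lo, hi = z_range if z_range is not None else (0.8, Lz - 0.8)
    if hi <= lo:
        lo, hi = 0.3 * Lz, 0.7 * Lz
    N = N1 + N2
    pos = np.empty((N, 3))
    n = 0
    tries = 0
    while n < N:
        p = np.array([rng.uniform(0, Lx), rng.uniform(0, Ly),
                      rng.uniform(lo, hi)])
        d = pos[:n] - p
        d[:, 0] -= Lx * np.round(d[:, 0] / Lx)
        d[:, 1] -= Ly * np.round(d[:, 1] / Ly)
        if n == 0 or np.min(np.sum(d * d, axis=1)) > min_dist**2:
            pos[n] = p
            n += 1
        tries += 1
        if tries > 1000 * N:
            raise RuntimeError("random placement failed; box too dense")
    vel = rng.normal(0.0, np.sqrt(T), size=(N, 3))
    vel -= vel.mean(axis=0)
    species = np.array([1] * N1 + [2] * N2, dtype=np.int8)
    sys_ = MDSystem(pos, vel, species, tuple(float(b) for b in box),
                    wall or WallSpec(),
                    ContinuousPotentialParams(q=q), T_target=T)
    _rescale(sys_)
    return sys_


# ---------------------------------------------------------------------------
# force kernel (cell list over x, y)
# ---------------------------------------------------------------------------

@njit(cache=False)
def _pair_v_f(r, like2, cross, inv_q2, inv_q):
    """(V, -dV/dr) for one pair; like2/cross select the species combination."""
    inv_r = 1.0 / r
    ir6 = inv_r**6
    ir12 = ir6 * ir6
    yk = 0.3 * np.exp(-0.5 * r) * inv_r
    dyk = 0.3 * np.exp(-0.5 * r) * (0.5 * inv_r + inv_r * inv_r)
    if cross:
        v = 6.0 * (ir12 + ir6 - yk) * inv_q
        f = 6.0 * (12.0 * ir12 * inv_r + 6.0 * ir6 * inv_r - dyk) * inv_q
    else:
        scale = inv_q2 if like2 else 1.0
        v = 6.0 * (ir12 - ir6 + yk) * scale
        f = 6.0 * (12.0 * ir12 * inv_r - 6.0 * ir6 * inv_r + dyk) * scale
    return v, f


@njit(cache=False)
def _forces(pos, spec, Lx, Ly, Lz, q, eps, r_cut, wall_mode, F,
            heads, nxt, nx, ny):
    """Pair + wall forces; returns (Epot, Eshift, min_pair_dist2).

    ``Epot`` is the truncated-unshifted energy.  The dynamics generated by the
    truncated forces conserves the *shifted* energy ``Epot - Eshift``, where
    ``Eshift`` sums ``V(r_cut)`` over the in-range pairs; ``run_nve`` uses the
    shifted energy as its conservation diagnostic.
    """
    N = pos.shape[0]
    for i in range(N):
        F[i, 0] = 0.0
        F[i, 1] = 0.0
        F[i, 2] = 0.0
    inv_q2 = 1.0 / (q * q)
    inv_q = 1.0 / q
    rc2 = r_cut * r_cut
    epot = 0.0
    eshift = 0.0
    vc11, _ = _pair_v_f(r_cut, False, False, inv_q2, inv_q)
    vc22, _ = _pair_v_f(r_cut, True, False, inv_q2, inv_q)
    vc12, _ = _pair_v_f(r_cut, False, True, inv_q2, inv_q)
    min_d2 = 1e30
    cw = Lx / nx
    ch = Ly / ny
    for i in range(N):
        xi = pos[i, 0]
        yi = pos[i, 1]
        zi = pos[i, 2]
        si = spec[i]
        cxi = int(xi / cw) % nx
        cyi = int(yi / ch) % ny
        # offset ranges collapse when there are fewer than 3 cells per axis,
        # so each neighbouring cell is visited exactly once
        ox_lo = -1 if nx >= 3 else 0
        ox_hi = 2 if nx >= 3 else nx
        oy_lo = -1 if ny >= 3 else 0
        oy_hi = 2 if ny >= 3 else ny
        for ox in range(ox_lo, ox_hi):
            for oy in range(oy_lo, oy_hi):
                cell = ((cxi + ox) % nx) * ny + ((cyi + oy) % ny)
                j = heads[cell]
                while j >= 0:
                    if j > i:
                        dx = xi - pos[j, 0]
                        dy = yi - pos[j, 1]
                        dz = zi - pos[j, 2]
                        dx -= Lx * np.rint(dx / Lx)
                        dy -= Ly * np.rint(dy / Ly)
                        d2 = dx * dx + dy * dy + dz * dz
                        if d2 < min_d2:
                            min_d2 = d2
                        if d2 < rc2:
                            r = np.sqrt(d2)
                            cross = si != spec[j]
                            like2 = si == 2
                            v, f = _pair_v_f(r, like2, cross, inv_q2, inv_q)
                            v *= eps
                            f *= eps
                            epot += v
                            if cross:
                                eshift += eps * vc12
                            elif like2:
                                eshift += eps * vc22
                            else:
                                eshift += eps * vc11
                            fx = f * dx / r
                            fy = f * dy / r
                            fz = f * dz / r
                            F[i, 0] += fx
                            F[i, 1] += fy
                            F[i, 2] += fz
                            F[j, 0] -= fx
                            F[j, 1] -= fy
                            F[j, 2] -= fz
                    j = nxt[j]
        # walls
        zt = zi - Lz
        epot += 2.0 * eps / zt**12
        F[i, 2] += 24.0 * eps / zt**13
        attract = (wall_mode == 2) or (wall_mode == 1 and si == 1)
        if attract:
            epot += 4.0 * eps * (zi**-12 - zi**-6)
            F[i, 2] += 4.0 * eps * (12.0 * zi**-13 - 6.0 * zi**-7)
        else:
            epot += 2.0 * eps / zi**12
            F[i, 2] += 24.0 * eps / zi**13
    return epot, eshift, min_d2


@njit(cache=False)
def _build_cells(pos, Lx, Ly, nx, ny, heads, nxt):
    for c in range(heads.shape[0]):
        heads[c] = -1
    N = pos.shape[0]
    cw = Lx / nx
    ch = Ly / ny
    for i in range(N):
        cx = int(pos[i, 0] / cw) % nx
        cy = int(pos[i, 1] / ch) % ny
        cell = cx * ny + cy
        nxt[i] = heads[cell]
        heads[cell] = i


class _ForceWorkspace:
    def __init__(self, system: MDSystem):
        N = system.N
        Lx, Ly, _ = system.box
        rc = system.params.r_cut
        self.nx = max(1, int(Lx / rc))
        self.ny = max(1, int(Ly / rc))
        if self.nx < 3 or self.ny < 3:
            # cells would self-overlap through the periodic images; fall back
            # to a single cell (all-pairs) which is always correct
            self.nx = 1
            self.ny = 1
        self.heads = np.empty(self.nx * self.ny, dtype=np.int64)
        self.nxt = np.empty(N, dtype=np.int64)
        self.F = np.zeros((N, 3))


def _compute_forces(system: MDSystem, ws: _ForceWorkspace):
    Lx, Ly, Lz = system.box
    _build_cells(system.positions, Lx, Ly, ws.nx, ws.ny, ws.heads, ws.nxt)
    epot, eshift, min_d2 = _forces(
        system.positions, system.species, Lx, Ly, Lz,
        system.params.q, system.params.epsilon, system.params.r_cut,
        system.wall.bottom, ws.F, ws.heads, ws.nxt, ws.nx, ws.ny)
    return epot, eshift, min_d2


def potential_energy(system: MDSystem) -> float:
    """Total potential energy (pairs + walls), in eps units."""
    ws = _ForceWorkspace(system)
    epot, _, _ = _compute_forces(system, ws)
    return float(epot)


def _rescale(system: MDSystem, zones=None):
    """Scale velocities so the kinetic temperature matches the target.

    ``zones`` is an optional list of ``(z_lo, z_hi, T)``; particles are
    rescaled per zone (used in the initial stage of adsorption runs).
    """
    if zones is None:
        zones = [(-np.inf, np.inf, system.T_target)]
    z = system.positions[:, 2]
    for z_lo, z_hi, T in zones:
        m = (z >= z_lo) & (z < z_hi)
        n = int(np.count_nonzero(m))
        if n == 0:
            continue
        v2 = float(np.sum(system.velocities[m] ** 2))
        if v2 == 0:
            continue
        system.velocities[m] *= np.sqrt(3 * n * T / v2)


class MDIntegrator:
    """Velocity-Verlet propagator bound to one system."""

    def __init__(self, system: MDSystem):
        self.system = system
        self.ws = _ForceWorkspace(system)
        self.epot, self.eshift, self._min_d2 = _compute_forces(system, self.ws)
        self.n_steps = 0

    def step(self, n: int = 1, thermostat: bool = True, zones=None):
        sys_ = self.system
        dt = sys_.dt
        for _ in range(n):
            sys_.velocities += 0.5 * dt * self.ws.F
            sys_.positions += dt * sys_.velocities
            sys_.positions[:, 0] %= sys_.box[0]
            sys_.positions[:, 1] %= sys_.box[1]
            self.epot, self.eshift, min_d2 = _compute_forces(sys_, self.ws)
            sys_.velocities += 0.5 * dt * self.ws.F
            sys_.time += dt
            self.n_steps += 1
            z = sys_.positions[:, 2]
            if min_d2 < 0.25 or np.any(z <= 0) or np.any(z >= sys_.box[2]):
                raise RuntimeError(
                    f"integration unstable at step {self.n_steps}: "
                    f"min pair distance {np.sqrt(max(min_d2, 0)):.3f}, "
                    f"z range [{z.min():.3f}, {z.max():.3f}]; reduce dt or T")
            if thermostat and self.n_steps % sys_.rescale_interval == 0:
                _rescale(sys_, zones)
        return self


def step(system: MDSystem, n: int = 1, thermostat: bool = True) -> MDSystem:
    """Advance ``system`` by ``n`` velocity-Verlet steps (in place)."""
    MDIntegrator(system).step(n, thermostat=thermostat)
    return system


def run_nve(system: MDSystem, n_steps: int) -> dict:
    """Integrate without thermostatting; returns energy-drift diagnostics.

    The conservation diagnostic uses the shifted potential (the Hamiltonian of
    the truncated-force dynamics); the unshifted energy jumps discontinuously
    whenever a pair crosses the cutoff and is reported separately.
    """
    integ = MDIntegrator(system)

    def shifted_total():
        return (integ.epot - integ.eshift
                + 1.5 * system.N * kinetic_temperature(system))

    e0 = shifted_total()
    emin = emax = e0
    for _ in range(n_steps):
        integ.step(1, thermostat=False)
        e = shifted_total()
        emin = min(emin, e)
        emax = max(emax, e)
    scale = max(abs(e0), 1.0)
    return {"E0": e0, "E_final": e, "max_drift": (emax - emin) / scale,
            "epot_unshifted": integ.epot}


# ---------------------------------------------------------------------------
# workflows
# ---------------------------------------------------------------------------

@dataclass
class MDTrajectory:
    """Snapshots (copies of the system) plus per-sample scalars."""

    snapshots: list[MDSystem]
    steps: list[int]
    epot: list[float]

    @property
    def final(self) -> MDSystem:
        return self.snapshots[-1]


def run_slit(N1: int = 200, N2: int = 200, q: float = 1.0, T: float = 0.12,
             box=(150.0, 150.0, 4.0), n_steps: int = 10**5,
             anneal_from: float = 0.5, seed: int = 0,
             snapshot_interval: int = 10**4) -> MDTrajectory:
    """Self-assembly between two repulsive walls (``Lz = 4`` by default).

    The run anneals from ``anneal_from`` down to ``T`` over the first third of
    the steps, then holds ``T`` constant; snapshots are stored periodically.
    """
    system = random_system(N1, N2, box, anneal_from, seed=seed, q=q,
                           wall=WallSpec(WALL_REPULSIVE))
    system.T_target = anneal_from
    integ = MDIntegrator(system)
    traj = MDTrajectory([], [], [])
    n_anneal = n_steps // 3
    ladder = np.geomspace(anneal_from, T, 6)
    for i, Ti in enumerate(ladder):
        system.T_target = float(Ti)
        integ.step(max(1, n_anneal // len(ladder)))
    system.T_target = T
    done = integ.n_steps
    while done < n_steps:
        chunk = min(snapshot_interval, n_steps - done)
        integ.step(chunk)
        done = integ.n_steps
        traj.snapshots.append(system.copy())
        traj.steps.append(done)
        traj.epot.append(integ.epot)
    return traj


def run_adsorption_scaled(N1: int, N2: int, q: float, T_final: float,
                          box=(40.0, 40.0, 80.0), wall: WallSpec | None = None,
                          n_steps: int = 10**5, seed: int = 0,
                          snapshot_interval: int = 10**4,
                          zones=None) -> MDTrajectory:
    """Adsorption at a wall, at reduced particle number and box.

    Enforces the charge-neutrality condition ``N1 = q * N2``; the initial
    stage uses a zoned thermostat (hotter far from the wall), after which the
    whole box is cooled to ``T_final``.
    """
    if N1 + N2 > 2000:
        raise ValueError(
            "N1 + N2 > 2000 is outside the scaled adsorption mode; "
            "full-scale adsorption runs are a non-goal")
    if abs(N1 - q * N2) > 0.5:
        raise ValueError(f"charge neutrality requires N1 = q*N2 "
                         f"(got N1={N1}, q*N2={q * N2:g})")
    wall = wall or WallSpec(WALL_ATTRACT_BOTH)
    Lz = box[2]
    if zones is None:
        zones = [(0.0, 0.1 * Lz, 0.04), (0.1 * Lz, 0.4 * Lz, 0.13),
                 (0.4 * Lz, np.inf, 0.17)]
    system = random_system(N1, N2, box, max(z[2] for z in zones), seed=seed,
                           q=q, wall=wall, z_range=(1.0, 0.6 * Lz))
    integ = MDIntegrator(system)
    traj = MDTrajectory([], [], [])
    n_zoned = n_steps // 3
    integ.step(n_zoned, zones=zones)
    system.T_target = T_final
    done = integ.n_steps
    while done < n_steps:
        chunk = min(snapshot_interval, n_steps - done)
        integ.step(chunk)
        done = integ.n_steps
        traj.snapshots.append(system.copy())
        traj.steps.append(done)
        traj.epot.append(integ.epot)
    return traj


def monolayer(system: MDSystem, z_center: float, thickness: float = 1.0):
    """Positions and species of particles in a slab of given thickness."""
    z = system.positions[:, 2]
    m = np.abs(z - z_center) <= thickness / 2
    return system.positions[m], system.species[m]


def largest_cluster_fraction(system: MDSystem, cutoff: float = 2.0) -> float:
    """Fraction of particles in the largest distance-``cutoff`` component."""
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    pos = system.positions
    N = len(pos)
    if N == 0:
        return 0.0
    Lx, Ly, _ = system.box
    d = pos[:, None, :] - pos[None, :, :]
    d[..., 0] -= Lx * np.round(d[..., 0] / Lx)
    d[..., 1] -= Ly * np.round(d[..., 1] / Ly)
    adj = (d**2).sum(-1) <= cutoff**2
    np.fill_diagonal(adj, False)
    ii, jj = np.nonzero(adj)
    g = coo_matrix((np.ones(len(ii)), (ii, jj)), shape=(N, N))
    _, labels = connected_components(g, directed=False)
    return int(np.bincount(labels).max()) / N
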