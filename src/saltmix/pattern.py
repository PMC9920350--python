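"""Classification of configurations into the catalog phases.

The paper-style identification of phases is visual; here each configuration is
reduced to an order-parameter fingerprint

    (rho1, rho2, f_like_nn, f_unlike_nn, f_like_3rd, f_unlike_3rd)

where ``rho_i`` are species densities and ``f_*`` are the fractions of the
``3 L^2`` first-shell (third-shell) site pairs occupied by like / unlike
particle pairs.  Every catalog phase has an exact fingerprint computable from
its unit cell; a configuration is assigned to the nearest catalog phase in
fingerprint space, or reported as disordered/mixed when nothing is within the
distance threshold (default 0.15, which separates all catalog fingerprints at
a comfortable margin).

Cluster structure is quantified separately: connected components of the
like-species first-shell adjacency graph (cluster-size histogram) and of the
"mixed" graph joining particles within Euclidean distance 2 (rafts).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import ConvexHull, QhullError

from .catalog import CATALOG, PhaseDefinition, tile_phase
from .lattice import (
    FIRST_SHELL,
    SECOND_SHELL,
    THIRD_SHELL,
    LatticeConfiguration,
    axial_to_xy,
)

__all__ = [
    "OrderParameters",
    "order_parameters",
    "phase_fingerprints",
    "classify",
    "Classification",
    "raft_report",
    "RaftReport",
    "CONTACT_THRESHOLD",
]

#: Continuous-to-lattice contact threshold, in particle diameters: pairs
#: closer than this count as "nearest" contacts (between the first and second
#: coordination distances of the dense liquid).
CONTACT_THRESHOLD = 1.35

#: All 18 offsets within Euclidean distance 2 (first + second + third shells).
_WITHIN_2 = FIRST_SHELL + SECOND_SHELL + THIRD_SHELL


@dataclass(frozen=True)
class OrderParameters:
    """Fingerprint and cluster structure of one configuration."""

    rho1: float
    rho2: float
    f_like_nn: float
    f_unlike_nn: float
    f_like_3rd: float
    f_unlike_3rd: float
    cluster_sizes: tuple[tuple[int, int], ...]  # (size, count) histogram
    largest_mixed_fraction: float

    @property
    def fingerprint(self) -> np.ndarray:
        return np.array([self.rho1, self.rho2, self.f_like_nn, self.f_unlike_nn,
                         self.f_like_3rd, self.f_unlike_3rd])


def _pair_counts(S: np.ndarray, offsets) -> tuple[int, int]:
    """(like, unlike) occupied-pair counts over half of ``offsets``."""
    like = unlike = 0
    for di, dj in offsets[:3]:
        P = S * np.roll(S, (-di, -dj), axis=(0, 1))
        like += int(np.count_nonzero(P == 1))
        unlike += int(np.count_nonzero(P == -1))
    return like, unlike


def _components(config: LatticeConfiguration, offsets, like_only: bool):
    """Connected-component labels over occupied sites."""
    S = config.S
    L = config.L
    occ = np.argwhere(S != 0)
    n = len(occ)
    if n == 0:
        return np.zeros(0, dtype=int), occ
    index = -np.ones((L, L), dtype=np.int64)
    index[occ[:, 0], occ[:, 1]] = np.arange(n)
    rows = []
    cols = []
    for di, dj in offsets:
        ni = (occ[:, 0] + di) % L
        nj = (occ[:, 1] + dj) % L
        tgt = index[ni, nj]
        ok = tgt >= 0
        if like_only:
            ok &= S[occ[:, 0], occ[:, 1]] == S[ni, nj]
        rows.append(np.arange(n)[ok])
        cols.append(tgt[ok])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    graph = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    _, labels = connected_components(graph, directed=False)
    return labels, occ


def order_parameters(config: LatticeConfiguration) -> OrderParameters:
    """Exact order parameters of a lattice configuration."""
    S = config.S.astype(np.int64)
    n_sites = config.lattice.n_sites
    pair_slots = 3 * n_sites
    l1, u1 = _pair_counts(S, FIRST_SHELL)
    l3, u3 = _pair_counts(S, THIRD_SHELL)
    labels, _ = _components(config, FIRST_SHELL, like_only=True)
    if len(labels):
        sizes = np.bincount(labels)
        hist: dict[int, int] = {}
        for s in sizes:
            hist[int(s)] = hist.get(int(s), 0) + 1
        cluster_sizes = tuple(sorted(hist.items()))
    else:
        cluster_sizes = ()
    mixed_labels, _ = _components(config, _WITHIN_2, like_only=False)
    if len(mixed_labels):
        largest = int(np.bincount(mixed_labels).max())
        frac = largest / len(mixed_labels)
    else:
        frac = 0.0
    return OrderParameters(
        rho1=config.N1 / n_sites,
        rho2=config.N2 / n_sites,
        f_like_nn=l1 / pair_slots,
        f_unlike_nn=u1 / pair_slots,
        f_like_3rd=l3 / pair_slots,
        f_unlike_3rd=u3 / pair_slots,
        cluster_sizes=cluster_sizes,
        largest_mixed_fraction=frac,
    )


@lru_cache(maxsize=None)
def phase_fingerprints() -> dict[str, np.ndarray]:
    """Exact fingerprints of every catalog phase that has a unit cell."""
    out = {}
    for name, phase in CATALOG.items():
        if not phase.has_cell:
            continue
        d1, d2, k = phase.hnf
        # smallest torus the cell tiles, large enough for the shells
        L = d1 * d2
        while L < 5 or L % d1 or L % d2 or ((L // d2) * k) % d1:
            L += d1 * d2
        op = order_parameters(tile_phase(name, L))
        out[name] = op.fingerprint
    return out


@dataclass(frozen=True)
class Classification:
    label: str
    distance: float
    fingerprint: np.ndarray
    distances: tuple[tuple[str, float], ...]

    @property
    def confidence(self) -> float:
        """1 at an ideal fixture, 0 at the disorder threshold."""
        return max(0.0, 1.0 - self.distance / 0.15)


def classify(config: LatticeConfiguration, catalog=None,
             threshold: float = 0.15) -> Classification:
    """Assign a configuration to the nearest catalog phase.

    Returns the joint label ``cc/zz``-style only implicitly: cc and zz have
    distinct fingerprints (clusters vs chains) and are reported individually.
    Configurations farther than ``threshold`` from every phase are labeled
    ``"disordered/mixed"``.
    """
    fps = phase_fingerprints()
    if catalog is not None:
        names = {p.name if isinstance(p, PhaseDefinition) else p for p in catalog}
        fps = {n: f for n, f in fps.items() if n in names}
    fp = order_parameters(config).fingerprint
    dists = sorted(((n, float(np.linalg.norm(fp - f))) for n, f in fps.items()),
                   key=lambda t: t[1])
    best, dmin = dists[0]
    label = best if dmin <= threshold else "disordered/mixed"
    return Classification(label, dmin, fp, tuple(dists))


@dataclass(frozen=True)
class RaftReport:
    """Connected 'rafts' (distance <= 2 components) of a configuration."""

    n_rafts: int
    sizes: tuple[int, ...]
    porosity: tuple[float, ...]

    @property
    def largest_fraction(self) -> float:
        total = sum(self.sizes)
        return max(self.sizes) / total if total else 0.0


def _unwrap(occ: np.ndarray, labels: np.ndarray, lab: int, L: int) -> np.ndarray:
    """Unwrap one component across the periodic boundary by BFS."""
    members = np.nonzero(labels == lab)[0]
    index = {tuple(occ[m]): m for m in members}
    pos = {}
    seed = members[0]
    pos[seed] = np.array(occ[seed], dtype=np.int64)
    stack = [seed]
    while stack:
        m = stack.pop()
        i, j = occ[m]
        for di, dj in _WITHIN_2:
            key = ((i + di) % L, (j + dj) % L)
            t = index.get(key)
            if t is not None and t not in pos:
                pos[t] = pos[m] + (di, dj)
                stack.append(t)
    return np.array([pos[m] for m in members])


def raft_report(config: LatticeConfiguration) -> RaftReport:
    """Rafts (components of the distance-<=2 particle graph) and porosity.

    Porosity of a raft is the fraction of lattice sites inside its convex
    hull (in the Euclidean embedding) that are empty.
    """
    labels, occ = _components(config, _WITHIN_2, like_only=False)
    if len(labels) == 0:
        return RaftReport(0, (), ())
    L = config.L
    sizes = []
    porosity = []
    for lab in range(labels.max() + 1):
        axial = _unwrap(occ, labels, lab, L)
        sizes.append(len(axial))
        porosity.append(_hull_porosity(axial, config))
    order = np.argsort(sizes)[::-1]
    return RaftReport(len(sizes), tuple(int(sizes[o]) for o in order),
                      tuple(float(porosity[o]) for o in order))


def _hull_porosity(axial: np.ndarray, config: LatticeConfiguration) -> float:
    if len(axial) < 3:
        return 0.0
    x, y = axial_to_xy(axial[:, 0], axial[:, 1])
    pts = np.column_stack([x, y])
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return 0.0
    # candidate axial sites inside the hull's bounding box
    i0, i1 = axial[:, 0].min(), axial[:, 0].max()
    j0, j1 = axial[:, 1].min(), axial[:, 1].max()
    ii, jj = np.meshgrid(np.arange(i0 - 1, i1 + 2), np.arange(j0 - 1, j1 + 2),
                         indexing="ij")
    cx, cy = axial_to_xy(ii.ravel(), jj.ravel())
    cand = np.column_stack([cx, cy])
    # inside test against hull facets (Ax + b <= 0)
    A = hull.equations[:, :2]
    b = hull.equations[:, 2]
    inside = (cand @ A.T + b <= 1e-9).all(axis=1)
    ai = ii.ravel()[inside] % config.L
    aj = jj.ravel()[inside] % config.L
    n_in = len(ai)
    if n_in == 0:
        return 0.0
    n_empty = int(np.count_nonzero(config.S[ai, aj] == 0))
    return n_empty / n_in
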