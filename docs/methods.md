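# Methods

## The lattice model

Particles of two species occupy cells of a periodic triangular lattice
(lattice constant `a = 1`, axial coordinates `(i, j)` embedded as
`i*a1 + j*a2` with `a1 = (1, 0)`, `a2 = (1/2, sqrt(3)/2)`).  Single occupancy
is encoded by a spin-1 variable `S in {+1, -1, 0}` (species 1, species 2,
empty).  Like particles attract at nearest-neighbour distance (`-J1`) and
repel at distance `2a` (`+J2`); unlike particles repel at contact (`+J1`) and
attract at `2a` (`-J2`).  The intermediate shell at `sqrt(3) a` does not
interact.  With `J1 = 1` as the energy unit and `J = J2/J1`, the energy is

    E = -Q1 + J * Q3,   Q_k = sum over shell-k pairs of S(x) S(x')

so every configuration's energy is an integer plus an integer multiple of
`J`.  All ground-state algebra is therefore done in exact rational
arithmetic; floating point only appears in the stochastic samplers.

A note on conventions: the interaction assignment above follows the model's
defining equations (first shell `-J1`/`+J1`, third shell `+J2`/`-J2`,
second shell inert).  A prose formulation that gives the second shell a
sign-changed interaction is inconsistent with the exact cluster energies
(`-5 J1` for the 4-particle rhombus, `(-12 + 3J) J1` for the 7-particle
hexagon) and is not used.

## Exact ground states: the phase catalog

At `T = 0` and fixed chemical potentials the stable pattern minimizes the
per-site grand potential `h* = (E - mu1* N1 - mu2* N2) / A`.  For a periodic
pattern `h*` is a linear function of `(J, mu1*, mu2*)` with rational
coefficients determined by one unit cell; the engine stores each catalog
phase as an explicit unit cell (sites + Hermite-normal-form lattice vectors)
and derives the coefficients by tiling one periodic repeat and evaluating
the energy exactly.

The catalog covers, for `J > 7/4`: vacuum `v`; dense one-component liquids
`d1/d2`; hexagonal crystals of 4-particle rhombic clusters `c1/c2`;
one-component stripes `l1/l2` (width 2, two empty rows); bubble phases
`b1/b2` (complement of `c1/c2`); alternating-cluster chains `cc`; zig-zag
chains `zz`; lamellae `ls` (alternating bilayers, full coverage); and
cluster-in-liquid phases `c12/c21`.  `cc` and `zz` share the same linear
form and are exactly degenerate everywhere.  The cells that are not pinned down by
the closed forms above were recovered by **exhaustive enumeration** of every
occupancy of every HNF unit cell with up to 12 sites (`enumerate_unit_cells`),
then cross-checked against the closed forms, coexistence lines and triple
points.  Notable geometry: `c1`, `b1`, `c12`, `cc` and the dimer raft all
live on the same `(6, 0), (2, 2)` superlattice; `zz` is the `(3, 0), (2, 2)`
zig-zag chain pattern.

Coexistence lines and triple points are solved analytically from the linear
forms with `Fraction` coefficients; quantities linear in `J` are carried as
exact affine pairs, so e.g. the cc-v boundary is `mu1* + mu2* = -1 - 3J` for
every rational `J`.  A triple point is reported only when the three phases'
lines meet at a common point that attains the global minimum of the
reference catalog.

### An overlooked phase: asymmetric diagonal stripes (ls23 / ls32)

The enumeration oracle found a periodic pattern absent from the reference
candidate list: three adjacent lattice lines of one species, two of the
other, and two empty lines per period, on the `(7, 0), (1, 1)` superlattice,
with

    h*(ls23) = (-5 - 6J - 2 mu1* - 3 mu2*) / 7

(hand-verified from the pair counts: Q1 = 5, Q3 = -6 per cell).  At `J = 3`
this phase undercuts the reference catalog in a band between the
one-component cluster/stripe region and the mixed cc region (22 of 1849
points on the integer grid over `[-21, 21]^2`), and it preempts four of the
six reference triple points (`b2-c12-l2`, `c12-l2-c2`, `c2-c12-cc`,
`c2-cc-v`) and their mirrors; only `d2-b2-c12` and `c12-cc-ls` are global
triple points of the extended catalog.  The package therefore distinguishes:

* the **reference catalog** (`FULL_CATALOG_NAMES`) — the candidate list
  behind the reference diagram, its lines and triple points;
* the **extended catalog** (`EXTENDED_CATALOG_NAMES`) — reference list plus
  `ls23`/`ls32`.  Exhaustive enumeration of all cells with up to 12 sites
  never goes below the extended catalog's minimum, and recovers it exactly,
  at every tested point.

Whether still larger cells hide further asymmetric stripe variants (e.g.
other width combinations) is an open question; the enumeration bound here
is 12 sites.

### Raft motifs

On the vacuum coexistence line `mu1* + mu2* = -1 - 3J` the grand potential
of the dense mixed phases vanishes, and two sparse motifs become degenerate
with them: chains of alternating dimers (`raft_dim`, exactly the cc pattern
with one row of each 4-cluster removed; explicit 12-site cell) at half the
cc density, and a triangle motif at one third the density with
`h*(tri) = h*(cc)/3`.  For the triangle motif the implied per-site linear
form (`rho1 = rho2 = 1/9`, energy `-(1 + 3J)/9` per site) has **no periodic
realization with a unit cell of up to 27 sites** (exhaustive enumeration;
also none as two 3-particle triangles per 54-site cell or three fused
triangle pairs per 81-site cell).  `raft_tri` is therefore cataloged by its
exact form only — the bulk limit of the triangle-raft family — and cannot be
generated as a lattice fixture.  The identities `h*(dim) = h*(cc)/2` and
`h*(tri) = h*(cc)/3` hold exactly by construction of the cells/forms and are
verified against the explicit dim and cc cells.

## Monte Carlo

Grand-canonical sampling uses single-site insertion/removal: a site is drawn
uniformly per attempt; an empty site receives species 1 or 2 with
probability 1/2 and accepts with `min(1, exp[(u_i + mu_i*)/T*])`; an
occupied site empties with `min(1, exp[-(u_i + mu_i*)/T*])`, with
`u1 = -u2 = Delta1 - J*Delta2` the local insertion energy gain (`Delta_k` =
sum of `S` over shell k).  The `1/T*` factor is required for the annealing
protocol to be meaningful and the pair (insertion, removal) satisfies
detailed balance exactly; this is unit-tested over all 338 local states.
Because `Delta1, Delta2 in [-6, 6]`, the acceptance probabilities are
precomputed per temperature into `2 x 13 x 13` tables; the kernel (numba,
with an inline xorshift64* generator seeded from the run seed) then runs at
about 20 ns per attempted move.  Energy bookkeeping tracks the integer pair
sums `(Q1, Q3)` incrementally and agrees with a from-scratch evaluation with
zero tolerance.

Canonical (fixed `N1, N2`) sampling uses displacement moves to empty
first-shell sites with Metropolis acceptance on the exact energy change;
particle numbers are conserved by construction.

Annealing starts from an empty lattice (grand canonical) or a random
placement (canonical) at `T* = 5.0` and cools to `T* = 0.2` through the
default schedule `(5.0, 2.0, 1.0, 0.6, 0.35, 0.2)`, with an equilibration
and a production period per temperature.  Library defaults are 1e5/1e6
steps per temperature (one MC step = `L^2` attempts); the test suite runs a
reduced 1e4/1e5 protocol at `L = 60`, which is sufficient for the final
configurations to classify correctly at the four reference state points
(c2, b2, ls, cc/zz) — verified for 12/12 of the seed/state combinations
during development.  The canonical raft study uses 14 + 14 particles on an
`L = 20` lattice: only the particle numbers matter for the raft structure,
and the smaller box shortens the diffusion-limited aggregation transient
without changing the asymptotic raft.

## Pattern classification

Phase identification in simulation studies of this kind is traditionally done by eye from snapshots.  Here a configuration is
reduced to the fingerprint `(rho1, rho2, f_like_nn, f_unlike_nn, f_like_3rd,
f_unlike_3rd)`, where `f_*` are fractions of the `3 L^2` site pairs of the
given shell occupied by like/unlike pairs.  Every catalog phase with a cell
has an exact fingerprint; a configuration gets the nearest phase label
(Euclidean distance), or `disordered/mixed` beyond the threshold 0.15.  The
minimum distance between two catalog fingerprints is 0.25 (ls vs c12),
except the physically degenerate pair cc/zz at 0.079 — those two label the
same thermodynamic state and either label is accepted wherever the pair is
degenerate.  The exact cc structure necessarily has unlike nearest-neighbour
contacts (the coefficient matching of its form forces one net like-contact
per particle, while the rhombus interior alone provides 2.5), so
`f_unlike_nn > 0` for cc — a property the classifier relies on rather than
the naive expectation that alternating clusters never touch.

Cluster structure is quantified by connected components: like-species
first-shell components (cluster-size histogram) and components of the
distance-<= 2 graph ("rafts"), whose porosity is the empty-site fraction
inside the component's convex hull in the Euclidean embedding (components
are unwrapped across the periodic boundary before hull construction).

## Continuous-model molecular dynamics

The continuous mixture interacts through `V11 = 6 eps [r^-12 - r^-6 +
0.3 e^(-r/2)/r]`, `V22 = V11/q^2`, `V12 = 6 eps [r^-12 + r^-6 -
0.3 e^(-r/2)/r]/q`, truncated (not shifted) at `r = 6.75`.  The grouping —
the whole bracket scaled by `1/q^2` (like species 2) and `1/q` (cross) — is
the reading consistent with rescaling all interactions by the charge ratio
and with the `q^2` scaling of the species-2 ordering temperature.  Walls:
repulsive `2 eps/(z - zw)^12`; attractive `4 eps (z^-12 - z^-6)` acting on
species 1 only or on both, per wall mode.

Integration is velocity-Verlet with unit mass.  The default timestep
`dt = 0.004` (velocity rescaling to the target temperature every 50 steps)
is an annealing timestep, stable for the `6 eps` core at the temperatures of
interest; strict energy-conservation checks use `dt = 5e-4`.  Because the
potential is truncated without shifting, the dynamics conserves the
*shifted* energy (the unshifted energy jumps by `V(r_cut)` whenever a pair
crosses the cutoff); the NVE diagnostic therefore monitors
`E_kin + E_pot - sum_pairs V(r_cut)`, which drifts by less than 1e-4
relative over 1e4 steps after equilibration.  Forces come from an x-y cell
list (cells >= r_cut; an all-pairs fallback is used when fewer than three
cells fit per axis); the pair set, and hence all energies, is independent of
the decomposition.

Workflows: `run_slit` (both walls repulsive, `Lz = 4`, geometric annealing
ladder over the first third of the run, then constant T) and
`run_adsorption_scaled` (<= 2000 particles; charge neutrality `N1 = q N2`
enforced; a zoned thermostat — colder near the wall, hotter far away —
during the initial stage, then uniform low T).  Desk-scale test sizes:
50 + 50 particles in a `30 x 30 x 4` slit aggregate into a raft holding
>= 50% of the particles within 1e5 steps; full-size slit morphology runs
(200 + 200 in `150 x 150 x 4`) are supported through the same API and CLI
but are not exercised in the test suite.

## What the fixtures show, and what they do not

The fixture generator produces mathematically ideal periodic configurations
and uniformly random initial states.  Passing classification tests on ideal
fixtures shows the fingerprint machinery is exact, not that thermal
configurations are easy to classify; the stochastic recovery tests cover the
latter at `T* = 0.2`, where defects (domain walls in ls, imperfect cluster
superlattices in c2) are present but local contact statistics remain close
to ideal.  No fixture emulates finite-temperature coexistence interfaces or
the disclination-ridden lamellae seen at slow quenches; classifying such
states correctly is out of scope.

## Numerical choices and degenerate inputs

* Exact arithmetic (`Fraction`) everywhere in the ground-state engine;
  1e-9 tolerance only when callers pass floats.
* `L >= 5` enforced so the minimum-image first/third shells are unambiguous.
* Degenerate minimizers are all reported (`cc/zz` labels); the coexistence
  solver flags identical-density pairs as `never` (parallel) or
  `degenerate` (identical everywhere).
* Seeds: every stochastic entry point takes an explicit seed; MC kernels
  derive an xorshift64* state from it, MD uses `numpy.random.default_rng`.
  Identical seeds reproduce bit-identical trajectories.

## Known limitations

* Finite-temperature phase boundaries are not located (plain annealing
  only, no parallel tempering or thermodynamic integration).
* Line tensions between coexisting phases and the resulting raft shapes are
  not computed.
* The enumeration bound of 12 sites leaves open whether further phases with
  larger cells exist; the discovered ls23/ls32 band shows the risk is real.
* The scaled adsorption mode preserves the wall-region geometry but not the
  reservoir size of the full-scale setup; only near-wall structure should be
  compared.
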