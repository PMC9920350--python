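"""Ground-state catalog: exact algebra, lines, triple points, oracle."""

import itertools
import warnings
from fractions import Fraction

import numpy as np
import pytest
import sympy

from saltmix.catalog import (
    CATALOG,
    FULL_CATALOG_NAMES,
    AffineJ,
    catalog_for,
    coexistence_line,
    enumerate_unit_cells,
    fixed_n_cluster_energies,
    minimal_phase,
    phase_diagram,
    phase_h,
    raft_h_relations,
    tile_phase,
    triple_points,
)
from saltmix.lattice import (
    ChemicalPotentials,
    InteractionParams,
    grand_hamiltonian_density,
)

J3 = InteractionParams(3)


def _mu(a, b):
    return ChemicalPotentials(a, b)


def _sym_h(name):
    """h* of a catalog phase as a sympy expression in (J, mu1, mu2)."""
    J, m1, m2 = sympy.symbols("J mu1 mu2")
    f = CATALOG[name].form
    return sympy.Rational(f.e0, f.area) + sympy.Rational(f.eJ, f.area) * J \
        - sympy.Rational(f.n1, f.area) * m1 - sympy.Rational(f.n2, f.area) * m2


class TestPhaseForms:
    def test_mixed_phase_forms_match_printed_algebra_symbolically(self):
        """cc/zz, ls and c12 reproduce the published closed forms exactly."""
        J, m1, m2 = sympy.symbols("J mu1 mu2")
        printed = {
            "cc": -(1 + 3 * J + m1 + m2) / 3,
            "zz": -(1 + 3 * J + m1 + m2) / 3,
            "ls": -(4 + 4 * J + 2 * (m1 + m2)) / 4,
            "c12": -(8 + 12 * J + 4 * m1 + 8 * m2) / 12,
        }
        for name, expr in printed.items():
            assert sympy.simplify(_sym_h(name) - expr) == 0, name

    @pytest.mark.parametrize("seed", range(4))
    def test_cell_evaluation_matches_form_at_random_rational_points(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(5):
            J = Fraction(int(rng.integers(2, 40)), int(rng.integers(1, 12)))
            if J <= Fraction(7, 4):
                J += 2
            mu = _mu(Fraction(int(rng.integers(-40, 40)), 3),
                     Fraction(int(rng.integers(-40, 40)), 7))
            params = InteractionParams(J)
            for name in FULL_CATALOG_NAMES + ("raft_dim",):
                cfg = tile_phase(name, 60)
                assert grand_hamiltonian_density(cfg, params, mu) \
                    == phase_h(name, params, mu), name

    def test_one_component_cluster_form_forced_by_triple_points(self):
        # the c2 cell must give h* = (-5 - 4*mu2)/12 per site
        f = CATALOG["c2"].form
        assert (f.e0, f.eJ, f.n1, f.n2, f.area) == (-5, 0, 0, 4, 12)

    def test_known_values(self):
        assert phase_h("cc", J3, _mu(-5, -5)) == 0  # on the cc-v line
        assert phase_h("ls", InteractionParams(2), _mu(-3, -1)) == -1  # 1 - J
        assert phase_h("c12", J3, _mu(0, 0)) == Fraction(-44, 12)


class TestDegeneracyAndRafts:
    @pytest.mark.parametrize("seed", range(3))
    def test_cc_zz_identical_and_raft_ratios_exact(self, seed):
        rng = np.random.default_rng(100 + seed)
        for _ in range(8):
            J = Fraction(int(rng.integers(1, 60)), int(rng.integers(1, 16)))
            mu = _mu(Fraction(int(rng.integers(-50, 50)), 4),
                     Fraction(int(rng.integers(-50, 50)), 5))
            params = InteractionParams(J)
            assert phase_h("cc", params, mu) == phase_h("zz", params, mu)
            h_dim, h_tri, h_cc = raft_h_relations(params, mu)
            assert h_dim == h_cc / 2
            assert h_tri == h_cc / 3

    def test_rafts_vanish_on_the_vacuum_coexistence_line(self):
        mu = _mu(-5, -5)  # mu1 + mu2 = -1 - 3J at J = 3
        h_dim, h_tri, h_cc = raft_h_relations(J3, mu)
        assert h_dim == h_tri == h_cc == 0


class TestMinimalPhase:
    @pytest.mark.parametrize("mu,expect", [
        ((-20, -20), {"v"}),
        ((-20, 10), {"b2"}),
        ((0, 0), {"ls"}),
        ((Fraction(-19, 5), Fraction(-19, 5)), {"cc", "zz"}),
        ((-20, 0), {"c2"}),
        ((10, 10), {"ls"}),
        ((20, 10), {"c21"}),
    ])
    def test_ground_state_regions_at_J3(self, mu, expect):
        assert minimal_phase(J3, _mu(*mu)) == expect

    def test_reduced_catalog_recovers_low_J_topology(self):
        params = InteractionParams(Fraction(1, 3))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            # vacuum below mu_i = -3 + 3J = -2, dense phases above
            assert minimal_phase(params, _mu(-3, -3)) == {"v"}
            assert minimal_phase(params, _mu(0, -3)) == {"d1"}
            assert minimal_phase(params, _mu(1, 1)) == {"d1", "d2"}

    def test_reduced_catalog_warns(self):
        with pytest.warns(UserWarning, match="reduced"):
            catalog_for(InteractionParams(1))


class TestCoexistenceLines:
    def test_printed_lines(self):
        ln = coexistence_line("cc", "ls")
        assert (ln.a1, ln.a2, ln.b.a0, ln.b.aJ) == (1, 1, -4, 0)
        ln = coexistence_line("cc", "v")
        assert (ln.a1, ln.a2, ln.b.a0, ln.b.aJ) == (1, 1, -1, -3)
        ln = coexistence_line("c12", "c2")
        assert (ln.a1 / ln.a2, ln.b.a0 / ln.a1, ln.b.aJ / ln.a1) \
            == (1, Fraction(-3, 4), -3)
        ln = coexistence_line("d1", "d2")
        assert (ln.a1, ln.a2) == (1, -1) and ln.b.is_zero

    def test_degenerate_and_never_flags(self):
        assert coexistence_line("cc", "zz").kind == "degenerate"
        assert coexistence_line("d1", "b1").kind == "line"
        # same densities, different energies: never coexist
        assert coexistence_line("cc", "raft_dim").kind != "degenerate"

    def test_line_is_locus_of_equal_h(self):
        ln = coexistence_line("c12", "cc")
        for m1 in (Fraction(-5), Fraction(0), Fraction(3)):
            m2 = (ln.b(3) - ln.a1 * m1) / ln.a2
            mu = _mu(m1, m2)
            assert phase_h("c12", J3, mu) == phase_h("cc", J3, mu)


_PRINTED_TRIPLES = {
    frozenset({"d2", "b2", "c12"}): (AffineJ(Fraction(9, 4), -6),
                                     AffineJ(Fraction(-19, 4), 6)),
    frozenset({"b2", "c12", "l2"}): (AffineJ(Fraction(9, 4), -6),
                                     AffineJ(Fraction(-5, 2), 3)),
    frozenset({"c12", "l2", "c2"}): (AffineJ(Fraction(11, 4), -6),
                                     AffineJ(Fraction(-7, 2), 3)),
    frozenset({"c2", "c12", "cc"}): (AffineJ(Fraction(1, 4), -3),
                                     AffineJ(-1)),
    frozenset({"c2", "cc", "v"}): (AffineJ(Fraction(1, 4), -3),
                                   AffineJ(Fraction(-5, 4))),
    frozenset({"c12", "cc", "ls"}): (AffineJ(-3), AffineJ(-1)),
}


class TestTriplePoints:
    def test_all_six_printed_points_and_their_mirrors(self):
        pts = {p.phases: (p.mu1, p.mu2) for p in triple_points(J3)}
        swap = {"d1": "d2", "d2": "d1", "c1": "c2", "c2": "c1", "l1": "l2",
                "l2": "l1", "b1": "b2", "b2": "b1", "c12": "c21",
                "c21": "c12", "v": "v", "cc": "cc", "zz": "zz", "ls": "ls"}
        for names, (m1, m2) in _PRINTED_TRIPLES.items():
            assert pts[names] == (m1, m2), names
            mirror = frozenset(swap[n] for n in names)
            assert pts[mirror] == (m2, m1), mirror

    def test_points_stable_in_J(self):
        # the same affine expressions must hold at another J > 7/4
        pts = {p.phases: (p.mu1, p.mu2) for p in triple_points(InteractionParams(2))}
        for names, val in _PRINTED_TRIPLES.items():
            assert pts[names] == val

    def test_gap_between_cluster_chain_triple_points_is_quarter(self):
        pts = {p.phases: p for p in triple_points(J3)}
        upper = pts[frozenset({"c2", "c12", "cc"})]
        lower = pts[frozenset({"c2", "cc", "v"})]
        assert upper.mu2(3) - lower.mu2(3) == Fraction(1, 4)
        assert upper.mu1(3) == lower.mu1(3)

    def test_every_point_lies_on_all_pairwise_lines_and_is_global_min(self):
        for tp in triple_points(J3):
            mu = _mu(*tp.at(3))
            hs = [phase_h(n, J3, mu) for n in tp.phases]
            assert len(set(hs)) == 1
            hmin = min(phase_h(n, J3, mu) for n in FULL_CATALOG_NAMES)
            assert hs[0] == hmin
            for a, b in itertools.combinations(sorted(tp.phases), 2):
                assert coexistence_line(a, b).evaluate(mu, 3)


class TestFixedNClusters:
    def test_28_particle_tilings(self):
        t = fixed_n_cluster_energies(3, 28)
        assert t["rhombi"] == -35
        assert t["hexagons"] == -48 + 12 * 3
        assert t["difference"] == -35 - 4 * (-12 + 3 * 3)

    def test_crossover(self):
        t = fixed_n_cluster_energies(Fraction(13, 12), 28)
        assert t["crossover_J"] == Fraction(13, 12)
        assert t["difference"] == 0

    def test_rejects_non_multiples_of_28(self):
        with pytest.raises(ValueError):
            fixed_n_cluster_energies(3, 30)


class TestEnumerationOracle:
    def test_small_cells_recover_lamellae_at_origin(self):
        res = enumerate_unit_cells(J3, 4, [(0, 0)])[0]
        # ls wins at the origin: h* = -(4 + 4J)/4 = -4 at J = 3
        assert res.h_min == pytest.approx(float(phase_h("ls", J3, _mu(0, 0))))
        assert res.h_min == pytest.approx(-4.0)

    def test_vacuum_wins_at_low_mu(self):
        res = enumerate_unit_cells(J3, 3, [(-20, -20)])[0]
        assert res.h_min == 0.0
        assert res.n1_per_cell == res.n2_per_cell == 0

    def test_reference_triple_point_is_preempted_by_discovered_stripes(self):
        # At the reference c2-c12-cc triple point the three named phases tie
        # at h* = -1/12, but the enumeration-discovered asymmetric stripe
        # phase ls23 lies below; the enumerator must find it.
        mu = _mu(Fraction(1, 4) - 9, -1)
        assert phase_h("c2", J3, mu) == phase_h("c12", J3, mu) \
            == phase_h("cc", J3, mu) == Fraction(-1, 12)
        assert phase_h("ls23", J3, mu) == Fraction(-5, 14)
        res = enumerate_unit_cells(J3, 12, [(float(mu.mu1), float(mu.mu2))])[0]
        assert res.h_min == pytest.approx(-5 / 14)

    def test_budget_enforced(self):
        with pytest.raises(ValueError, match="budget"):
            enumerate_unit_cells(J3, 13, [(0, 0)])


class TestDiscoveredStripePhase:
    """The asymmetric diagonal-stripe phase found by exhaustive enumeration."""

    def test_form_matches_cell_evaluation(self):
        mu = _mu(Fraction(-10), Fraction(0))
        cfg = tile_phase("ls23", 14)
        assert grand_hamiltonian_density(cfg, J3, mu) == phase_h("ls23", J3, mu)
        f = CATALOG["ls23"].form
        assert (f.e0, f.eJ, f.n1, f.n2, f.area) == (-5, -6, 2, 3, 7)

    def test_undercuts_reference_catalog_in_a_band(self):
        mu = _mu(-10, 0)
        ref = min(phase_h(n, J3, mu) for n in FULL_CATALOG_NAMES)
        assert phase_h("ls23", J3, mu) < ref

    def test_extended_catalog_changes_minimal_phase_only_in_the_band(self):
        assert minimal_phase(J3, _mu(-10, 0), extended=True) == {"ls23"}
        assert "ls23" not in minimal_phase(J3, _mu(-10, 0))
        for mu in [(-20, -20), (0, 0), (-20, 10)]:
            assert minimal_phase(J3, _mu(*mu), extended=True) \
                == minimal_phase(J3, _mu(*mu))

    def test_mirror_symmetry(self):
        mu = _mu(Fraction(-2), Fraction(-8))
        assert phase_h("ls32", J3, mu) == phase_h("ls23", J3, mu.swapped())


class TestDiagram:
    def test_grid_labels_and_export(self):
        result = phase_diagram(J3, -6, 2, 2.0)
        df = result.to_frame()
        assert set(df.columns) == {"mu1", "mu2", "phase"}
        row = df[(df.mu1 == -4) & (df.mu2 == -4)].iloc[0]
        assert row.phase == "cc/zz"
        assert len(result.triple_points) == 12
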