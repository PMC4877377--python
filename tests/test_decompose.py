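"""Conformal decomposition: support reduction, peeling, and certification."""

from fractions import Fraction

import pytest

from confelem.decompose import (
    ConformalSum,
    conformal_sum_cone,
    conformal_sum_polyhedron,
    conformal_sum_scone,
    find_conformal_SM,
    lemma2_step,
    verify,
)
from confelem.exactla import canonical_ray, vec
from confelem.geometry import conforms
from confelem.special import is_SM


class TestLemma2Step:
    def test_peel_first_em(self, examples):
        C = examples["flux_cone"].obj
        lam, x2 = lemma2_step(C, vec((2, 1, 1, 1)), vec((1, 0, 0, 1)))
        assert lam == 1
        assert x2 == vec((1, 1, 1, 0))

    def test_peel_other_em(self, examples):
        C = examples["flux_cone"].obj
        lam, x2 = lemma2_step(C, vec((2, 1, 1, 1)), vec((1, 1, 1, 0)))
        assert lam == 1
        assert x2 == vec((1, 0, 0, 1))

    def test_quadrant(self, examples):
        C = examples["quadrant"].obj
        lam, x2 = lemma2_step(C, vec((1, 1)), vec((1, 0)))
        assert (lam, x2) == (1, vec((0, 1)))

    def test_rejects_proportional(self, examples):
        C = examples["flux_cone"].obj
        with pytest.raises(ValueError, match="proportional"):
            lemma2_step(C, vec((2, 0, 0, 2)), vec((1, 0, 0, 1)))

    def test_rejects_support_violation(self, examples):
        C = examples["flux_cone"].obj
        with pytest.raises(ValueError, match="supp"):
            lemma2_step(C, vec((1, 1, 1, 0)), vec((1, 0, 0, 1)))


class TestFindConformalSM:
    def test_never_returns_anticonforming_em(self, examples):
        """From (2,1,1,1) only the EMs without a sign flip may emerge."""
        C = examples["flux_cone"].obj
        e = find_conformal_SM(C, vec((2, 1, 1, 1)))
        assert is_SM(C, e)
        assert conforms(e, vec((2, 1, 1, 1)))
        assert canonical_ray(e) in {(1, 0, 0, 1), (1, 1, 1, 0)}

    def test_unique_conforming_class(self, examples):
        C = examples["flux_cone"].obj
        e = find_conformal_SM(C, vec((0, 2, 2, -2)))
        assert canonical_ray(e) == (0, 1, 1, -1)

    def test_sm_input_returned_unchanged(self, examples):
        C = examples["flux_cone"].obj
        assert find_conformal_SM(C, vec((3, 0, 0, 3))) == vec((3, 0, 0, 3))

    def test_deterministic(self, examples):
        C = examples["flux_cone"].obj
        runs = {find_conformal_SM(C, vec((2, 1, 1, 1))) for _ in range(3)}
        assert len(runs) == 1


class TestSConeSum:
    def test_running_example(self, examples):
        """The unique cancelation-free decomposition of the flux (2,1,1,1)."""
        C = examples["flux_cone"].obj
        s = conformal_sum_scone(C, vec((2, 1, 1, 1)))
        assert {canonical_ray(t) for t in s.cone_terms} == {(1, 0, 0, 1), (1, 1, 1, 0)}
        assert s.reconstruct() == vec((2, 1, 1, 1))
        assert verify(s, C)

    def test_single_term_on_em(self, examples):
        C = examples["flux_cone"].obj
        s = conformal_sum_scone(C, vec((0, 3, 3, -3)))
        assert s.cone_terms == (vec((0, 3, 3, -3)),)

    def test_zero_gives_empty_sum(self, examples):
        C = examples["flux_cone"].obj
        s = conformal_sum_scone(C, vec((0, 0, 0, 0)))
        assert s.cone_terms == () and s.convex_terms == ()
        assert verify(s, C)

    def test_nonmember_rejected(self, examples):
        with pytest.raises(ValueError):
            conformal_sum_scone(examples["flux_cone"].obj, vec((0, 1, 1, 1)))


class TestConeSum:
    @pytest.mark.parametrize(
        "x,expected",
        [((1, 2), {(0, 1), (1, 1)}), ((-1, 4), {(-1, 3), (0, 1)})],
    )
    def test_example2_unique_pairs(self, examples, x, expected):
        C = examples["cone2"].obj
        s = conformal_sum_cone(C, vec(x))
        assert {canonical_ray(t) for t in s.cone_terms} == expected
        assert s.reconstruct() == vec(x)
        assert verify(s, C)

    def test_single_term_on_ev(self, examples):
        C = examples["cone2"].obj
        s = conformal_sum_cone(C, vec((-2, 6)))
        assert s.cone_terms == (vec((-2, 6)),)


class TestPolyhedronSum:
    def test_flux_polyhedron_interior_flux(self, examples):
        """(2,1,1,1) is the half-half mix of the two nonzero ccND points."""
        P = examples["flux_poly"].obj
        s = conformal_sum_polyhedron(P, vec((2, 1, 1, 1)))
        assert s.cone_terms == ()
        assert {(p, w) for p, w in s.convex_terms} == {
            (vec((2, 0, 0, 2)), Fraction(1, 2)),
            (vec((2, 2, 2, 0)), Fraction(1, 2)),
        }
        assert verify(s, P)

    def test_recession_direction_plus_zero_point(self, examples):
        P = examples["flux_poly"].obj
        s = conformal_sum_polyhedron(P, vec((0, 2, 2, -2)))
        assert [canonical_ray(t) for t in s.cone_terms] == [(0, 1, 1, -1)]
        assert s.convex_terms == ((vec((0, 0, 0, 0)), Fraction(1)),)
        assert verify(s, P)

    def test_vertex_decomposes_to_itself(self, examples):
        P = examples["flux_poly"].obj
        s = conformal_sum_polyhedron(P, vec((2, 0, 0, 2)))
        assert s.cone_terms == ()
        assert s.convex_terms == ((vec((2, 0, 0, 2)), Fraction(1)),)

    def test_weights_always_sum_to_one(self, examples):
        P = examples["poly3"].obj
        for x in [("1/6", "1/2"), (1, 1), (0, 2), ("1/2", "3/4")]:
            xs = vec(x)
            if not P.contains(xs):
                continue
            s = conformal_sum_polyhedron(P, xs)
            assert s.weight_total == 1
            assert len(s.convex_terms) >= 1
            assert s.reconstruct() == xs
            assert verify(s, P)


class TestVerifyRejectsBadSums:
    def test_cancelation_flagged(self, examples):
        """2*e1 + e2 reconstructs (2,1,1,1) but cancels the last flux."""
        C = examples["flux_cone"].obj
        bad = ConformalSum(
            target=vec((2, 1, 1, 1)),
            cone_terms=(vec((2, 0, 0, 2)), vec((0, 1, 1, -1))),
        )
        assert bad.reconstruct() == vec((2, 1, 1, 1))
        report = verify(bad, C)
        assert not report
        assert any("conform" in p for p in report.problems)

    def test_bad_weights_flagged(self, examples):
        P = examples["flux_poly"].obj
        bad = ConformalSum(
            target=vec(("4/3", "2/3", "2/3", "2/3")),
            cone_terms=(),
            convex_terms=(
                (vec((2, 0, 0, 2)), Fraction(1, 3)),
                (vec((2, 2, 2, 0)), Fraction(1, 3)),
            ),
        )
        report = verify(bad, P)
        assert not report
        assert any("sum to one" in p for p in report.problems)

    def test_wrong_reconstruction_flagged(self, examples):
        C = examples["flux_cone"].obj
        bad = ConformalSum(target=vec((2, 1, 1, 1)), cone_terms=(vec((1, 0, 0, 1)),))
        report = verify(bad, C)
        assert any("reconstruction" in p for p in report.problems)

    def test_nonelementary_term_flagged(self, examples):
        C = examples["flux_cone"].obj
        bad = ConformalSum(target=vec((2, 1, 1, 1)), cone_terms=(vec((2, 1, 1, 1)),))
        report = verify(bad, C)
        assert any("not elementary" in p for p in report.problems)


class TestOrderingAndBounds:
    def test_triangular_order(self, examples):
        """Each term owns a coordinate that is zero in all predecessors."""
        C = examples["flux_cone"].obj
        s = conformal_sum_scone(C, vec((2, 1, 1, 1)))
        for k, t in enumerate(s.cone_terms):
            assert any(
                t[i] != 0 and all(p[i] == 0 for p in s.cone_terms[:k])
                for i in range(4)
            )

    def test_cardinality_bounds(self, examples):
        C = examples["flux_cone"].obj
        x = vec((2, 1, 1, 1))
        s = conformal_sum_scone(C, x)
        assert len(s.cone_terms) <= C.subspace.dim
        assert len(s.cone_terms) <= 4
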