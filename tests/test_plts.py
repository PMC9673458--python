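"""PLTS data model, transformations and algebra."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from plfcm import (
    LinguisticScale,
    PLTS,
    PLTSError,
    aggregate_expert_opinions,
    format_plts,
    g_inverse,
    g_transform,
    pad_pair,
    parse_plts,
    plts_add,
    plts_mult,
    plts_power,
    scalar_mult,
)
from plfcm.measures import plts_distance

from conftest import random_plts

S5 = LinguisticScale(5)
S3 = LinguisticScale(3)


def P(text, scale=S5):
    return parse_plts(text, scale)


# -- construction and text syntax ---------------------------------------------


class TestConstruction:
    def test_scale_validation(self):
        with pytest.raises(ValueError):
            LinguisticScale(0)
        with pytest.raises(ValueError):
            LinguisticScale(2, labels=("a", "b"))

    def test_rejects_out_of_range_term(self):
        with pytest.raises(PLTSError):
            PLTS(((4.0, 1.0),), S3)

    def test_rejects_descending_entries(self):
        with pytest.raises(PLTSError):
            PLTS(((1.0, 0.5), (-1.0, 0.5)), S5)

    def test_rejects_oversum(self):
        with pytest.raises(PLTSError):
            PLTS(((0.0, 0.7), (1.0, 0.7)), S5)

    def test_parse_arbitrary_order_and_merge(self):
        plts = P("{s3:0.2, s-3:0.5, s3:0.1, s0:0.2}")
        assert plts.terms == (-3.0, 0.0, 3.0)
        assert plts.probabilities == pytest.approx((0.5, 0.2, 0.30000000000000004))

    @pytest.mark.parametrize(
        "text", ["", "{}", "{s-3}", "{x:0.5}", "{s-3:0.5, junk}"]
    )
    def test_parse_rejects_malformed(self, text):
        with pytest.raises(PLTSError):
            parse_plts(text, S5)

    def test_parse_integer_terms_flag(self):
        with pytest.raises(PLTSError):
            parse_plts("{s1.5:1}", S5, integer_terms=True)
        assert parse_plts("{s1.5:1}", S5).terms == (1.5,)

    def test_format_round_trip(self):
        for text in ["{s-3:0.15, s0:0.2, s3:0.65}", "{s-3:0.75, s0:0, s3:0.25}", "{s0:1}"]:
            assert format_plts(P(text)) == text


# -- normalize ------------------------------------------------------------------


class TestNormalize:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("{s-3:0.5, s0:0.5}", (0.5, 0.5)),
            ("{s-1:0.2, s1:0.2}", (0.5, 0.5)),
            ("{s-3:0.45, s0:0.30, s3:0.15}", (0.5, 1 / 3, 1 / 6)),
        ],
    )
    def test_rescales_to_unit_sum(self, raw, expected):
        norm = P(raw).normalize()
        assert norm.probabilities == pytest.approx(expected)
        assert norm.terms == P(raw).terms

    def test_idempotent(self):
        plts = P("{s-1:0.2, s1:0.2}").normalize()
        assert plts.normalize() is plts

    def test_all_zero_is_invalid(self):
        with pytest.raises(PLTSError):
            PLTS(((0.0, 0.0),), S5).normalize()


# -- padding ----------------------------------------------------------------------


class TestPadding:
    def test_equal_lengths_unchanged(self):
        a, b = P("{s-3:0.5, s3:0.5}"), P("{s0:0.4, s1:0.6}")
        assert pad_pair(a, b) == (a, b)

    def test_shorter_gains_zero_probability_terms(self):
        a, b = pad_pair(P("{s0:1}"), P("{s-1:0.5, s1:0.5}"))
        assert len(a) == len(b) == 2
        assert a.entries == ((0.0, 0.0), (0.0, 1.0))
        assert b == P("{s-1:0.5, s1:0.5}")

    def test_scale_mismatch_rejected(self):
        with pytest.raises(PLTSError):
            pad_pair(P("{s0:1}"), P("{s0:1}", S3))

    def test_padded_pair_supports_distance(self):
        d = plts_distance(P("{s0:1}"), P("{s-1:0.5, s1:0.5}"))
        assert 0 <= d <= 1


# -- score --------------------------------------------------------------------------


@pytest.mark.parametrize(
    "text, expected",
    [
        ("{s2:1}", 2.0),
        ("{s-1:0.5, s1:0.5}", 0.0),
        ("{s-3:0.15, s0:0.40, s3:0.45}", 0.9),
    ],
)
def test_score_expectation(text, expected):
    assert P(text).score() == pytest.approx(expected, abs=1e-12)


# -- equivalent transformations -------------------------------------------------------


class TestTransform:
    def test_state_scale_triple(self):
        assert [g_transform(t, S5) for t in (-3, 0, 3)] == [0.2, 0.5, 0.8]

    def test_midpoint_and_endpoints(self):
        for tau in (1, 3, 5, 9):
            s = LinguisticScale(tau)
            assert g_transform(0, s) == 0.5
            assert g_transform(tau, s) == 1.0
            assert g_transform(-tau, s) == 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(PLTSError):
            g_transform(4, S3)
        with pytest.raises(PLTSError):
            g_inverse(1.5, S3)

    def test_inverse_values(self):
        assert g_inverse(0.5, S5) == 0.0
        assert g_inverse(0.2, S5) == pytest.approx(-3.0, abs=1e-12)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_round_trip_identity(self, seed):
        rng = np.random.default_rng(seed)
        plts = random_plts(rng, S5)
        back = g_inverse(g_transform(plts))
        assert back.terms == pytest.approx(plts.terms, abs=1e-12)
        assert back.probabilities == pytest.approx(plts.probabilities, abs=1e-12)

    def test_transformed_probabilities_carried_through(self):
        t = g_transform(P("{s-3:0.3, s3:0.7}"))
        assert t.memberships == (0.2, 0.8)
        assert t.probabilities == (0.3, 0.7)


# -- Cartesian operators ---------------------------------------------------------------


def naive_combine(a, b, op):
    """Independent double-loop oracle for the Cartesian operators."""
    tau = a.scale.tau
    pairs = {}
    for t1, p1 in a.entries:
        for t2, p2 in b.entries:
            m = op((t1 + tau) / (2 * tau), (t2 + tau) / (2 * tau))
            key = round(m, 12)
            pairs[key] = pairs.get(key, 0.0) + p1 * p2
    return sorted(pairs.items())


class TestAlgebra:
    def test_probabilistic_sum_of_midpoints(self):
        out = plts_add(P("{s0:1}"), P("{s0:1}"))
        # memberships 0.5 + 0.5 - 0.25 = 0.75 -> term (2*0.75 - 1) * 5
        assert out.terms == pytest.approx((2.5,), abs=1e-12)
        assert out.probabilities == (1.0,)

    def test_add_identity_element(self):
        a = P("{s-3:0.3, s3:0.7}")
        out = plts_add(a, P("{s-5:1}"))  # membership 0 is the neutral element
        assert out.terms == pytest.approx(a.terms, abs=1e-12)

    def test_scalar_mult_one_is_identity(self):
        a = P("{s-3:0.3, s0:0.2, s3:0.5}")
        out = scalar_mult(1.0, a)
        assert out.terms == pytest.approx(a.terms, abs=1e-12)
        assert out.probabilities == pytest.approx(a.probabilities, abs=1e-12)

    def test_power_one_is_identity(self):
        a = P("{s-1:0.4, s2:0.6}")
        out = plts_power(a, 1.0)
        assert out.terms == pytest.approx(a.terms, abs=1e-12)

    def test_scale_mismatch_and_bad_scalar(self):
        with pytest.raises(PLTSError):
            plts_add(P("{s0:1}"), P("{s0:1}", S3))
        with pytest.raises(PLTSError):
            scalar_mult(-1.0, P("{s0:1}"))
        with pytest.raises(PLTSError):
            plts_power(P("{s0:1}"), 0.0)

    @pytest.mark.parametrize("opname", ["add", "mult"])
    @pytest.mark.parametrize("seed", range(20))
    def test_oracle_equivalence(self, opname, seed):
        rng = np.random.default_rng(seed)
        a, b = random_plts(rng, S5), random_plts(rng, S5)
        if opname == "add":
            got = plts_add(a, b)
            expected = naive_combine(a, b, lambda x, y: x + y - x * y)
        else:
            got = plts_mult(a, b)
            expected = naive_combine(a, b, lambda x, y: x * y)
        gm = g_transform(got)
        assert gm.memberships == pytest.approx([m for m, _ in expected], abs=1e-12)
        assert gm.probabilities == pytest.approx([p for _, p in expected], abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_commutative_and_associative_with_unit_mass(self, seed):
        rng = np.random.default_rng(100 + seed)
        a, b, c = (random_plts(rng, S5) for _ in range(3))
        for op in (plts_add, plts_mult):
            ab, ba = op(a, b), op(b, a)
            assert g_transform(ab).memberships == pytest.approx(
                g_transform(ba).memberships, abs=1e-12
            )
            assert sum(ab.probabilities) == pytest.approx(1.0, abs=1e-9)
            # associativity, compared on distribution moments (robust to how
            # coincident memberships get merged)
            lhs = g_transform(op(op(a, b), c))
            rhs = g_transform(op(a, op(b, c)))
            for mom in (1, 2):
                lm = sum(m**mom * p for m, p in lhs.entries)
                rm = sum(m**mom * p for m, p in rhs.entries)
                assert lm == pytest.approx(rm, abs=1e-10)


# -- complement ---------------------------------------------------------------------------


class TestComplement:
    def test_sign_flip_and_fixed_point(self):
        assert P("{s3:1}").complement() == P("{s-3:1}")
        assert P("{s0:1}").complement() == P("{s0:1}")

    @pytest.mark.parametrize("seed", range(10))
    def test_involution(self, seed):
        rng = np.random.default_rng(200 + seed)
        a = random_plts(rng, S5)
        assert a.complement().complement() == a

    def test_extreme_complement_is_maximally_distant(self):
        a = P("{s5:1}")
        assert plts_distance(a, a.complement()) == pytest.approx(1.0, abs=1e-12)


# -- expert pooling -----------------------------------------------------------------------


class TestExpertPooling:
    def test_three_expert_worked_example(self):
        opinions = [
            P("{s-3:0.6, s-1:0.3, s0:0.1}", S3),
            P("{s-3:0.5, s0:0.5}", S3),
            P("{s-3:0.4, s-2:0.3, s0:0.3}", S3),
        ]
        pooled = aggregate_expert_opinions(opinions)
        assert pooled.terms == (-3.0, -2.0, -1.0, 0.0)
        assert pooled.probabilities == pytest.approx((0.5, 0.1, 0.1, 0.3), abs=1e-12)

    def test_single_expert_identity(self):
        a = P("{s-3:0.4, s1:0.6}", S3)
        pooled = aggregate_expert_opinions([a])
        assert pooled.terms == a.terms
        assert pooled.probabilities == pytest.approx(a.probabilities, abs=1e-12)

    def test_two_identical_opinions(self):
        a = P("{s-2:0.3, s2:0.7}", S3)
        pooled = aggregate_expert_opinions([a, a])
        assert pooled.terms == a.terms
        assert pooled.probabilities == pytest.approx(a.probabilities, abs=1e-12)

    def test_errors(self):
        with pytest.raises(PLTSError):
            aggregate_expert_opinions([])
        with pytest.raises(PLTSError):
            aggregate_expert_opinions([P("{s0:1}", S3)], weights=[0.5, 0.5])
        with pytest.raises(PLTSError):
            aggregate_expert_opinions(
                [P("{s0:1}", S3), P("{s1:1}", S3)], weights=[0.9, 0.9]
            )
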