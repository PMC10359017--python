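"""Closed-form rare-error-limit CESS classification."""

import math

import numpy as np
import pytest

from recinorm import (
    ErrorRates, cess_check, classify_cess, catalog_lookup, generous_scoring,
    make_norm, nash_payoff_gap, second_order_cess, sl2_bounds, ss1_bounds,
    swap_labels,
)
from recinorm.norms import BB, BG, C, D, GB, GG, sl2_norm, ss1_norm
from tests.conftest import LEADING_EIGHT, SECONDARY_SIXTEEN


class TestCatalogClassification:
    def test_l2_branch_and_bounds(self):
        v = classify_cess(catalog_lookup("L2"))
        assert v.is_cess and v.branch == "P(B,G)=1"
        assert v.bc_lower == 1.0 and math.isinf(v.bc_upper)

    def test_s1_branch_and_bounds(self):
        v = classify_cess(catalog_lookup("S1"))
        assert v.is_cess and v.branch == "P(B,G)=0"
        assert v.bc_lower == 2.0

    @pytest.mark.parametrize("name", LEADING_EIGHT)
    def test_leading_eight_bound_is_one(self, name):
        assert classify_cess(catalog_lookup(name)).bc_lower == 1.0

    @pytest.mark.parametrize("name", SECONDARY_SIXTEEN)
    def test_secondary_sixteen_bound_is_two(self, name):
        assert classify_cess(catalog_lookup(name)).bc_lower == 2.0

    def test_unconditional_cooperation_fails(self):
        v = classify_cess(make_norm([1] * 4, [1] * 8, [1] * 8))
        assert not v.is_cess
        assert any("P(G,B)=0" in f for f in v.failed_conditions)

    def test_forced_pbb_reported(self):
        v = classify_cess(catalog_lookup("L1"))
        assert v.forced_pbb == 1.0  # only cooperation restores reputation
        v = classify_cess(catalog_lookup("L6"))
        assert v.forced_pbb == 0.0

    def test_wrong_pbb_rejected(self):
        n = catalog_lookup("L6")
        bad = make_norm([1, 0, 1, 1], n.R1, n.R2)  # P(B,B)=1 against the grain
        v = classify_cess(bad)
        assert not v.is_cess and v.forced_pbb == 0.0


class TestOrientationInvariance:
    def test_swapped_catalog_norms_classify_identically(self):
        for name in ("L1", "L6", "S1", "S16"):
            n = catalog_lookup(name)
            v, vs = classify_cess(n), classify_cess(swap_labels(n))
            assert v.is_cess == vs.is_cess
            assert v.bc_lower == vs.bc_lower and v.bc_upper == vs.bc_upper
            assert vs.orientation == "swapped"

    def test_random_stochastic_norms(self, random_stochastic_norms):
        for n in random_stochastic_norms:
            assert (classify_cess(n).is_cess
                    == classify_cess(swap_labels(n)).is_cess)


class TestStochasticFamilies:
    def test_sl2_printed_example_is_cess_at_unit_bound(self):
        bound, is_cess, strict = sl2_bounds(0.3, 0.5, 0.7)
        assert is_cess and bound == pytest.approx(1.0)
        assert not strict  # 1 - p1 = 0.7 is not strictly above p3 = 0.7

    def test_sl2_degenerate_deterministic_point(self):
        bound, is_cess, _ = sl2_bounds(0.0, 1.0, 1.0, 0.0)
        assert is_cess and bound == pytest.approx(1.0)

    def test_sl2_caption_closed_form(self):
        # b/c > max{(p3+p4)/(1-p1), (p3+p4)/p3, 1} wherever the family is CESS.
        rng = np.random.default_rng(1)
        for _ in range(50):
            p1, p3, p4 = rng.random(3)
            bound, is_cess, _ = sl2_bounds(p1, 1.0, p3, p4)
            if not is_cess:
                continue
            expected = max((p3 + p4) / (1.0 - p1), (p3 + p4) / p3, 1.0)
            assert bound == pytest.approx(expected)

    def test_sl2_needs_recovery(self):
        # p2 + p3 (+ p4) must exceed 1, else a bad reputation never heals.
        _, is_cess, _ = sl2_bounds(0.0, 0.3, 0.3)
        assert not is_cess

    def test_ss1_bound_closed_form(self):
        bound, is_cess = ss1_bounds(0.0, 1.0, 0.1)
        assert is_cess and bound == pytest.approx(1.1)
        rng = np.random.default_rng(2)
        for _ in range(50):
            p1, p2, p3 = rng.random(3)
            bound, is_cess = ss1_bounds(p1, p2, p3)
            if p2 + p3 > 1.0 and p1 < 1.0 and p3 > 0:
                assert is_cess
                assert bound == pytest.approx(1.0 + p3 / (1.0 - p1))
            else:
                assert not is_cess

    def test_parameter_range_validated(self):
        with pytest.raises(ValueError):
            sl2_bounds(1.5, 0.5, 0.5)


class TestSecondOrder:
    @pytest.mark.parametrize("name", ["L3", "L6"])
    def test_simple_standing_and_stern_judging_hold_for_all_bc(self, name):
        v, unit = second_order_cess(catalog_lookup(name))
        assert v.is_cess and unit and v.bc_lower == 1.0

    def test_third_order_norm_rejected(self):
        with pytest.raises(ValueError, match="third order"):
            second_order_cess(catalog_lookup("L1"))

    def test_forgiving_defection_among_good_breaks_stability(self):
        n = catalog_lookup("L6")
        r1 = n.R1.copy()
        r1[GG, D] = 1.0
        r1[BG, D] = 1.0  # keep second order
        v, _ = second_order_cess(make_norm(n.P, r1, n.R2))
        assert not v.is_cess
        assert any("R1(G,G,D)<1" in f for f in v.failed_conditions)


class TestGenerousScoring:
    def test_construction(self):
        n = generous_scoring(2.0, 1.0)
        assert np.all(n.R1[:, D] == 0.5)

    @pytest.mark.parametrize("b,c", [(2.0, 1.0), (3.0, 1.0), (5.0, 2.0)])
    def test_never_a_strict_cess(self, b, c):
        v = classify_cess(generous_scoring(b, c))
        assert not v.is_cess
        # The bounds collapse onto the norm's own b/c ratio.
        assert v.bc_lower == pytest.approx(b / c)
        assert v.bc_upper == pytest.approx(b / c)

    def test_nash_indifference_in_rare_error_limit(self):
        n = generous_scoring(2.0, 1.0)
        gap_coarse = nash_payoff_gap(n, 2.0, 1.0, mu=1e-4)
        gap_fine = nash_payoff_gap(n, 2.0, 1.0, mu=1e-6)
        assert abs(gap_fine) < 1e-4
        assert abs(gap_fine) < abs(gap_coarse)  # vanishes with the error rate

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            generous_scoring(1.0, 2.0)


class TestAnalyticNumericalAgreement:
    def test_catalog_verdicts_and_bounds_agree(self, donor_only_cess_norm,
                                               mu3):
        analytic = classify_cess(donor_only_cess_norm)
        numerical = cess_check(donor_only_cess_norm, mu3)
        assert analytic.is_cess and numerical.is_cess
        assert numerical.bc_lower == pytest.approx(analytic.bc_lower,
                                                   abs=0.05)

    def test_random_deterministic_norms_agree(self,
                                              random_deterministic_norms,
                                              mu3):
        for n in random_deterministic_norms:
            assert (classify_cess(n).is_cess
                    == cess_check(n, mu3).is_cess)
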