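"""Norm representation: validation, catalog, encoding, relabeling symmetry."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from recinorm import (
    ErrorRates, Norm, canonical_id, catalog_lookup, decode_deterministic,
    effective_norm, encode_deterministic, make_norm, norm_from_json,
    norm_to_json, passive_r2, swap_labels,
)
from recinorm.norms import BB, BG, C, D, GB, GG

probs = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)


def norm_strategy():
    return st.builds(
        lambda e: Norm(e[:4], np.reshape(e[4:12], (4, 2)),
                       np.reshape(e[12:], (4, 2))),
        st.lists(probs, min_size=20, max_size=20),
    )


class TestValidation:
    def test_all_zero_norm_defects_and_assigns_bad(self):
        n = make_norm([0] * 4, [0] * 8, [0] * 8)
        assert np.all(n.P == 0) and np.all(n.R1 == 0) and np.all(n.R2 == 0)
        assert n.is_deterministic

    def test_out_of_range_entry_is_named(self):
        r1 = np.zeros((4, 2))
        r1[GG, C] = 1.2
        with pytest.raises(ValueError, match=r"R1\(GG\.C\)"):
            make_norm([0] * 4, r1, [0] * 8)

    def test_mapping_input_with_wrong_keys_rejected(self):
        with pytest.raises(ValueError, match="keys mismatch"):
            make_norm({"GG": 1, "GB": 0, "BG": 1, "XX": 0},
                      [0] * 8, [0] * 8)


class TestCatalog:
    def test_l1_matches_table(self):
        n = catalog_lookup("L1")
        assert n.is_deterministic and n.is_recipient_passive
        assert n.P.tolist() == [1, 0, 1, 1]
        assert n.R1.tolist() == [[1, 0], [1, 1], [1, 0], [1, 0]]

    def test_l6_is_stern_judging(self):
        n = catalog_lookup("Stern Judging")
        assert n.name == "L6"
        # Second-order: assess by the recipient's standing and the action.
        assert n.R1[:, C].tolist() == [1, 0, 1, 0]
        assert n.R1[:, D].tolist() == [0, 1, 0, 1]
        assert n.P.tolist() == [1, 0, 1, 0]
        assert n.order == 2

    def test_forgiver_alias(self):
        assert catalog_lookup("Forgiver").name == "S16"

    def test_s16_only_punishes_defection_among_good(self):
        n = catalog_lookup("S16")
        r1 = n.R1.copy()
        r1[GG, D] = 1
        assert np.all(r1 == 1.0)  # every other donor assessment is good

    def test_ss1_parametric_entries(self):
        n = catalog_lookup("sS1", p1=0.0, p2=1.0, p3=0.1)
        assert n.R1[GG, D] == 0.0
        assert n.R1[GB, D] == 1.0
        assert n.R1[BG, D] == 0.1

    def test_generous_scoring_forgives_with_1_minus_c_over_b(self):
        n = catalog_lookup("GenerousScoring", b=2.0, c=1.0)
        assert np.all(n.R1[:, D] == 0.5)
        assert np.all(n.R1[:, C] == 1.0)
        assert n.order == 1

    def test_unknown_name(self):
        with pytest.raises(KeyError):
            catalog_lookup("L9")

    @pytest.mark.parametrize("name,order", [("L1", 3), ("L6", 2), ("L3", 2)])
    def test_order_detection(self, name, order):
        assert catalog_lookup(name).order == order


class TestEffectiveRules:
    def test_implementation_error_scales_cooperation(self):
        n = catalog_lookup("L1")
        eff = effective_norm(n, ErrorRates(mu_e=0.1))
        assert eff.P[GG] == pytest.approx(0.9)

    def test_assessment_error_flips(self):
        n = catalog_lookup("L1")
        eff = effective_norm(n, ErrorRates(mu_a1=0.001))
        assert eff.R1[GG, C] == pytest.approx(0.999)

    def test_zero_errors_identity(self):
        n = catalog_lookup("L3")
        eff = effective_norm(n, ErrorRates())
        assert np.array_equal(eff.P, n.P) and np.array_equal(eff.R1, n.R1)

    @settings(max_examples=40, derandomize=True)
    @given(norm_strategy(),
           st.floats(0, 0.99), st.floats(0, 0.49), st.floats(0, 0.49))
    def test_effective_rules_respect_error_bounds(self, n, me, m1, m2):
        eff = effective_norm(n, ErrorRates(me, m1, m2))
        assert np.all(eff.P <= 1.0 - me + 1e-12)
        assert np.all((eff.R1 >= m1 - 1e-12) & (eff.R1 <= 1 - m1 + 1e-12))
        assert np.all((eff.R2 >= m2 - 1e-12) & (eff.R2 <= 1 - m2 + 1e-12))

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            ErrorRates(mu_e=1.0)
        with pytest.raises(ValueError):
            ErrorRates(mu_a1=0.5)


class TestEncoding:
    @pytest.mark.parametrize("nid", [0, 1, 987654, (1 << 20) - 1, 768716])
    def test_round_trip(self, nid):
        assert encode_deterministic(decode_deterministic(nid)) == nid

    def test_decode_zero_is_all_zero(self):
        n = decode_deterministic(0)
        assert np.all(n.entries() == 0.0)

    def test_l1_with_passive_r2_packs_to_hand_computed_id(self):
        # P=(1,0,1,1) -> 0b1011; R1 rows (1,0),(1,1),(1,0),(1,0) ->
        # 0b10111010; passive R2 -> 0b11001100.
        expected = (0b1011 << 16) | (0b10111010 << 8) | 0b11001100
        assert expected == 768716
        assert encode_deterministic(catalog_lookup("L1")) == expected

    def test_stochastic_norm_has_no_encoding(self):
        with pytest.raises(ValueError, match="deterministic"):
            encode_deterministic(catalog_lookup("sS1", p1=0, p2=1, p3=0.1))

    def test_out_of_range_id(self):
        with pytest.raises(ValueError):
            decode_deterministic(1 << 20)


class TestSwapSymmetry:
    @settings(max_examples=40, derandomize=True)
    @given(norm_strategy())
    def test_swap_is_involution(self, n):
        back = swap_labels(swap_labels(n))
        assert np.allclose(back.entries(), n.entries())

    def test_swap_of_always_good_is_always_bad(self):
        n = make_norm([1] * 4, [1] * 8, [1] * 8)
        s = swap_labels(n)
        assert np.all(s.R1 == 0.0) and np.all(s.R2 == 0.0)

    def test_swap_permutes_contexts(self):
        n = catalog_lookup("L6")
        s = swap_labels(n)
        assert s.P[GG] == n.P[BB] and s.P[GB] == n.P[BG]
        assert s.R1[GG, C] == 1.0 - n.R1[BB, C]

    @pytest.mark.parametrize("nid", [0, 37, 987654, 768716])
    def test_canonical_id_idempotent_and_minimal(self, nid):
        cid = canonical_id(nid)
        assert canonical_id(cid) == cid
        assert cid <= nid


class TestJsonSchema:
    def test_round_trip(self):
        n = catalog_lookup("sL2", p1=0.3, p2=0.5, p3=0.7)
        m = norm_from_json(norm_to_json(n))
        assert np.allclose(m.entries(), n.entries())
        assert m.name == "sL2"

    def test_unexpected_key_rejected(self):
        payload = json.loads(norm_to_json(catalog_lookup("L1")))
        payload["extra"] = 1
        with pytest.raises(ValueError, match="unexpected"):
            norm_from_json(payload)

    def test_missing_rule_rejected(self):
        payload = json.loads(norm_to_json(catalog_lookup("L1")))
        del payload["R2"]
        with pytest.raises(ValueError, match="R2"):
            norm_from_json(payload)


def test_passive_r2_keeps_good_recipients_good():
    r2 = passive_r2()
    assert r2[GG].tolist() == [1, 1] and r2[BG].tolist() == [1, 1]
    assert r2[GB].tolist() == [0, 0] and r2[BB].tolist() == [0, 0]
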