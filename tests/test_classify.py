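import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from avhue import (
    Subtype,
    classify_vesicle,
    compute_color,
    compute_hue_angle,
    compute_saturation,
    default_rules,
    profile_neurons,
    profiles_to_frame,
    rules_from_config,
)
from avhue.classify import rules_to_json, validate_rules
from avhue.segment import ChannelThresholds


def phasor_hue(r, g, b):
    """Independent colour-wheel hue: argument of R + G*e^{i120} + B*e^{i240}."""
    z = r + g * np.exp(2j * np.pi / 3) + b * np.exp(4j * np.pi / 3)
    return float(np.degrees(np.angle(z)) % 360.0)


def hue_diff(a, b):
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


class TestHueAngle:
    @pytest.mark.parametrize(
        "rgb,expected",
        [
            ((1, 0, 0), 0.0),       # pure mRFP -> red axis
            ((0, 1, 0), 120.0),     # pure eGFP -> green axis
            ((0, 0, 1), 240.0),     # pure CTSD -> blue axis
            ((1, 1, 0), 60.0),      # AP signature -> yellow
            ((1, 0, 1), 300.0),     # AL signature -> magenta
            ((0, 1, 1), 180.0),     # cyan axis
        ],
    )
    def test_canonical_axes(self, rgb, expected):
        assert compute_hue_angle(*rgb) == pytest.approx(expected, abs=1e-12)

    def test_achromatic_is_undefined(self):
        assert math.isnan(compute_hue_angle(0.4, 0.4, 0.4))
        assert math.isnan(compute_hue_angle(0, 0, 0))

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            compute_hue_angle(-0.1, 0.2, 0.3)

    def test_agrees_with_phasor_oracle(self, rng):
        triples = rng.uniform(0, 1, size=(2000, 3))
        triples = triples[np.ptp(triples, axis=1) > 1e-6]
        for r, g, b in triples:
            assert hue_diff(compute_hue_angle(r, g, b), phasor_hue(r, g, b)) < 1e-9

    # intensities of 0 or >= 1e-9 of full scale: subnormal floats are not
    # physical intensities and lose precision in the opponent components
    intensity = st.one_of(st.just(0.0), st.floats(1e-9, 1.0))

    @settings(derandomize=True, max_examples=200)
    @given(r=intensity, g=intensity, b=intensity, k=st.floats(1e-3, 1e3))
    def test_scale_invariance(self, r, g, b, k):
        h1 = compute_hue_angle(r, g, b)
        h2 = compute_hue_angle(k * r, k * g, k * b)
        if math.isnan(h1):
            assert math.isnan(h2)
        else:
            assert hue_diff(h1, h2) < 1e-6

    @settings(derandomize=True, max_examples=200)
    @given(r=intensity, g=intensity, b=intensity)
    def test_channel_rotation_shifts_hue_120_degrees(self, r, g, b):
        h = compute_hue_angle(r, g, b)
        if math.isnan(h):
            return
        rotated = compute_hue_angle(b, r, g)  # R<-B, G<-R, B<-G
        assert hue_diff(rotated, h + 120.0) < 1e-6


class TestSaturation:
    @pytest.mark.parametrize(
        "rgb,expected",
        [((1, 0, 0), 100.0), ((0.5, 0.5, 0.5), 0.0), ((0.75, 0.25, 0.25), 50.0)],
    )
    def test_formula(self, rgb, expected):
        assert compute_saturation(*rgb) == pytest.approx(expected)

    def test_zero_for_black(self):
        assert compute_saturation(0, 0, 0) == 0.0

    def test_bit_depth_normalisation(self):
        # (191.25, 63.75, 63.75) / 255 = (0.75, 0.25, 0.25)
        assert compute_saturation(191.25, 63.75, 63.75, bit_depth=8) == pytest.approx(50.0)

    def test_full_lightness_flagged_saturated_white(self):
        color = compute_color(255, 255, 255, bit_depth=8)
        assert color.saturated_white and color.saturation_pct == 0.0

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            compute_saturation(1, -1, 0)

    @settings(derandomize=True, max_examples=200)
    @given(r=st.floats(0, 1), g=st.floats(0, 1), b=st.floats(0, 1))
    def test_matches_direct_formula(self, r, g, b):
        mx, mn = max(r, g, b), min(r, g, b)
        expected = 0.0 if mx + mn == 0 else (mx - mn) / (mx + mn) * 100.0
        assert compute_saturation(r, g, b) == pytest.approx(expected, abs=1e-9)


THR = ChannelThresholds(10.0, 10.0, 10.0)  # gfp, rfp, ctsd


def _color(r, g, b):
    return compute_color(r, g, b, bit_depth=8)


class TestClassification:
    def test_yellow_with_rfp_gfp_present_is_ap(self):
        color = _color(200, 200, 5)  # hue 60, high saturation
        assert classify_vesicle(color, THR) is Subtype.AP

    def test_blue_with_only_ctsd_is_ly(self):
        color = _color(5, 5, 200)  # hue 240
        assert classify_vesicle(color, THR) is Subtype.LY

    def test_magenta_with_rfp_ctsd_is_al(self):
        color = _color(200, 5, 200)  # hue 300
        assert classify_vesicle(color, THR) is Subtype.AL

    def test_white_low_saturation_all_present_is_pa_al(self):
        color = _color(200, 195, 205)  # near-achromatic, all above threshold
        assert color.saturation_pct < 25
        assert classify_vesicle(color, THR) is Subtype.PA_AL

    def test_blue_hue_with_rfp_also_present_is_not_ly(self):
        color = _color(100, 5, 200)  # hue in blue-purple region, R above threshold
        assert classify_vesicle(color, THR) is not Subtype.LY

    def test_sub_threshold_vesicle_is_unclassified(self):
        assert classify_vesicle(_color(5, 5, 5), THR) is Subtype.UNCLASSIFIED

    def test_red_only_defaults_to_unclassified(self):
        color = _color(200, 5, 5)  # hue ~0, CTSD below threshold
        assert classify_vesicle(color, THR) is Subtype.UNCLASSIFIED

    def test_red_only_option_counts_ctsd_negative_al(self):
        rules = default_rules(red_as_ctsd_negative_al=True)
        assert classify_vesicle(_color(200, 5, 5), THR, rules) is Subtype.AL

    def test_scale_invariance_with_thresholds(self):
        color = _color(200, 200, 5)
        scaled = compute_color(100, 100, 2.5, bit_depth=8)
        thr_scaled = ChannelThresholds(5.0, 5.0, 5.0)
        assert classify_vesicle(color, THR) is classify_vesicle(scaled, thr_scaled)


class TestRules:
    def test_overlapping_hue_ranges_rejected(self):
        with pytest.raises(ValueError, match="overlapping hue ranges"):
            rules_from_config(
                {
                    "AP": {"hue_range": [30, 90]},
                    "AL": {"hue_range": [80, 150]},
                }
            )

    def test_wrapping_range_overlap_detected(self):
        with pytest.raises(ValueError, match="overlapping"):
            rules_from_config(
                {"AL": {"hue_range": [330, 30]}, "AP": {"hue_range": [20, 90]}}
            )

    def test_config_round_trip(self):
        rules = rules_from_config(
            {
                "PA_AL": {"requires_above": ["RFP_LC3", "GFP_LC3", "CTSD"], "saturation_max_pct": 25},
                "AP": {"hue_range": [30, 90], "requires_above": ["RFP_LC3", "GFP_LC3"]},
            }
        )
        assert rules[0].subtype is Subtype.PA_AL
        assert "hue_ranges" in rules_to_json(rules)

    def test_default_rules_are_valid(self):
        validate_rules(default_rules())


class TestNeuronProfiles:
    def test_counts_and_total(self, segmented_small):
        _, mask, _, vesicles, _, _ = segmented_small
        profiles = profile_neurons(vesicles, neuron_ids=mask.roi_ids)
        assert len(profiles) == mask.n_rois
        frame = profiles_to_frame(profiles)
        # conservation: per-neuron subtype counts (incl. UNCLASSIFIED) sum to total
        parts = frame[["AP", "AL", "PA_AL", "LY", "UNCLASSIFIED"]].sum(axis=1)
        assert (parts == frame["total"]).all()
        # field-level conservation against assigned vesicles
        assert frame["total"].sum() == sum(1 for v in vesicles if v.neuron_id > 0)

    def test_zero_vesicle_neuron_still_reported(self):
        profiles = profile_neurons([], neuron_ids=[1, 2])
        assert [p.neuron_id for p in profiles] == [1, 2]
        assert all(p.total == 0 for p in profiles)

    def test_explicit_counts(self):
        from avhue.segment import Vesicle

        def v(i, subtype):
            return Vesicle(
                id=i,
                coords=np.zeros((1, 2), int),
                area_px=4,
                area_um2=0.16,
                centroid=(0, 0),
                mean_r=0,
                mean_g=0,
                mean_b=0,
                neuron_id=1,
                subtype=subtype,
            )

        vesicles = [v(i, Subtype.AP) for i in range(3)] + [v(9 + i, Subtype.LY) for i in range(2)]
        (profile,) = profile_neurons(vesicles)
        assert profile.counts == {"AP": 3, "AL": 0, "PA_AL": 0, "LY": 2, "UNCLASSIFIED": 0}
        assert profile.total == 5

    def test_subtype_recovery_on_small_scene(self, segmented_small):
        from avhue import classification_accuracy

        _, _, gt, vesicles, _, _ = segmented_small
        assert classification_accuracy(gt, vesicles) >= 0.95
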