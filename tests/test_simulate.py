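import numpy as np
import pandas as pd
import pytest

from avhue import (
    ChannelRole,
    IRConfig,
    SceneConfig,
    SUBTYPE_SIGNATURES,
    Subtype,
    generate_ir_overlay,
    generate_scene,
    read_ground_truth,
    write_ground_truth,
)
from avhue.simulate import RFP_POSITIVE_SUBTYPES, derive_composition

SMALL = dict(width_px=512, height_px=512, n_neurons=6, rng_seed=3)


class TestGenerateScene:
    def test_deterministic_under_fixed_seed(self):
        cfg = SceneConfig(**SMALL)
        f1, m1, g1 = generate_scene(cfg)
        f2, m2, g2 = generate_scene(cfg)
        np.testing.assert_array_equal(f1.pixels, f2.pixels)
        np.testing.assert_array_equal(m1.labels, m2.labels)
        pd.testing.assert_frame_equal(g1.vesicles, g2.vesicles)

    def test_empty_scene(self):
        field, mask, gt = generate_scene(SceneConfig(**{**SMALL, "n_neurons": 0}))
        assert mask.n_rois == 0 and gt.n_vesicles == 0

    def test_configured_counts_are_exact(self):
        cfg = SceneConfig(
            **{**SMALL, "vesicles_per_neuron": {"AP": 5, "AL": 5, "PA_AL": 2, "LY": 8}}
        )
        _, _, gt = generate_scene(cfg)
        assert gt.n_vesicles == 6 * 20
        assert (gt.composition["total"] == 20).all()

    def test_vesicles_lie_inside_their_soma(self, small_scene):
        _, mask, gt = small_scene
        rows = gt.vesicles["row"].round().astype(int)
        cols = gt.vesicles["col"].round().astype(int)
        owners = mask.labels[rows, cols]
        np.testing.assert_array_equal(owners, gt.vesicles["neuron_id"].to_numpy())

    def test_composition_consistent_with_vesicle_records(self, small_scene):
        _, mask, gt = small_scene
        gt.validate()
        # independent group-by oracle
        oracle = (
            gt.vesicles.groupby(["neuron_id", "subtype"]).size().unstack(fill_value=0)
        )
        for s in ("AP", "AL", "PA_AL", "LY"):
            got = gt.composition.set_index("neuron_id")[s]
            want = oracle[s] if s in oracle else pd.Series(0, index=got.index)
            assert (got == want.reindex(got.index, fill_value=0)).all()

    def test_clump_count_matches_configuration(self):
        cfg = SceneConfig(**{**SMALL, "clump_fraction": 0.25})
        _, _, gt = generate_scene(cfg)
        per_neuron_total = gt.composition["total"]
        expected_pairs = int(sum(round(0.25 * t / 2.0) for t in per_neuron_total))
        assert gt.n_clumps == expected_pairs
        # each clump id used exactly twice (doublets)
        counts = gt.vesicles.loc[gt.vesicles["clump_id"] >= 0, "clump_id"].value_counts()
        assert (counts == 2).all()

    def test_density_limit_is_reported(self):
        cfg = SceneConfig(width_px=256, height_px=256, n_neurons=40, rng_seed=0)
        with pytest.raises(RuntimeError, match="density limit"):
            generate_scene(cfg)


class TestSignatureRendering:
    def test_peak_intensities_follow_signatures_before_noise(self):
        """Noise-free, blur-free render: spot peaks sit at the signature
        amplitudes (to within sub-pixel centre offset)."""
        cfg = SceneConfig(
            **SMALL,
            psf_sigma_um=0.0,
            background_level=0.0,
            soma_fill_level=0.0,
            apply_noise=False,
        )
        field, _, gt = generate_scene(cfg)
        full = field.full_scale
        for rec in gt.vesicles.itertuples(index=False):
            sig = SUBTYPE_SIGNATURES[Subtype(rec.subtype)].channel_means
            r, c = int(round(rec.row)), int(round(rec.col))
            sigma = rec.radius_px / 2.0
            # nearest pixel lies within 0.5 px of the true centre per axis
            floor = float(np.exp(-0.25 / sigma**2))
            for role, expected in sig.items():
                window = field.channel(role)[r - 1 : r + 2, c - 1 : c + 2]
                peak = window.max() / full
                if expected == 0.0:
                    assert peak < 0.05  # only tails of neighbouring spots
                else:
                    assert expected * floor * 0.999 <= peak <= expected * 1.05


class TestIROverlay:
    @pytest.fixture(scope="class")
    def overlay(self):
        cfg = SceneConfig(
            width_px=512,
            height_px=512,
            n_neurons=8,
            vesicles_per_neuron={"AP": 2, "AL": 2, "PA_AL": 1, "LY": 2},
            rng_seed=5,
        )
        field, mask, gt = generate_scene(cfg)
        ircfg = IRConfig(n_objects=40, assoc_fraction=0.4, rng_seed=6)
        field2, gt2 = generate_ir_overlay(field, gt, ircfg, cfg)
        return cfg, field, gt, field2, gt2

    def test_ir_channel_added(self, overlay):
        cfg, field, gt, field2, gt2 = overlay
        assert not field.has_role(ChannelRole.IR) and field2.has_role(ChannelRole.IR)
        assert field2.n_channels == field.n_channels + 1

    def test_association_bookkeeping(self, overlay):
        cfg, field, gt, field2, gt2 = overlay
        objs = gt2.ir_objects
        assert len(objs) == 40
        assert objs["associated"].sum() == round(0.4 * 40)

    def test_associated_objects_overlap_rfp_vesicles(self, overlay):
        """Exhaustive geometric check of the recorded association flags."""
        cfg, field, gt, field2, gt2 = overlay
        rfp = gt.vesicles[gt.vesicles["subtype"].isin([s.value for s in RFP_POSITIVE_SUBTYPES])]
        for o in gt2.ir_objects.itertuples(index=False):
            d = np.hypot(rfp["row"] - o.row, rfp["col"] - o.col)
            touches = d < (rfp["radius_px"] + o.radius_px)
            if o.associated:
                assert touches.any()
            else:
                assert not touches.any()

    def test_assoc_fraction_zero_and_one(self):
        cfg = SceneConfig(
            width_px=512,
            height_px=512,
            n_neurons=8,
            vesicles_per_neuron={"AP": 2, "AL": 2, "PA_AL": 1, "LY": 2},
            rng_seed=5,
        )
        field, mask, gt = generate_scene(cfg)
        _, g0 = generate_ir_overlay(field, gt, IRConfig(n_objects=20, assoc_fraction=0.0, rng_seed=1), cfg)
        assert g0.ir_objects["associated"].sum() == 0
        _, g1 = generate_ir_overlay(field, gt, IRConfig(n_objects=20, assoc_fraction=1.0, rng_seed=1), cfg)
        assert g1.ir_objects["associated"].all()

    def test_existing_ir_channel_rejected(self, overlay):
        cfg, field, gt, field2, gt2 = overlay
        with pytest.raises(ValueError, match="already has an IR channel"):
            generate_ir_overlay(field2, gt2, IRConfig(n_objects=1), cfg)


class TestGroundTruthIO:
    def test_round_trip(self, tmp_path, small_scene):
        _, _, gt = small_scene
        d = write_ground_truth(gt, tmp_path / "gt")
        back = read_ground_truth(d)
        pd.testing.assert_frame_equal(back.vesicles, gt.vesicles)
        pd.testing.assert_frame_equal(back.composition, gt.composition)
        np.testing.assert_array_equal(back.soma_mask.labels, gt.soma_mask.labels)

    def test_composition_rederivable_after_round_trip(self, tmp_path, small_scene):
        _, _, gt = small_scene
        back = read_ground_truth(write_ground_truth(gt, tmp_path / "gt"))
        derived = derive_composition(back.vesicles, back.soma_mask.roi_ids)
        pd.testing.assert_frame_equal(derived, back.composition)

    def test_empty_ground_truth_headers(self, tmp_path):
        _, _, gt = generate_scene(SceneConfig(**{**SMALL, "n_neurons": 0}))
        back = read_ground_truth(write_ground_truth(gt, tmp_path / "gt"))
        assert len(back.vesicles) == 0 and list(back.vesicles.columns) == list(gt.vesicles.columns)
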