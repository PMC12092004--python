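import numpy as np
import pytest
from scipy import ndimage as ndi

from avhue import (
    ChannelRole,
    MultiChannelField,
    ROILabelMask,
    apply_size_exclusion,
    assign_to_neurons,
    build_puncta_mask,
    compute_channel_thresholds,
    extract_vesicles,
    watershed_split,
)
from avhue.segment import ChannelThresholds

CMAP3 = {"GFP_LC3": 0, "RFP_LC3": 1, "CTSD": 2}


def _field(planes, pixel_size=0.2, bit_depth=16):
    return MultiChannelField(np.asarray(planes), pixel_size, CMAP3, bit_depth)


def _two_roi_mask(h=16, w=16):
    lab = np.zeros((h, w), np.int32)
    lab[2:6, 2:6] = 1
    lab[10:14, 10:14] = 2
    return ROILabelMask(lab)


class TestChannelThresholds:
    def test_uniform_perikarya_give_their_value(self):
        planes = np.full((3, 16, 16), 50.0)
        thr = compute_channel_thresholds(_field(planes), _two_roi_mask(), n_sample=2)
        assert thr.gfp_lc3 == thr.rfp_lc3 == thr.ctsd == 50.0

    def test_mean_of_roi_means(self):
        planes = np.zeros((3, 16, 16))
        planes[:, 2:6, 2:6] = 40.0
        planes[:, 10:14, 10:14] = 60.0
        thr = compute_channel_thresholds(_field(planes), _two_roi_mask(), n_sample=2)
        assert thr.rfp_lc3 == pytest.approx(50.0)

    def test_fewer_rois_than_sample_warns_and_uses_all(self):
        planes = np.full((3, 16, 16), 7.0)
        with pytest.warns(UserWarning, match="using all"):
            thr = compute_channel_thresholds(_field(planes), _two_roi_mask(), n_sample=20)
        assert thr.sampled_roi_ids == (1, 2)

    def test_empty_mask_is_an_error(self):
        planes = np.zeros((3, 16, 16))
        with pytest.raises(ValueError, match="no ROIs"):
            compute_channel_thresholds(
                _field(planes), ROILabelMask(np.zeros((16, 16), np.int32)), n_sample=2
            )

    def test_matches_independent_per_roi_averaging(self, small_scene):
        """Seeded sampling: threshold equals the hand-computed mean of the
        sampled ROIs' mean intensities."""
        field, mask, _ = small_scene
        thr = compute_channel_thresholds(field, mask, n_sample=4, seed=42)
        chan = field.channel(ChannelRole.CTSD).astype(float)
        hand = np.mean([chan[mask.labels == i].mean() for i in thr.sampled_roi_ids])
        assert thr.ctsd == pytest.approx(hand, rel=1e-12)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            ChannelThresholds(-1.0, 0.0, 0.0)


class TestPunctaMask:
    def test_all_below_gives_empty_mask(self):
        planes = np.full((3, 8, 8), 10.0)
        masks = build_puncta_mask(_field(planes), ChannelThresholds(20, 20, 20))
        assert not masks.combined.any()

    def test_pixel_exactly_at_threshold_is_excluded(self):
        planes = np.zeros((3, 8, 8))
        planes[1, 4, 4] = 20.0
        planes[1, 4, 5] = 20.1
        masks = build_puncta_mask(_field(planes), ChannelThresholds(20, 20, 20))
        assert not masks.rfp_lc3[4, 4] and masks.rfp_lc3[4, 5]

    @pytest.mark.parametrize("bump", [1.0, 5.0, 25.0])
    def test_raising_threshold_never_grows_mask(self, rng, bump):
        planes = rng.uniform(0, 100, size=(3, 32, 32))
        f = _field(planes)
        base = build_puncta_mask(f, ChannelThresholds(50, 50, 50)).combined.sum()
        raised = build_puncta_mask(f, ChannelThresholds(50 + bump, 50 + bump, 50 + bump)).combined.sum()
        assert raised <= base


def _gaussian_pair(shape=(48, 48), centers=((24, 20), (24, 26)), sigma=2.0, amp=1000.0):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    img = np.zeros(shape, float)
    for r0, c0 in centers:
        img += amp * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma**2))
    return img


class TestWatershed:
    def test_single_disk_one_label(self):
        img = _gaussian_pair(centers=((24, 24),))
        labels = watershed_split(img > 100, img)
        assert labels.max() == 1

    def test_empty_mask_zero_labels(self):
        assert watershed_split(np.zeros((8, 8), bool), np.zeros((8, 8))).max() == 0

    def test_doublet_split_into_two(self):
        img = _gaussian_pair()  # centres 6 px apart, sigma 2 px
        labels = watershed_split(img > 100, img)
        assert labels.max() == 2

    def test_pixel_conservation(self):
        img = _gaussian_pair()
        mask = img > 100
        labels = watershed_split(mask, img)
        assert (labels > 0).sum() == mask.sum()
        assert not (mask & (labels == 0)).any()

    def test_pixel_conservation_on_scene(self, segmented_small):
        field, mask, gt, vesicles, thresholds, labeled = segmented_small
        masks = build_puncta_mask(field, thresholds)
        landscape = sum(
            field.channel(r).astype(float) for r in ("RFP_LC3", "GFP_LC3", "CTSD")
        )
        labels = watershed_split(masks.combined, landscape)
        assert (labels > 0).sum() == masks.combined.sum()


class TestSizeExclusion:
    def test_single_pixel_removed(self):
        lab = np.zeros((8, 8), np.int32)
        lab[4, 4] = 1
        assert apply_size_exclusion(lab, min_area_px=3).max() == 0

    def test_large_puncta_unchanged(self):
        lab = np.zeros((8, 8), np.int32)
        lab[2:5, 2:5] = 1
        lab[6:8, 0:4] = 2
        out = apply_size_exclusion(lab, min_area_px=3)
        assert out.max() == 2 and (out > 0).sum() == (lab > 0).sum()

    def test_min_greater_than_max_rejected(self):
        with pytest.raises(ValueError):
            apply_size_exclusion(np.zeros((4, 4), np.int32), min_area_px=5, max_area_px=3)

    def test_noise_specks_removed_without_losing_true_puncta(self, rng):
        """50 injected 1-px specks all removed; every real disk survives."""
        img = np.zeros((128, 128), bool)
        for k in range(5):  # true 5x5 puncta
            r, c = 12 + 20 * k, 30
            img[r : r + 5, c : c + 5] = True
        specks = 0
        while specks < 50:
            r, c = rng.integers(0, 128, 2)
            if not img[max(r - 2, 0) : r + 3, max(c - 2, 0) : c + 3].any():
                img[r, c] = True
                specks += 1
        labels, _ = ndi.label(img, structure=np.ones((3, 3), int))
        out = apply_size_exclusion(labels, min_area_px=3)
        assert out.max() == 5
        assert (out > 0).sum() == 5 * 25


class TestExtractAndAssign:
    def test_uniform_label_means(self):
        planes = np.zeros((3, 8, 8))
        planes[1, 2:4, 2:4] = 100.0  # RFP
        lab = np.zeros((8, 8), np.int32)
        lab[2:4, 2:4] = 1
        vesicles = extract_vesicles(lab, _field(planes, pixel_size=0.5))
        (v,) = vesicles
        assert v.mean_r == 100.0 and v.mean_g == 0.0 and v.mean_b == 0.0
        assert v.area_px == 4 and v.area_um2 == pytest.approx(4 * 0.25)

    def test_no_labels_empty_list(self):
        assert extract_vesicles(np.zeros((8, 8), np.int32), _field(np.zeros((3, 8, 8)))) == []

    def test_majority_assignment(self):
        lab = np.zeros((8, 8), np.int32)
        lab[:, 0:3] = 1  # neuron 1 owns cols 0-2
        lab[:, 3:5] = 2
        mask = ROILabelMask(lab)
        ves_lab = np.zeros((8, 8), np.int32)
        ves_lab[0, 0:5] = 1  # 3 px on neuron 1, 2 px on neuron 2
        vesicles = extract_vesicles(ves_lab, _field(np.ones((3, 8, 8))))
        assign_to_neurons(vesicles, mask)
        assert vesicles[0].neuron_id == 1

    def test_background_majority_gets_zero(self):
        mask = ROILabelMask(np.zeros((8, 8), np.int32))
        ves_lab = np.zeros((8, 8), np.int32)
        ves_lab[0, 0:4] = 1
        vesicles = extract_vesicles(ves_lab, _field(np.ones((3, 8, 8))))
        assign_to_neurons(vesicles, mask)
        assert vesicles[0].neuron_id == 0

    def test_scene_counts_recovered(self, segmented_small):
        _, mask, gt, vesicles, _, _ = segmented_small
        detected = sum(1 for v in vesicles if v.neuron_id > 0)
        assert detected == pytest.approx(gt.n_vesicles, rel=0.05)

    def test_intensity_ratio_matches_signature(self, segmented_small):
        """Detected AP puncta keep mRFP/eGFP ratio near the configured 1:1."""
        from avhue import classification_accuracy  # noqa: F401  (fixture already classified)

        field, mask, gt, vesicles, thresholds, _ = segmented_small
        aps = [v for v in vesicles if getattr(v.subtype, "value", v.subtype) == "AP"]
        assert aps
        ratios = [v.mean_r / v.mean_g for v in aps]
        assert np.median(ratios) == pytest.approx(1.0, rel=0.15)
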