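"""End-to-end orchestration: scene -> segmentation -> classification ->
IR partition -> tables, plus multi-field group experiments with the
figure-legend statistics.

``run_pipeline`` consumes a single JSON-style configuration covering
every module's parameters, runs the full analysis on one field (synthetic
or loaded from files), and writes the vesicle table, neuron profiles, IR
partitions and a provenance record (config hash, seeds, effective
subtype rules) to an output directory.  Runs are deterministic given the
configured seeds.

``run_group_experiment`` simulates several fields per experimental group,
pools per-neuron subtype counts, and compares groups per subtype with the
unpaired two-tailed t-test (two groups) or one-way ANOVA + Sidak.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field as dc_field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .classify import (
    Subtype,
    classify_vesicles,
    default_rules,
    profile_neurons,
    profiles_to_frame,
    rules_from_config,
    rules_to_json,
)
from .io import (
    ChannelRole,
    MultiChannelField,
    ROILabelMask,
    load_field,
    load_roi_mask,
    write_vesicle_table,
)
from .ir import partition_av_association, partitions_to_frame, segment_ir
from .segment import compute_channel_thresholds, role_puncta_mask, segment_field
from .simulate import IRConfig, SceneConfig, generate_ir_overlay, generate_scene, write_ground_truth
from .stats import GroupSample, anova_sidak, results_to_frame, summarize_groups, unpaired_t_test

__all__ = [
    "SegmentationSettings",
    "PipelineConfig",
    "config_from_json",
    "run_pipeline",
    "run_group_experiment",
]

_COUNT_SUBTYPES = [Subtype.AP, Subtype.AL, Subtype.PA_AL, Subtype.LY]


@dataclass
class SegmentationSettings:
    """Config keys mirroring the segmentation module's knobs."""

    thresholds_n_sample: int = 20
    thresholds_seed: int = 0
    watershed_min_separation_px: int = 2
    watershed_smoothing_sigma_px: float = 1.0
    size_min_area_px: int = 10
    size_max_area_px: int | None = None
    ir_min_area_px: int = 6


@dataclass
class PipelineConfig:
    """One run's full parameter set.

    mode "synthetic" renders a scene from ``scene`` (+ optional ``ir``);
    mode "files" reads ``image_path``/``mask_path`` with ``channel_map`` and
    ``pixel_size_um``.  ``subtype_rules`` optionally overrides the default
    hue/saturation rules.
    """

    mode: str = "synthetic"
    scene: SceneConfig = dc_field(default_factory=SceneConfig)
    ir: IRConfig | None = None
    segmentation: SegmentationSettings = dc_field(default_factory=SegmentationSettings)
    subtype_rules: Mapping | None = None
    image_path: str | None = None
    mask_path: str | None = None
    channel_map: Mapping[str, int] | None = None
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValueError("mode must be 'synthetic' or 'files'")
        if self.mode == "files":
            missing = [
                k
                for k in ("image_path", "mask_path", "channel_map", "pixel_size_um")
                if getattr(self, k) is None
            ]
            if missing:
                raise ValueError(f"mode 'files' requires: {', '.join(missing)}")
            roles = {ChannelRole[r] for r in self.channel_map}
            need = {ChannelRole.GFP_LC3, ChannelRole.RFP_LC3, ChannelRole.CTSD}
            if not need <= roles:
                absent = ", ".join(r.value for r in sorted(need - roles, key=lambda r: r.value))
                raise ValueError(f"channel_map must bind GFP_LC3, RFP_LC3 and CTSD; missing: {absent}")


def config_from_json(source: str | Path | Mapping) -> PipelineConfig:
    """Build a validated config from a JSON file path or an already-parsed dict."""
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            raw = json.load(fh)
    else:
        raw = dict(source)
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {', '.join(sorted(unknown))}")
    kwargs = dict(raw)
    if "scene" in kwargs and isinstance(kwargs["scene"], Mapping):
        scene = dict(kwargs["scene"])
        if "vesicle_radius_um" in scene:
            scene["vesicle_radius_um"] = tuple(scene["vesicle_radius_um"])
        kwargs["scene"] = SceneConfig(**scene)
    if kwargs.get("ir") is not None and isinstance(kwargs["ir"], Mapping):
        ir = dict(kwargs["ir"])
        if "radius_um" in ir:
            ir["radius_um"] = tuple(ir["radius_um"])
        kwargs["ir"] = IRConfig(**ir)
    if "segmentation" in kwargs and isinstance(kwargs["segmentation"], Mapping):
        kwargs["segmentation"] = SegmentationSettings(**kwargs["segmentation"])
    return PipelineConfig(**kwargs)


def _config_hash(config: PipelineConfig) -> str:
    def _default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, Mapping):
            return dict(o)
        return str(o)

    payload = json.dumps(dataclasses.asdict(config), default=_default, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig | Mapping | str | Path, out_dir: str | Path) -> dict:
    """Run the full single-field analysis and write result tables.

    Returns a dict with the in-memory results (field, mask, vesicles,
    thresholds, profiles, ir_partitions, ground_truth) alongside the files
    written under ``out_dir``.
    """
    if not isinstance(config, PipelineConfig):
        config = config_from_json(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    ground_truth = None
    if config.mode == "synthetic":
        field, mask, ground_truth = generate_scene(config.scene)
        if config.ir is not None:
            field, ground_truth = generate_ir_overlay(field, ground_truth, config.ir, config.scene)
        write_ground_truth(ground_truth, out_dir / "ground_truth")
    else:
        field = load_field(config.image_path, config.channel_map, config.pixel_size_um)
        mask = load_roi_mask(config.mask_path, expected_shape=field.shape)

    seg = config.segmentation
    vesicles, thresholds, labeled = segment_field(
        field,
        mask,
        n_sample=seg.thresholds_n_sample,
        seed=seg.thresholds_seed,
        min_separation_px=seg.watershed_min_separation_px,
        smoothing_sigma_px=seg.watershed_smoothing_sigma_px,
        min_area_px=seg.size_min_area_px,
        max_area_px=seg.size_max_area_px,
    )
    rules = rules_from_config(config.subtype_rules) if config.subtype_rules else default_rules()
    classify_vesicles(vesicles, thresholds, bit_depth=field.bit_depth, rules=rules)
    profiles = profile_neurons(vesicles, neuron_ids=mask.roi_ids)

    rules_json = rules_to_json(rules)
    write_vesicle_table(
        vesicles,
        out_dir / "vesicles.csv",
        metadata={"subtype_rules": rules_json, "thresholds": json.dumps(thresholds.as_dict())},
    )
    profiles_frame = profiles_to_frame(profiles)
    profiles_frame.to_csv(out_dir / "neuron_profiles.csv", index=False)

    ir_partitions = None
    if field.has_role(ChannelRole.IR):
        ir_thr = compute_channel_thresholds(  # perikarya-average rule on IR channel
            _ir_as_ctsd_view(field), mask, n_sample=seg.thresholds_n_sample, seed=seg.thresholds_seed
        ).ctsd
        ir_labels = segment_ir(field, ir_thr, min_area_px=seg.ir_min_area_px)
        rfp_mask = role_puncta_mask(
            field, thresholds, ChannelRole.RFP_LC3, min_area_px=seg.size_min_area_px
        )
        ir_partitions = partition_av_association(
            ir_labels, rfp_mask, mask, pixel_size_um=field.pixel_size_um
        )
        partitions_to_frame(ir_partitions).to_csv(out_dir / "ir_partitions.csv", index=False)

    provenance = {
        "package_version": __version__,
        "config_hash": _config_hash(config),
        "mode": config.mode,
        "seeds": {
            "scene": config.scene.rng_seed if config.mode == "synthetic" else None,
            "ir": config.ir.rng_seed if config.ir is not None else None,
            "thresholds": seg.thresholds_seed,
        },
        "thresholds": thresholds.as_dict(),
        "effective_subtype_rules": json.loads(rules_json),
        "n_vesicles": len(vesicles),
        "n_neurons": int(mask.n_rois),
    }
    with open(out_dir / "provenance.json", "w", encoding="utf-8") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)

    return {
        "field": field,
        "mask": mask,
        "ground_truth": ground_truth,
        "vesicles": vesicles,
        "labeled": labeled,
        "thresholds": thresholds,
        "profiles": profiles,
        "profiles_frame": profiles_frame,
        "ir_partitions": ir_partitions,
        "provenance": provenance,
        "out_dir": out_dir,
    }


def _ir_as_ctsd_view(field: MultiChannelField) -> MultiChannelField:
    """A shallow view binding the IR channel to the CTSD slot so the
    perikarya-average threshold helper can run on it."""
    cmap = dict(field.channel_map)
    cmap[ChannelRole.CTSD] = cmap[ChannelRole.IR]
    return MultiChannelField(field.pixels, field.pixel_size_um, cmap, field.bit_depth)


def per_neuron_counts(profiles_frame: pd.DataFrame) -> pd.DataFrame:
    """Per-neuron subtype counts in long-friendly wide form."""
    cols = ["neuron_id"] + [s.value for s in _COUNT_SUBTYPES] + ["total"]
    return profiles_frame[cols].copy()


def run_group_experiment(
    group_scenes: Mapping[str, SceneConfig],
    n_fields_per_group: int = 10,
    segmentation: SegmentationSettings | None = None,
    base_seed: int = 0,
    comparisons: Sequence[tuple[str, str]] | None = None,
) -> dict:
    """Simulate and analyse a multi-group experiment on per-neuron counts.

    Each group's scene config is replicated over ``n_fields_per_group``
    fields with derived seeds; per-neuron subtype counts are pooled across
    fields (neurons are the unit of analysis).  Two groups are compared per
    subtype with the unpaired two-tailed t-test; three or more use one-way
    ANOVA + Sidak over ``comparisons`` (default: every pair against the
    first group).
    """
    seg = segmentation or SegmentationSettings()
    counts_by_group: dict[str, pd.DataFrame] = {}
    for gi, (label, scene) in enumerate(group_scenes.items()):
        frames = []
        for fi in range(n_fields_per_group):
            seed = (base_seed * 1_000_003 + gi * 10_007 + fi) % (2**31)
            field, mask, _ = generate_scene(replace(scene, rng_seed=seed))
            vesicles, thresholds, _ = segment_field(
                field,
                mask,
                n_sample=seg.thresholds_n_sample,
                seed=seg.thresholds_seed,
                min_separation_px=seg.watershed_min_separation_px,
                smoothing_sigma_px=seg.watershed_smoothing_sigma_px,
                min_area_px=seg.size_min_area_px,
                max_area_px=seg.size_max_area_px,
            )
            classify_vesicles(vesicles, thresholds, bit_depth=field.bit_depth)
            frame = profiles_to_frame(profile_neurons(vesicles, neuron_ids=mask.roi_ids))
            frame.insert(0, "field", fi)
            frames.append(per_neuron_counts_with_field(frame))
        counts_by_group[label] = pd.concat(frames, ignore_index=True)

    labels = list(counts_by_group)
    tests: dict[str, list] = {}
    summaries = {}
    for subtype in _COUNT_SUBTYPES:
        samples = [
            GroupSample(label, counts_by_group[label][subtype.value].to_numpy(), unit="neuron")
            for label in labels
        ]
        summaries[subtype.value] = summarize_groups(samples)
        if len(samples) == 2:
            tests[subtype.value] = [unpaired_t_test(samples[0], samples[1])]
        else:
            pairs = list(comparisons) if comparisons else [(labels[0], l) for l in labels[1:]]
            _, pairwise = anova_sidak(samples, pairs)
            tests[subtype.value] = pairwise
    return {
        "counts": counts_by_group,
        "summaries": summaries,
        "tests": tests,
        "tests_frame": pd.concat(
            [results_to_frame(rs).assign(subtype=s) for s, rs in tests.items()], ignore_index=True
        ),
    }


def per_neuron_counts_with_field(frame: pd.DataFrame) -> pd.DataFrame:
    cols = ["field", "neuron_id"] + [s.value for s in _COUNT_SUBTYPES] + ["total"]
    return frame[cols].copy()
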