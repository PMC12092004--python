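"""Hue-angle / saturation classification of tandem-fluorescent-LC3 puncta.

The tfLC3 (mRFP-eGFP-LC3) reporter plus a cathepsin-D (CTSD) immunolabel
gives every vesicle a three-channel colour signature: autophagosomes (AP)
carry both LC3 fluorophores (yellow), autolysosomes (AL) have quenched
eGFP but CTSD (purple/magenta), poorly-acidified AL (pa-AL) keep all
three signals (white, low saturation), and pure lysosomes (LY) are
CTSD-only (blue).  Each vesicle's mean channel intensities (R = mRFP-LC3,
G = eGFP-LC3, B = CTSD) are reduced to a hue angle and a saturation
percentage, and vesicles are binned into subtypes by hue range, channel
presence above the perikarya-derived thresholds, and a saturation cutoff
for the achromatic "white" class.

Hue is the colour-wheel angle of the opponent-axis vector
``(2R - G - B, sqrt(3) * (G - B))`` in degrees, mapped to [0, 360); it is
undefined (NaN) for achromatic input.  Note the first component is the
x-axis of the atan2: spreadsheet ATAN2 takes (x, y), so the numpy call is
``arctan2(sqrt(3) * (G - B), 2R - G - B)``.  Saturation is
``(max - min) / (max + min) * 100`` on [0, 1]-normalised intensities,
valid while lightness ``(max + min) / 2`` is below 1; a vesicle at full
lightness is flagged saturated-white and given saturation 0.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field as dc_field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ChannelRole

__all__ = [
    "Subtype",
    "VesicleColor",
    "SubtypeRule",
    "NeuronProfile",
    "compute_hue_angle",
    "compute_saturation",
    "compute_color",
    "default_rules",
    "rules_from_config",
    "validate_rules",
    "classify_vesicle",
    "classify_vesicles",
    "profile_neurons",
    "profiles_to_frame",
]


class Subtype(str, enum.Enum):
    AP = "AP"          # autophagosome: eGFP + mRFP, yellow
    AL = "AL"          # autolysosome: mRFP + CTSD, purple
    PA_AL = "PA_AL"    # poorly acidified AL: all three, white
    LY = "LY"          # lysosome: CTSD only, blue
    UNCLASSIFIED = "UNCLASSIFIED"


def compute_hue_angle(R, G, B):
    """Hue angle in degrees on [0, 360), or NaN when achromatic.

    Accepts scalars or broadcastable arrays of non-negative intensities;
    hue is invariant under positive rescaling of (R, G, B).
    """
    R, G, B = np.asarray(R, float), np.asarray(G, float), np.asarray(B, float)
    if np.any(R < 0) or np.any(G < 0) or np.any(B < 0):
        raise ValueError("channel intensities must be non-negative")
    x = 2.0 * R - G - B
    y = math.sqrt(3.0) * (G - B)
    with np.errstate(invalid="ignore"):
        hue = np.degrees(np.arctan2(y, x))
    hue = np.where(hue < 0, hue + 360.0, hue)
    hue = np.where(hue >= 360.0, 0.0, hue)  # guard against rounding at the seam
    hue = np.where((x == 0) & (y == 0), np.nan, hue)
    return float(hue) if hue.ndim == 0 else hue


def compute_saturation(R, G, B, bit_depth: int | None = None):
    """Saturation percent on [0, 100]: (max - min) / (max + min) * 100.

    Intensities are normalised to [0, 1] by ``2**bit_depth - 1`` when
    ``bit_depth`` is given (pass None for already-normalised input).  Returns
    0 for achromatic input (max + min == 0) and for the degenerate
    full-lightness case (lightness == 1, see :func:`compute_color`).
    """
    R, G, B = np.asarray(R, float), np.asarray(G, float), np.asarray(B, float)
    if np.any(R < 0) or np.any(G < 0) or np.any(B < 0):
        raise ValueError("channel intensities must be non-negative")
    if bit_depth is not None:
        scale = float(2**bit_depth - 1)
        R, G, B = R / scale, G / scale, B / scale
    stacked = np.stack(np.broadcast_arrays(R, G, B))
    mx, mn = stacked.max(axis=0), stacked.min(axis=0)
    tot = mx + mn
    with np.errstate(divide="ignore", invalid="ignore"):
        sat = np.where(tot > 0, (mx - mn) / np.where(tot > 0, tot, 1.0) * 100.0, 0.0)
    lightness = tot / 2.0
    sat = np.where(lightness >= 1.0, 0.0, sat)
    return float(sat) if sat.ndim == 0 else sat


@dataclass
class VesicleColor:
    """Colour summary of one vesicle in native units plus derived quantities.

    ``r`` is the mRFP-LC3 mean, ``g`` the eGFP-LC3 mean and ``b`` the CTSD
    mean over the vesicle's pixels.
    """

    r: float
    g: float
    b: float
    hue_deg: float
    saturation_pct: float
    lightness: float
    saturated_white: bool = False


def compute_color(r: float, g: float, b: float, bit_depth: int = 16) -> VesicleColor:
    """Derive hue, saturation and lightness from native mean intensities."""
    scale = float(2**bit_depth - 1)
    rn, gn, bn = r / scale, g / scale, b / scale
    mx, mn = max(rn, gn, bn), min(rn, gn, bn)
    lightness = (mx + mn) / 2.0
    white = lightness >= 1.0
    return VesicleColor(
        r=float(r),
        g=float(g),
        b=float(b),
        hue_deg=compute_hue_angle(r, g, b),
        saturation_pct=0.0 if white else compute_saturation(rn, gn, bn),
        lightness=lightness,
        saturated_white=white,
    )


@dataclass(frozen=True)
class SubtypeRule:
    """One classification rule, evaluated in priority order.

    hue_ranges are half-open [lo, hi) intervals in degrees; an interval with
    lo > hi wraps through 0/360.  ``requires_above``/``requires_below`` name
    channel roles whose vesicle mean must lie above/below its threshold.
    ``only_above`` demands that *no other* classification channel exceeds its
    threshold.
    """

    subtype: Subtype
    hue_ranges: tuple[tuple[float, float], ...] = ()
    saturation_max_pct: float | None = None
    saturation_min_pct: float | None = None
    requires_above: tuple[ChannelRole, ...] = ()
    requires_below: tuple[ChannelRole, ...] = ()
    only_above: bool = False

    def hue_matches(self, hue_deg: float) -> bool:
        if not self.hue_ranges:
            return True
        if math.isnan(hue_deg):
            return False
        for lo, hi in self.hue_ranges:
            if lo <= hi:
                if lo <= hue_deg < hi:
                    return True
            elif hue_deg >= lo or hue_deg < hi:
                return True
        return False


def default_rules(
    white_cutoff_pct: float = 25.0, red_as_ctsd_negative_al: bool = False
) -> tuple[SubtypeRule, ...]:
    """The default subtype rules, in priority order.

    Hue windows centre on the canonical colour axes (yellow 60°, blue 240°,
    magenta 300°): AP [30°, 90°), LY [210°, 270°), AL [270°, 330°).  pa-AL is
    hue-free: it is the near-achromatic "white" class, caught first by the
    all-channels-present + low-saturation test.  Red-only vesicles (hue near
    0°, CTSD below threshold) are UNCLASSIFIED by default; set
    ``red_as_ctsd_negative_al`` to count them as CTSD-negative AL.
    """
    rules = [
        SubtypeRule(
            Subtype.PA_AL,
            requires_above=(ChannelRole.RFP_LC3, ChannelRole.GFP_LC3, ChannelRole.CTSD),
            saturation_max_pct=white_cutoff_pct,
        ),
        SubtypeRule(
            Subtype.AP,
            hue_ranges=((30.0, 90.0),),
            requires_above=(ChannelRole.RFP_LC3, ChannelRole.GFP_LC3),
        ),
        SubtypeRule(
            Subtype.AL,
            hue_ranges=((270.0, 330.0),),
            requires_above=(ChannelRole.RFP_LC3, ChannelRole.CTSD),
        ),
        SubtypeRule(
            Subtype.LY,
            hue_ranges=((210.0, 270.0),),
            requires_above=(ChannelRole.CTSD,),
            only_above=True,
        ),
    ]
    if red_as_ctsd_negative_al:
        rules.append(
            SubtypeRule(
                Subtype.AL,
                hue_ranges=((330.0, 30.0),),
                requires_above=(ChannelRole.RFP_LC3,),
                requires_below=(ChannelRole.CTSD,),
            )
        )
    validate_rules(rules)
    return tuple(rules)


def validate_rules(rules: Sequence[SubtypeRule]) -> None:
    """Reject configurations whose hue windows overlap (ambiguous colours)."""

    def _segments(rule: SubtypeRule):
        for lo, hi in rule.hue_ranges:
            if lo <= hi:
                yield lo, hi
            else:
                yield lo, 360.0
                yield 0.0, hi

    segs = [(seg, rule.subtype) for rule in rules for seg in _segments(rule)]
    for i, ((lo1, hi1), s1) in enumerate(segs):
        for (lo2, hi2), s2 in segs[i + 1 :]:
            if lo1 < hi2 and lo2 < hi1:
                raise ValueError(
                    f"overlapping hue ranges: {s1.value} [{lo1},{hi1}) and {s2.value} [{lo2},{hi2})"
                )


def rules_from_config(config: Mapping[str, Mapping]) -> tuple[SubtypeRule, ...]:
    """Build rules from a JSON ``subtype_rules`` block.

    Example::

        {"AP": {"hue_range": [30, 90], "requires_above": ["RFP_LC3", "GFP_LC3"]},
         "PA_AL": {"requires_above": ["RFP_LC3", "GFP_LC3", "CTSD"],
                   "saturation_max_pct": 25}}

    Rule order in the mapping is the evaluation priority.
    """
    rules = []
    for name, block in config.items():
        ranges = block.get("hue_ranges")
        if ranges is None and "hue_range" in block:
            ranges = [block["hue_range"]]
        rules.append(
            SubtypeRule(
                subtype=Subtype[name],
                hue_ranges=tuple((float(lo), float(hi)) for lo, hi in (ranges or ())),
                saturation_max_pct=block.get("saturation_max_pct"),
                saturation_min_pct=block.get("saturation_min_pct"),
                requires_above=tuple(ChannelRole[r] for r in block.get("requires_above", ())),
                requires_below=tuple(ChannelRole[r] for r in block.get("requires_below", ())),
                only_above=bool(block.get("only_above", False)),
            )
        )
    validate_rules(rules)
    return tuple(rules)


def rules_to_json(rules: Sequence[SubtypeRule]) -> str:
    """Serialise the effective rules for table-metadata echoing."""
    payload = [
        {
            "subtype": r.subtype.value,
            "hue_ranges": [list(h) for h in r.hue_ranges],
            "saturation_max_pct": r.saturation_max_pct,
            "saturation_min_pct": r.saturation_min_pct,
            "requires_above": [c.value for c in r.requires_above],
            "requires_below": [c.value for c in r.requires_below],
            "only_above": r.only_above,
        }
        for r in rules
    ]
    return json.dumps(payload, separators=(",", ":"))


def _above(role: ChannelRole, color: VesicleColor, thresholds) -> bool:
    value = {
        ChannelRole.RFP_LC3: color.r,
        ChannelRole.GFP_LC3: color.g,
        ChannelRole.CTSD: color.b,
    }[role]
    return value > thresholds.for_role(role)


def classify_vesicle(color: VesicleColor, thresholds, rules: Sequence[SubtypeRule] | None = None) -> Subtype:
    """Assign one vesicle to a subtype by the first matching rule.

    ``thresholds`` is a :class:`avhue.segment.ChannelThresholds` (native
    units, same scale as ``color.r/g/b``).  A vesicle matching no rule is
    UNCLASSIFIED — including achromatic-but-sub-threshold edge cases.
    """
    if rules is None:
        rules = default_rules()
    for rule in rules:
        if not rule.hue_matches(color.hue_deg):
            continue
        if rule.saturation_max_pct is not None and not color.saturation_pct < rule.saturation_max_pct:
            continue
        if rule.saturation_min_pct is not None and not color.saturation_pct >= rule.saturation_min_pct:
            continue
        if not all(_above(role, color, thresholds) for role in rule.requires_above):
            continue
        if any(_above(role, color, thresholds) for role in rule.requires_below):
            continue
        if rule.only_above:
            others = {ChannelRole.GFP_LC3, ChannelRole.RFP_LC3, ChannelRole.CTSD} - set(rule.requires_above)
            if any(_above(role, color, thresholds) for role in others):
                continue
        return rule.subtype
    return Subtype.UNCLASSIFIED


def classify_vesicles(vesicles, thresholds, bit_depth: int = 16, rules: Sequence[SubtypeRule] | None = None):
    """Fill hue_deg, saturation_pct and subtype on every vesicle, in place."""
    if rules is None:
        rules = default_rules()
    for v in vesicles:
        color = compute_color(v.mean_r, v.mean_g, v.mean_b, bit_depth=bit_depth)
        v.hue_deg = color.hue_deg
        v.saturation_pct = color.saturation_pct
        v.subtype = classify_vesicle(color, thresholds, rules)
    return vesicles


@dataclass
class NeuronProfile:
    """Per-neuron vesicle census: the 'Vesicle #/Neuron' unit of analysis."""

    neuron_id: int
    counts: dict = dc_field(default_factory=dict)
    mean_area_um2: dict = dc_field(default_factory=dict)

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))


_PROFILE_SUBTYPES = [Subtype.AP, Subtype.AL, Subtype.PA_AL, Subtype.LY, Subtype.UNCLASSIFIED]


def profile_neurons(vesicles, neuron_ids: Iterable[int] | None = None) -> list[NeuronProfile]:
    """Count classified vesicles per neuron (neuron_id > 0).

    ``neuron_ids`` lists the neurons to report (e.g. every label in the soma
    mask); neurons with zero vesicles still get an all-zero profile.  Vesicles
    with neuron_id 0 (background majority) are excluded.
    """
    assigned = [v for v in vesicles if v.neuron_id > 0]
    if neuron_ids is None:
        neuron_ids = sorted({v.neuron_id for v in assigned})
    profiles = []
    for nid in sorted(int(n) for n in neuron_ids):
        mine = [v for v in assigned if v.neuron_id == nid]
        counts = {s: 0 for s in _PROFILE_SUBTYPES}
        areas: dict[Subtype, list[float]] = {s: [] for s in _PROFILE_SUBTYPES}
        for v in mine:
            s = Subtype(v.subtype) if v.subtype is not None else Subtype.UNCLASSIFIED
            counts[s] += 1
            areas[s].append(v.area_um2)
        profiles.append(
            NeuronProfile(
                neuron_id=nid,
                counts={s.value: c for s, c in counts.items()},
                mean_area_um2={
                    s.value: (float(np.mean(a)) if a else float("nan")) for s, a in areas.items()
                },
            )
        )
    return profiles


def profiles_to_frame(profiles: Sequence[NeuronProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {"neuron_id": p.neuron_id}
        row.update({s.value: p.counts.get(s.value, 0) for s in _PROFILE_SUBTYPES})
        row["total"] = p.total
        row.update(
            {f"mean_area_um2_{s.value}": p.mean_area_um2.get(s.value, float("nan")) for s in _PROFILE_SUBTYPES}
        )
        rows.append(row)
    columns = (
        ["neuron_id"]
        + [s.value for s in _PROFILE_SUBTYPES]
        + ["total"]
        + [f"mean_area_um2_{s.value}" for s in _PROFILE_SUBTYPES]
    )
    return pd.DataFrame(rows, columns=columns)
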