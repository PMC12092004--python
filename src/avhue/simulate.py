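"""Synthetic confocal scene generator with per-vesicle ground truth.

Emulates single-plane, three-channel (eGFP-LC3 / mRFP-LC3 / CTSD)
confocal fields of neuronal somata containing punctate vesicles whose
channel signatures follow the tandem-fluorescent reporter logic:

====== ======== ======== ===== ==========================
subtype eGFP-LC3 mRFP-LC3 CTSD  rendered colour
====== ======== ======== ===== ==========================
AP      high     high     low   yellow
AL      low      high     high  purple/magenta
pa-AL   high     high     high  white (low saturation)
LY      low      low      high  blue
====== ======== ======== ===== ==========================

Forward model: vesicles are isotropic 2-D Gaussian spots (amplitude =
signature mean as a fraction of full scale, sigma = radius / 2) summed
into each channel, on top of a diffuse soma cytoplasm level and a field
background; the field is blurred with a global Gaussian PSF, converted
to expected photoelectrons, and corrupted with Poisson shot noise plus
Gaussian read noise before quantisation to the configured bit depth.
Intensity ratios — hence hue — are analytically known at spot centres.

Everything is deterministic given ``rng_seed`` (numpy PCG64 generator;
the seed fully pins placement, radii and noise draws).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .classify import Subtype
from .io import ChannelRole, MaskKind, MultiChannelField, ROILabelMask, load_roi_mask, save_roi_mask

__all__ = [
    "SubtypeSignature",
    "SUBTYPE_SIGNATURES",
    "SceneConfig",
    "IRConfig",
    "SyntheticGroundTruth",
    "generate_scene",
    "generate_ir_overlay",
    "write_ground_truth",
    "read_ground_truth",
]


@dataclass(frozen=True)
class SubtypeSignature:
    """Expected peak channel intensities (fractions of full scale)."""

    subtype: Subtype
    channel_means: Mapping[ChannelRole, float]
    note: str = ""


#: Default reporter signatures.  pa-AL uses equal peaks in all three
#: channels so its rendered saturation is ~0 ("white").
SUBTYPE_SIGNATURES: dict[Subtype, SubtypeSignature] = {
    Subtype.AP: SubtypeSignature(
        Subtype.AP,
        {ChannelRole.GFP_LC3: 0.8, ChannelRole.RFP_LC3: 0.8, ChannelRole.CTSD: 0.0},
        "yellow",
    ),
    Subtype.AL: SubtypeSignature(
        Subtype.AL,
        {ChannelRole.GFP_LC3: 0.0, ChannelRole.RFP_LC3: 0.8, ChannelRole.CTSD: 0.8},
        "purple",
    ),
    Subtype.PA_AL: SubtypeSignature(
        Subtype.PA_AL,
        {ChannelRole.GFP_LC3: 0.8, ChannelRole.RFP_LC3: 0.8, ChannelRole.CTSD: 0.8},
        "white",
    ),
    Subtype.LY: SubtypeSignature(
        Subtype.LY,
        {ChannelRole.GFP_LC3: 0.0, ChannelRole.RFP_LC3: 0.0, ChannelRole.CTSD: 0.8},
        "blue",
    ),
}

#: Subtypes whose mRFP-LC3 channel is high (used for IR association).
RFP_POSITIVE_SUBTYPES = (Subtype.AP, Subtype.AL, Subtype.PA_AL)

_SCENE_ROLES = (ChannelRole.GFP_LC3, ChannelRole.RFP_LC3, ChannelRole.CTSD)


@dataclass
class SceneConfig:
    """Parameters of one synthetic field.

    Defaults emulate a 40x confocal field: 1024x1024 px spanning
    212.34 x 212.34 um^2 (~0.2074 um/px), 16-bit.  Counts may be fixed
    per neuron or Poisson-sampled around the given means
    (``count_distribution``).  ``clump_fraction`` is the fraction of
    vesicles placed as touching same-subtype doublets.
    """

    width_px: int = 1024
    height_px: int = 1024
    pixel_size_um: float = 212.34 / 1024
    n_neurons: int = 10
    soma_radius_um: float = 10.0
    vesicles_per_neuron: Mapping[str, float] = dc_field(
        default_factory=lambda: {"AP": 5, "AL": 5, "PA_AL": 2, "LY": 8}
    )
    count_distribution: str = "fixed"  # "fixed" | "poisson"
    vesicle_radius_um: tuple[float, float] = (0.4, 1.0)
    psf_sigma_um: float = 0.1
    background_level: float = 0.02
    soma_fill_level: float = 0.05
    photons_full_scale: float = 1000.0
    read_noise_electrons: float = 2.0
    clump_fraction: float = 0.1
    bit_depth: int = 16
    apply_noise: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0 or self.pixel_size_um <= 0:
            raise ValueError("field geometry must be positive")
        if self.n_neurons < 0:
            raise ValueError("n_neurons must be >= 0")
        if self.soma_radius_um <= 0:
            raise ValueError("soma_radius_um must be > 0")
        if any(v < 0 for v in self.vesicles_per_neuron.values()):
            raise ValueError("vesicle counts must be >= 0")
        lo, hi = self.vesicle_radius_um
        if lo <= 0 or hi < lo:
            raise ValueError("vesicle_radius_um must be a positive (lo, hi) range")
        if not 0.0 <= self.clump_fraction <= 1.0:
            raise ValueError("clump_fraction must lie in [0, 1]")
        if self.count_distribution not in ("fixed", "poisson"):
            raise ValueError("count_distribution must be 'fixed' or 'poisson'")

    def packing_capacity(self) -> int:
        """Upper bound on vesicles per soma from random sequential packing.

        Random sequential adsorption of discs jams near 54.7% coverage; a
        conservative 50% factor over the mean claimed disc keeps placement
        reliable.  Poisson-sampled totals are truncated here.
        """
        soma_r_px = self.soma_radius_um / self.pixel_size_um
        mean_r_px = float(np.mean(self.vesicle_radius_um)) / self.pixel_size_um
        placement_r = soma_r_px - mean_r_px - 2
        claimed_r = mean_r_px + 1.5  # half the min centre separation
        return max(1, int(0.5 * (placement_r / claimed_r) ** 2))

    def hard(self) -> "SceneConfig":
        """A 2x-noise preset: quarter the photon budget, double read noise."""
        return replace(
            self,
            photons_full_scale=self.photons_full_scale / 4.0,
            read_noise_electrons=self.read_noise_electrons * 2.0,
        )


@dataclass
class IRConfig:
    """Parameters of the fourth (immunoreactivity) channel overlay."""

    n_objects: int = 200
    assoc_fraction: float = 0.5
    radius_um: tuple[float, float] = (0.3, 0.8)
    amplitude: float = 0.6
    background_level: float = 0.02
    soma_fill_level: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_objects < 0:
            raise ValueError("n_objects must be >= 0")
        if not 0.0 <= self.assoc_fraction <= 1.0:
            raise ValueError("assoc_fraction must lie in [0, 1]")


@dataclass
class SyntheticGroundTruth:
    """Simulator truth: per-vesicle records, per-neuron composition, masks."""

    vesicles: pd.DataFrame
    composition: pd.DataFrame
    soma_mask: ROILabelMask
    ir_objects: pd.DataFrame | None = None

    _VESICLE_COLUMNS = [
        "vesicle_id",
        "neuron_id",
        "row",
        "col",
        "radius_um",
        "radius_px",
        "subtype",
        "clump_id",
    ]
    _IR_COLUMNS = ["object_id", "neuron_id", "row", "col", "radius_px", "associated"]

    def validate(self) -> None:
        """Check that composition sums equal per-vesicle record counts."""
        derived = derive_composition(self.vesicles, self.soma_mask.roi_ids)
        if not derived.equals(self.composition.reset_index(drop=True)):
            raise AssertionError("composition table disagrees with per-vesicle records")

    @property
    def n_vesicles(self) -> int:
        return len(self.vesicles)

    @property
    def n_clumps(self) -> int:
        ids = self.vesicles["clump_id"]
        return int(ids[ids >= 0].nunique())


_SUBTYPE_ORDER = [Subtype.AP, Subtype.AL, Subtype.PA_AL, Subtype.LY]


def derive_composition(vesicles: pd.DataFrame, neuron_ids) -> pd.DataFrame:
    """Group-by count of true subtypes per neuron (all neurons reported)."""
    rows = []
    for nid in sorted(int(i) for i in neuron_ids):
        mine = vesicles[vesicles["neuron_id"] == nid]
        row = {"neuron_id": nid}
        for s in _SUBTYPE_ORDER:
            row[s.value] = int((mine["subtype"] == s.value).sum())
        row["total"] = int(len(mine))
        rows.append(row)
    cols = ["neuron_id"] + [s.value for s in _SUBTYPE_ORDER] + ["total"]
    return pd.DataFrame(rows, columns=cols).astype(int) if rows else pd.DataFrame(columns=cols, dtype=int)


def _place_somata(config: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Non-overlapping soma centres (row, col); raises past the density limit."""
    r_px = config.soma_radius_um / config.pixel_size_um
    margin = r_px + 2
    centres: list[tuple[float, float]] = []
    for k in range(config.n_neurons):
        for _ in range(5000):
            row = rng.uniform(margin, config.height_px - margin)
            col = rng.uniform(margin, config.width_px - margin)
            if all((row - r0) ** 2 + (col - c0) ** 2 >= (2 * r_px + 2) ** 2 for r0, c0 in centres):
                centres.append((row, col))
                break
        else:
            raise RuntimeError(
                f"could not place soma {k + 1}/{config.n_neurons}: density limit reached "
                f"(soma radius {config.soma_radius_um} um in {config.width_px}x{config.height_px} px)"
            )
    return np.asarray(centres, float).reshape(-1, 2)


def _soma_mask(config: SceneConfig, centres: np.ndarray) -> np.ndarray:
    rr, cc = np.mgrid[0 : config.height_px, 0 : config.width_px]
    labels = np.zeros((config.height_px, config.width_px), dtype=np.int32)
    r_px = config.soma_radius_um / config.pixel_size_um
    for k, (row, col) in enumerate(centres, start=1):
        labels[(rr - row) ** 2 + (cc - col) ** 2 <= r_px**2] = k
    return labels


def _sample_counts(config: SceneConfig, rng: np.random.Generator) -> dict[Subtype, int]:
    means = {s: float(config.vesicles_per_neuron.get(s.value, 0)) for s in _SUBTYPE_ORDER}
    if config.count_distribution == "fixed":
        return {s: int(round(m)) for s, m in means.items()}
    # Independent Poissons conditioned on a feasible total: draw the total
    # (truncated at the soma's packing capacity), split multinomially.
    mu = sum(means.values())
    if mu == 0:
        return {s: 0 for s in _SUBTYPE_ORDER}
    cap = config.packing_capacity()
    total = int(rng.poisson(mu))
    for _ in range(100):
        if total <= cap:
            break
        total = int(rng.poisson(mu))
    total = min(total, cap)
    split = rng.multinomial(total, [means[s] / mu for s in _SUBTYPE_ORDER])
    return dict(zip(_SUBTYPE_ORDER, (int(c) for c in split)))


def _add_gaussian_spot(img: np.ndarray, row: float, col: float, sigma: float, amplitude: float) -> None:
    """Accumulate an isotropic Gaussian into ``img`` over a +-4 sigma window."""
    if amplitude == 0.0:
        return
    h, w = img.shape
    half = int(math.ceil(4 * sigma)) + 1
    r0, r1 = max(0, int(row) - half), min(h, int(row) + half + 1)
    c0, c1 = max(0, int(col) - half), min(w, int(col) + half + 1)
    if r0 >= r1 or c0 >= c1:
        return
    rr = np.arange(r0, r1)[:, None] - row
    cc = np.arange(c0, c1)[None, :] - col
    img[r0:r1, c0:c1] += amplitude * np.exp(-(rr**2 + cc**2) / (2.0 * sigma**2))


def _place_vesicles_for_neuron(
    config: SceneConfig,
    rng: np.random.Generator,
    soma_centre: tuple[float, float],
    counts: dict[Subtype, int],
    next_clump_id: int,
) -> tuple[list[dict], int]:
    """Place single vesicles and touching doublets inside one soma."""
    soma_r_px = config.soma_radius_um / config.pixel_size_um
    subtype_list: list[Subtype] = []
    for s in _SUBTYPE_ORDER:
        subtype_list.extend([s] * counts[s])
    rng.shuffle(subtype_list)  # type: ignore[arg-type]

    n_total = len(subtype_list)
    n_pairs = int(round(config.clump_fraction * n_total / 2.0))
    # Pair off within the same subtype so doublets stay colour-pure.
    pairs: list[Subtype] = []
    pool = {s: counts[s] for s in _SUBTYPE_ORDER}
    for s in sorted(pool, key=lambda s: -pool[s]):
        while len(pairs) < n_pairs and pool[s] >= 2:
            pairs.append(s)
            pool[s] -= 2
    singles: list[Subtype] = []
    for s in _SUBTYPE_ORDER:
        singles.extend([s] * pool[s])
    rng.shuffle(singles)  # type: ignore[arg-type]

    lo, hi = config.vesicle_radius_um
    placed: list[dict] = []  # row, col, radius_px

    def _fits(row: float, col: float, r_px: float, ignore_partner: dict | None = None) -> bool:
        dr = math.hypot(row - soma_centre[0], col - soma_centre[1])
        if dr > soma_r_px - r_px - 2:
            return False
        for other in placed:
            if other is ignore_partner:
                continue
            d = math.hypot(row - other["row"], col - other["col"])
            if d < r_px + other["radius_px"] + 3:
                return False
        return True

    records: list[dict] = []

    def _record(subtype: Subtype, row: float, col: float, r_um: float, clump_id: int) -> None:
        r_px = r_um / config.pixel_size_um
        entry = {"row": row, "col": col, "radius_px": r_px}
        placed.append(entry)
        records.append(
            {
                "neuron_row": soma_centre[0],
                "row": row,
                "col": col,
                "radius_um": r_um,
                "radius_px": r_px,
                "subtype": subtype.value,
                "clump_id": clump_id,
            }
        )

    for s in pairs:
        r1 = rng.uniform(lo, hi)
        r2 = rng.uniform(lo, hi)
        for _ in range(10000):
            theta0 = rng.uniform(0, 2 * math.pi)
            rad0 = (soma_r_px - r1 / config.pixel_size_um - 2) * math.sqrt(rng.uniform(0, 1))
            row = soma_centre[0] + rad0 * math.sin(theta0)
            col = soma_centre[1] + rad0 * math.cos(theta0)
            if not _fits(row, col, r1 / config.pixel_size_um):
                continue
            theta = rng.uniform(0, 2 * math.pi)
            d = (r1 + r2) / config.pixel_size_um  # touching: centre distance = sum of radii
            row2, col2 = row + d * math.sin(theta), col + d * math.cos(theta)
            probe = {"row": row, "col": col, "radius_px": r1 / config.pixel_size_um}
            placed.append(probe)
            ok = _fits(row2, col2, r2 / config.pixel_size_um, ignore_partner=probe)
            placed.pop()
            if ok:
                _record(s, row, col, r1, next_clump_id)
                _record(s, row2, col2, r2, next_clump_id)
                next_clump_id += 1
                break
        else:
            raise RuntimeError("could not place doublet: vesicle density limit reached")

    # Larger vesicles first: packing succeeds far more often.
    single_radii = sorted(
        ((rng.uniform(lo, hi), s) for s in singles), key=lambda t: -t[0]
    )
    for r_um, s in single_radii:
        r_px = r_um / config.pixel_size_um
        for _ in range(10000):
            theta = rng.uniform(0, 2 * math.pi)
            rad = (soma_r_px - r_px - 2) * math.sqrt(rng.uniform(0, 1))
            row = soma_centre[0] + rad * math.sin(theta)
            col = soma_centre[1] + rad * math.cos(theta)
            if _fits(row, col, r_px):
                _record(s, row, col, r_um, -1)
                break
        else:
            raise RuntimeError("could not place vesicle: density limit reached")

    return records, next_clump_id


def _apply_noise_and_quantise(clean: np.ndarray, config: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Photon-budget Poisson + Gaussian read noise, then DN quantisation."""
    full = 2**config.bit_depth - 1
    if not config.apply_noise:
        return np.clip(clean, 0, None) * full  # float DN, noise-free
    expected_e = np.clip(clean, 0, None) * config.photons_full_scale
    noisy = rng.poisson(expected_e).astype(float)
    if config.read_noise_electrons > 0:
        noisy += rng.normal(0.0, config.read_noise_electrons, size=noisy.shape)
    dn = np.clip(noisy, 0, None) / config.photons_full_scale * full
    dtype = np.uint8 if config.bit_depth <= 8 else np.uint16
    return np.clip(np.round(dn), 0, full).astype(dtype)


def generate_scene(config: SceneConfig) -> tuple[MultiChannelField, ROILabelMask, SyntheticGroundTruth]:
    """Render one field and return it with its soma mask and ground truth."""
    rng = np.random.default_rng(config.rng_seed)
    centres = _place_somata(config, rng)
    soma_labels = _soma_mask(config, centres)

    records: list[dict] = []
    clump_id = 0
    for nid in range(1, config.n_neurons + 1):
        counts = _sample_counts(config, rng)
        recs, clump_id = _place_vesicles_for_neuron(config, rng, tuple(centres[nid - 1]), counts, clump_id)
        for r in recs:
            r["neuron_id"] = nid
        records.extend(recs)

    vesicles = pd.DataFrame(
        [
            {
                "vesicle_id": i,
                "neuron_id": r["neuron_id"],
                "row": r["row"],
                "col": r["col"],
                "radius_um": r["radius_um"],
                "radius_px": r["radius_px"],
                "subtype": r["subtype"],
                "clump_id": r["clump_id"],
            }
            for i, r in enumerate(records)
        ],
        columns=SyntheticGroundTruth._VESICLE_COLUMNS,
    )
    if vesicles.empty:
        vesicles = vesicles.astype(
            {"vesicle_id": int, "neuron_id": int, "subtype": str, "clump_id": int},
            errors="ignore",
        )

    channels = {
        role: np.full((config.height_px, config.width_px), config.background_level, float)
        for role in _SCENE_ROLES
    }
    in_soma = soma_labels > 0
    for img in channels.values():
        img[in_soma] += config.soma_fill_level
    for r in records:
        sig = SUBTYPE_SIGNATURES[Subtype(r["subtype"])]
        sigma = r["radius_px"] / 2.0
        for role in _SCENE_ROLES:
            _add_gaussian_spot(channels[role], r["row"], r["col"], sigma, sig.channel_means[role])

    psf_sigma_px = config.psf_sigma_um / config.pixel_size_um
    stack = []
    for role in _SCENE_ROLES:
        img = channels[role]
        if psf_sigma_px > 0:
            img = ndi.gaussian_filter(img, psf_sigma_px)
        stack.append(_apply_noise_and_quantise(img, config, rng))
    pixels = np.stack(stack)

    field = MultiChannelField(
        pixels,
        pixel_size_um=config.pixel_size_um,
        channel_map={role: i for i, role in enumerate(_SCENE_ROLES)},
        bit_depth=config.bit_depth,
    )
    mask = ROILabelMask(soma_labels, kind=MaskKind.PERIKARYON)
    gt = SyntheticGroundTruth(
        vesicles=vesicles,
        composition=derive_composition(vesicles, mask.roi_ids),
        soma_mask=mask,
    )
    return field, mask, gt


def generate_ir_overlay(
    field: MultiChannelField,
    ground_truth: SyntheticGroundTruth,
    ir_config: IRConfig,
    scene_config: SceneConfig | None = None,
) -> tuple[MultiChannelField, SyntheticGroundTruth]:
    """Add a fourth (IR) channel with a known AV-association fraction.

    ``round(assoc_fraction * n_objects)`` objects are centred on mRFP-positive
    ground-truth vesicles (guaranteed overlap); the rest are placed inside
    somata at a safe clearance from every mRFP-positive vesicle so their
    thresholded footprints cannot touch an mRFP punctum.  Per-object truth is
    recorded in ``ground_truth.ir_objects``.
    """
    if field.has_role(ChannelRole.IR):
        raise ValueError("field already has an IR channel")
    noise = scene_config if scene_config is not None else SceneConfig()
    rng = np.random.default_rng(ir_config.rng_seed)
    px = field.pixel_size_um
    soma = ground_truth.soma_mask.labels
    gt_ves = ground_truth.vesicles
    rfp_pos = gt_ves[gt_ves["subtype"].isin([s.value for s in RFP_POSITIVE_SUBTYPES])]

    n_assoc = int(round(ir_config.assoc_fraction * ir_config.n_objects))
    if n_assoc > 0 and len(rfp_pos) == 0:
        raise RuntimeError("cannot place associated IR objects: no mRFP-positive vesicles")

    lo, hi = ir_config.radius_um
    placed: list[dict] = []

    def _clear_of_others(row: float, col: float, r_px: float) -> bool:
        return all(
            math.hypot(row - o["row"], col - o["col"]) >= r_px + o["radius_px"] + 4 for o in placed
        )

    # Associated objects: jittered onto a random mRFP-positive vesicle centre.
    candidates = rfp_pos.sample(frac=1.0, random_state=int(rng.integers(2**31))) if len(rfp_pos) else rfp_pos
    ci = 0
    for k in range(n_assoc):
        for _ in range(3000):
            ves = candidates.iloc[ci % len(candidates)]
            ci += 1
            r_um = rng.uniform(lo, hi)
            r_px = r_um / px
            jitter = 0.3 * ves["radius_px"]
            row = float(ves["row"]) + rng.uniform(-jitter, jitter)
            col = float(ves["col"]) + rng.uniform(-jitter, jitter)
            if _clear_of_others(row, col, r_px):
                placed.append(
                    {"row": row, "col": col, "radius_px": r_px, "neuron_id": int(ves["neuron_id"]), "associated": True}
                )
                break
        else:
            raise RuntimeError("could not place associated IR object: density limit reached")

    # Unassociated objects: inside a soma, clear of every mRFP-positive halo.
    soma_ids = ground_truth.soma_mask.roi_ids
    if ir_config.n_objects - n_assoc > 0 and soma_ids.size == 0:
        raise RuntimeError("cannot place IR objects: no somata in scene")
    centres_by_id = {
        int(nid): ndi.center_of_mass(soma == nid) for nid in soma_ids
    }
    soma_r_px = (
        scene_config.soma_radius_um / px if scene_config is not None else math.sqrt((soma > 0).sum() / max(len(soma_ids), 1) / math.pi)
    )
    for k in range(ir_config.n_objects - n_assoc):
        for _ in range(5000):
            nid = int(rng.choice(soma_ids))
            c_row, c_col = centres_by_id[nid]
            r_um = rng.uniform(lo, hi)
            r_px = r_um / px
            theta = rng.uniform(0, 2 * math.pi)
            rad = (soma_r_px - r_px - 2) * math.sqrt(rng.uniform(0, 1))
            row = c_row + rad * math.sin(theta)
            col = c_col + rad * math.cos(theta)
            if not (0 <= int(row) < soma.shape[0] and 0 <= int(col) < soma.shape[1]):
                continue
            if soma[int(row), int(col)] != nid:
                continue
            if not _clear_of_others(row, col, r_px):
                continue
            # Clearance: thresholded halos extend to ~1.2x the Gaussian radius.
            near = rfp_pos[
                (rfp_pos["row"] - row) ** 2 + (rfp_pos["col"] - col) ** 2
                < (1.6 * rfp_pos["radius_px"] + 1.6 * r_px + 3) ** 2
            ]
            if len(near):
                continue
            placed.append({"row": row, "col": col, "radius_px": r_px, "neuron_id": nid, "associated": False})
            break
        else:
            raise RuntimeError("could not place unassociated IR object: density limit reached")

    # Render the IR plane with the same forward model as the reporter channels.
    plane = np.full(field.shape, ir_config.background_level, float)
    plane[soma > 0] += ir_config.soma_fill_level
    for o in placed:
        _add_gaussian_spot(plane, o["row"], o["col"], o["radius_px"] / 2.0, ir_config.amplitude)
    psf_sigma_px = noise.psf_sigma_um / px
    if psf_sigma_px > 0:
        plane = ndi.gaussian_filter(plane, psf_sigma_px)
    plane = _apply_noise_and_quantise(plane, noise, rng)
    if np.issubdtype(field.pixels.dtype, np.integer) and not np.issubdtype(np.asarray(plane).dtype, np.integer):
        plane = np.clip(np.round(plane), 0, 2**field.bit_depth - 1).astype(field.pixels.dtype)

    new_field = field.with_channel(ChannelRole.IR, plane)
    ir_objects = pd.DataFrame(
        [
            {
                "object_id": i,
                "neuron_id": o["neuron_id"],
                "row": o["row"],
                "col": o["col"],
                "radius_px": o["radius_px"],
                "associated": bool(o["associated"]),
            }
            for i, o in enumerate(placed)
        ],
        columns=SyntheticGroundTruth._IR_COLUMNS,
    )
    gt = SyntheticGroundTruth(
        vesicles=ground_truth.vesicles,
        composition=ground_truth.composition,
        soma_mask=ground_truth.soma_mask,
        ir_objects=ir_objects,
    )
    return new_field, gt


def write_ground_truth(gt: SyntheticGroundTruth, directory: str | Path) -> Path:
    """Write vesicles.csv, composition.csv, soma_mask.tif (+ ir_objects.csv)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    gt.vesicles.to_csv(directory / "vesicles.csv", index=False)
    gt.composition.to_csv(directory / "composition.csv", index=False)
    save_roi_mask(gt.soma_mask, directory / "soma_mask.tif")
    if gt.ir_objects is not None:
        gt.ir_objects.to_csv(directory / "ir_objects.csv", index=False)
    return directory


def read_ground_truth(directory: str | Path) -> SyntheticGroundTruth:
    directory = Path(directory)
    ir_path = directory / "ir_objects.csv"
    return SyntheticGroundTruth(
        vesicles=pd.read_csv(directory / "vesicles.csv"),
        composition=pd.read_csv(directory / "composition.csv"),
        soma_mask=load_roi_mask(directory / "soma_mask.tif"),
        ir_objects=pd.read_csv(ir_path) if ir_path.exists() else None,
    )
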