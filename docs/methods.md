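# Methods

## Colour model and classification

Each segmented punctum is summarised by the mean native intensities of
the mRFP-LC3 (R), eGFP-LC3 (G) and CTSD (B) channels over its pixels.
Hue is the angle of the opponent-axis vector `(2R − G − B, √3(G − B))`
in degrees, mapped into [0°, 360°); this is the colour-wheel (phasor)
hue, identical to `arg(R + G·e^{i120°} + B·e^{i240°})`. It is *not* the
piecewise hex-cone hue of HSL/HSV — the two agree only on the six
primary/secondary axes — so tests validate against an independently
coded phasor oracle rather than `colorsys`. A subtle trap: the
spreadsheet convention writes ATAN2(x, y) while C-family `atan2` takes
(y, x); the implementation uses `arctan2(√3(G−B), 2R−G−B)` and is locked
by axis tests (pure R → 0°, R=G → 60°, pure G → 120°, pure B → 240°,
R=B → 300°). Hue is undefined (NaN) for achromatic input.

Saturation is `(max − min)/(max + min) × 100` on intensities normalised
to [0, 1] by `2^bit_depth − 1`. The formula is the HSL lower-cone
expression and is reported as-is (no upper-cone branch); it is valid
while lightness `(max + min)/2 < 1`, which holds for real data. A
vesicle at exactly full lightness is flagged `saturated_white` and given
saturation 0.

Classification evaluates rules in priority order:

1. **pa-AL** — all three channels above threshold and saturation < 25%
   (the "white", near-achromatic class; checked first because its hue is
   meaningless);
2. **AP** — hue in [30°, 90°) with R and G above threshold;
3. **AL** — hue in [270°, 330°) with R and B above threshold;
4. **LY** — hue in [210°, 270°) with B, and *only* B, above threshold;
5. otherwise **UNCLASSIFIED**.

The hue windows centre on the canonical colour axes (yellow 60°, blue
240°, magenta 300°); the original interactive workflow does not publish
numeric boundaries, so these defaults are assumptions, exposed in the
`subtype_rules` config block and echoed into every output table's
metadata. Hue windows must be pairwise disjoint (validated at load).
Red-only vesicles (hue near 0°, CTSD below threshold) are UNCLASSIFIED
by default since AL is defined here by CTSD coincidence; a config switch
(`red_as_ctsd_negative_al`) counts them as CTSD-negative AL instead.
Hue and saturation are scale-invariant, so classification is unchanged
by any positive rescaling that preserves the channel-presence flags.
Classification operates per vesicle, not per pixel.

## Segmentation

Channel thresholds follow the perikarya-average rule: for each channel,
the threshold is the mean over a seeded sample of 20 neuronal perikarya
(fewer, with a warning, if the mask has fewer) of each ROI's mean pixel
intensity. Masks use strict `intensity > threshold`; ties are excluded
for determinism. The vesicle mask is the union of the three per-channel
masks. Clumps are split by marker-controlled watershed on the inverted
sum-of-channels landscape after Gaussian smoothing (σ = 1 px), with
markers at local maxima separated by ≥ 2 px and 8-connectivity; mask
components that receive no marker keep a label of their own, so label
areas always sum to the mask area. Vesicles are assigned to the neuron
owning the majority of their pixels (ties break to the lower label);
background-majority vesicles are excluded from per-neuron counts.

Size exclusion: the pipeline default is a minimum punctum area of 10 px
(~0.43 µm² at 0.2074 µm/px). This is deliberate: the perikarya-mean
threshold sits only ~2σ of shot noise above the soma's diffuse signal,
so isolated supra-threshold noise clusters of 3–5 px are common, while
the smallest resolvable vesicle the simulator produces (0.4 µm radius)
has a thresholded footprint of ≥ ~17 px. Ten pixels separates the two
populations with margin; IR objects use a 6-px floor by the same
argument (smallest simulated IR object ~9 px). Both are config keys
(`size_filter.min_area_px`, `ir_min_area_px`), and the generic
`apply_size_exclusion` helper defaults to the permissive 3 px.

A consequence worth knowing: the perikarya-mean threshold is
self-referential — somata with few vesicles yield thresholds barely
above the diffuse soma signal, inflating false puncta. At the default
composition (20 vesicles/neuron) detected counts match ground truth
exactly; at ~12 vesicles/neuron specificity degrades unless the size
filter is raised.

## IR quantification

IR objects are connected components (8-connectivity) of the strictly
thresholded IR channel after size exclusion. Association with
autophagic vacuoles is an object-level property: one pixel of overlap
with the *segmented* mRFP-LC3 puncta mask commits the object's whole
area to the AV-associated form (a pixel-level splitting mode exists for
sensitivity analysis). Using the segmented mask rather than the raw
thresholded mask matters: raw masks carry supra-threshold noise salt
that falsely associates isolated objects. Per cell, associated +
unassociated area equals total area exactly (the parts are summed after
scaling to µm²), and both absolute areas and fractions of cell area are
reported, since the original per-cell normalisation is not published.
Integrated density sums intensities over pixels strictly above an
exclusion threshold (regions with minimal staining, e.g. striatal fiber
bundles, fall below it); included and excluded areas are reported.
`count_rate_per_100` converts manual tallies (e.g. electron-microscopy
lipofuscin counts) to per-100-neuron rates, unrounded and rounded.

## Statistics

Two groups: unpaired two-tailed Student's t-test with pooled variance
(the common Prism default), Welch by flag; the degenerate all-constant
case reports t = 0, p = 1 with a note. Three or more groups: one-way
ANOVA, then pairwise comparisons on the pooled within-group mean square
with N − k degrees of freedom over an explicit list of selected pairs,
Sidak-adjusted as `p_adj = 1 − (1 − p)^m` with m the number of requested
comparisons (m = 1 returns p exactly). Summaries report mean, SEM
(sd/√n, ddof = 1) and n. The unit of analysis is the neuron, matching
per-neuron vesicle counts; this treats neurons within a mouse as
independent, as the source workflow does — per-animal aggregation is
left to the caller. No hierarchical modelling is attempted.

## Synthetic scenes

The generator emulates single-plane, three-channel confocal fields:
1024×1024 px spanning 212.34 µm (0.2074 µm/px), 16-bit. Somata are
non-overlapping discs (default radius 10 µm — a ~20 µm perikaryon) with
a diffuse cytoplasmic level of 0.05 of full scale over a 0.02 field
background. Vesicles are isotropic Gaussian spots (σ = radius/2,
radius ~ U(0.4, 1.0) µm, amplitude 0.8 of full scale in each "high"
channel per the subtype signatures; pa-AL uses equal peaks in all three
channels so its rendered saturation is ≈ 0). A fraction of vesicles
(default 0.1) is placed as touching same-subtype doublets (centre
distance = sum of radii) to exercise the watershed. Channels are blurred
with a global Gaussian PSF (σ = 0.1 µm), converted to expected
photoelectrons (1000 e⁻ at full scale), Poisson-sampled, perturbed with
2 e⁻ Gaussian read noise and quantised. A `hard()` preset quarters the
photon budget and doubles the read noise (2× relative noise) to
exercise graceful degradation. Everything is driven by one numpy PCG64
generator per scene, so output is bit-reproducible given the seed;
determinism across platforms rests on numpy's stability guarantees for
`default_rng`.

Per-neuron compositions default to 5 AP, 5 AL, 2 pa-AL and 8 LY; in
`poisson` mode the per-neuron total is drawn Poisson (truncated at the
soma's random-sequential-packing capacity, a ~1e-4 tail event at the
defaults) and split multinomially, which equals independent Poisson
subtype counts conditioned on a feasible total. The IR overlay places a
configured number of Gaussian objects (radius U(0.3, 0.8) µm, amplitude
0.6) either centred on mRFP-positive vesicles (associated) or inside
somata at a clearance beyond both thresholded halos (unassociated), and
records per-object truth.

What the simulator does *not* reproduce: lipofuscin autofluorescence,
photobleaching, 3-D optics and z-leakage, spatially varying background,
vesicle size/intensity distributions estimated from real data (none are
published), chromatic aberration, or segmentation errors from irregular
soma shapes. Passing tests therefore demonstrate that the analysis
logic is correct under a standard fluorescence forward model at
realistic SNR — not that real-tissue images of arbitrary quality will
be classified this accurately.

## Numerical choices and degenerate inputs

- Hue at the 0°/360° seam maps to 0°; achromatic input returns NaN and
  fails every hue window.
- Saturation returns 0 when max + min = 0 and at full lightness.
- Thresholds use strict `>`; a pixel exactly at threshold is background.
- Watershed ties and plateaus resolve via scikit-image's deterministic
  flooding; orphan mask components are labelled after flooding, so
  pixel conservation is exact.
- Empty scenes, empty masks, zero-vesicle neurons and header-only
  tables are all legal and round-trip.
- Problem sizes in the validation suite: unit tests run 512-px scenes
  with 6 neurons; end-to-end checks use full 1024-px scenes (10–25
  neurons), 10 fields per group and 100 neurons per group for the
  experiment-level checks, and 10,000 replicates for the statistical
  calibration — sizes at which every stochastic criterion is stable
  across seeds.

## Known limitations

- Hue-window defaults and the 25% white cutoff are assumptions standing
  in for unpublished interactive settings; conclusions sensitive to
  them should sweep the config.
- The perikarya-mean threshold couples detection specificity to vesicle
  load (see Segmentation); heavily diseased vs healthy tissue may
  warrant a fixed or robust (e.g. percentile-based) threshold, which
  can be injected via `segment_field(thresholds=...)`.
- Object-level association weights large IR aggregates heavily; the
  pixel-level mode bounds that sensitivity.
- Neuron-level statistics ignore within-animal correlation.
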