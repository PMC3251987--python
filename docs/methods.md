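# Methods

## Verification model

A verification trial compares a probe capture against an enrolled
capture of a claimed finger. Both images pass the same deterministic
chain — segmentation, fixed-size crop, downscale, high-pass enhancement,
POC alignment, binary code extraction — and the decision statistic is the
normalized Hamming distance between the two codes. The method carries no
trained parameters; its behavior is fully determined by the pipeline
constants below.

### Preprocessing

The capture (640 × 480, 8-bit) is binarized at the Otsu threshold, the
level maximizing between-class variance over the 256-bin histogram; the
foreground is the brighter finger. The crop window (480 × 160,
width × height) is centered on the rounded foreground centroid
(round-half-up as a deterministic tie-break) and shifted inside the frame
when the centroid lies near a border, so every ROI pixel is real data
rather than padding. Bilinear downscaling by 0.4 gives the 192 × 64
working resolution.

The enhancement mask is `H(x, y) = a (1 − e^{−D²/2D₀²}) + b` on an
`S × S` grid, `D` the Euclidean distance to the mask center. Its center
weight is exactly `b` and its far-field limit `a + b`, i.e. it is a
high-pass with adjustable amplitude `a` and DC level `b`. The image is
convolved with reflected-border padding (zero padding would imprint a
dark frame that the binary codes pick up as structure) and the
real-valued result is min–max rescaled to 8 bits; a constant result maps
to mid-gray 128 by convention. `D₀` defaults to `S/2`, tying the
Gaussian width to the mask extent; it is exposed as `enhance.D0` because
no canonical value exists for it.

### Alignment

The POC surface is `Re F⁻¹[ F·Ḡ / |F·Ḡ| ]`. Its argmax, unwrapped to
signed shifts in `(−W/2, W/2] × (−H/2, H/2]`, estimates the integer
translation; no sub-pixel refinement is attempted because the common
regions are cropped at whole pixels anyway. Spectral bins whose
cross-power magnitude falls below a machine-epsilon-scaled floor are
zeroed rather than phase-normalized, the standard guard against
division blow-up on empty bins. An optional Hann taper
(`align.window: hann`) is available for images with strong border
discontinuities; it is off by default.

Pairs with `|t_x| ≥ 20` or `|t_y| ≥ 10` (strict bounds) are rejected:
displacements that large indicate different fingers, and such pairs are
scored with the maximal distance 1.0 rather than an arbitrary
mid-range value, so they can never be falsely accepted.

### Feature codes

LLBP places a length-`N` (odd, center position `(N+1)/2`) horizontal and
vertical line at each pixel and compares every line pixel to the center
via `s(x) = 1 iff x ≥ 0`, so equal intensities encode as 1 and the codes
are invariant under any constant intensity shift. Bits are stored in
pixel order along the line with the center excluded, horizontal half
before vertical half; the binomially weighted sums (weights `2^{c−n−1}`
and `2^{n−c−1}` outward from the center) are used only where a decimal
value is needed — the magnitude map `√(h² + v²)` and grayscale
visualization. Matching depends only on a consistent bit order, not on
the weighting.

A margin of `(N−1)/2` pixels is trimmed on all four sides for every LLBP
variant — including the single-direction ones, which keeps the
horizontal and vertical maps co-registered for concatenation. On a
192 × 64 enhanced image this yields the template geometries
172 × 44 × 40 bits (LLBP, N = 21), 176 × 48 × 16 (vertical LLBP,
N = 17), and for the LBP(8, 1) baseline 190 × 62 × 8.

LBP samples `P` points on a radius-`R` circle, first sample at angle 0,
counter-clockwise, bilinearly interpolating non-integer positions;
sample coordinates within 1e-9 of a pixel are treated as exact so that
the axial neighbors compare exactly. Because the comparison is a hard
threshold, interpolation ties at exactly the center value encode as 1
like every other equality.

Per-pair templates are recomputed on the aligned common regions, so the
code length shrinks with the shift magnitude and the Hamming
normalization always uses the actual per-pair length.

### Evaluation

Acceptance at threshold `t` is `hd ≤ t`. FAR and FRR are evaluated on
1001 evenly spaced thresholds in [0, 1]; the EER is linearly
interpolated between the two grid points bracketing the sign change of
FAR − FRR (the estimator is unbiased for any grid once the curves are
piecewise linear between scores; 1001 points keep the interpolation
error below the score resolution of any realistic score set). If the
curves never cross inside the grid the boundary value is returned with
a warning. Rates are reported in percent to match the conventional
tabulation. The `(N, S)` grid search re-runs preprocessing per `S` and
scoring per `N` on every pair of a tuning subset; cells fail
independently so one infeasible parameter combination (e.g. a line
longer than the image) does not abort the table.

## Synthetic data generator

The generator emulates the structure such a verification study's
database: subjects × four labeled fingers × repeated samples, 640 × 480
8-bit frames. Each finger is a deterministic model drawn from its seed:
a bright superellipse band (transmitted intensity ~175 against a ~25
background, brighter toward the edges where the tissue is thinner) and
3–7 dark veins — cubic splines through 4–7 control points spanning the
finger lengthwise, widths 3–8 px, depths 40–70 intensity units. Veins of
that width and contrast are what the line-shaped LLBP neighborhood is
designed for; mostly longitudinal paths mirror real finger vasculature.

Each sample re-renders the model with the nuisance factors the pipeline
must absorb: integer translation jitter up to ±8 px horizontally and
±4 px vertically (within the alignment limits, as a capture guide
window enforces in practice), a global brightness offset (σ = 8), optical
Gaussian blur (σ = 1.5 px) and additive sensor noise (σ = 6). The whole
dataset is a pure function of the root seed and counts; bit-identical
regeneration is tested.

Not modeled: skin scattering and irregular shading, depth-dependent vein
contrast, LED illumination gradients, finger rotation, and
session-to-session physiological change. Passing tests on this data
therefore demonstrate the pipeline's mechanics (geometry, invariances,
alignment, separation of structurally distinct vein patterns under the
stated nuisance levels) — not field accuracy on real captures, where
published error rates for this method are on the order of 2 % EER.

## Problem sizes in the test suite

The property suite verifies descriptors against naive per-pixel loops on
50 random 32 × 32 images, POC on 100 seeded shifts of a 192 × 64 image,
Hamming metric axioms on 1000 random 16-bit triples, and the EER
estimator on 1000-draw separable and identically distributed score sets.
The end-to-end check evaluates all 19,900 pairs of a 20-finger × 10-sample
synthetic dataset at the default operating point; at the default
generator conditions it measures EER = 0 %, with roughly two thirds of
imposter pairs already removed by alignment rejection. These sizes give
each statistical check a comfortable margin while keeping the full suite
around a minute on one CPU.

## Known limitations

- Translation-only registration: rotation or scale differences between
  captures are outside the model (physically constrained at capture).
- The EER of the synthetic benchmark is not comparable to accuracy on
  real NIR databases; the generator's imposters differ more strongly
  than two distinct real fingers can.
- Single-template matching: no enrollment fusion or score normalization
  across fingers.
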