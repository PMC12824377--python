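# Methods

`thzchem` implements a pulse-resolved chemical-imaging pipeline for
reflection-mode terahertz time-domain spectroscopy (THz-TDS), together
with a physics-based waveform simulator that stands in for the
instrument.  This note documents the model, its assumptions, the
parameters that matter, and the design decisions taken where the design
was genuinely open.

## Scene and waveform model

A scene is a flat metal holder plane (modelled as a perfect reflector,
field reflectivity −1) carrying one or more cylindrical sample disks
(default 10 mm diameter, 2–4 mm thickness), raster-scanned on a 1-mm grid
over a 12 × 12 mm² field of view (13 × 13 pixels, endpoints included).
Each pixel's trace holds 10,100 samples at dt = 0.02 ps (202 ps), the only
assignment consistent with a 650-sample pulse window spanning 13 ps.

Each material is described by a refractive index with a
frequency-independent real part n and a Lorentzian absorption model

    alpha(nu) = alpha0 + sum_j A_j gamma_j^2 / ((nu − nu_j)^2 + gamma_j^2)

with nu in THz and alpha in 1/cm.  The Fresnel coefficients use the
complex index n + i·c·alpha/(4·pi·nu), so the surface reflection carries
the weak (~1%) spectral signature any absorbing medium imprints on it;
without this, every surface, holder, and cover echo is an identical
scaled copy of the reference pulse — a degeneracy real materials do not
have, and one that destabilizes shape-based classification (see
Networks).  Dispersion of the real part and Kramers–Kronig consistency
remain out of scope.  The shipped registry of eight
fingerprints (four pharmaceutical excipients, four energetic materials)
uses synthetic constants — pairwise-distinguishable line sets below
3.2 THz, n between 1.55 and 1.90, baseline alpha 0.3–0.6 /cm — chosen to
be *plausible*, not to reproduce the true optical constants of the named
compounds.

A pixel's waveform is synthesized in the frequency domain as a sum of
delayed echo rays convolved with a band-limited reference pulse:

* **Reference pulse.** A Ricker (Gaussian second-derivative) transient
  with sigma = 2/(pi·f_max) ≈ 0.14 ps, giving an amplitude spectrum below
  1% of its peak at the 4.5-THz band edge.  The Ricker's unique unit
  extremum keeps |amplitude| peak detection unambiguous to one sample,
  which a bipolar first-derivative pulse would not.
* **Echo expansion.** Fresnel coefficients at the air/sample interface
  (r01 = (1−n)/(1+n)), reflectivity −1 at the sample/metal floor,
  propagation phase exp(−2πi·nu·2nd/c) and Beer–Lambert amplitude loss
  exp(−alpha·d) per one-way pass.  Internal round trips are truncated at
  K = 3; at registry absorption levels the K = 3 echo is already below
  the 8% detection threshold.  This produces the echo taxonomy P1 (top
  surface), P2 (bare metal, visible where the beam is not fully on a
  disk), P3 (bottom interface), P4+ (Fabry–Pérot round trips).  The metal
  echo at a fixed 80 ps is the global time reference; the sample surface
  echo leads it by 2d/c.
* **Beam footprint.** The 2-mm beam is a uniform disk; the per-placement
  overlap fraction f is the exact circle–circle lens area.  The trace is
  f times the sample-stack response plus (1−f) times the bare-metal
  response.
* **Edges.** Pixels with f in the transition band (0.05, 0.85) are ground
  truth "edge"; their sample rays are additionally multiplied by a
  scattering-loss factor drawn uniformly from (0.4, 0.6) — the physical
  statement being only that boundary signals are scattering-dominated and
  much weaker than bulk reflections.
* **Geometry jitter.** Every pixel draws a surface-height and a thickness
  offset uniform in ±7.5 µm (typical pressed-pellet tolerance).  Without
  this, all pixels of a scene share one sub-sample echo phase, and a
  classifier can memorize that scene-wide constant instead of pulse
  shape — a simulator artifact, not a property of real scans.  Tests that
  check analytic delays to ±1 sample switch this jitter off.
* **Cover.** Concealment adds a 0.18-mm dielectric layer (n = 1.5,
  alpha = 6 /cm, rough-surface specular loss 0.6) with its top face 7 mm
  above the holder plane.  It contributes one extra *leading* reflection
  and attenuates/delays everything beneath it.  The internal second-face
  echo of fibrous paper is suppressed by scattering and is not modelled.
* **Cracks.** Optional line-shaped pixel sets where sample rays are
  attenuated (×0.45) and delayed by a ±0.1-ps jitter, preserving the P3
  segment shape.
* **Noise.** White Gaussian, with sigma set so that the peak spectral
  dynamic range of a background pixel — 20·log10(peak |FFT| over the RMS
  per-bin noise floor sigma·sqrt(N)) — equals the configured 96 dB.  At
  96 dB the per-sample noise is ~3·10⁻⁶ of the metal-echo amplitude, so
  classification is effectively noise-limited only far below the default
  dynamic range.

All randomness flows from the scene seed through per-pixel
`SeedSequence` spawn keys; identical (scene, acquisition, seed) gives
bit-identical cubes.

## Pulse extraction

Detection runs on |trace| (metal echoes are sign-flipped), keeping local
maxima above 8% of a background reference amplitude (the maximum |field|
over the border pixels).  Among threshold-passing candidates the subset
with pairwise separation ≥ 650 samples that maximizes the *total* peak
amplitude is selected exactly by dynamic programming, with ties resolved
to the lexicographically earliest index set.  (A greedy largest-first
scan does not maximize total amplitude: three candidates at 0/300/750
samples with amplitudes 0.5/0.6/0.5 defeat it.)  Each kept peak is cut
into a 650-sample window centered on the peak, zero-padded at trace
boundaries; a pixel keeps at most 8 segments (largest amplitudes win,
re-ranked by arrival).

A geometric consequence of the 13-ps minimum separation: P2 and P3 can
both be kept only when 2d(n−1)/c ≥ 13 ps.  At d = 3 mm this requires
n ≥ 1.65; for lower-index materials the stronger of the two wins at
partial-overlap pixels.  Interior pixels (no P2) are unaffected.

## Label generation

The holder echo P2 is identified by the modal arrival index of the
dominant pulse over background pixels (spread-derived tolerance, at least
±3 samples) and labeled background wherever it occurs.  Other segments
inherit the pixel's chemical code; segments at edge pixels are labeled
with the underlying chemical but flagged and excluded from classifier
training by default.  In covered scenes the leading cover reflections
(arriving earlier than any credible surface echo) are excluded from
training.  The per-material edge threshold is
max(detection·1.25, 0.6 × median bulk amplitude), required to sit
strictly between the detection threshold and the bulk level; a pixel is
labeled edge iff it has at least one non-P2 pulse and all its non-P2
pulses fall below its material's threshold.  Labeling is fully automated
against simulator ground truth; a manual-override CSV hook
(`assign_pulse_labels(..., manual_overrides=...)`) supports real data.

## Networks

**ClassNet** (per-pulse, 9-way): two 1-D conv/ReLU/max-pool stages
(16 then 32 channels, kernel 9, pool 2), a 128-unit hidden layer, and a
zero-initialized softmax head (the untrained network outputs the uniform
distribution).  Input segments are divided by their peak |amplitude|
before the convolutional stack: the chemical information lives in the
pulse *shape* (the absorption ring-down of P3/P4), which is consistent
under edge scattering, partial beam overlap, and cover attenuation,
whereas raw amplitude varies with all of them.  A practical consequence:
all "clean" reflections (P1, P2, cover echo) collapse into one shape
cluster carrying conflicting labels, so the trained network assigns them
non-saturated probabilities, and the pixel decision is carried by the
fingerprint-bearing echoes.  Without this normalization, confident
out-of-distribution extrapolations (e.g. on the cover echo) hijack the
winner-takes-all fusion.

**EdgeNet** (per-pixel, binary): each row of the zero-padded 8 × 650
pulse stack is linearly embedded to d_model = 128 and passed through a
4-layer pre-norm transformer encoder with 8 attention heads and an
MLP width of 256, followed by mean pooling over the sequence axis and a
2-way head.  No positional encoding is ever added; with mean pooling the
network is exactly permutation invariant in its pulse rows, matching the
premise that echo order is unknown.  Zero-pad rows ride along as
ordinary tokens (no masking).  EdgeNet sees *raw* amplitudes — edge
pixels are precisely the weak-amplitude patterns.

Both are trained with Adam (lr 10⁻³, batch 64, cross-entropy), seeded
and single-threaded.  The canonical epoch count is 200; the desk-scale
benchmark configuration trains ClassNet for 30 and EdgeNet for 40 epochs,
which is past convergence at the benchmark's data volume (~5,000 labeled
pulses, ~2,700 pixel stacks).  Class imbalance is handled by per-class
balanced resampling (256 draws per class per epoch); the 20% validation
split is by scene, never by segment.  The networks run on an in-package
NumPy reverse-mode autodiff engine (`thzchem.nn`) in float32; gradient
correctness is checked against central finite differences in the test
suite.

## Fusion and post-processing

Per-pixel aggregation is winner-takes-all: the global argmax over every
(pulse, class) probability, ties to the lower class code; a
mean-probability alternative sits behind `FusionConfig.aggregation`.
(The mean variant was measured and rejected as the default: averaging
drags the winning probability of concealed sample pixels below the 0.95
edge guard, while global argmax lets the confident fingerprint echo carry
the pixel.)  Probabilities are computed with a float64 softmax so that
near-saturated values stay ordered by logit margin rather than collapsing
into exact ties resolved by class index.  Pixels with no detected pulses
are background with probability 1.  A
pixel becomes Edge iff EdgeNet votes edge (p > 0.5) *and* the winning
class probability is below 0.95.  The map is then cleaned by one
synchronous 3 × 3 majority vote (center included, truncated border
neighborhoods, ties keep the original label — all unstated conventions,
fixed here) and 8-connected components smaller than 3 pixels are
dissolved into the modal label of their boundary.  Majority voting runs
before morphological cleanup, following the order in which the two steps
are described.

## Evaluation

Confusion matrices count ground truth (rows) against prediction
(columns); edge-truth pixels are excluded unless requested, since the
transition ring has no well-defined chemical identity.  The average
accuracy is the unweighted (macro) mean of per-class recalls over the
classes present plus background — the macro reading of "average accuracy
including the background region"; empty classes are dropped with a
warning.

## Benchmark protocol and problem sizes

The default benchmark simulates, per chemical, two training scenes and
one disjoint-seed uncovered test scene, plus one covered test scene per
energetic material; covered and cracked variants are rejected in
training splits.  Scene seeds occupy disjoint integer ranges derived from
the base seed; a ±0.7-mm center offset is drawn per scene.  Test disk
thicknesses are uniform on 2–4 mm; *training* thicknesses are stratified
so each class's training samples span that range (one thin, one thick),
the experimental-design reading of training tablets "ranging from 2 to
4 mm".  Without stratification a class can train only on thick disks,
leaving its thin-disk second-round-trip echo (whose detectability is
threshold-marginal) entirely unseen and prone to confident
misclassification.  All told: 16 training cubes, 8 + 4 test
cubes of 169 pixels each, a few thousand training pulses — sized so the
whole train-and-test cycle completes in a few minutes on one CPU core.

## What the simulator does and does not show

Passing the synthetic benchmark demonstrates that the pipeline's
machinery — extraction, labeling, shape-based per-pulse classification,
set-based edge detection, fusion, and spatial cleanup — recovers
pixel-level chemical maps under partial overlap, edge scattering,
thickness variation, and unseen concealment.  It does not validate the
registry fingerprints against real optical constants (unverifiable from
public sources), nor real-instrument artifacts: dispersion and
Kramers–Kronig consistency are omitted, the metal is a perfect reflector,
edge scattering is a scalar loss rather than a pulse-deforming process,
overlapping (unresolved) echoes are never generated, and the noise is
white.  Real covered measurements would add cover-material variability
that the single-layer model does not span.

## Numerical choices

Spectral work uses the one-sided FFT of 650-sample windows (bin spacing
exactly 1/13 ps = 76.92 GHz); absorbance A = −ln(|S3|/|S2|) is evaluated
only where |S2| exceeds 1% of its peak, with no Fresnel or thickness
normalization (A is a dimensionless attenuation).  Line centers are the
most prominent absorbance maxima (prominence floor 0.3).  Waveform
synthesis zero-pads to twice the trace length so late echoes cannot wrap
around.  Peak-selection DP breaks ties at 10⁻¹² relative tolerance.
Degenerate inputs are defined everywhere: all-zero traces detect no
pulses, pixels without pulses aggregate to background, all-equal
amplitude distributions fall back to a threshold just above detection
with a warning.
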