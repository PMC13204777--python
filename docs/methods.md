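# Methods

## The model

`msod` implements a four-layer model of the *Drosophila* visual pathway for
detecting small moving objects against moving clutter, and confirming them
against small-object-like background features ("pseudo-objects").

**Retina.** RGB input is converted to luma (0.2989 R + 0.5870 G + 0.1140 B)
and each frame is smoothed with a unit-sum isotropic Gaussian of width
σ₁ = 1 px, producing the photoreceptor signal P(x, y, t). P feeds two
parallel branches.

**Lamina (motion branch).** The large monopolar cell (LMC) response is the
causal temporal convolution of P with the band-pass

  H(t) = (n₂!·t^{n₁} − n₁!·t^{n₂}) / (n₁!·n₂!) · e^{−t},  n₁ = 1, n₂ = 6,

whose discrete taps are rescaled on the negative lobe so they sum to exactly
zero: any static input is annihilated once the filter has filled. Lateral
inhibition convolves LMC with the separable spatio-temporal kernel
W_I = W_SP·W_TP + W_SN·W_TN, where W_SP/W_SN are the rectified halves of the
difference-of-Gaussians DoG = G_{σ₂} − G_{σ₃} (σ₂ = 1.5, σ₃ = 2.0; each
Gaussian unit-sum before subtraction, so the DoG is zero-sum) and W_TP/W_TN
are unit-sum exponential low-passes with λ₁ = 3 and λ₂ = 9 (λ₂ > λ₁: the
inhibitory surround is slower). The result LMCI is half-wave rectified into
non-negative ON (luminance increase) and OFF (luminance decrease) channels
with disjoint support; S_ON − S_OFF reconstructs LMCI exactly.

**Lamina (contrast branch).** Amacrine/T1 cells compute local contrast from
P directly: T1 = (annulus mean over the 31×31 window minus its 11×11 centre)
− (11×11 centre mean). The annulus divisor is 31² − 11² = 840, the centre
divisor 11² = 121 — the only reading in which each divisor counts the pixels
actually summed. There is no temporal filtering in this branch.

**Medulla.** Tm3 (from ON) and Tm2 (from OFF) apply second-order lateral
inhibition: convolution with W1 = A·[DoG]⁺ + B·[DoG]⁻ (A = 1, B = 3)
followed by rectification. Because B > A the kernel's net sum is negative,
so spatially extended (wide-field) activity is suppressed while compact
blobs survive — this is the size selectivity of the model. Mi1 and Tm1 are
the gamma-delayed copies of Tm3 and Tm2 (order n₃ = 5, time constant
τ₃ = 25 ms; the gamma kernel has unit integral and its mode at t = τ).

**Lobula (LC11).** A complete Hassenstein–Reichardt correlator with
feedback:

  LC11₁(t) = (S_Tm3 + k·F₁)·(S_Tm1 + k·F₁),
  LC11₂(t) = (S_Tm2 + k·F₂)·(S_Mi1 + k·F₂),
  LC11 = LC11₁ − LC11₂,

where F_i is the gamma-weighted (n₄ = 10, τ₄ = 25 ms) sum of that
half-correlator's own strictly past outputs and k = 0.01. Using only lags
≥ 1 makes the recursion explicit rather than an implicit fixed point; with
k = 0 it reduces exactly to the feedforward product correlator. A dark
target passing a pixel produces OFF at entry and ON at exit separated by the
transit time; the 25 ms delay pairs them, so LC11 is positive at dark
targets and negative at bright ones — non-directional but polarity-signed.

**Mushroom body.** Per frame, the positive LC11 map is divided by its own
maximum (the absolute response scale of the model is arbitrary, so the
detection threshold Th = 0.2 is applied scale-free), thresholded, and
reduced to local maxima by non-maximum suppression over a 5×5 window.
Detections are linked frame-to-frame by greedy nearest-neighbour association
within a 10 px radius (ties go to the older trajectory; a trajectory missing
for more than `gap_max` = 2 consecutive frames is closed). Each trajectory
samples T1 along its path (the contrast trajectory CT) and keeps the running
*sample* standard deviation of CT (ddof = 1; SD of fewer than two points is
0). A trajectory point is confirmed iff the trajectory has at least
`min_traj_length` = 3 points by then and SD > Th2 = 4.0. The rationale: a
genuinely moving object sweeps over changing background, so its local
contrast fluctuates and SD grows; a background-locked pseudo-object sees the
same surround in every frame, its CT is constant, and its SD stays near 0.

## Temporal units and millisecond integration

The temporal constants above are *milliseconds*. That is the only unit
system in which the three temporal subsystems are mutually consistent: the
band-pass H spans ~0–30 ms, the inhibition exponentials 3/9 ms, and the
25 ms correlator delay matches the ~20 ms transit of a 5 px target at
250 px/s — the coincidence the correlator is built to detect. Read in frame
units at 30 FPS, the same numbers put the delay at 25 frames, longer than a
21-frame sequence, and the correlator output is numerically negligible (the
package exposes this reading via `time_unit='frame'` for sensitivity
studies; it is not the default because it is blind at these frame rates).

A 30 FPS video is a sample-and-hold signal — a display holds each frame for
33 ms — so the model integrates every frame over `substeps` = 12 equal
sub-frame steps (dt ≈ 2.78 ms). Luminance steps at frame transitions then
produce the millisecond ON/OFF bursts the correlator pairs. Results are
insensitive to the step between `substeps` = 12 and 26; below ~10 the
positive lobe of H (0 < t < 3.73 ms) falls between samples and the model
degrades, which fixes the default at the cheap end of the converged range.
The burst for the t → t+1 transition occurs early in block t+1 and is
localized at the frame-t object footprint, so the per-frame LC11 map for
frame t is the magnitude extremum over block t+1; the final frame has no
subsequent transition and is excluded from evaluation.

## Discrete kernels

1-D kernels are sampled at the model step and truncated at the smallest lag
count covering ≥ 99.9% of the absolute continuous mass, then renormalized:
smoothing/delay kernels (Gaussian, exponential, gamma) to unit sum, the
band-pass to an exact zero sum by rescaling its negative taps (preserving
the positive lobe shape and H(0) = 0; plain mean subtraction would break
both). 2-D Gaussians default to radius ⌈3σ⌉. Spatial convolution is
"same"-size with replicate padding; temporal convolution is strictly causal
with zero history before the sequence start.

## Synthetic stimuli

The generator emulates the reference laboratory stimuli: a textured panorama
translating horizontally behind a 500×250 px viewport at 30 FPS for 700 ms
(21 frames), with small dark rectangles either painted *into* the panorama
(background-locked pseudo-objects, rigidly carried by it) or moving
independently across the viewport. The baseline condition has the background
drifting right at 250 px/s, three 5×5 luminance-0 pseudo-objects, and one
independent 5×5 luminance-0 object starting at x = 400 moving left at
250 px/s. Parameter sweeps vary target width/height (2–12 px), joint size,
luminance (0–250 in steps of 25) and speed (250–500 px/s) with everything
else at baseline.

The default texture (`panorama`) is a multi-octave smooth noise base
(Gaussian noise at scales 6/12/24/48 px) combined with soft-edged vertical
stripes of random width 16–64 px and luminance, like a facade or tree line,
stretched to [48, 240]. Three properties of the reference panoramas
(photographs, not distributed) shaped this design:

- *Coarse dominant structure.* Features must be large compared to the
  8.3 px per-frame background displacement, otherwise every texture grain is
  itself a small moving object and the clutter-suppression problem becomes
  unsolvable by any size-selective detector.
- *Contrast structure along every path.* The trajectory-contrast test only
  works where the local mean varies as the target moves. The stripe
  component guarantees horizontal local-mean variation everywhere, and its
  widths straddle the 11/31 px centre/surround windows so the two contrast
  pools decorrelate. Crucially, stripe edges are *extended* vertical lines
  with no corners: compact 2-D features (e.g. the corners of rectangular
  patches) survive size-selective suppression and act as artificial targets,
  which masks the real one through the per-frame response normalization.
- *Mid-tone luminance range.* The range [48, 240] avoids pure-black fields
  in which a luminance-0 target is locally invisible (zero photometric
  evidence at the ground-truth position), a degenerate overlap the reference
  stimuli avoid — their painted rectangles are the darkest scene elements.

Single-scale `bandlimited_noise` and the plain multi-octave `perlin` base
remain available as texture kinds.

What the generator does *not* emulate: photometric noise beyond optional
additive Gaussian noise, perspective or parallax (the panorama is rigid),
occlusions, illumination changes, and photographic edge statistics. Passing
tests on these stimuli therefore demonstrate the mechanism — correlator
selectivity for small independent movers plus trajectory-contrast rejection
of background-locked features — not performance on real footage.

## Evaluation

Warm-up frames are excluded from every metric; the default warm-up is the
time for the temporal filters to deliver 95% of their absolute mass
(band-pass + slow exponential + medulla delay, ≈ 100 ms ≈ 3 frames at
30 FPS), and the final frame is excluded as described above. DR is the
fraction of evaluated frames with a confirmed detection within 5 px of the
true target centre. Pr/Rc/F1 are pixel-level, comparing object-sized boxes
stamped at confirmed detections against true target boxes. SNR and VN are
conventions of this package (the quantities are standard, their formulas
here are not): per frame, SNR is the peak response inside the 5-px-dilated
truth region over the RMS outside it, averaged over frames; VN is the
percentage of absolute response mass outside the dilated region. Only
orderings of SNR/VN across pipeline stages are meaningful.

## Numerical choices and degenerate inputs

- All processing is float; grayscale output is never re-quantized.
- Detections within 10 px of the viewport border are discarded: the border
  continually reveals new scene content whose motion response corresponds to
  no object.
- NMS ties break deterministically by (score desc, y, x); association ties
  by trajectory creation index.
- SD of < 2 points is 0; empty predictions give Pr = Rc = F1 = 0; an
  all-zero response stack gives SNR = VN = 0.
- The pipeline is a pure function of (frames, parameters): re-runs are
  bit-identical.
- Feedback stability: with k·‖Γ‖₁ = 0.01 the squared-product recursion
  decays double-exponentially once its drive vanishes; responses stay finite
  for bounded inputs at the default gain.

## Problem sizes

The full benchmark scene (500×250 × 21 frames, 12 substeps) runs in roughly
half a minute on one core. Multi-scene studies (size-selectivity and
luminance sweeps in the test suite and the acceptance script) use a reduced
viewport (250×120 or similar) with the same object parameters, frame rate
and velocities, which preserves the physics of the task at a fraction of the
cost; the baseline false-positive-suppression study runs at full size.

## Known limitations

- Confirmation has an onset lag: the running contrast SD needs several
  trajectory points to exceed Th2 = 4, so the first few frames of even a
  clearly tracked mover are unconfirmed, and on texture realizations where
  the contrast series varies little the SD can plateau just below the
  threshold. Raw LC11 detection coverage of the mover is typically 95–100%;
  frame-level confirmed coverage is ~75–85% across seeds. This mirrors the
  behaviour of the modelled system, whose reported frame-level detection
  accuracy is likewise below 80%.

- At 30 FPS input the model's temporal fidelity is bounded by the
  sample-and-hold assumption; true inter-frame motion (e.g., motion blur) is
  not modelled.
- Per-frame max normalization before Th makes detection *relative*: a frame
  whose strongest response is clutter can mask a weak target that frame.
- The tracker is single-hypothesis greedy nearest-neighbour; crossing
  trajectories can swap identities (they are still counted correctly by the
  position-based metrics).
- Velocities well above 250 px/s shorten the target transit below the fixed
  25 ms delay and the response fades — an inherited property of the model,
  not of this implementation.
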