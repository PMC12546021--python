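# Methods

## Frame measurements

**Sharpness.**  `Var_L` is the population variance of the response of the
3×3 4-neighbour Laplacian kernel (centre −4) applied to the BT.601
grayscale image, with edge replication at the borders.  The Laplacian
annihilates constants, so `Var_L` is invariant to global brightness
offsets and scales quadratically with pattern amplitude.  A frame is
*blurred* when `Var_L` is strictly below the threshold (default 50).  The
threshold applies to 8-bit frames at roughly SD-video resolution; `Var_L`
grows with both contrast and resolution, so deployments at other
resolutions should re-examine it — it is a plain configuration knob
(`EngineConfig.blur_threshold`).

**Perceptual hash.**  The 64-bit DCT hash: 8-bit grayscale, Lanczos
resize to 32×32, unnormalized 2-D DCT-II, top-left 8×8 coefficient block,
thresholded against the block median (DC term included in the median;
coefficients equal to the median map to 0).  Bits pack row-major,
first bit most significant; the hex rendering is 16 lowercase digits.
This is the widely used "pHash" dialect of the common Python hashing
libraries, pinned here so hashes are reproducible bit-for-bit.  Hash
distances are computed between consecutive *processed* frames (stride
aware); no smoothing is applied before zone lookup.

**Speed zones.**  `D ≤ 20` normal, `21 ≤ D ≤ 30` warning, `D > 30`
danger.  The three zones partition [0, 64]; the thresholds are
configurable but these defaults are the contract the overlay colors
(blue/yellow/red) encode.

## Withdrawal state machine

Withdrawal start is the first frame of the first run of at least
`start_run_length` (default 5) consecutive ileocecal-classified processed
frames.  The debounce length is a design choice: a single mis-classified
frame must not start the timers, and five consecutive frames is ~0.2 s
at 25 fps.  Blurred ileocecal frames participate in start detection like
any other ileocecal frame — start detection precedes blur-based
exclusion, which only shapes Time 2.

After start, bucket priority is instrument > blur > effective:
instrument frames count toward Time 1 even when also blurred, which keeps
the buckets disjoint and makes `EWT = WT − Time1 − Time2` an identity
rather than an approximation.  Ileocecal-labelled frames after start
count as effective unless blurred (the mucosa is visible; there is no
reason to exclude the landmark region from observation time).

Withdrawal ends at the last frame of the stream: the inputs this engine
consumes are withdrawal recordings, and no anal-egress detector is
modelled.  Seconds are frames/fps; with `frame_stride > 1` each processed
frame stands for `stride` source frames and the conversion scales
accordingly (documented as an approximation — sub-stride events are
invisible).  If no frame rate is available the engine falls back to
25 fps with a logged warning.

## Synthetic withdrawal generator

The generator's purpose is parameter recovery: every quantity the engine
estimates must have a frame-exact ground truth.  A scenario is an ordered
list of segments (`pre_insertion`, `ileocecal`, `effective`,
`instrument`, `blurred`) with a frame rate, frame size (default 256×256)
and a single seed from which all randomness flows.

**Texture.**  A 512×512 toroidal canvas of band-limited value noise: two
mid-frequency octaves (48- and 128-cell grids, cubic-interpolated) plus
per-pixel fine grain, under a radial vignette.  Amplitudes put sharp
frames at `Var_L` ≈ 700–800, far above the 100 floor the generator
enforces (2× the blur threshold).  Gaussian blur episodes (default
σ = 6 px) land near `Var_L` ≈ 2; generation fails loudly if any blurred
frame reaches half the threshold or any sharp frame dips below twice it,
so engine tests can never straddle the decision boundary.

**Markers.**  Ileocecal frames carry a dark annulus centred on the frame
(radius 30% of the short side); instrument frames carry a bright straight
chord entering from the bottom edge.  The shipped heuristic classifier
probes exactly these footprints against the frame mean, which makes the
generator/heuristic pair a closed, documented contract.

**Motion.**  Camera motion is a translation over the toroidal canvas plus
a bank of 63 low-frequency cosine harmonics aligned with the hash's 8×8
DCT block.  The canvas deliberately has no low-frequency octave, so the
harmonic bank dominates those DCT coefficients; the bank's sign vector
stays balanced (±) and each frame step flips a motion-controlled, even
number of signs chosen by rotating pointers.  Each flip toggles one hash
bit, so the realized Hamming distance tracks the commanded flip count
tightly.  This is the key deviation from photorealism: pure translation
of a stationary texture can only decorrelate hash bits toward chance
(mean distance ≈ 32) and cannot hold the warning band [21, 30] or reach
the danger zone reliably.  `calibrate_motion` sweeps a per-zone grid of
strengths, measures realized distances on a probe sequence, and accepts
the best strength only if ≥ 90% of within-segment distances land in the
requested zone; zone truth is recorded per frame, with boundary frames
(motion-regime changes) carrying no expectation.

**What passing tests show.**  Exact recovery on these videos validates
the accounting logic, threshold semantics, and determinism of the
pipeline — not clinical classification accuracy.  Real endoscopy frames
have specular highlights, fluid, peristalsis and lighting drift that the
generator does not emulate, and a real deployment replaces the sidecar
stub with a trained classifier whose errors propagate into the timers.

## Evaluation layer

Scalar metrics are the standard confusion-count ratios; zero-denominator
cases report 0 with an explicit flag instead of NaN so weighted averages
stay defined.  Weighted averages normalize per-class sample counts.
ROC is built by descending-score thresholding with ties grouped; AUC is
the trapezoid rule, which equals the Mann–Whitney pairwise probability
(tested exactly).  AP is plain trapezoidal integration of precision over
recall — the direct discretization of the integral definition, not the
11-point or step-interpolated variants — anchored at recall 0 with the
first threshold's precision.

Agreement between two timing series: ICC(A,1) — single-measure, absolute
agreement, two-way random effects — computed from the two-way ANOVA mean
squares with the McGraw–Wong F-based 95% CI (cross-checked against
pingouin in the tests); Bland–Altman bias = mean(a − b) with limits
bias ± 1.96·SD(a − b) (sample SD); Pearson r (flagged NaN for
zero-variance series); Wilcoxon signed-rank with zero differences
dropped, exact null for n ≤ 25 and the continuity-corrected normal
approximation above.  Degenerate inputs (identical series) yield
ICC = 1, zero-width limits and a flagged trivial Wilcoxon rather than an
error.

## Numerical and interface choices

* Letterboxing to 640×640 uses `min`-scale, round-half-up dimensions,
  centred content, mid-gray 114 padding, bilinear resampling; idempotent
  on already-letterboxed frames.
* Hash hex, frame logs and summaries serialize deterministically; two
  runs on identical input are byte-identical.
* The overlay draws only inside two declared rectangles (timer block,
  speed bar); band colors are fixed constants and the pointer position is
  a monotone, clamped function of the distance.  Frames smaller than the
  overlay footprint get a scaled-down overlay with a warning.
* Problem sizes in the test suite: randomized scenarios are 240 frames at
  10 fps, 256×256 px (20 seeds in the recovery suite); the worked-example
  scenario is 1,560 frames.  These sizes keep the full pipeline — render,
  hash, classify, account — comfortably reproducible on a laptop while
  leaving the frame counts large enough for frame-exact accounting to be
  a meaningful check.
* The acceptance script's blur-boundary search uses a 64×64 zero-mean
  ±1 pattern whose `Var_L` scales exactly quadratically with amplitude;
  bisection stops when the bracketed variance interval is below 1e-6.

## Known limitations

* No photorealistic colon simulation, lesions, fluid or irrigation
  rendering; the marker signatures are schematic.
* The classifier slot ships only non-learned implementations; clinical
  use requires an external trained model via the adapter.
* The blur threshold's resolution dependence is documented but not
  auto-calibrated.
* MP4 I/O depends on an optional imageio plugin; PNG frame directories
  are the portable path.
* `frame_stride > 1` trades temporal resolution for speed; events shorter
  than the stride are missed by construction.
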