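# Methods

## The splicing model

Three k-space matrices `K_hi`, `K_mid`, `K_lo` of the same object are
acquired with receiving gains in strictly descending 6 dB steps (defaults
12, 6, 0 dB on a relative scale). The M phase-encoding lines are partitioned
into three symmetric regions; for the reference M = 220 geometry these are
lines 1–36 ∪ 185–220 (region 1), 37–72 ∪ 149–184 (region 2) and 73–148
(region 3), i.e. 36/220 of the lines per side for each outer region. Other
sizes scale these proportions, with the per-side width rounded to an even
integer so every region size stays divisible by four (the line-group
machinery consumes complete groups). The spliced matrix takes region 1 from
`K_hi`, region 2 from `K_mid` and region 3 from `K_lo`.

### Gain normalization

For two acquisitions A (higher gain) and B, the lines under analysis are
processed in consecutive groups of four; each group is represented by the
line whose index equals the group label `ceil(m/4)·4` (its last line), the
only reading under which exactly one magnitude vector per group carries the
group's label. Per group, the elementwise ratios of the middle-N magnitudes
(`N = 120` by default, the window over which the central columns of every
line are well exercised) are averaged into the group factor β; the overall
factor is the unweighted mean of the per-group βs. ΔG1 is estimated from
(hi, mid) on regions 2∪3, ΔG2 from (mid, lo) on region 3 only, and the
hi↔lo factor is the mean over shared (region-3) groups of the per-group
products ΔG1·ΔG2. Region 2 is multiplied by avg[ΔG1] and region 3 by the
chained average; multiplication is by a real positive scalar, so phases are
untouched.

Numerical guards: sample pairs whose denominator magnitude is ≤ 1e−6 times
the line's maximum are excluded (quantized synthetic data can produce exact
zeros); a group losing all its pairs raises a degenerate-data error naming
the group. Line groups containing ADC-clipped samples (known when the
simulator recorded clip masks) are excluded from estimation entirely, and
clipping *inside a spliced region* is a hard error — estimation from
saturated samples would bias the factors, and a clipped region cannot be
repaired by scaling.

### Phase normalization

Per-sample phase differences γ (degrees, wrapped to (−180°, 180°]) are
computed over the same middle-N window. Only the central (region-3,
unclipped) lines summarize the map: the surrounding k-space is
noise-dominated and its phase differences fluctuate wildly, while the
central block's are stable and representative of the global inter-scan
offset. Summaries are circular — the circular mean locates the offset, the
circular standard deviation measures dispersion — because phases wrap and
the quantity of interest is the mode near zero. The hi↔lo offset is the
wrapped sum of the two pairwise offsets. Compensation is applied to a
region only when the relevant offset magnitude reaches `threshold_deg`
(default 2°; stable hardware shows ≈0 and compensating measured noise
would add variance). Zero-magnitude samples carry no phase and are flagged
and excluded rather than assigned one.

## The synthetic study

The generator emulates a homogeneous spherical water phantom (diameter 0.9
of the field of view, mirroring a 200 mm sphere in a 220 mm view; unit
intensity; 2-pixel linear rim) scanned on a 220×440 matrix. The receiver
chain per scan: centered unnormalized 2-D DFT of the image → additive
circular complex Gaussian pre-gain noise (coil/body, `pre_noise_sigma = 1.0`
per component in k-space units) → amplification by `10^(gain_db/20)` and an
optional global phase rotation → additive post-gain noise
(`post_noise_sigma = 0.5`) → independent uniform mid-rise quantization of
the real and imaginary channels (12 bits per channel over ±`full_scale`,
saturating at the extreme code ±(FS − Δ/2)). The inverse DFT carries the
1/(M·K) factor, so k-space energy is M·K times image energy (asserted in
tests). All randomness flows through explicit integer seeds; `acquire` is a
pure function of (image, receiver, seed).

`full_scale = 32000` was calibrated to the study conditions, not to any
outcome: the lowest-gain DC peak of the unit phantom is ≈ 30170, so the
lowest gain never clips; the highest gain clips only the central lines
(110–112), far from the outer region it contributes; and the quantization
step Δ ≈ 15.6 exceeds every outer-region amplitude (region-1 max ≈ 7,
region-2 max ≈ 35), putting the lowest-gain scan deep in the
quantization-limited regime on the regions where splicing is supposed to
help. Note a mid-rise quantizer has no zero level: signals far below Δ are
driven to ±Δ/2, so the effective quantization noise on the outer regions is
close to Δ/2 per component.

### What the default boost does and does not show

With region line-fractions f₁ = f₂ = 72/220 and f₃ = 76/220, fixed
post-gain noise variance F (quantization + receiver chain) and
input-referred thermal variance σ², the image-domain noise ratio of spliced
to lowest-gain reconstruction is

    (f₁(σ² + F/16) + f₂(σ² + F/4) + f₃(σ² + F)) / (σ² + F),

so the boost grows with F/σ². Under the default (quantization-dominant,
F/σ² ≫ 1) study this yields a median boost near 50%, the method's headroom
for this geometry. Hardware studies report 5–13%: there coil/body noise
(σ²) dominates and F is a modest fraction of the total. The default
deliberately reproduces the quantization-limited regime rather than the
hardware noise composition; the test suite asserts the boost clears the
lower edge of the reported range, and the formula above explains where any
intermediate value would come from. What passing does *not* show: gains on
real multi-coil data with ghosting, B0 drift, or physiological noise — none
of which the generator models (no pulse-sequence timing, coil sensitivities,
or spatially varying phase either).

For the factor-recovery checks, the study conditions call for estimation
lines far above the noise floor. The phantom's jinc-like spectrum crosses
zero inside the analysis window (minimum middle-window magnitude ≈ 4.5e−4
on regions 2–3), so "per-sample magnitude SNR ≥ 20 everywhere" pins the
noise at `pre_noise_sigma = 1.8e−5` with quantization disabled; under those
conditions the estimator recovers the exact ratios 10^(6/20) = 1.99526 and
10^(12/20) = 3.98107 to ≪1%. Under the default 12-bit study the estimates
(≈1.88 and ≈3.77) are biased low by quantization noise in the weaker
estimation lines — the same qualitative bias direction a ratio-of-Rice
estimator shows whenever the denominator SNR is finite.

## SNR measurement

SNR = SI/SD: SI is the mean over a w×w ROI (default w = M/10) centered on
the maximum of the boxcar-smoothed image — smoothed so placement is
deterministic and immune to single-pixel spikes — and SD is the mean of the
four corner rectangles' standard deviations (each 10% of the image per
dimension, unbiased n−1 denominator, per the two-step average-of-corner-SDs
definition). Boosts are only defined between reports with identical ROI and
corner bounds (fixed from the baseline), making the comparison a pure
k-space effect. Corners are not masked for ghosts: any such bias is common
to both images in a paired comparison. A noiseless image has SD = 0 and no
defined SNR (degenerate-background error).

## Design choices where the design was open

- **Centered k-space convention** on disk and in memory (DC at the matrix
  center), with the symmetric `fftshift`/`ifftshift` DFT sandwich; the
  reconstruction module owns the reordering.
- **HDF5 primary format** (complex dataset + `gain_db` attribute + JSON
  metadata attribute, `track_times` off so rewrites are byte-identical);
  a float32 interleaved raw dialect with JSON sidecar for interoperability.
- **Representative-line reading** of the four-line grouping (see above);
  computing β from all four lines of each group is a documented alternative
  the estimator could adopt, at 4× the samples per group.
- **Region-average compensation** (one factor for all of region 2, one for
  region 3) rather than per-group factors: matches the summed-then-averaged
  definition of the applied factor.
- **Unweighted group averaging**: per-group βs enter the average with equal
  weight regardless of line amplitude.
- **1-based public line indexing**, matching the m = 1..220 convention of
  the field's line-numbering; storage is 0-based NumPy.
- **Problem sizes in tests**: the full 220×440 study simulates in ~0.1 s,
  so unit and acceptance tests run it directly; the CLI tests use a 64×128
  study purely to keep I/O small.

## Known limitations

Single-channel, single-slice, three-region pipeline (the partition type is
general but the estimator chain is fixed at three regions); no vendor raw
or ISMRMRD ingestion; no spatially varying phase correction; the simulator
omits coil sensitivity, ghosting and physiological noise, so absolute SNR
values are not comparable to scanner measurements — only paired contrasts
within a study are meaningful.
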