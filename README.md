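# kspacesplice

Receiver-gain-staggered k-space splicing for MRI image SNR enhancement.

## The problem

In MRI, each row of k-space (a phase-encoding line) is one received echo, and
echo amplitude varies enormously across lines: the central lines carry the
bulk of the image energy while the outer lines sit orders of magnitude lower.
A receiver with a fixed receiving gain (RG) must be set so the central lines
do not saturate the ADC, which leaves the outer lines far below full scale,
where quantization noise eats into their signal-to-noise ratio.

This package implements a post-acquisition remedy that needs no receiver
hardware changes: scan the object three times at RGs τ, τ−6 and τ−12 dB,
then splice one k-space from the three —

- **region 1** (outer lines) from the **highest** gain τ, where the weak
  echoes best exploit the ADC's dynamic range,
- **region 2** (intermediate lines) from τ−6,
- **region 3** (central lines) from the **lowest** gain τ−12, the only
  setting that does not clip them.

Before splicing, regions 2 and 3 are normalized *up* to the amplitude scale
of the maximum gain. The gain-difference factor between two scans is not
taken from the dial — attenuator steps are inexact — but estimated from the
data: over consecutive groups of four lines, the per-sample magnitude ratios

        α_i = δ_A,i / δ_B,i ,   β = (1/N) Σ α_i

are computed on the middle *N* = 120 frequency-encoding samples of each
group's representative line, giving per-group factors ΔG1 (τ vs τ−6, on
regions 2–3) and ΔG2 (τ−6 vs τ−12, on region 3). Region 2 is scaled by
avg[ΔG1] and region 3 by the chained factor avg[ΔG1·ΔG2]. Phase differences
between scans are mapped per sample (γ_ij = ε_A,ij − ε_B,ij, wrapped to
(−180°, 180°]) and summarized by a circular mean over the noise-robust
central window; compensation is applied only when that offset exceeds a
threshold (it is ≈0 on stable hardware). The spliced k-space is inverse
Fourier transformed, and image quality is scored as SNR = SI/SD — mean ROI
intensity over the average standard deviation of the four corner background
areas — against the lowest-gain reconstruction with *paired* ROI/corner
bounds.

A synthetic study (homogeneous spherical phantom, 220×440 matrix, three
gains 6 dB apart, circular Gaussian receiver noise, 12-bit mid-rise ADC with
clipping) makes every stage testable without scanner data.

## Worked example

```sh
$ kspace-splice full --out run
boost 49.5276% (baseline SNR 73.9181, spliced SNR 110.5280)
```

This simulates the default study (unit-intensity phantom; gains 12/6/0 dB;
12-bit ADC with full scale 32000, just above the lowest-gain DC peak, so the
outer lines sit below one quantization step), splices, reconstructs and
evaluates. `run/audit.json` records the estimation chain:

- `dg1_avg = 1.8788` — estimated avg[ΔG1]; below the ideal 10^(6/20) ≈ 2
  because quantization noise contaminates the weaker estimation lines,
- `chained_avg = 3.7651` — estimated avg[ΔG1·ΔG2] (ideal ≈ 4),
- `phase_central_offsets_deg = [-0.134, 0.172]` — both within the 2°
  threshold, so phase compensation correctly defaults to zero.

`run/snr_report.json` holds the paired measurements: baseline (lowest-gain)
SNR 73.92, spliced SNR 110.53, i.e. a 49.5% boost. The boost is large
because the default receiver is deliberately quantization-limited on the
outer regions — the regime the method exists for; see `docs/methods.md` for
how the boost depends on the noise composition. Hardware studies, where
coil/body noise dominates, sit in the single-digit-to-low-teens percent
range.

The same stages are available piecewise (`kspace-splice simulate`,
`splice`, `evaluate`) and as a library:

```python
from kspacesplice import simulate_study, splice, reconstruct, measure_snr, snr_boost

hi, mid, lo = simulate_study(seeds=(101, 202, 303))
result = splice(hi, mid, lo)                 # estimates ΔG1, ΔG2, phases
baseline = measure_snr(reconstruct(lo))
spliced = measure_snr(reconstruct(result.kspace), roi=baseline.roi_bounds)
print(snr_boost(spliced, baseline))          # 49.53 (percent)
```

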