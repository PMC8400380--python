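"""Synthetic three-gain acquisition study.

Emulates the experiment every downstream stage is tested against: a
homogeneous spherical water phantom scanned three times with receiving gains
6 dB apart, through a receiver chain consisting of

1. centered 2-D DFT of the phantom image (the ideal echo signal),
2. additive circular complex Gaussian *pre-gain* noise (coil/body noise,
   input-referred),
3. amplification by ``10**(gain_db/20)`` and an optional global phase
   rotation (the programmable-attenuator path may shift phase between scans),
4. additive circular complex Gaussian *post-gain* noise (receiver chain),
5. independent uniform mid-rise ADC quantization of the real and imaginary
   channels, with saturation (clipping) at full scale.

The DFT is unnormalized on the forward side and carries the ``1/(M*K)``
factor on the inverse side, so k-space energy is ``M*K`` times image energy
(Parseval); all SNR figures are ratios and do not depend on this constant.

Default receiver parameters put the lowest-gain scan in the
quantization-limited regime on the outer line regions — outer-line signal
amplitudes sit below one ADC step while the central lines approach full
scale — which is the regime in which region-wise gain switching pays off.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .core import KSpaceAcquisition, db_to_amplitude
from .errors import ConfigError, ShapeError

__all__ = [
    "PhantomSpec",
    "ReceiverModel",
    "make_phantom",
    "acquire",
    "simulate_study",
    "centered_fft2",
    "centered_ifft2",
    "DEFAULT_GAINS_DB",
]

#: Receiving-gain labels of the three scans, relative dB (τ, τ−6, τ−12 with τ=12).
DEFAULT_GAINS_DB: tuple[float, float, float] = (12.0, 6.0, 0.0)


def centered_fft2(image: np.ndarray) -> np.ndarray:
    """Unnormalized forward 2-D DFT with the DC sample at the matrix center."""
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(image)))


def centered_ifft2(kspace: np.ndarray) -> np.ndarray:
    """Inverse of :func:`centered_fft2` (carries the ``1/(M*K)`` factor)."""
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(kspace)))


@dataclass(frozen=True)
class PhantomSpec:
    """Homogeneous spherical phantom on an M×K scan matrix.

    ``radius_frac`` is the sphere radius as a fraction of ``min(M, K)/2``
    (the default 0.9 mirrors a 200 mm sphere in a 220 mm field of view);
    ``intensity`` is the flat interior brightness in arbitrary units;
    ``edge_softness`` is the width in pixels of the linear roll-off at the rim.
    """

    M: int = 220
    K: int = 440
    radius_frac: float = 0.9
    intensity: float = 1.0
    edge_softness: float = 2.0

    def __post_init__(self) -> None:
        if self.M <= 0 or self.K <= 0 or self.M % 4:
            raise ConfigError("M, K must be positive with M divisible by 4")
        if not 0.0 < self.radius_frac < 1.0:
            raise ConfigError("radius_frac must lie in (0, 1)")
        if self.intensity <= 0:
            raise ConfigError("intensity must be positive")
        if self.edge_softness < 0:
            raise ConfigError("edge_softness must be >= 0")


@dataclass(frozen=True)
class ReceiverModel:
    """Receiver-chain parameters for one scan.

    ``pre_noise_sigma`` / ``post_noise_sigma`` are per-real-component standard
    deviations of the circular complex Gaussian noise added before / after the
    gain stage, in k-space amplitude units.  ``adc_bits`` is the quantizer
    depth per real channel (0 disables quantization); ``full_scale`` is the
    saturation amplitude of the ADC; ``phase_offset_deg`` is a global phase
    rotation applied to the whole scan.
    """

    gain_db: float = 0.0
    pre_noise_sigma: float = 1.0
    post_noise_sigma: float = 0.5
    adc_bits: int = 12
    full_scale: float = 32000.0
    phase_offset_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.pre_noise_sigma < 0 or self.post_noise_sigma < 0:
            raise ConfigError("noise sigmas must be >= 0")
        if self.adc_bits != 0 and not 4 <= self.adc_bits <= 32:
            raise ConfigError("adc_bits must be 0 (disabled) or in 4..32")
        if self.full_scale <= 0:
            raise ConfigError("full_scale must be positive")
        if not np.isfinite(self.gain_db) or not np.isfinite(self.phase_offset_deg):
            raise ConfigError("gain_db and phase_offset_deg must be finite")


def make_phantom(spec: PhantomSpec) -> np.ndarray:
    """Render the phantom image: ``intensity`` strictly inside the sphere,
    0 outside, a linear ramp of width ``edge_softness`` at the rim."""
    r, c = np.ogrid[: spec.M, : spec.K]
    radius = spec.radius_frac * min(spec.M, spec.K) / 2.0
    dist = np.hypot(r - spec.M // 2, c - spec.K // 2)
    if spec.edge_softness == 0:
        profile = (dist < radius).astype(float)
    else:
        profile = np.clip((radius - dist) / spec.edge_softness, 0.0, 1.0)
    return spec.intensity * profile


def _quantize_midrise(x: np.ndarray, bits: int, full_scale: float) -> tuple[np.ndarray, np.ndarray]:
    """Uniform mid-rise quantizer with 2**bits levels over [-FS, +FS].

    Returns (quantized, clipped_mask).  Reconstruction levels are the
    mid-points ±(k + 1/2)·step; saturation reproduces the extreme code
    ±(FS − step/2).  Inputs with |x| > FS are flagged as clipped.
    """
    step = 2.0 * full_scale / (2**bits)
    top = full_scale - step / 2.0
    q = (np.floor(x / step) + 0.5) * step
    q = np.clip(q, -top, top)
    clipped = np.abs(x) > full_scale
    return q, clipped


def acquire(image: np.ndarray, rx: ReceiverModel, seed: int) -> KSpaceAcquisition:
    """Simulate one scan of ``image`` through the receiver chain.

    Deterministic: the same (image, rx, seed) triple always yields the same
    acquisition.  The returned metadata records the receiver parameters, the
    seed and the 1-based indices of lines containing clipped samples.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ShapeError("image must be 2-D")
    if not np.all(np.isfinite(image)):
        raise ShapeError("image contains NaN or Inf")
    rng = np.random.default_rng(seed)
    S = centered_fft2(image)
    if rx.pre_noise_sigma > 0:
        S = S + rx.pre_noise_sigma * (
            rng.standard_normal(S.shape) + 1j * rng.standard_normal(S.shape)
        )
    S = S * (db_to_amplitude(rx.gain_db) * np.exp(1j * np.deg2rad(rx.phase_offset_deg)))
    if rx.post_noise_sigma > 0:
        S = S + rx.post_noise_sigma * (
            rng.standard_normal(S.shape) + 1j * rng.standard_normal(S.shape)
        )
    clipped = np.zeros(S.shape, dtype=bool)
    if rx.adc_bits:
        re, clip_re = _quantize_midrise(S.real, rx.adc_bits, rx.full_scale)
        im, clip_im = _quantize_midrise(S.imag, rx.adc_bits, rx.full_scale)
        S = re + 1j * im
        clipped = clip_re | clip_im
    clip_lines = tuple(int(m) for m in (np.nonzero(clipped.any(axis=1))[0] + 1))
    meta = {
        "seed": int(seed),
        "gain_db": rx.gain_db,
        "pre_noise_sigma": rx.pre_noise_sigma,
        "post_noise_sigma": rx.post_noise_sigma,
        "adc_bits": rx.adc_bits,
        "full_scale": rx.full_scale,
        "phase_offset_deg": rx.phase_offset_deg,
        "clip_lines": clip_lines,
        "n_clipped_samples": int(clipped.sum()),
    }
    return KSpaceAcquisition(data=S, gain_db=rx.gain_db, meta=meta)


def simulate_study(
    spec: PhantomSpec = PhantomSpec(),
    base_rx: ReceiverModel = ReceiverModel(),
    gains_db: Sequence[float] = DEFAULT_GAINS_DB,
    seeds: Sequence[int] = (101, 202, 303),
    phase_offsets_deg: Sequence[float] | None = None,
) -> tuple[KSpaceAcquisition, KSpaceAcquisition, KSpaceAcquisition]:
    """Scan the same phantom three times, varying only the receiving gain.

    Each scan gets its own seed (independent noise realizations, as three
    separate sequence scans) and, optionally, its own global phase offset.
    Gains must be strictly descending; the highest gain is expected to clip
    central lines — the splicer only uses the non-clipping region of each
    scan.  Returns the acquisitions in (high, mid, low) gain order.
    """
    gains = [float(g) for g in gains_db]
    if len(gains) != 3:
        raise ConfigError(f"expected three gains, got {len(gains)}")
    if not (gains[0] > gains[1] > gains[2]):
        raise ConfigError(f"gains must be strictly descending, got {gains}")
    if len(seeds) != 3:
        raise ConfigError(f"expected three seeds, got {len(seeds)}")
    offsets = [0.0, 0.0, 0.0] if phase_offsets_deg is None else list(phase_offsets_deg)
    if len(offsets) != 3:
        raise ConfigError("expected three phase offsets")
    image = make_phantom(spec)
    out = []
    for gain, seed, phi in zip(gains, seeds, offsets):
        rx = replace(base_rx, gain_db=gain, phase_offset_deg=phi)
        out.append(acquire(image, rx, int(seed)))
    return tuple(out)  # type: ignore[return-value]
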