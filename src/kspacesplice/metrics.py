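"""Image reconstruction and the SI/SD signal-to-noise metric.

SNR = SI/SD: SI is the mean intensity over a bright region of interest and
SD the average of the standard deviations of four corner background
("black") rectangles.  Ghost signal leaking into the corners inflates SD
equally for all images being compared, so boosts measured with *paired*
ROI/corner bounds remain pure k-space effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

from .core import KSpaceAcquisition
from .errors import DegenerateDataError, ShapeError
from .synthetic import centered_ifft2

__all__ = ["SNRReport", "reconstruct", "measure_snr", "snr_boost", "Rect"]

#: Inclusive 1-based rectangle (row_lo, row_hi, col_lo, col_hi).
Rect = tuple[int, int, int, int]


@dataclass(frozen=True)
class SNRReport:
    """SI/SD measurement of one magnitude image."""

    si: float
    sd_corners: tuple[float, float, float, float]
    sd: float
    snr: float
    roi_bounds: Rect
    corner_bounds: tuple[Rect, Rect, Rect, Rect]

    def as_dict(self) -> dict:
        return {
            "si": self.si,
            "sd_corners": list(self.sd_corners),
            "sd": self.sd,
            "snr": self.snr,
            "roi_bounds": list(self.roi_bounds),
            "corner_bounds": [list(c) for c in self.corner_bounds],
        }


def reconstruct(acq: KSpaceAcquisition) -> np.ndarray:
    """Magnitude image from a centered k-space acquisition (inverse 2-D DFT)."""
    return np.abs(centered_ifft2(acq.data))


def _rect_view(image: np.ndarray, rect: Rect) -> np.ndarray:
    r0, r1, c0, c1 = rect
    return image[r0 - 1 : r1, c0 - 1 : c1]


def _auto_roi(image: np.ndarray, side: int) -> Rect:
    """Square ROI centered on the maximum of the boxcar-smoothed image.

    Smoothing makes the placement deterministic and robust to single-pixel
    noise spikes.
    """
    M, K = image.shape
    smooth = uniform_filter(image, size=side, mode="constant")
    r, c = np.unravel_index(int(np.argmax(smooth)), image.shape)
    half = side // 2
    r0 = int(np.clip(r - half, 0, M - side))
    c0 = int(np.clip(c - half, 0, K - side))
    return (r0 + 1, r0 + side, c0 + 1, c0 + side)


def measure_snr(
    image: np.ndarray,
    roi: Rect | None = None,
    corner_frac: float = 0.1,
    roi_side: int | None = None,
) -> SNRReport:
    """Measure SNR = SI/SD on a nonnegative magnitude image.

    The ROI is either given explicitly (1-based inclusive bounds) or placed
    automatically: a square of side ``roi_side`` (default M/10) centered on
    the brightest smoothed area.  The four background rectangles are the
    image corners, each ``corner_frac·M × corner_frac·K`` pixels.  Per-corner
    standard deviations use the unbiased (n−1) denominator and are averaged
    into SD.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ShapeError("image must be 2-D")
    if np.any(image < 0):
        raise ShapeError("magnitude image must be nonnegative")
    if not 0.0 < corner_frac <= 0.25:
        raise ValueError("corner_frac must lie in (0, 0.25]")
    M, K = image.shape
    if roi is None:
        side = roi_side if roi_side is not None else max(M // 10, 2)
        roi = _auto_roi(image, side)
    ch = max(int(round(corner_frac * M)), 2)
    cw = max(int(round(corner_frac * K)), 2)
    corners: tuple[Rect, Rect, Rect, Rect] = (
        (1, ch, 1, cw),
        (1, ch, K - cw + 1, K),
        (M - ch + 1, M, 1, cw),
        (M - ch + 1, M, K - cw + 1, K),
    )
    si = float(_rect_view(image, roi).mean())
    sds = tuple(float(_rect_view(image, c).std(ddof=1)) for c in corners)
    sd = float(np.mean(sds))
    if sd == 0:
        raise DegenerateDataError("background corners have zero spread; SNR undefined")
    return SNRReport(
        si=si, sd_corners=sds, sd=sd, snr=si / sd, roi_bounds=roi, corner_bounds=corners
    )


def snr_boost(test: SNRReport, baseline: SNRReport) -> float:
    """Percent SNR improvement of ``test`` over ``baseline``.

    Requires identical ROI and corner bounds (fix them from the baseline and
    reuse) so the comparison is paired.
    """
    if test.roi_bounds != baseline.roi_bounds or test.corner_bounds != baseline.corner_bounds:
        raise ShapeError("SNR reports use different ROI/corner bounds; comparison must be paired")
    return 100.0 * (test.snr - baseline.snr) / baseline.snr
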