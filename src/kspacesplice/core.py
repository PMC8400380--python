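"""Core data model: k-space acquisitions and phase-encoding-line region partitions.

A k-space matrix is indexed ``[line m, column k]`` with 1-based line numbers
``m = 1..M`` (phase-encoding lines) and columns ``k = 1..K`` (frequency-encoding
steps) in the public API; storage is an ordinary 0-based NumPy array.  k-space
is kept *centered*: the high-amplitude DC region sits at the matrix center, so
reconstruction must reorder before applying a standard DFT.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import numpy as np

from .errors import InvalidSizeError, MetadataError, ShapeError

# Line-ranges of the reference 220-line partition: the outer region covers
# 36 lines per side, the intermediate region the next 36 per side, and the
# central region the remaining 76 contiguous lines.
_REF_M = 220
_REF_SIDE = 36


def db_to_amplitude(db: float) -> float:
    """Convert a gain difference in dB to a linear amplitude ratio.

    A 6 dB receiving-gain step corresponds to ``10**(6/20) ≈ 2`` in amplitude,
    a 12 dB step to ``10**(12/20) ≈ 4``.
    """
    return float(10.0 ** (db / 20.0))


@dataclass
class KSpaceAcquisition:
    """One k-space matrix acquired under a single receiving-gain setting.

    Parameters
    ----------
    data
        Complex 2-D array of shape ``(M, K)``; line ``m`` is row ``m - 1``.
    gain_db
        Receiving-gain label in dB on a relative scale (e.g. τ, τ−6, τ−12).
    meta
        Free-form provenance (seed, receiver parameters, channel, slice,
        clipped-line indices, applied compensations).
    """

    data: np.ndarray
    gain_db: float
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.iscomplexobj(self.data):
            self.data = self.data.astype(np.complex128)
        validate_kspace_matrix(self.data)
        self.gain_db = float(self.gain_db)
        if not np.isfinite(self.gain_db):
            raise MetadataError("gain_db must be finite")

    @property
    def M(self) -> int:
        """Number of phase-encoding lines."""
        return self.data.shape[0]

    @property
    def K(self) -> int:
        """Number of frequency-encoding steps per line."""
        return self.data.shape[1]

    def line(self, m: int) -> np.ndarray:
        """Return phase-encoding line ``m`` (1-based)."""
        if not 1 <= m <= self.M:
            raise IndexError(f"line {m} outside 1..{self.M}")
        return self.data[m - 1]

    def lines(self, ms: Iterable[int]) -> np.ndarray:
        """Return the stack of 1-based lines ``ms`` in the given order."""
        idx = np.asarray(list(ms), dtype=int) - 1
        if idx.size and (idx.min() < 0 or idx.max() >= self.M):
            raise IndexError("line index outside 1..M")
        return self.data[idx]

    def clip_lines(self) -> tuple[int, ...]:
        """1-based lines containing ADC-clipped samples, if the acquisition
        recorded them (simulator output); empty tuple otherwise."""
        return tuple(int(m) for m in self.meta.get("clip_lines", ()))

    def replace_data(self, data: np.ndarray, **meta_updates: Any) -> "KSpaceAcquisition":
        """Copy of this acquisition with new data and updated metadata."""
        meta = dict(self.meta)
        meta.update(meta_updates)
        return KSpaceAcquisition(data=data, gain_db=self.gain_db, meta=meta)


def validate_kspace_matrix(data: np.ndarray) -> None:
    """Check the k-space matrix invariants (2-D, M ≥ 12 and divisible by 4, finite)."""
    if data.ndim != 2:
        raise ShapeError(f"k-space data must be 2-D, got ndim={data.ndim}")
    M = data.shape[0]
    if M < 12 or M % 4:
        raise InvalidSizeError(f"line count M={M} must be >= 12 and divisible by 4")
    if not np.all(np.isfinite(data.view(float))):
        raise ShapeError("k-space data contains NaN or Inf")


@dataclass(frozen=True)
class RegionPartition:
    """The three phase-encoding-line index sets of the splicing layout.

    ``region1`` holds the outer (lowest-amplitude) lines, ``region2`` the
    intermediate lines and ``region3`` the central (highest-amplitude) block.
    Regions 1 and 2 are each the union of a leading and a trailing symmetric
    block; region 3 is one contiguous central block.  All indices are 1-based.
    """

    region1: tuple[int, ...]
    region2: tuple[int, ...]
    region3: tuple[int, ...]
    M: int

    def __post_init__(self) -> None:
        all_lines = sorted(self.region1 + self.region2 + self.region3)
        if all_lines != list(range(1, self.M + 1)):
            raise InvalidSizeError("regions must disjointly cover 1..M")
        r3 = self.region3
        if list(r3) != list(range(r3[0], r3[-1] + 1)):
            raise InvalidSizeError("region3 must be a contiguous central block")

    @property
    def regions(self) -> tuple[tuple[int, ...], ...]:
        return (self.region1, self.region2, self.region3)

    def region_of(self, m: int) -> int:
        """Return 1, 2 or 3 — the region containing line ``m``."""
        for i, reg in enumerate(self.regions, start=1):
            if m in reg:
                return i
        raise IndexError(f"line {m} outside 1..{self.M}")


def default_partition(M: int) -> RegionPartition:
    """Three-region partition of ``M`` phase-encoding lines.

    For the reference 220-line matrix this returns the canonical split —
    region 1 = lines 1–36 and 185–220, region 2 = 37–72 and 149–184,
    region 3 = 73–148.  Other sizes scale the same proportions (36/220 of
    the lines per side for each outer region), with the per-side width
    rounded to an even integer so every region size stays divisible by 4.
    """
    if M < 12 or M % 4:
        raise InvalidSizeError(f"M={M} must be >= 12 and divisible by 4")
    if M == _REF_M:
        side = _REF_SIDE
    else:
        side = 2 * round(M * _REF_SIDE / _REF_M / 2)
        side = max(side, 2)
        # keep a nonempty central block
        while M - 4 * side < 4:
            side -= 2
    lead1 = tuple(range(1, side + 1))
    trail1 = tuple(range(M - side + 1, M + 1))
    lead2 = tuple(range(side + 1, 2 * side + 1))
    trail2 = tuple(range(M - 2 * side + 1, M - side + 1))
    region3 = tuple(range(2 * side + 1, M - 2 * side + 1))
    return RegionPartition(
        region1=lead1 + trail1, region2=lead2 + trail2, region3=region3, M=M
    )


def as_line_tuple(lines: Sequence[int] | Iterable[int]) -> tuple[int, ...]:
    """Normalize an iterable of 1-based line indices to a sorted tuple."""
    out = tuple(sorted(int(m) for m in lines))
    if len(set(out)) != len(out):
        raise InvalidSizeError("duplicate line indices")
    return out
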