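"""Assembly of the spliced k-space from three gain-staggered acquisitions.

The spliced matrix K takes its outer region from the highest-gain scan
(maximizing dynamic range where the echo is weakest), the intermediate
region from the middle gain, and the central region from the lowest gain
(the only one guaranteed not to saturate there).  Regions 2 and 3 are
normalized *up* to the amplitude scale of the maximum gain with the
estimated factors avg[ΔG1] and avg[ΔG1·ΔG2], and phase compensation is
applied only when the measured central phase offsets exceed a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Sequence

import numpy as np

from .core import KSpaceAcquisition, RegionPartition, as_line_tuple, default_partition
from .errors import ClippingError, ConfigError, PipelineError, ShapeError
from .gain import GainFactors, apply_gain, chained_gain_factor, gain_factor, line_groups
from .metrics import SNRReport, measure_snr, reconstruct, snr_boost
from .phase import (
    PhaseDiffMap,
    apply_phase,
    phase_compensation_value,
    phase_diff_map,
    summed_phase_offset,
)

__all__ = ["SpliceResult", "splice", "run_pipeline"]


@dataclass(frozen=True)
class SpliceResult:
    """Spliced k-space plus the full compensation audit trail."""

    kspace: KSpaceAcquisition
    factors: GainFactors
    phase_offsets_deg: tuple[float, float]  # applied to regions 2 and 3
    partition: RegionPartition
    phase_maps: tuple[PhaseDiffMap, PhaseDiffMap]

    def audit(self) -> dict[str, Any]:
        """JSON-serializable record sufficient to reproduce the splice."""
        m12, m23 = self.phase_maps
        return {
            "factors": self.factors.as_dict(),
            "phase_offsets_deg": list(self.phase_offsets_deg),
            "phase_central_offsets_deg": [
                m12.central_offset_deg,
                m23.central_offset_deg,
            ],
            "phase_central_dispersions_deg": [
                m12.central_dispersion_deg,
                m23.central_dispersion_deg,
            ],
            "partition": {
                "region1": list(self.partition.region1),
                "region2": list(self.partition.region2),
                "region3": list(self.partition.region3),
                "M": self.partition.M,
            },
            "region_sources_gain_db": dict(self.kspace.meta.get("region_sources", {})),
        }


def _drop_clipped_groups(
    lines: Sequence[int], *acqs: KSpaceAcquisition
) -> tuple[int, ...]:
    """Remove whole four-line groups containing clipped lines of any of the
    given acquisitions; estimation must only see unclipped samples."""
    clipped: set[int] = set()
    for acq in acqs:
        clipped.update(acq.clip_lines())
    kept: list[int] = []
    for _, block in line_groups(lines):
        if not clipped.intersection(block):
            kept.extend(block)
    return tuple(kept)


def _check_clip_safety(acq: KSpaceAcquisition, region: Sequence[int], name: str) -> None:
    inside = sorted(set(acq.clip_lines()) & set(region))
    if inside:
        raise ClippingError(
            f"{name} acquisition has ADC-clipped samples on lines {inside}, "
            "inside the region the splice takes from it"
        )


def splice(
    acq_hi: KSpaceAcquisition,
    acq_mid: KSpaceAcquisition,
    acq_lo: KSpaceAcquisition,
    partition: RegionPartition | None = None,
    N: int = 120,
    eps: float = 1e-6,
    phase_threshold_deg: float = 2.0,
) -> SpliceResult:
    """Splice three same-shape acquisitions with descending gains into one.

    Chain: estimate ΔG1 on regions 2∪3 of (hi, mid) and ΔG2 on region 3 of
    (mid, lo); compose the chained factor over the shared region-3 groups;
    assemble region 1 from hi, region 2 from mid scaled by avg[ΔG1], region 3
    from lo scaled by avg[ΔG1·ΔG2]; measure central phase offsets and apply
    compensation to regions 2 and 3 only if above threshold.  Line groups
    containing clipped samples are excluded from estimation, and clipping
    inside a spliced region is a hard error.
    """
    for other in (acq_mid, acq_lo):
        if other.data.shape != acq_hi.data.shape:
            raise ShapeError("acquisitions must share one shape")
    if not (acq_hi.gain_db > acq_mid.gain_db > acq_lo.gain_db):
        raise ConfigError(
            "gains must be strictly descending (hi > mid > lo), got "
            f"{acq_hi.gain_db}, {acq_mid.gain_db}, {acq_lo.gain_db}"
        )
    part = partition if partition is not None else default_partition(acq_hi.M)
    _check_clip_safety(acq_hi, part.region1, "highest-gain")
    _check_clip_safety(acq_mid, part.region2, "middle-gain")
    _check_clip_safety(acq_lo, part.region3, "lowest-gain")

    lines23 = as_line_tuple(part.region2 + part.region3)
    dg1_lines = _drop_clipped_groups(lines23, acq_hi, acq_mid)
    dg2_lines = _drop_clipped_groups(part.region3, acq_mid, acq_lo)
    dg1 = gain_factor(acq_hi, acq_mid, dg1_lines, N=N, eps=eps)
    dg2 = gain_factor(acq_mid, acq_lo, dg2_lines, N=N, eps=eps)
    chained = chained_gain_factor(dg1, dg2)
    factors = GainFactors(dg1=dg1, dg2=dg2, dg1_avg=dg1.average, chained_avg=chained)

    map12 = phase_diff_map(
        acq_hi, acq_mid, dg1_lines, N=N, summary_lines=dg2_lines or part.region3
    )
    map23 = phase_diff_map(acq_mid, acq_lo, dg2_lines or part.region3, N=N)
    offset2 = phase_compensation_value(map12, phase_threshold_deg)
    offset3 = phase_compensation_value(
        summed_phase_offset(map12, map23), phase_threshold_deg
    )

    mid_comp = apply_gain(acq_mid, part.region2, factors.dg1_avg)
    lo_comp = apply_gain(acq_lo, part.region3, factors.chained_avg)
    if offset2:
        mid_comp = apply_phase(mid_comp, part.region2, offset2)
    if offset3:
        lo_comp = apply_phase(lo_comp, part.region3, offset3)

    data = np.empty_like(acq_hi.data, dtype=np.complex128)
    idx1 = np.asarray(part.region1, dtype=int) - 1
    idx2 = np.asarray(part.region2, dtype=int) - 1
    idx3 = np.asarray(part.region3, dtype=int) - 1
    data[idx1] = acq_hi.data[idx1]
    data[idx2] = mid_comp.data[idx2]
    data[idx3] = lo_comp.data[idx3]

    meta = {
        "spliced": True,
        "region_sources": {
            "region1": acq_hi.gain_db,
            "region2": acq_mid.gain_db,
            "region3": acq_lo.gain_db,
        },
        "dg1_avg": factors.dg1_avg,
        "chained_avg": factors.chained_avg,
        "phase_offsets_deg": [offset2, offset3],
        "source_seeds": [
            acq.meta.get("seed") for acq in (acq_hi, acq_mid, acq_lo)
        ],
    }
    kspace = KSpaceAcquisition(data=data, gain_db=acq_hi.gain_db, meta=meta)
    return SpliceResult(
        kspace=kspace,
        factors=factors,
        phase_offsets_deg=(offset2, offset3),
        partition=part,
        phase_maps=(map12, map23),
    )


def run_pipeline(config: "PipelineConfig") -> tuple[SpliceResult, dict[str, Any]]:
    """End-to-end execution: obtain the three acquisitions, splice, and
    compare the spliced reconstruction's SNR against the lowest-gain one.

    Returns the splice result and an evaluation dictionary holding the
    paired SNR reports and the percent boost.  Stage failures are re-raised
    tagged with the stage that produced them.
    """
    from .config import PipelineConfig  # local import to avoid a cycle

    if not isinstance(config, PipelineConfig):
        raise ConfigError(f"expected PipelineConfig, got {type(config).__name__}")
    stage = "acquire"
    try:
        acq_hi, acq_mid, acq_lo = config.acquisitions()
        stage = "splice"
        result = splice(
            acq_hi,
            acq_mid,
            acq_lo,
            N=config.n_middle,
            phase_threshold_deg=config.phase_threshold_deg,
        )
        stage = "reconstruct"
        img_spliced = reconstruct(result.kspace)
        img_lo = reconstruct(acq_lo)
        stage = "evaluate"
        baseline = measure_snr(img_lo, corner_frac=config.corner_frac, roi=config.roi)
        spliced = measure_snr(
            img_spliced, roi=baseline.roi_bounds, corner_frac=config.corner_frac
        )
        boost = snr_boost(spliced, baseline)
    except Exception as exc:
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc)) from exc
    evaluation = {
        "baseline": baseline.as_dict(),
        "spliced": spliced.as_dict(),
        "boost_pct": boost,
    }
    return result, evaluation
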