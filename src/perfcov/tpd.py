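"""Total perfusion deficit (TPD) scoring on polar maps.

TPD combines the extent (area) and severity (depth) of hypoperfusion into
one percentage of the analyzed LV surface: 0% for a map at the normal mean,
100% for no visible uptake anywhere.  The same formulation restricted to a
6-ring coverage mask (two consecutive rings at the center of the apical,
mid and basal zones) yields the 3-slice TPD, which models conventional
3-short-axis-slice perfusion acquisitions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np

from .normal_limits import NormalLimits, abnormality_mask, deviation_map
from .polarmap import CoverageMask, PolarMap, SegmentModel, whole_heart_mask

__all__ = [
    "TPDResult",
    "build_three_slice_mask",
    "compute_tpd",
    "compute_three_slice_tpd",
    "segment_extents",
    "score_patient",
    "fractional_deficit_severity",
]

#: Severity hook signature: (normal mean grid, value grid, mad grid) -> grid
#: of per-pixel severities in [0, 1].
SeverityFn = Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray]


def fractional_deficit_severity(
    mean: np.ndarray, values: np.ndarray, mad: np.ndarray
) -> np.ndarray:
    """Default severity: fractional deficit relative to the normal mean.

    ``s = clip((mean - value) / mean, 0, 1)`` — zero uptake scores 1, so an
    empty map integrates to TPD 100%.
    """
    safe_mean = np.maximum(mean, 1e-12)
    return np.clip((mean - values) / safe_mean, 0.0, 1.0)


@dataclass(frozen=True)
class TPDResult:
    """Per-patient TPD pair plus segmental defect extents."""

    whole_heart_tpd: float
    three_slice_tpd: float
    per_segment_extent: Mapping[int, float]
    abnormal_area_percent: float


def build_three_slice_mask(model: SegmentModel) -> CoverageMask:
    """Two consecutive rings centered in each of the apical/mid/basal zones.

    The selected rings are ``floor(midpoint)`` and ``floor(midpoint) + 1``
    of each zone's ring interval (both rings when the zone has exactly 2).
    Apex-cap rings are never included, so the mask always covers exactly
    ``6 * A`` pixels.
    """
    include = np.zeros((model.R, model.A), dtype=bool)
    for zone in ("apical", "mid", "basal"):
        start, stop = model.zone_bounds[zone]
        if stop - start < 2:
            raise ValueError(f"zone {zone!r} has fewer than 2 rings")
        lo = (start + stop - 1) // 2
        include[lo : lo + 2, :] = True
    return CoverageMask(include=include)


def _check_inputs(pmap: PolarMap, limits: NormalLimits, model: SegmentModel) -> None:
    model.check_map(pmap)
    if pmap.gender != limits.gender:
        raise ValueError(
            f"gender mismatch: map is {pmap.gender!r}, limits are {limits.gender!r}"
        )
    if limits.shape != (model.R, model.A):
        raise ValueError("limits grid does not match model grid")


def compute_tpd(
    pmap: PolarMap,
    limits: NormalLimits,
    mask: CoverageMask,
    model: SegmentModel,
    severity_fn: SeverityFn = fractional_deficit_severity,
) -> float:
    """Area-weighted integral of hypoperfusion severity over abnormal pixels.

    ``TPD = 100 * sum_{p in mask, abnormal} w_p s_p / sum_{p in mask} w_p``
    where abnormality is the MAD-threshold comparison against the normal
    limits and ``s_p`` the severity hook (default: clamped fractional
    deficit).  Result is in [0, 100].
    """
    _check_inputs(pmap, limits, model)
    if mask.shape != (model.R, model.A):
        raise ValueError("mask shape does not match model grid")
    if not mask.include.any():
        raise ValueError("coverage mask is empty")

    dev = deviation_map(pmap, limits)
    abnormal = abnormality_mask(dev, limits.threshold_mad)
    severity = severity_fn(limits.mean, pmap.values, limits.mad)

    w = model.area_weight
    inc = mask.include
    numer = float((w * severity * abnormal * inc).sum())
    denom = float((w * inc).sum())
    return 100.0 * numer / denom


def compute_three_slice_tpd(
    pmap: PolarMap,
    limits: NormalLimits,
    model: SegmentModel,
    severity_fn: SeverityFn = fractional_deficit_severity,
    denominator: str = "masked",
) -> float:
    """TPD restricted to the 3-slice mask.

    ``denominator="masked"`` (default) normalizes by the masked area only,
    so a uniform defect scores identically under both coverages;
    ``denominator="whole"`` keeps the whole-LV denominator.
    """
    mask = build_three_slice_mask(model)
    tpd = compute_tpd(pmap, limits, mask, model, severity_fn=severity_fn)
    if denominator == "masked":
        return tpd
    if denominator == "whole":
        w = model.area_weight
        return tpd * float((w * mask.include).sum()) / float(w.sum())
    raise ValueError(f"denominator must be 'masked' or 'whole', got {denominator!r}")


def segment_extents(
    pmap: PolarMap,
    limits: NormalLimits,
    model: SegmentModel,
) -> dict[int, float]:
    """Percent of each segment's weighted area that is abnormal."""
    _check_inputs(pmap, limits, model)
    dev = deviation_map(pmap, limits)
    abnormal = abnormality_mask(dev, limits.threshold_mad)
    w = model.area_weight
    extents: dict[int, float] = {}
    for seg in range(1, 18):
        seg_mask = model.segment_mask(seg)
        total = float(w[seg_mask].sum())
        hit = float(w[seg_mask & abnormal].sum())
        extents[seg] = 100.0 * hit / total
    return extents


def score_patient(
    pmap: PolarMap,
    limits: NormalLimits,
    model: SegmentModel,
    severity_fn: SeverityFn = fractional_deficit_severity,
    denominator: str = "masked",
) -> TPDResult:
    """Whole-heart and 3-slice TPD plus segmental extents for one map."""
    wh = compute_tpd(pmap, limits, whole_heart_mask(model), model, severity_fn)
    ts = compute_three_slice_tpd(pmap, limits, model, severity_fn, denominator)
    extents = segment_extents(pmap, limits, model)

    dev = deviation_map(pmap, limits)
    abnormal = abnormality_mask(dev, limits.threshold_mad)
    w = model.area_weight
    abn_pct = 100.0 * float(w[abnormal].sum()) / float(w.sum())
    return TPDResult(
        whole_heart_tpd=wh,
        three_slice_tpd=ts,
        per_segment_extent=extents,
        abnormal_area_percent=abn_pct,
    )
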