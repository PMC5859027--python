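"""Left-ventricular polar-map grid model.

A polar map (bullseye plot) places the LV apex at the grid center and the
base at the rim: rows are rings (short-axis position, apex outward), columns
are circumferential sectors.  This module defines the grid container, its
partition into the standard 17-segment LV model (6 basal, 6 mid, 4 apical
segments plus the apex cap), per-pixel area weights, count normalization,
and a plain-text file format.

Conventions (documented, not anatomically mandated by any source data):

* ring 0 is the apex center, ring ``R - 1`` the base;
* sector 0 is anchored at the anterior wall, counting counterclockwise as
  viewed from the apex;
* radial zones are ordered apex-cap, apical, mid, basal from ring 0 out.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Mapping

import numpy as np

__all__ = [
    "GENDERS",
    "ZONES",
    "PolarMap",
    "SegmentModel",
    "CoverageMask",
    "build_segment_model",
    "normalize_map",
    "top_decile_mean",
    "read_polar_map",
    "write_polar_map",
    "whole_heart_mask",
]

GENDERS = ("male", "female")

#: Radial zone names in ring order, apex outward.
ZONES = ("apex_cap", "apical", "mid", "basal")

#: Minimum ring count per zone: a 2-ring slice must fit in each of the
#: apical/mid/basal zones.
_ZONE_MIN_RINGS = {"apex_cap": 1, "apical": 2, "mid": 2, "basal": 2}

#: Segments expected in each zone (sanity contract for the partition).
ZONE_SEGMENTS = {
    "basal": tuple(range(1, 7)),
    "mid": tuple(range(7, 13)),
    "apical": tuple(range(13, 17)),
    "apex_cap": (17,),
}


@dataclass(frozen=True)
class PolarMap:
    """One subject's grid of relative tracer uptake.

    Parameters
    ----------
    subject_id
        Opaque identifier.
    gender
        ``"male"`` or ``"female"``; normal limits are gender-matched.
    values
        Non-negative float array of shape ``(R, A)``.
    normalized
        True once :func:`normalize_map` has scaled the grid so the
        reference statistic equals 100.
    """

    subject_id: str
    gender: str
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.gender not in GENDERS:
            raise ValueError(f"gender must be one of {GENDERS}, got {self.gender!r}")
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError(f"values must be a 2-D grid, got ndim={v.ndim}")
        if not np.all(np.isfinite(v)):
            raise ValueError("values must be finite")
        if np.any(v < 0):
            raise ValueError("uptake values must be non-negative")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class SegmentModel:
    """Pixel-to-segment map with radial zone boundaries and area weights.

    ``zone_bounds`` maps each zone name to a half-open ring interval
    ``(start, stop)``; the intervals are disjoint, contiguous and cover
    ``0..R-1``.  ``segment_of`` holds segment ids 1..17 per pixel and
    ``area_weight`` a strictly positive weight proportional to the LV
    surface area the pixel represents.
    """

    R: int
    A: int
    zone_bounds: Mapping[str, tuple[int, int]]
    segment_of: np.ndarray
    area_weight: np.ndarray

    def zone_rings(self, zone: str) -> range:
        start, stop = self.zone_bounds[zone]
        return range(start, stop)

    def segment_mask(self, segment: int) -> np.ndarray:
        return self.segment_of == segment

    def check_map(self, pmap: PolarMap) -> None:
        if pmap.shape != (self.R, self.A):
            raise ValueError(
                f"map shape {pmap.shape} does not match model grid ({self.R}, {self.A})"
            )


@dataclass(frozen=True)
class CoverageMask:
    """Boolean ring/sector inclusion mask (whole-heart or 3-slice)."""

    include: np.ndarray

    def __post_init__(self) -> None:
        inc = np.asarray(self.include, dtype=bool)
        if inc.ndim != 2:
            raise ValueError("mask must be a 2-D grid")
        object.__setattr__(self, "include", inc)

    @property
    def shape(self) -> tuple[int, int]:
        return self.include.shape  # type: ignore[return-value]

    @property
    def n_pixels(self) -> int:
        return int(self.include.sum())


def _allocate_rings(R: int, zone_fractions: tuple[float, float, float, float]) -> list[int]:
    """Largest-remainder apportionment of R rings over the four zones.

    Zone minimums (1 ring apex cap, 2 rings elsewhere) are enforced after
    apportionment by moving rings from the zones with the most slack.
    """
    quotas = [f * R for f in zone_fractions]
    counts = [math.floor(q) for q in quotas]
    leftover = R - sum(counts)
    by_remainder = sorted(range(4), key=lambda i: (-(quotas[i] - counts[i]), i))
    for i in by_remainder[:leftover]:
        counts[i] += 1

    minimums = [_ZONE_MIN_RINGS[z] for z in ZONES]
    for i in range(4):
        while counts[i] < minimums[i]:
            slack = [counts[j] - minimums[j] for j in range(4)]
            donor = int(np.argmax(slack))
            if slack[donor] <= 0:
                raise ValueError(
                    f"cannot allocate rings: R={R} too small for zone minimums"
                )
            counts[donor] -= 1
            counts[i] += 1
    return counts


def build_segment_model(
    R: int = 24,
    A: int = 36,
    zone_fractions: tuple[float, float, float, float] = (1 / 8, 7 / 24, 7 / 24, 7 / 24),
    weight_offset: float = 30.0,
) -> SegmentModel:
    """Build the 17-segment partition of an ``R x A`` polar grid.

    ``zone_fractions`` are the radial proportions of the apex-cap, apical,
    mid and basal zones (in ring order from the apex).  Basal and mid zones
    are split into 6 equal angular sectors (segments 1-6 and 7-12), the
    apical zone into 4 (segments 13-16), and the apex cap is segment 17.

    ``weight_offset`` inflates the flat-disc ring weight ``2 r + 1`` by a
    constant per pixel, approximating the blunt apical cap of the LV
    ellipsoid: a pure flat-disc weighting gives the apex almost no surface
    area, which understates apical defects.
    """
    if R < 8:
        raise ValueError(f"need R >= 8 rings, got {R}")
    if A % 12 != 0 or A <= 0:
        raise ValueError(f"A must be a positive multiple of 12, got {A}")
    if len(zone_fractions) != 4:
        raise ValueError("zone_fractions must have exactly 4 entries")
    if any(f <= 0 for f in zone_fractions):
        raise ValueError("zone_fractions must be positive")
    if not math.isclose(sum(zone_fractions), 1.0, abs_tol=1e-9):
        raise ValueError(f"zone_fractions must sum to 1, got {sum(zone_fractions)}")
    if weight_offset < 0:
        raise ValueError("weight_offset must be non-negative")

    counts = _allocate_rings(R, tuple(zone_fractions))
    bounds: dict[str, tuple[int, int]] = {}
    start = 0
    for zone, n in zip(ZONES, counts):
        bounds[zone] = (start, start + n)
        start += n

    seg = np.empty((R, A), dtype=int)
    sectors = np.arange(A)
    seg[bounds["apex_cap"][0] : bounds["apex_cap"][1], :] = 17
    seg[bounds["apical"][0] : bounds["apical"][1], :] = 13 + sectors // (A // 4)
    seg[bounds["mid"][0] : bounds["mid"][1], :] = 7 + sectors // (A // 6)
    seg[bounds["basal"][0] : bounds["basal"][1], :] = 1 + sectors // (A // 6)

    rings = np.arange(R, dtype=float)
    weight = np.broadcast_to((2.0 * rings + 1.0 + weight_offset)[:, None], (R, A)).copy()

    return SegmentModel(R=R, A=A, zone_bounds=bounds, segment_of=seg, area_weight=weight)


def top_decile_mean(values: np.ndarray) -> float:
    """Mean of the brightest 10% of pixels (at least one pixel)."""
    flat = np.sort(np.asarray(values, dtype=float).ravel())
    k = max(1, math.ceil(flat.size * 0.1))
    return float(flat[-k:].mean())


def normalize_map(
    pmap: PolarMap,
    reference: Callable[[np.ndarray], float] = top_decile_mean,
) -> PolarMap:
    """Scale a map by one positive constant so ``reference(values) == 100``.

    Idempotent: normalizing an already-normalized map is a no-op (the
    scaling is linear, so the reference statistic is already 100).
    """
    ref = reference(pmap.values)
    if not ref > 0:
        raise ValueError(
            f"cannot normalize map {pmap.subject_id!r}: reference statistic is {ref}"
        )
    return replace(pmap, values=pmap.values * (100.0 / ref), normalized=True)


def whole_heart_mask(model: SegmentModel) -> CoverageMask:
    return CoverageMask(include=np.ones((model.R, model.A), dtype=bool))


# ---------------------------------------------------------------------------
# Plain-text polar-map file format
#
#   # subject_id=S0001
#   # gender=male
#   # rings=24
#   # sectors=36
#   # normalized=1
#   <R rows of A whitespace-separated values>
# ---------------------------------------------------------------------------

_REQUIRED_HEADER = ("subject_id", "gender", "rings", "sectors")


def write_polar_map(pmap: PolarMap, path: str | Path) -> None:
    R, A = pmap.shape
    path = Path(path)
    with path.open("w", newline="\n") as fh:
        fh.write(f"# subject_id={pmap.subject_id}\n")
        fh.write(f"# gender={pmap.gender}\n")
        fh.write(f"# rings={R}\n")
        fh.write(f"# sectors={A}\n")
        fh.write(f"# normalized={int(pmap.normalized)}\n")
        np.savetxt(fh, pmap.values, fmt="%.10g")


def read_polar_map(path: str | Path) -> PolarMap:
    path = Path(path)
    header: dict[str, str] = {}
    rows: list[str] = []
    with path.open("r") as fh:  # universal newlines: CRLF and LF parse alike
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    header[key.strip()] = value.strip()
            else:
                rows.append(line)

    missing = [k for k in _REQUIRED_HEADER if k not in header]
    if missing:
        raise ValueError(f"{path}: missing header fields {missing}")
    R, A = int(header["rings"]), int(header["sectors"])
    try:
        values = np.array([[float(x) for x in row.split()] for row in rows])
    except ValueError as exc:
        raise ValueError(f"{path}: malformed matrix row ({exc})") from exc
    if values.shape != (R, A):
        raise ValueError(
            f"{path}: declared grid ({R}, {A}) but found shape {values.shape}"
        )
    return PolarMap(
        subject_id=header["subject_id"],
        gender=header["gender"],
        values=values,
        normalized=bool(int(header.get("normalized", "0"))),
    )
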