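"""Gender-matched normal perfusion limits and per-pixel deviation scoring.

Limits are per-pixel mean uptake and mean absolute deviation (MAD) about
that mean, fitted over a defect-free cohort of normalized maps of one
gender.  A pixel is scored by its one-sided deviation below the normal
mean in MAD units; pixels at or beyond ``threshold_mad`` (default 3.0,
roughly 2.5 SD for Gaussian noise) are abnormal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .polarmap import GENDERS, PolarMap, read_polar_map, write_polar_map

__all__ = [
    "NormalLimits",
    "fit_normal_limits",
    "deviation_map",
    "abnormality_mask",
    "save_limits",
    "load_limits",
]

DEFAULT_THRESHOLD_MAD = 3.0
#: Lower bound on the per-pixel MAD (on the 0-100 normalized scale); keeps
#: the deviation finite at near-deterministic pixels.
DEFAULT_MAD_FLOOR = 1.0


@dataclass(frozen=True)
class NormalLimits:
    gender: str
    mean: np.ndarray
    mad: np.ndarray
    threshold_mad: float = DEFAULT_THRESHOLD_MAD
    mad_floor: float = DEFAULT_MAD_FLOOR
    n_subjects: int = 0

    def __post_init__(self) -> None:
        if self.gender not in GENDERS:
            raise ValueError(f"gender must be one of {GENDERS}")
        mean = np.asarray(self.mean, dtype=float)
        mad = np.asarray(self.mad, dtype=float)
        if mean.shape != mad.shape or mean.ndim != 2:
            raise ValueError("mean and mad must be 2-D grids of the same shape")
        if np.any(mean < 0):
            raise ValueError("mean uptake must be non-negative")
        if not self.mad_floor > 0:
            raise ValueError("mad_floor must be positive")
        if np.any(mad < self.mad_floor):
            raise ValueError("mad must be floored at mad_floor")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "mad", mad)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mean.shape  # type: ignore[return-value]


def fit_normal_limits(
    maps: Sequence[PolarMap],
    gender: str,
    threshold_mad: float = DEFAULT_THRESHOLD_MAD,
    mad_floor: float = DEFAULT_MAD_FLOOR,
) -> NormalLimits:
    """Fit per-pixel mean and MAD from >= 2 normalized same-gender maps."""
    if len(maps) < 2:
        raise ValueError(f"need at least 2 maps to fit limits, got {len(maps)}")
    if gender not in GENDERS:
        raise ValueError(f"gender must be one of {GENDERS}")
    for m in maps:
        if m.gender != gender:
            raise ValueError(
                f"map {m.subject_id!r} has gender {m.gender!r}, expected {gender!r}"
            )
        if not m.normalized:
            raise ValueError(f"map {m.subject_id!r} is not normalized")
    shapes = {m.shape for m in maps}
    if len(shapes) != 1:
        raise ValueError(f"maps have mixed grid shapes: {sorted(shapes)}")

    stack = np.stack([m.values for m in maps])
    mean = stack.mean(axis=0)
    mad = np.abs(stack - mean).mean(axis=0)
    mad = np.maximum(mad, mad_floor)
    return NormalLimits(
        gender=gender,
        mean=mean,
        mad=mad,
        threshold_mad=threshold_mad,
        mad_floor=mad_floor,
        n_subjects=len(maps),
    )


def deviation_map(pmap: PolarMap, limits: NormalLimits) -> np.ndarray:
    """One-sided hypoperfusion deviation, ``max(0, (mean - value) / mad)``.

    Super-normal uptake scores 0; only deficits count.
    """
    if pmap.gender != limits.gender:
        raise ValueError(
            f"gender mismatch: map is {pmap.gender!r}, limits are {limits.gender!r}"
        )
    if not pmap.normalized:
        raise ValueError(f"map {pmap.subject_id!r} must be normalized")
    if pmap.shape != limits.shape:
        raise ValueError(f"shape mismatch: map {pmap.shape}, limits {limits.shape}")
    return np.maximum(0.0, (limits.mean - pmap.values) / limits.mad)


def abnormality_mask(dev: np.ndarray, threshold_mad: float = DEFAULT_THRESHOLD_MAD) -> np.ndarray:
    """Pixels abnormal iff deviation >= threshold (boundary inclusive)."""
    if not threshold_mad > 0:
        raise ValueError("threshold_mad must be positive")
    return np.asarray(dev, dtype=float) >= threshold_mad


def save_limits(limits: NormalLimits, directory: str | Path) -> None:
    """Serialize as two polar-map files (mean, mad) plus a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tag = limits.gender
    write_polar_map(
        PolarMap(f"limits_mean_{tag}", limits.gender, limits.mean, normalized=True),
        directory / f"limits_mean_{tag}.txt",
    )
    write_polar_map(
        PolarMap(f"limits_mad_{tag}", limits.gender, limits.mad, normalized=True),
        directory / f"limits_mad_{tag}.txt",
    )
    meta = {
        "gender": limits.gender,
        "threshold_mad": limits.threshold_mad,
        "mad_floor": limits.mad_floor,
        "n_subjects": limits.n_subjects,
    }
    (directory / f"limits_meta_{tag}.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True) + "\n"
    )


def load_limits(directory: str | Path, gender: str) -> NormalLimits:
    directory = Path(directory)
    meta = json.loads((directory / f"limits_meta_{gender}.json").read_text())
    mean = read_polar_map(directory / f"limits_mean_{gender}.txt")
    mad = read_polar_map(directory / f"limits_mad_{gender}.txt")
    return NormalLimits(
        gender=gender,
        mean=mean.values,
        mad=mad.values,
        threshold_mad=float(meta["threshold_mad"]),
        mad_floor=float(meta["mad_floor"]),
        n_subjects=int(meta["n_subjects"]),
    )
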