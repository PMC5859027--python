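"""Synthetic normal and patient cohort generation.

Generates polar maps with the statistical structure the downstream analysis
assumes: a defect-free normal-limits cohort (pixel noise around a smooth
gender-specific baseline) and a patient cohort with a configurable mixture
of no-disease / 1- / 2- / 3-vessel coronary disease, defects planted as
contiguous regions inside the affected vessel's territory.  A configurable
fraction of single-vessel LAD cases carry an apex-only defect (confined to
segment 17), the discordance class under study: such defects sit entirely
outside the 3-slice coverage mask.

Everything is driven by ``numpy.random.Generator`` so cohorts are fully
reproducible from an integer seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .polarmap import GENDERS, PolarMap, SegmentModel, write_polar_map

__all__ = [
    "VESSELS",
    "TERRITORY_SEGMENTS",
    "DiseaseSpec",
    "CohortConfig",
    "territory_map",
    "baseline_profile",
    "generate_normal_map",
    "generate_patient_map",
    "generate_normal_cohort",
    "generate_cohort",
    "draw_disease_classes",
    "grow_region",
]

VESSELS = ("LAD", "LCX", "RCA")

#: Standard coronary territory assignment of the 17 LV segments.
TERRITORY_SEGMENTS: dict[str, tuple[int, ...]] = {
    "LAD": (1, 2, 7, 8, 13, 14, 17),
    "RCA": (3, 4, 9, 10, 15),
    "LCX": (5, 6, 11, 12, 16),
}

#: Disease-class labels in mixture order.
CLASSES = ("none", "one_vessel", "two_vessel", "three_vessel", "branch_only")


def territory_map(model: SegmentModel) -> dict[int, str]:
    """Map each segment id 1..17 to its supplying vessel."""
    out: dict[int, str] = {}
    for vessel, segs in TERRITORY_SEGMENTS.items():
        for seg in segs:
            out[seg] = vessel
    assert set(out) == set(range(1, 18))
    return out


@dataclass(frozen=True)
class DiseaseSpec:
    """Defect description for one patient.

    ``apical_only`` restricts a single-vessel LAD defect to segment 17
    (the apex cap), the lesion class that 3-slice coverage cannot see.
    """

    vessels: frozenset[str]
    defect_severity: float
    defect_extent: float
    apical_only: bool = False
    branch_only: bool = False

    def __post_init__(self) -> None:
        vessels = frozenset(self.vessels)
        if not vessels <= set(VESSELS):
            raise ValueError(f"unknown vessels: {vessels - set(VESSELS)}")
        if vessels and not 0.0 < self.defect_severity <= 1.0:
            raise ValueError("defect_severity must be in (0, 1]")
        if vessels and not 0.0 < self.defect_extent <= 1.0:
            raise ValueError("defect_extent must be in (0, 1]")
        if self.apical_only and vessels != {"LAD"}:
            raise ValueError("apical_only requires vessels == {'LAD'}")
        object.__setattr__(self, "vessels", vessels)


@dataclass(frozen=True)
class CohortConfig:
    """Patient-cohort generation parameters.

    ``mixture`` gives the probabilities of no-disease, 1-, 2- and 3-vessel
    classes; any remainder is branch-only disease (a ≥70% stenosis confined
    to a diagonal/marginal/descending branch), modeled as a small-extent
    defect in a random parent territory and counted as CAD-positive.
    """

    n_patients: int = 651
    mixture: tuple[float, float, float, float] = (0.29, 0.36, 0.19, 0.11)
    apical_fraction: float = 0.15
    male_fraction: float = 0.57
    noise_sd: float = 8.0
    severity_range: tuple[float, float] = (0.08, 0.75)
    extent_range: tuple[float, float] = (0.08, 0.65)
    apical_severity_range: tuple[float, float] = (0.55, 1.0)
    apical_extent_range: tuple[float, float] = (0.85, 1.0)
    branch_extent_range: tuple[float, float] = (0.02, 0.10)
    #: Probability that any patient (diseased or not) carries an artifactual
    #: low-grade perfusion heterogeneity, and its severity/extent ranges;
    #: this keeps synthetic specificity below 100%, as in clinical cohorts.
    artifact_prob: float = 0.6
    artifact_severity_range: tuple[float, float] = (0.2, 0.6)
    artifact_extent_range: tuple[float, float] = (0.05, 0.4)
    #: Probability that a (non-apex-only) LAD defect is seeded in the
    #: apical LAD segments (13, 14, 17): LAD lesions preferentially involve
    #: the distal/apical territory.
    lad_apical_seed_prob: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.mixture) != 4 or any(p < 0 for p in self.mixture):
            raise ValueError("mixture must be 4 non-negative probabilities")
        if sum(self.mixture) > 1.0 + 1e-9:
            raise ValueError("mixture must sum to at most 1")
        if not 0.0 <= self.apical_fraction <= 1.0:
            raise ValueError("apical_fraction must be in [0, 1]")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ValueError("male_fraction must be in [0, 1]")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be positive")

    @property
    def branch_fraction(self) -> float:
        return max(0.0, 1.0 - sum(self.mixture))


def baseline_profile(model: SegmentModel, gender: str) -> np.ndarray:
    """Smooth gender-specific baseline uptake with a mild apex-to-base falloff."""
    if gender not in GENDERS:
        raise ValueError(f"gender must be one of {GENDERS}")
    peak = 88.0 if gender == "male" else 84.0
    falloff = 8.0 if gender == "male" else 6.0
    radial = peak - falloff * (np.arange(model.R) / max(model.R - 1, 1))
    return np.broadcast_to(radial[:, None], (model.R, model.A)).copy()


def generate_normal_map(
    model: SegmentModel,
    gender: str,
    noise_sd: float,
    rng: np.random.Generator,
    subject_id: str = "normal",
    baseline: np.ndarray | None = None,
) -> PolarMap:
    """Defect-free map: baseline plus i.i.d. Gaussian pixel noise, floored at 0."""
    if not noise_sd > 0:
        raise ValueError("noise_sd must be positive")
    if baseline is None:
        baseline = baseline_profile(model, gender)
    values = np.maximum(0.0, baseline + rng.normal(0.0, noise_sd, size=baseline.shape))
    return PolarMap(subject_id=subject_id, gender=gender, values=values)


def grow_region(
    model: SegmentModel,
    candidate: np.ndarray,
    target_weight: float,
    rng: np.random.Generator,
    seed_from: np.ndarray | None = None,
) -> np.ndarray:
    """Grow a contiguous pixel region inside ``candidate`` by randomized BFS.

    Growth starts at a uniformly drawn pixel of ``seed_from`` (default: the
    candidate set itself) and expands across 4-neighbors (sectors wrap
    circumferentially) until the accumulated area weight reaches
    ``target_weight`` or the candidate set is exhausted.  Achieved weight
    overshoots the target by at most one pixel's weight.
    """
    candidate = np.asarray(candidate, dtype=bool)
    region = np.zeros_like(candidate)
    seed_pool = candidate if seed_from is None else (np.asarray(seed_from, bool) & candidate)
    pix = np.argwhere(seed_pool)
    if pix.size == 0 or target_weight <= 0:
        return region

    seed_r, seed_a = pix[rng.integers(len(pix))]
    frontier: list[tuple[int, int]] = [(int(seed_r), int(seed_a))]
    in_frontier = {frontier[0]}
    acc = 0.0
    w = model.area_weight
    while frontier and acc < target_weight:
        idx = int(rng.integers(len(frontier)))
        r, a = frontier.pop(idx)
        in_frontier.discard((r, a))
        region[r, a] = True
        acc += w[r, a]
        for nr, na in ((r - 1, a), (r + 1, a), (r, (a - 1) % model.A), (r, (a + 1) % model.A)):
            if 0 <= nr < model.R and candidate[nr, na] and not region[nr, na]:
                if (nr, na) not in in_frontier:
                    frontier.append((nr, na))
                    in_frontier.add((nr, na))
    return region


def _defect_region(
    model: SegmentModel,
    spec: DiseaseSpec,
    vessel: str,
    rng: np.random.Generator,
    lad_apical_seed_prob: float = 0.0,
) -> np.ndarray:
    tmap = territory_map(model)
    if spec.apical_only:
        segs = {17}
    else:
        segs = {s for s, v in tmap.items() if v == vessel}
    candidate = np.isin(model.segment_of, list(segs))
    seed_from = None
    if (
        vessel == "LAD"
        and not spec.apical_only
        and rng.random() < lad_apical_seed_prob
    ):
        seed_from = np.isin(model.segment_of, (13, 14, 17))
    target = spec.defect_extent * float(model.area_weight[candidate].sum())
    return grow_region(model, candidate, target, rng, seed_from=seed_from)


def generate_patient_map(
    model: SegmentModel,
    spec: DiseaseSpec,
    gender: str,
    noise_sd: float,
    rng: np.random.Generator,
    subject_id: str = "patient",
    baseline: np.ndarray | None = None,
    artifacts: Sequence[tuple[str, float, float]] = (),
    lad_apical_seed_prob: float = 0.0,
) -> tuple[PolarMap, dict]:
    """Plant per-vessel defects into a baseline map, then add pixel noise.

    Each diseased vessel's uptake is multiplied by ``1 - defect_severity``
    over a contiguous region covering ``defect_extent`` of the territory's
    weighted area.  ``artifacts`` are (vessel, severity, extent) triples of
    truth-independent perfusion heterogeneity applied to any patient; they
    emulate the attenuation/variant findings that keep real-world
    specificity below 100%.
    """
    if baseline is None:
        baseline = baseline_profile(model, gender)
    values = baseline.copy()

    for vessel in sorted(spec.vessels):
        region = _defect_region(model, spec, vessel, rng, lad_apical_seed_prob)
        values[region] *= 1.0 - spec.defect_severity
    for vessel, severity, extent in artifacts:
        art = DiseaseSpec(
            vessels=frozenset({vessel}), defect_severity=severity, defect_extent=extent
        )
        region = _defect_region(model, art, vessel, rng)
        values[region] *= 1.0 - severity

    values = np.maximum(0.0, values + rng.normal(0.0, noise_sd, size=values.shape))
    pmap = PolarMap(subject_id=subject_id, gender=gender, values=values)
    truth = {
        "subject_id": subject_id,
        "gender": gender,
        "vessels": sorted(spec.vessels),
        "apical_only": spec.apical_only,
        "branch_only": spec.branch_only,
        "defect_severity": spec.defect_severity if spec.vessels else 0.0,
        "defect_extent": spec.defect_extent if spec.vessels else 0.0,
    }
    return pmap, truth


def generate_normal_cohort(
    model: SegmentModel,
    n_per_gender: int,
    noise_sd: float,
    rng: np.random.Generator,
) -> dict[str, list[PolarMap]]:
    """Defect-free limits cohort: ``n_per_gender`` maps per gender."""
    out: dict[str, list[PolarMap]] = {}
    for gender in GENDERS:
        baseline = baseline_profile(model, gender)
        out[gender] = [
            generate_normal_map(
                model, gender, noise_sd, rng,
                subject_id=f"N_{gender[0]}{i:03d}", baseline=baseline,
            )
            for i in range(n_per_gender)
        ]
    return out


def draw_disease_classes(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """Vector of class indices into ``CLASSES`` drawn from the mixture."""
    probs = list(config.mixture) + [config.branch_fraction]
    probs = np.asarray(probs, dtype=float)
    probs = probs / probs.sum()
    return rng.choice(len(CLASSES), size=config.n_patients, p=probs)


def _draw_spec(config: CohortConfig, cls: str, rng: np.random.Generator) -> DiseaseSpec:
    if cls == "none":
        return DiseaseSpec(vessels=frozenset(), defect_severity=1.0, defect_extent=1.0)
    if cls == "branch_only":
        vessel = VESSELS[rng.integers(3)]
        return DiseaseSpec(
            vessels=frozenset({vessel}),
            defect_severity=rng.uniform(*config.severity_range),
            defect_extent=rng.uniform(*config.branch_extent_range),
            branch_only=True,
        )
    k = {"one_vessel": 1, "two_vessel": 2, "three_vessel": 3}[cls]
    combos = list(itertools.combinations(VESSELS, k))
    vessels = frozenset(combos[rng.integers(len(combos))])
    if vessels == {"LAD"} and rng.random() < config.apical_fraction:
        return DiseaseSpec(
            vessels=vessels,
            defect_severity=rng.uniform(*config.apical_severity_range),
            defect_extent=rng.uniform(*config.apical_extent_range),
            apical_only=True,
        )
    return DiseaseSpec(
        vessels=vessels,
        defect_severity=rng.uniform(*config.severity_range),
        defect_extent=rng.uniform(*config.extent_range),
    )


def generate_cohort(
    config: CohortConfig,
    model: SegmentModel,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, dict[str, PolarMap], pd.DataFrame]:
    """Draw a full patient cohort; optionally write map files and manifest.

    Returns ``(manifest, maps, truth)``: the manifest carries per-vessel
    ≥70%-stenosis flags (the angiographic reference standard), ``maps`` is
    keyed by subject id, and ``truth`` records the generating parameters.
    Fully determined by ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    classes = draw_disease_classes(config, rng)
    baselines = {g: baseline_profile(model, g) for g in GENDERS}

    manifest_rows, truth_rows = [], []
    maps: dict[str, PolarMap] = {}
    for i, cls_idx in enumerate(classes):
        cls = CLASSES[cls_idx]
        subject_id = f"P{i:04d}"
        gender = "male" if rng.random() < config.male_fraction else "female"
        spec = _draw_spec(config, cls, rng)
        artifacts: list[tuple[str, float, float]] = []
        if rng.random() < config.artifact_prob:
            artifacts.append(
                (
                    VESSELS[rng.integers(3)],
                    rng.uniform(*config.artifact_severity_range),
                    rng.uniform(*config.artifact_extent_range),
                )
            )
        pmap, truth = generate_patient_map(
            model, spec, gender, config.noise_sd, rng,
            subject_id=subject_id, baseline=baselines[gender], artifacts=artifacts,
            lad_apical_seed_prob=config.lad_apical_seed_prob,
        )
        maps[subject_id] = pmap
        truth["disease_class"] = cls
        truth_rows.append(truth)
        manifest_rows.append(
            {
                "subject_id": subject_id,
                "gender": gender,
                "lad": int("LAD" in spec.vessels and not spec.branch_only),
                "lcx": int("LCX" in spec.vessels and not spec.branch_only),
                "rca": int("RCA" in spec.vessels and not spec.branch_only),
                "branch_only": int(spec.branch_only),
                "path": "",
            }
        )

    manifest = pd.DataFrame(manifest_rows)
    truth = pd.DataFrame(truth_rows)

    if out_dir is not None:
        out_dir = Path(out_dir)
        map_dir = out_dir / "maps"
        map_dir.mkdir(parents=True, exist_ok=True)
        for i, row in manifest.iterrows():
            rel = f"maps/{row.subject_id}.txt"
            write_polar_map(maps[row.subject_id], out_dir / rel)
            manifest.loc[i, "path"] = rel
        manifest.to_csv(out_dir / "manifest.csv", index=False, lineterminator="\n")
        truth.to_csv(out_dir / "truth.csv", index=False, lineterminator="\n")
    return manifest, maps, truth
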