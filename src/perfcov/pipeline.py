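"""End-to-end study orchestration.

Builds (or loads) gender-matched normal limits, scores every patient with
whole-heart and 3-slice TPD, and assembles the full paired comparison:
ROC/AUC with DeLong's test, sensitivity/specificity with McNemar tests at
the TPD cutoff, 2x2 concordance, regression and Bland-Altman agreement
among CAD-positive patients, and the discordant-case breakdown (how many
whole-heart-only detections were mainly apical).

Randomness is a single integer seed split per stage, so enlarging the
patient cohort does not perturb normal-limits generation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import stats as st
from .normal_limits import (
    DEFAULT_MAD_FLOOR,
    DEFAULT_THRESHOLD_MAD,
    NormalLimits,
    fit_normal_limits,
    save_limits,
)
from .polarmap import (
    GENDERS,
    PolarMap,
    SegmentModel,
    build_segment_model,
    normalize_map,
    read_polar_map,
)
from .synthcohort import CohortConfig, generate_cohort, generate_normal_cohort
from .tpd import score_patient

__all__ = [
    "StudyConfig",
    "StudyReport",
    "run_study",
    "classify_discordant_cases",
    "score_cohort",
    "load_cohort",
]

logger = logging.getLogger(__name__)

#: Apical segments for the "mainly apical" discordance call.
APICAL_SEGMENTS = frozenset(range(13, 18))


@dataclass(frozen=True)
class StudyConfig:
    """Full-study parameters; synthetic generation is used when no cohort
    paths are given."""

    rings: int = 24
    sectors: int = 36
    zone_fractions: tuple[float, float, float, float] = (1 / 8, 7 / 24, 7 / 24, 7 / 24)
    weight_offset: float = 30.0
    threshold_mad: float = DEFAULT_THRESHOLD_MAD
    mad_floor: float = DEFAULT_MAD_FLOOR
    tpd_cutoff: float = 3.0
    three_slice_denominator: str = "masked"
    n_normals_per_gender: int = 50
    cohort: CohortConfig = field(default_factory=CohortConfig)
    normal_cohort_dir: str | None = None
    patient_manifest: str | None = None
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if not self.tpd_cutoff > 0:
            raise ValueError("tpd_cutoff must be positive")
        if not self.threshold_mad > 0:
            raise ValueError("threshold_mad must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort = CohortConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw.pop("cohort", {}).items()
        })
        raw = {k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()}
        return cls(cohort=cohort, **raw)

    def build_model(self) -> SegmentModel:
        return build_segment_model(
            R=self.rings,
            A=self.sectors,
            zone_fractions=self.zone_fractions,
            weight_offset=self.weight_offset,
        )


@dataclass
class StudyReport:
    """All comparison statistics plus the per-patient score table."""

    n_patients: int
    n_cad: int
    n_no_cad: int
    tpd_cutoff: float
    roc: st.RocComparison | None
    sensitivity_whole_heart: float | None
    sensitivity_three_slice: float | None
    sensitivity_mcnemar_p: float | None
    specificity_whole_heart: float | None
    specificity_three_slice: float | None
    specificity_mcnemar_p: float | None
    sensitivity_undefined: bool
    specificity_undefined: bool
    optimal_cutoff_whole_heart: float | None
    optimal_cutoff_three_slice: float | None
    agreement: st.AgreementReport | None
    discordant: dict
    patients: pd.DataFrame = field(repr=False)

    def to_dict(self) -> dict:
        out = {
            k: v
            for k, v in dataclasses.asdict(self).items()
            if k != "patients"
        }
        return out

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True, default=_jsonify)


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def load_cohort(manifest_path: str | Path) -> tuple[pd.DataFrame, dict[str, PolarMap]]:
    """Load a cohort manifest CSV and the polar-map files it references."""
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    required = {"subject_id", "gender", "lad", "lcx", "rca", "branch_only", "path"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    maps = {
        row.subject_id: read_polar_map(manifest_path.parent / row.path)
        for row in manifest.itertuples()
    }
    return manifest, maps


def score_cohort(
    manifest: pd.DataFrame,
    maps: dict[str, PolarMap],
    limits: dict[str, NormalLimits],
    model: SegmentModel,
    three_slice_denominator: str = "masked",
) -> pd.DataFrame:
    """Per-patient whole-heart/3-slice TPD pairs and segment extents."""
    rows = []
    for row in manifest.itertuples():
        pmap = maps[row.subject_id]
        pmap = pmap if pmap.normalized else normalize_map(pmap)
        result = score_patient(
            pmap, limits[pmap.gender], model, denominator=three_slice_denominator
        )
        logger.debug(
            "%s wh=%.2f ts=%.2f", row.subject_id,
            result.whole_heart_tpd, result.three_slice_tpd,
        )
        rec = {
            "subject_id": row.subject_id,
            "gender": pmap.gender,
            "cad": int(bool(row.lad or row.lcx or row.rca or row.branch_only)),
            "whole_heart_tpd": result.whole_heart_tpd,
            "three_slice_tpd": result.three_slice_tpd,
            "abnormal_area_percent": result.abnormal_area_percent,
        }
        for seg in range(1, 18):
            rec[f"seg{seg}_extent"] = result.per_segment_extent[seg]
        rows.append(rec)
    return pd.DataFrame(rows)


def classify_discordant_cases(patients: pd.DataFrame, cutoff: float = 3.0) -> pd.Series:
    """Label threshold-discordant patients.

    ``apical-miss``: whole-heart-only detection whose maximal segment
    extent lies in the apical segments (13-17); ``non-apical-miss``: other
    whole-heart-only detections; ``reverse-discordant``: 3-slice-only
    detections.  Concordant patients get an empty label.
    """
    extent_cols = [f"seg{s}_extent" for s in range(1, 18)]
    labels = []
    for row in patients.itertuples():
        wh_pos = row.whole_heart_tpd >= cutoff
        ts_pos = row.three_slice_tpd >= cutoff
        if wh_pos and not ts_pos:
            extents = np.array([getattr(row, c) for c in extent_cols])
            peak_segment = int(np.argmax(extents)) + 1
            labels.append(
                "apical-miss" if peak_segment in APICAL_SEGMENTS else "non-apical-miss"
            )
        elif ts_pos and not wh_pos:
            labels.append("reverse-discordant")
        else:
            labels.append("")
    return pd.Series(labels, index=patients.index, name="discordance")


def _sens_spec(df: pd.DataFrame, cutoff: float) -> dict:
    """Sensitivity/specificity pairs + McNemar p's; flags undefined arms."""
    cad = df[df.cad == 1]
    no_cad = df[df.cad == 0]
    out: dict = {
        "sensitivity_undefined": len(cad) == 0,
        "specificity_undefined": len(no_cad) == 0,
    }
    if len(cad):
        wh_pos = cad.whole_heart_tpd >= cutoff
        ts_pos = cad.three_slice_tpd >= cutoff
        out["sensitivity_whole_heart"] = 100.0 * float(wh_pos.mean())
        out["sensitivity_three_slice"] = 100.0 * float(ts_pos.mean())
        out["sensitivity_mcnemar_p"] = st.mcnemar_test(
            int((wh_pos & ~ts_pos).sum()), int((~wh_pos & ts_pos).sum())
        )
    else:
        out["sensitivity_whole_heart"] = None
        out["sensitivity_three_slice"] = None
        out["sensitivity_mcnemar_p"] = None
    if len(no_cad):
        wh_neg = no_cad.whole_heart_tpd < cutoff
        ts_neg = no_cad.three_slice_tpd < cutoff
        out["specificity_whole_heart"] = 100.0 * float(wh_neg.mean())
        out["specificity_three_slice"] = 100.0 * float(ts_neg.mean())
        out["specificity_mcnemar_p"] = st.mcnemar_test(
            int((wh_neg & ~ts_neg).sum()), int((~wh_neg & ts_neg).sum())
        )
    else:
        out["specificity_whole_heart"] = None
        out["specificity_three_slice"] = None
        out["specificity_mcnemar_p"] = None
    return out


def _discordant_summary(
    patients: pd.DataFrame, truth: pd.DataFrame | None, cutoff: float
) -> dict:
    """Breakdown of threshold discordance among CAD-positive patients."""
    cad = patients[patients.cad == 1]
    labels = classify_discordant_cases(cad, cutoff)
    n_wh_only = int((labels == "apical-miss").sum() + (labels == "non-apical-miss").sum())
    n_apical = int((labels == "apical-miss").sum())
    out = {
        "whole_heart_only": n_wh_only,
        "three_slice_only": int((labels == "reverse-discordant").sum()),
        "apical_miss": n_apical,
        "apical_miss_fraction": (100.0 * n_apical / n_wh_only) if n_wh_only else None,
    }
    if truth is not None and "apical_only" in truth.columns:
        merged = cad.merge(truth[["subject_id", "apical_only"]], on="subject_id")
        labels_m = classify_discordant_cases(merged, cutoff)
        wh_only = labels_m.isin(["apical-miss", "non-apical-miss"])
        prevalence = float(truth.apical_only.mean())
        among = float(merged.loc[wh_only, "apical_only"].mean()) if wh_only.any() else 0.0
        out["apical_only_prevalence"] = prevalence
        out["apical_only_among_missed"] = among
        out["apical_enrichment"] = (among / prevalence) if prevalence > 0 else None
    return out


def run_study(config: StudyConfig) -> StudyReport:
    """Run the full whole-heart vs 3-slice comparison; deterministic per seed."""
    model = config.build_model()
    seedseq = np.random.SeedSequence(config.seed)
    normal_seq, patient_seq = seedseq.spawn(2)

    # --- normal limits -----------------------------------------------------
    if config.normal_cohort_dir is not None:
        manifest_n, maps_n = load_cohort(Path(config.normal_cohort_dir) / "manifest.csv")
        by_gender = {
            g: [maps_n[s] for s in manifest_n[manifest_n.gender == g].subject_id]
            for g in GENDERS
        }
    else:
        rng = np.random.default_rng(normal_seq)
        by_gender = generate_normal_cohort(
            model, config.n_normals_per_gender, config.cohort.noise_sd, rng
        )
    limits: dict[str, NormalLimits] = {}
    for gender, gmaps in by_gender.items():
        normalized = [m if m.normalized else normalize_map(m) for m in gmaps]
        limits[gender] = fit_normal_limits(
            normalized, gender,
            threshold_mad=config.threshold_mad, mad_floor=config.mad_floor,
        )
    logger.info(
        "fitted normal limits: %s",
        {g: lim.n_subjects for g, lim in limits.items()},
    )

    # --- patient cohort ----------------------------------------------------
    truth: pd.DataFrame | None = None
    if config.patient_manifest is not None:
        manifest, maps = load_cohort(config.patient_manifest)
    else:
        cohort_cfg = dataclasses.replace(
            config.cohort, seed=int(patient_seq.generate_state(1)[0])
        )
        manifest, maps, truth = generate_cohort(cohort_cfg, model)
    logger.info("scoring %d patients", len(manifest))

    patients = score_cohort(
        manifest, maps, limits, model,
        three_slice_denominator=config.three_slice_denominator,
    )

    # --- statistics --------------------------------------------------------
    labels = patients.cad.to_numpy()
    both_classes = 0 < labels.sum() < len(labels)
    roc = (
        st.delong_paired_test(
            patients.whole_heart_tpd.to_numpy(),
            patients.three_slice_tpd.to_numpy(),
            labels,
        )
        if both_classes
        else None
    )
    cut_wh = (
        st.optimal_cutoff(patients.whole_heart_tpd.to_numpy(), labels)
        if both_classes
        else None
    )
    cut_ts = (
        st.optimal_cutoff(patients.three_slice_tpd.to_numpy(), labels)
        if both_classes
        else None
    )
    ss = _sens_spec(patients, config.tpd_cutoff)

    cad = patients[patients.cad == 1]
    agreement = (
        st.agreement_report(
            cad.whole_heart_tpd.to_numpy(),
            cad.three_slice_tpd.to_numpy(),
            threshold=config.tpd_cutoff,
        )
        if len(cad) >= 3
        else None
    )
    discordant = _discordant_summary(patients, truth, config.tpd_cutoff)

    report = StudyReport(
        n_patients=len(patients),
        n_cad=int(labels.sum()),
        n_no_cad=int(len(labels) - labels.sum()),
        tpd_cutoff=config.tpd_cutoff,
        roc=roc,
        optimal_cutoff_whole_heart=cut_wh,
        optimal_cutoff_three_slice=cut_ts,
        agreement=agreement,
        discordant=discordant,
        patients=patients,
        **ss,
    )

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.to_json() + "\n")
        patients.to_csv(out / "patients.csv", index=False, lineterminator="\n")
        for gender, lim in limits.items():
            save_limits(lim, out)
        logger.info("wrote report to %s", out)
    return report
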