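# perfcov

Whole-heart versus 3-slice myocardial perfusion coverage analysis on
left-ventricular polar maps.

Nuclear perfusion imaging covers the whole left ventricle; conventional
3-slice CMR perfusion covers only basal, mid-ventricular and apical
short-axis slices. `perfcov` quantifies what that coverage difference does
to automated ischemia scoring:

* **Polar maps & 17-segment model** — ring x sector uptake grids with the
  standard 6 basal / 6 mid / 4 apical / apex-cap segment partition, area
  weights, count normalization, and a plain-text file format
  (`perfcov.polarmap`).
* **Normal limits** — gender-matched per-pixel mean and mean absolute
  deviation (MAD) fitted from a defect-free cohort; pixels ≥ 3.0 MAD below
  the normal mean (≈ 2.5 SD) are abnormal (`perfcov.normal_limits`).
* **TPD scoring** — total perfusion deficit, the area-weighted integral of
  hypoperfusion severity over abnormal pixels (0% = normal, 100% = no
  uptake), both whole-heart and restricted to a 6-ring 3-slice coverage
  mask (two consecutive rings centered in each of the apical, mid, and
  basal zones; the apex cap is never covered) (`perfcov.tpd`).
* **Synthetic cohorts** — reproducible normal and patient cohorts with a
  configurable no-disease / 1- / 2- / 3-vessel / branch-only mixture,
  contiguous territory defects, and apex-only LAD defects that whole-heart
  scoring sees but 3-slice scoring misses (`perfcov.synthcohort`).
* **Paired statistics** — Mann-Whitney AUC with DeLong's paired test,
  Youden-index cutoff selection, exact/asymptotic McNemar tests,
  Bland-Altman agreement, OLS regression with intercept CI, and 2x2
  threshold concordance (`perfcov.stats`).
* **Pipeline** — one call (or CLI command) runs limits fitting, cohort
  scoring, the full comparison, and the discordant-case breakdown
  ("mainly apical" = maximal segment extent in segments 13–17)
  (`perfcov.pipeline`).

## CLI

```bash
perfcov run --seed 1 --out results/study            # full synthetic study
perfcov run --seed 1 --out results/study --figures  # + ROC/BA/regression PNGs

# or stage by stage:
perfcov simulate --seed 1 --n-patients 651 --out results/cohort
perfcov limits   --seed 1 --out results/limits
perfcov score    --manifest results/cohort/manifest.csv \
                 --limits-dir results/limits --out results/patients.csv
perfcov compare  --scores results/patients.csv --out results/comparison.json
```

`run` writes `report.json` (AUCs with DeLong p, sensitivity/specificity
with McNemar p at the 3% TPD cutoff, concordance, regression, Bland-Altman,
discordance breakdown), `patients.csv` (per-patient TPD pairs + segment
extents), and the fitted limits. All stages are deterministic per `--seed`.
A YAML config (`--config`) can override any `StudyConfig`/`CohortConfig`
field; flags win over the config file.

To analyze real data instead of synthetic cohorts, point
`StudyConfig.patient_manifest` at a cohort manifest CSV
(`subject_id,gender,lad,lcx,rca,branch_only,path`, flags meaning ≥70%
stenosis) whose `path` column references polar-map text files.

## Python API sketch

```python
from perfcov import StudyConfig, run_study

report = run_study(StudyConfig(seed=1))
print(report.roc.auc_a, report.roc.auc_b, report.roc.delong_p)
print(report.agreement.bias, report.discordant["apical_miss_fraction"])
```
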