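"""Optional study figures (requires matplotlib).

ROC overlay, Bland-Altman, and scatter-with-regression plots from a
per-patient score table.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import stats as st


def _require_pyplot():
    try:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover
        raise ImportError("figure output requires matplotlib (pip install perfcov[plots])") from exc
    return plt


def _roc_points(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(-scores, kind="stable")
    tps = np.cumsum(labels[order] == 1)
    fps = np.cumsum(labels[order] == 0)
    tpr = np.concatenate([[0], tps / max(tps[-1], 1)])
    fpr = np.concatenate([[0], fps / max(fps[-1], 1)])
    return fpr, tpr


def plot_roc_overlay(patients: pd.DataFrame, path: str | Path) -> None:
    plt = _require_pyplot()
    labels = patients.cad.to_numpy()
    fig, ax = plt.subplots(figsize=(5, 5))
    for col, name in (
        ("whole_heart_tpd", "whole-heart TPD"),
        ("three_slice_tpd", "3-slice TPD"),
    ):
        scores = patients[col].to_numpy()
        fpr, tpr = _roc_points(scores, labels)
        auc = st.roc_auc(scores, labels)
        ax.plot(fpr, tpr, label=f"{name} (AUC {auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_bland_altman(patients: pd.DataFrame, path: str | Path) -> None:
    plt = _require_pyplot()
    cad = patients[patients.cad == 1]
    a = cad.whole_heart_tpd.to_numpy()
    b = cad.three_slice_tpd.to_numpy()
    ba = st.bland_altman(a, b)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter((a + b) / 2, b - a, s=12, alpha=0.6)
    for y, style in ((ba["bias"], "-"), (ba["loa_low"], "--"), (ba["loa_high"], "--")):
        ax.axhline(y, color="tab:red", linestyle=style, lw=1)
    ax.set_xlabel("mean TPD (%)")
    ax.set_ylabel("3-slice - whole-heart TPD (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_regression(patients: pd.DataFrame, path: str | Path) -> None:
    plt = _require_pyplot()
    cad = patients[patients.cad == 1]
    x = cad.three_slice_tpd.to_numpy()
    y = cad.whole_heart_tpd.to_numpy()
    reg = st.linreg_with_ci(x, y)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(x, y, s=12, alpha=0.6)
    xs = np.linspace(0, max(x.max(), 1), 50)
    ax.plot(xs, reg["intercept"] + reg["slope"] * xs, "tab:red",
            label=f"y = {reg['slope']:.2f}x + {reg['intercept']:.2f} (R² {reg['r_squared']:.2f})")
    ax.set_xlabel("3-slice TPD (%)")
    ax.set_ylabel("whole-heart TPD (%)")
    ax.legend(loc="upper left")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def save_study_figures(patients: pd.DataFrame, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    plot_roc_overlay(patients, out_dir / "roc_overlay.png")
    plot_bland_altman(patients, out_dir / "bland_altman.png")
    plot_regression(patients, out_dir / "regression.png")
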