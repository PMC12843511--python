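"""End-to-end desk-scale studies composed from the pipeline stages.

These workflows run the full chain -- synthetic acquisition, segmentation,
morphometrics, leave-one-experiment-out splitting, training, evaluation --
at sizes a workstation handles in minutes (default study: 3 experiments x
24 wells x 36 loops at 96-px frames; the acquisition geometry otherwise
matches the full design).  They back the package's headline readouts:
early-loop fate-signal recovery against a shuffled-label baseline, and the
over-time growth of inter-organoid morphological distance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score

from .heterogeneity import (fit_pc_space, inter_organoid_distance_curve,
                            intra_organoid_change, project_table)
from .morphometrics import compute_morphometrics
from .partitioning import make_loeo_splits
from .prediction import train_feature_classifier
from .synthetic_acquisition import AcquisitionConfig, FateSpec, simulate_study

__all__ = ["desk_config", "signal_recovery_study", "heterogeneity_trend"]


def desk_config(seed: int, n_experiments: int = 3, wells_per_plate: int = 24,
                duration_h: float = 18.0, frame_px: int = 96) -> AcquisitionConfig:
    """The desk-scale acquisition: 36 loops at 30-min intervals, 96-px frames."""
    return AcquisitionConfig(n_experiments=n_experiments,
                             wells_per_plate=wells_per_plate,
                             duration_h=duration_h, interval_min=30.0,
                             frame_px=frame_px, seed=seed, exclusion_prob=0.0)


def _organoid_labels(wells, task: str) -> pd.Series:
    attr = {"rpe_emergence": "rpe_present", "lens_emergence": "lens_present",
            "rpe_class": "rpe_class", "lens_class": "lens_class"}[task]
    return pd.Series({(w.experiment_id, w.well_id): int(getattr(w.outcome, attr))
                      for w in wells})


def _shuffle_labels(labels: pd.Series, seed: int) -> pd.Series:
    rng = np.random.default_rng([seed, 97])
    keys = sorted(labels.index)
    perm = rng.permutation(len(keys))
    return pd.Series({keys[i]: labels.loc[keys[j]]
                      for i, j in enumerate(perm)})


def signal_recovery_study(seed: int, signal_strength: float,
                          task: str = "rpe_emergence",
                          early_frac: float = 0.25,
                          model=None) -> dict:
    """Early-loop outcome recovery vs a shuffled-label baseline.

    Runs the full pipeline on the desk-scale study with the given latent-cue
    strength, trains the feature classifier and its shuffled-label twin on
    every leave-one-experiment-out fold, and scores both on the held-out
    test experiment over the *early* loops (the first ``early_frac`` of the
    series, before any structure is rendered).  The baseline twin is always
    scored against the true labels.

    Returns per-fold early-loop weighted F1 for model and baseline plus the
    gap and the baseline's standard error over folds.
    """
    cfg = desk_config(seed)
    fate = FateSpec(signal_strength=signal_strength)
    wells = simulate_study(cfg, fate)
    table = compute_morphometrics(wells)
    labels = _organoid_labels(wells, task)
    shuffled = _shuffle_labels(labels, seed)
    model = model if model is not None else LogisticRegression(max_iter=2000)

    early_cut = int(np.ceil(early_frac * cfg.n_loops))
    organoids = table[["experiment_id", "well_id"]].drop_duplicates()
    model_f1, baseline_f1 = [], []
    for split in make_loeo_splits(organoids, seed=seed):
        run = train_feature_classifier(table, labels, split, model, task=task)
        base = train_feature_classifier(table, shuffled, split, model,
                                        task=task, model_id="baseline")
        model_f1.append(_early_f1(run.predictions, labels, early_cut))
        baseline_f1.append(_early_f1(base.predictions, labels, early_cut))
    model_f1 = np.asarray(model_f1)
    baseline_f1 = np.asarray(baseline_f1)
    sem = (baseline_f1.std(ddof=1) / np.sqrt(len(baseline_f1))
           if len(baseline_f1) > 1 else 0.0)
    return dict(model_f1=model_f1, baseline_f1=baseline_f1,
                gap=float(model_f1.mean() - baseline_f1.mean()),
                baseline_sem=float(sem), early_loops=early_cut,
                n_rows=len(table))


def _early_f1(predictions: pd.DataFrame, true_labels: pd.Series,
              early_cut: int) -> float:
    rows = predictions[(predictions["subset"] == "test")
                       & (predictions["loop"] < early_cut)].copy()
    rows["y_true"] = [true_labels.loc[k] for k in
                      zip(rows["experiment_id"], rows["well_id"])]
    scores = [f1_score(g["y_true"], g["y_pred"], average="weighted",
                       zero_division=0) for _, g in rows.groupby("loop")]
    return float(np.mean(scores))


def heterogeneity_trend(seed: int, n_experiments: int = 1,
                        wells_per_plate: int = 24) -> dict:
    """Inter- and intra-organoid PC-distance curves on the default generator.

    Returns the per-loop mean pairwise inter-organoid distance, the
    winsorised consecutive-loop change curve, and their Spearman rank
    correlations against loop index.
    """
    cfg = desk_config(seed, n_experiments=n_experiments,
                      wells_per_plate=wells_per_plate)
    wells = simulate_study(cfg, FateSpec())
    table = compute_morphometrics(wells)
    space = fit_pc_space(table)
    projected = project_table(table, space)
    inter = inter_organoid_distance_curve(projected)
    intra = intra_organoid_change(projected)
    rho_inter = float(spearmanr(inter["loop"],
                                inter["mean_pairwise_distance"]).statistic)
    rho_intra = float(spearmanr(intra["loop"], intra["mean_change"]).statistic)
    return dict(inter_curve=inter, intra_curve=intra,
                spearman_inter=rho_inter, spearman_intra=rho_intra)
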