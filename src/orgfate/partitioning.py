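"""Data partitioning and annotation sampling.

Implements the leave-one-experiment-out (LOEO) cross-validation design --
each biological replicate experiment serves once as the held-out test set,
with an organoid-grouped 90/10 train/validation split of the remaining
experiments -- plus the two-annotator ground-truth consensus rule (seeded
coin flip on disagreement) and the balanced expert-panel subset sampler
(six annotators, loops binned into six equal timeframes, one image per
available well-timeframe per annotator).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SplitPlan",
    "AnnotationTask",
    "make_loeo_splits",
    "consensus_ground_truth",
    "expert_subset_assignment",
]


@dataclass(frozen=True)
class SplitPlan:
    """One LOEO fold: a test experiment and organoid-level train/val sets."""

    fold_id: int
    test_experiment: str
    train_organoids: frozenset
    validation_organoids: frozenset
    seed: int

    def __post_init__(self) -> None:
        if self.train_organoids & self.validation_organoids:
            raise ValueError("train and validation organoids overlap")


@dataclass(frozen=True)
class AnnotationTask:
    annotator: int
    experiment_id: str
    well_id: str
    timeframe: int
    image_id: str


def _organoid_key(experiment_id: str, well_id: str) -> tuple:
    return (experiment_id, well_id)


def make_loeo_splits(organoids: pd.DataFrame, val_frac: float = 0.10,
                     seed: int = 0) -> list[SplitPlan]:
    """Leave-one-experiment-out folds with grouped 90/10 train/val splits.

    ``organoids`` needs columns ``experiment_id`` and ``well_id``, one row
    per organoid.  For each fold, all organoids of one experiment form the
    test set; the remaining organoids are split at the organoid level so
    every organoid's images land wholly in one partition.  The validation
    count is floor(val_frac * n), but at least 1.
    """
    df = organoids[["experiment_id", "well_id"]].drop_duplicates()
    experiments = sorted(df["experiment_id"].unique())
    if len(experiments) < 2:
        raise ValueError("need >= 2 experiments for leave-one-experiment-out")
    counts = df.groupby("experiment_id").size()
    if (counts == 0).any():
        raise ValueError("experiment with zero organoids")

    plans = []
    for fold_id, test_exp in enumerate(experiments):
        rest = df[df["experiment_id"] != test_exp]
        keys = sorted(_organoid_key(e, w) for e, w in
                      zip(rest["experiment_id"], rest["well_id"]))
        rng = np.random.default_rng([seed, fold_id])
        perm = rng.permutation(len(keys))
        n_val = max(1, int(np.floor(val_frac * len(keys))))
        val = frozenset(keys[i] for i in perm[:n_val])
        train = frozenset(keys[i] for i in perm[n_val:])
        plans.append(SplitPlan(fold_id=fold_id, test_experiment=test_exp,
                               train_organoids=train, validation_organoids=val,
                               seed=seed))
    return plans


def consensus_ground_truth(ann1: pd.Series, ann2: pd.Series,
                           seed: int = 0) -> pd.DataFrame:
    """Two-annotator consensus labels with a seeded fair coin on disagreement.

    Returns a frame indexed like the inputs with columns ``label``,
    ``high_confidence`` and ``chosen_annotator`` (0 = consensus), plus a
    ``disagreement_rate`` entry in ``attrs``.
    """
    if not ann1.index.equals(ann2.index):
        raise ValueError("annotators must label the same organoids")
    if ann1.isna().any() or ann2.isna().any():
        raise ValueError("missing label from an annotator")
    agree = (ann1 == ann2).to_numpy()
    rng = np.random.default_rng([seed, 17])
    flips = rng.integers(1, 3, size=len(ann1))  # 1 or 2, drawn for every row
    label = ann1.copy()
    chosen = np.zeros(len(ann1), dtype=int)
    for i, (ok, flip) in enumerate(zip(agree, flips)):
        if not ok:
            chosen[i] = flip
            label.iloc[i] = ann1.iloc[i] if flip == 1 else ann2.iloc[i]
    out = pd.DataFrame({"label": label, "high_confidence": agree,
                        "chosen_annotator": chosen}, index=ann1.index)
    out.attrs["disagreement_rate"] = float((~agree).mean())
    return out


def _stream(seed: int, *parts) -> np.random.Generator:
    """One RNG stream per key so adding wells never perturbs existing draws."""
    ints = [seed] + [zlib.crc32(str(p).encode()) for p in parts]
    return np.random.default_rng(ints)


def expert_subset_assignment(metadata: pd.DataFrame, n_annotators: int = 6,
                             n_timeframes: int = 6, seed: int = 0,
                             n_loops: int | None = None) -> pd.DataFrame:
    """Balanced expert-panel sampling over equal timeframes.

    ``metadata`` needs columns ``experiment_id``, ``well_id``, ``loop`` and
    ``image_id`` and should be restricted to middle-z-slice rows.  Loops are
    binned into ``n_timeframes`` equal bins (144 loops -> 6 bins of 24).
    For every (experiment, well, timeframe) with at least one image, each
    annotator receives exactly one image: sampled without replacement when
    the pool has >= n_annotators unique images, with replacement otherwise.
    Well-timeframes with no image are skipped for all annotators, keeping
    loads equal.  The result carries ``n_duplicate_assignments`` (images
    assigned to more than one annotator) in ``attrs``.
    """
    required = {"experiment_id", "well_id", "loop", "image_id"}
    if not required.issubset(metadata.columns):
        raise ValueError(f"metadata must have columns {sorted(required)}")
    if n_loops is None:
        n_loops = int(metadata["loop"].max()) + 1
    loops = metadata["loop"].to_numpy()
    if (loops < 0).any() or (loops >= n_loops).any():
        raise ValueError("loop index outside [0, n_loops)")
    timeframe = (loops * n_timeframes) // n_loops
    meta = metadata.assign(timeframe=timeframe)

    tasks: list[AnnotationTask] = []
    for (exp, well, tf), group in meta.groupby(
            ["experiment_id", "well_id", "timeframe"], sort=True):
        pool = sorted(group["image_id"].unique())
        rng = _stream(seed, exp, well, int(tf))
        replace = len(pool) < n_annotators
        picks = rng.choice(len(pool), size=n_annotators, replace=replace)
        for annotator, idx in enumerate(picks, start=1):
            tasks.append(AnnotationTask(annotator=annotator, experiment_id=exp,
                                        well_id=well, timeframe=int(tf),
                                        image_id=pool[int(idx)]))
    out = pd.DataFrame([t.__dict__ for t in tasks])
    _sanity_check_tasks(out, n_annotators)
    dup = out.groupby(["experiment_id", "well_id", "timeframe", "image_id"]).size()
    out.attrs["n_duplicate_assignments"] = int((dup - 1).clip(lower=0).sum())
    return out


def _sanity_check_tasks(tasks: pd.DataFrame, n_annotators: int) -> None:
    loads = tasks.groupby("annotator").size()
    if loads.nunique() != 1 or len(loads) != n_annotators:
        raise AssertionError("annotator loads are unbalanced")
    per_cell = tasks.groupby(["annotator", "experiment_id", "well_id",
                              "timeframe"]).size()
    if (per_cell != 1).any():
        raise AssertionError("annotator must get exactly one image per "
                             "available well-timeframe")
    per_ann = tasks.groupby(["annotator", "image_id"]).size()
    if (per_ann > 1).any():
        raise AssertionError("file repeated within an annotator")
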