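"""Outcome prediction harness: training, calibration, ensembling, evaluation.

Two model families predict an organoid's final outcome from a single early
frame: feature-based classifiers on the morphometrics table (any estimator
with fit/predict_proba; scaling is z-score then min-max to [0, 1], fitted
on training rows only) and image-based classifiers on mask-centred crops
(360 px crop -> 224 px resample -> organoid-only normalisation).  The
default image model is a small convolutional network implemented here in
numpy -- two 3x3 convolution blocks over an internally pooled input, Adam,
class-weighted cross-entropy, gradient-norm clipping at 1.0, learning rate
halved on validation-loss plateau (patience 7), best state kept by
validation loss.  Larger architectures plug in behind the same contract.

Evaluation: per-loop weighted F1 curves against ground truth, shuffled-label
baseline twins, temperature-scaling calibration, validation-F1-weighted
probability ensembling, bin-centre-distance stratified F1, and pairwise
statistical comparison of methods via per-experiment time-normalised
trapezoidal AUC, paired Wilcoxon signed-rank tests (Pratt zero handling)
and Holm-Bonferroni adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from skimage.transform import resize, resize_local_mean
from sklearn.base import clone
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import f1_score
from sklearn.preprocessing import MinMaxScaler, StandardScaler
from statsmodels.stats.multitest import multipletests

from .partitioning import SplitPlan

__all__ = [
    "PredictionRun",
    "FeatureScaler",
    "train_feature_classifier",
    "tune_classifier",
    "prepare_cnn_input",
    "TinyConvNet",
    "train_image_classifier",
    "class_weights",
    "temperature_calibrate",
    "ensemble_predict",
    "f1_over_time",
    "f1_by_bin_distance",
    "compare_classifiers",
    "morphology_cluster_targets",
]

META = ["experiment_id", "well_id", "loop"]


@dataclass
class PredictionRun:
    """Predictions of one model on one fold's validation and test rows."""

    task: str
    fold: SplitPlan
    model_id: str
    classes: np.ndarray
    predictions: pd.DataFrame  # META + subset + y_true + y_pred + p_<class>...
    best_validation_f1: float = float("nan")

    def proba(self, subset: str | None = None) -> np.ndarray:
        df = self.predictions
        if subset is not None:
            df = df[df["subset"] == subset]
        return df[[f"p_{c}" for c in self.classes]].to_numpy()


class FeatureScaler:
    """Z-score then min-max to [0, 1]; statistics from training rows only."""

    def __init__(self) -> None:
        self._std = StandardScaler()
        self._mm = MinMaxScaler()
        self.fitted_on_: int | None = None

    def fit(self, x: np.ndarray) -> "FeatureScaler":
        z = self._std.fit_transform(np.asarray(x, dtype=np.float64))
        self._mm.fit(z)
        self.fitted_on_ = x.shape[0]
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        return self._mm.transform(self._std.transform(np.asarray(x, np.float64)))


def _organoid_keys(df: pd.DataFrame) -> pd.Series:
    return list(zip(df["experiment_id"], df["well_id"]))


def _split_rows(features: pd.DataFrame, split: SplitPlan):
    keys = _organoid_keys(features)
    exp = features["experiment_id"]
    in_test = (exp == split.test_experiment).to_numpy()
    in_train = np.array([k in split.train_organoids for k in keys])
    in_val = np.array([k in split.validation_organoids for k in keys])
    return in_train & ~in_test, in_val & ~in_test, in_test


def train_feature_classifier(features: pd.DataFrame, labels: pd.Series,
                             split: SplitPlan, model,
                             model_id: str | None = None,
                             task: str = "outcome") -> PredictionRun:
    """Fit a tabular classifier on one LOEO fold and score val + test rows.

    ``features`` is a morphometrics table (META + feature columns); ``labels``
    is indexed by (experiment_id, well_id) organoid keys and gives the final
    outcome each row inherits.  Scalers are fitted strictly on training rows.
    """
    feat_cols = [c for c in features.columns if c not in META]
    tr, va, te = _split_rows(features, split)
    if not tr.any():
        raise ValueError("empty training partition")
    x = features[feat_cols].to_numpy(dtype=np.float64)
    y = np.array([labels.loc[k] for k in _organoid_keys(features)])
    if len(np.unique(y[tr])) < 2:
        raise ValueError("training fold contains a single class")

    scaler = FeatureScaler().fit(x[tr])
    est = clone(model)
    if "random_state" in est.get_params():
        est.set_params(random_state=0)
    est.fit(scaler.transform(x[tr]), y[tr])
    classes = np.asarray(est.classes_)

    eval_mask = va | te
    proba = est.predict_proba(scaler.transform(x[eval_mask]))
    pred = classes[np.argmax(proba, axis=1)]
    out = features.loc[eval_mask, META].copy().reset_index(drop=True)
    out["subset"] = np.where(te[eval_mask], "test", "validation")
    out["y_true"] = y[eval_mask]
    out["y_pred"] = pred
    for j, c in enumerate(classes):
        out[f"p_{c}"] = proba[:, j]
    run = PredictionRun(task=task, fold=split,
                        model_id=model_id or type(est).__name__,
                        classes=classes, predictions=out)
    run.best_validation_f1 = _best_per_loop_f1(out, "validation")
    return run


def _best_per_loop_f1(pred: pd.DataFrame, subset: str) -> float:
    rows = pred[pred["subset"] == subset]
    if rows.empty:
        return float("nan")
    best = 0.0
    for _, grp in rows.groupby("loop"):
        best = max(best, f1_score(grp["y_true"], grp["y_pred"],
                                  average="weighted", zero_division=0))
    return float(best)


def tune_classifier(model, param_distributions, x, y, seed: int = 0,
                    factor: int = 3, cv: int = 5, min_resources="smallest"):
    """Halving-style random hyperparameter search (reduction factor 3, 5-fold CV)."""
    from sklearn.experimental import enable_halving_search_cv  # noqa: F401
    from sklearn.model_selection import HalvingRandomSearchCV

    search = HalvingRandomSearchCV(
        clone(model), param_distributions, factor=factor, cv=cv,
        min_resources=min_resources, random_state=seed, scoring="f1_weighted")
    search.fit(x, y)
    return search


# ---------------------------------------------------------------------------
# image path

def prepare_cnn_input(image: np.ndarray, mask: np.ndarray,
                      crop_px: int = 360, out_px: int = 224):
    """Mask-centred crop -> resample -> [0, 1] -> organoid-only normalisation.

    A ``crop_px`` square window centred on the mask centroid is cut (padded
    with the background median where it exceeds the frame), resampled to
    ``out_px`` square, scaled to [0, 1], and the organoid pixels are
    standardised to zero mean / unit variance *in place*; background pixels
    keep their scaled values.  Returns (image, mask) at ``out_px`` square.
    """
    img = np.asarray(image, dtype=np.float64)
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    cy, cx = (np.mean(np.nonzero(mask), axis=1)).round().astype(int)
    half = crop_px // 2
    bg = float(np.median(img[~mask])) if (~mask).any() else float(img.min())
    canvas = np.full((crop_px, crop_px), bg)
    mcanvas = np.zeros((crop_px, crop_px), dtype=bool)
    y0, x0 = cy - half, cx - half
    sy0, sx0 = max(y0, 0), max(x0, 0)
    sy1 = min(y0 + crop_px, img.shape[0])
    sx1 = min(x0 + crop_px, img.shape[1])
    canvas[sy0 - y0:sy1 - y0, sx0 - x0:sx1 - x0] = img[sy0:sy1, sx0:sx1]
    mcanvas[sy0 - y0:sy1 - y0, sx0 - x0:sx1 - x0] = mask[sy0:sy1, sx0:sx1]

    small = resize_local_mean(canvas, (out_px, out_px))
    msmall = resize(mcanvas.astype(np.float64), (out_px, out_px), order=1,
                    anti_aliasing=False) >= 0.5
    lo, hi = small.min(), small.max()
    scaled = (small - lo) / (hi - lo) if hi > lo else np.zeros_like(small)
    out = scaled.copy()
    inside = scaled[msmall]
    if inside.size and inside.std() > 0:
        out[msmall] = (inside - inside.mean()) / inside.std()
    return out.astype(np.float32), msmall


def default_augment(img: np.ndarray, mask: np.ndarray | None,
                    rng: np.random.Generator):
    """Light training-time augmentation: D4 symmetries + intensity jitter."""
    k = int(rng.integers(0, 4))
    img = np.rot90(img, k)
    if mask is not None:
        mask = np.rot90(mask, k)
    if rng.random() < 0.5:
        img = img[:, ::-1]
        if mask is not None:
            mask = mask[:, ::-1]
    img = img * (1.0 + rng.normal(0.0, 0.05)) + rng.normal(0.0, 0.02)
    return (np.ascontiguousarray(img),
            None if mask is None else np.ascontiguousarray(mask))


def class_weights(y: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """Inverse-frequency loss weights: w_c = n / (K * n_c)."""
    y = np.asarray(y)
    n, k = len(y), len(classes)
    counts = np.array([(y == c).sum() for c in classes], dtype=np.float64)
    if (counts == 0).any():
        raise ValueError("class absent from training labels")
    return n / (k * counts)


class TinyConvNet:
    """Small convolutional classifier trained with numpy (CPU, minutes).

    Architecture: block-mean pool of the 224-px input to ``pool_px``, then
    conv3x3(c1)-ReLU-maxpool2, conv3x3(c2)-ReLU-global-average-pool, dense
    softmax head.  Training uses Adam with class-weighted cross-entropy,
    global gradient-norm clipping at ``clip``, learning rate halved when the
    validation loss plateaus (patience 7), and the best state by validation
    loss is restored after training.
    """

    def __init__(self, n_classes: int, pool_px: int = 28,
                 channels: tuple = (8, 16), seed: int = 0) -> None:
        self.n_classes = n_classes
        self.pool_px = pool_px
        rng = np.random.default_rng([seed, 29])
        c1, c2 = channels
        self.params = {
            "w1": rng.normal(0, np.sqrt(2.0 / 9), (c1, 1, 3, 3)),
            "b1": np.zeros(c1),
            "w2": rng.normal(0, np.sqrt(2.0 / (9 * c1)), (c2, c1, 3, 3)),
            "b2": np.zeros(c2),
            "wd": rng.normal(0, np.sqrt(1.0 / c2), (c2, n_classes)),
            "bd": np.zeros(n_classes),
        }
        self.history: list[dict] = []

    # -- primitive layers ---------------------------------------------------
    @staticmethod
    def _conv(x, w, b):
        n, c, h, wd = x.shape
        f = w.shape[0]
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
        col = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, h * wd, c * 9)
        out = col @ w.reshape(f, -1).T + b
        return out.reshape(n, h, wd, f).transpose(0, 3, 1, 2), col

    @staticmethod
    def _conv_backward(dout, col, w, x_shape):
        n, c, h, wd = x_shape
        f = w.shape[0]
        dflat = dout.transpose(0, 2, 3, 1).reshape(n, h * wd, f)
        dw = np.einsum("nif,nik->fk", dflat, col).reshape(w.shape)
        db = dflat.sum(axis=(0, 1))
        dcol = dflat @ w.reshape(f, -1)                       # (n, h*w, c*9)
        dxp = np.zeros((n, c, h + 2, wd + 2))
        dcol = dcol.reshape(n, h, wd, c, 3, 3)
        for di in range(3):
            for dj in range(3):
                dxp[:, :, di:di + h, dj:dj + wd] += dcol[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
        return dxp[:, :, 1:-1, 1:-1], dw, db

    def _forward(self, x):
        cache = {}
        a1, cache["col1"] = self._conv(x[:, None, :, :], self.params["w1"],
                                       self.params["b1"])
        cache["x_shape1"] = (x.shape[0], 1, x.shape[1], x.shape[2])
        r1 = np.maximum(a1, 0.0)
        cache["r1_pos"] = a1 > 0
        n, c, h, w = r1.shape
        blocks = r1.reshape(n, c, h // 2, 2, w // 2, 2)
        p1 = blocks.max(axis=(3, 5))
        cache["pool_mask"] = blocks == p1[:, :, :, None, :, None]
        cache["p1_shape"] = r1.shape
        a2, cache["col2"] = self._conv(p1, self.params["w2"], self.params["b2"])
        cache["x_shape2"] = p1.shape
        r2 = np.maximum(a2, 0.0)
        cache["r2_pos"] = a2 > 0
        g = r2.mean(axis=(2, 3))                              # global avg pool
        cache["r2_shape"] = r2.shape
        logits = g @ self.params["wd"] + self.params["bd"]
        cache["g"] = g
        return logits, cache

    def _backward(self, dlogits, cache):
        grads = {}
        grads["wd"] = cache["g"].T @ dlogits
        grads["bd"] = dlogits.sum(axis=0)
        dg = dlogits @ self.params["wd"].T
        n, c, h, w = cache["r2_shape"]
        dr2 = np.broadcast_to(dg[:, :, None, None], (n, c, h, w)) / (h * w)
        da2 = dr2 * cache["r2_pos"]
        dp1, grads["w2"], grads["b2"] = self._conv_backward(
            da2, cache["col2"], self.params["w2"], cache["x_shape2"])
        n, c, h, w = cache["p1_shape"]
        dblocks = cache["pool_mask"] * dp1[:, :, :, None, :, None]
        dr1 = dblocks.reshape(n, c, h, w)
        da1 = dr1 * cache["r1_pos"]
        _, grads["w1"], grads["b1"] = self._conv_backward(
            da1, cache["col1"], self.params["w1"], cache["x_shape1"])
        return grads

    # -- training -----------------------------------------------------------
    def _pool_input(self, x):
        x = np.asarray(x, dtype=np.float64)
        if x.shape[1:] == (self.pool_px, self.pool_px):
            return x
        return np.stack([resize_local_mean(im, (self.pool_px, self.pool_px))
                         for im in x])

    def _loss_grad(self, x, y_idx, weights):
        logits, cache = self._forward(x)
        logits = logits - logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        p /= p.sum(axis=1, keepdims=True)
        w = weights[y_idx]
        nll = -np.log(np.clip(p[np.arange(len(y_idx)), y_idx], 1e-12, None))
        loss = float((w * nll).sum() / w.sum())
        dlogits = p.copy()
        dlogits[np.arange(len(y_idx)), y_idx] -= 1.0
        dlogits *= (w / w.sum())[:, None]
        return loss, self._backward(dlogits, cache)

    def _eval_loss(self, x, y_idx, weights):
        logits = self.predict_logits(x, pooled=True)
        logits = logits - logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        p /= p.sum(axis=1, keepdims=True)
        w = weights[y_idx]
        nll = -np.log(np.clip(p[np.arange(len(y_idx)), y_idx], 1e-12, None))
        return float((w * nll).sum() / w.sum())

    def fit(self, x, y_idx, x_val, y_val_idx, weights, epochs: int = 30,
            lr: float = 5e-3, batch_size: int = 32, clip: float = 1.0,
            patience: int = 7, seed: int = 0, augment=None) -> "TinyConvNet":
        xp = self._pool_input(x)
        xvp = self._pool_input(x_val)
        weights = np.asarray(weights, dtype=np.float64)
        rng = np.random.default_rng([seed, 31])
        m = {k: np.zeros_like(v) for k, v in self.params.items()}
        v = {k: np.zeros_like(v) for k, v in self.params.items()}
        step = 0
        best_val = np.inf
        best_state = {k: p.copy() for k, p in self.params.items()}
        stale = 0
        for epoch in range(epochs):
            order = rng.permutation(len(xp))
            ep_loss = 0.0
            for start in range(0, len(order), batch_size):
                idx = order[start:start + batch_size]
                xb = xp[idx]
                if augment is not None:
                    xb = np.stack([augment(im, None, rng)[0] for im in xb])
                loss, grads = self._loss_grad(xb, y_idx[idx], weights)
                ep_loss += loss * len(idx)
                norm = np.sqrt(sum(float((g ** 2).sum()) for g in grads.values()))
                if norm > clip:
                    grads = {k: g * (clip / norm) for k, g in grads.items()}
                step += 1
                for k in self.params:
                    m[k] = 0.9 * m[k] + 0.1 * grads[k]
                    v[k] = 0.999 * v[k] + 0.001 * grads[k] ** 2
                    mh = m[k] / (1 - 0.9 ** step)
                    vh = v[k] / (1 - 0.999 ** step)
                    self.params[k] -= lr * mh / (np.sqrt(vh) + 1e-8)
            val_loss = self._eval_loss(xvp, y_val_idx, weights)
            self.history.append(dict(epoch=epoch, lr=lr,
                                     train_loss=ep_loss / len(xp),
                                     val_loss=val_loss))
            # relative improvement threshold, as plateau schedulers define it
            if not np.isfinite(best_val) or val_loss < best_val - 1e-4 * abs(best_val):
                best_val = val_loss
                best_state = {k: p.copy() for k, p in self.params.items()}
                stale = 0
            else:
                stale += 1
                if stale >= patience:
                    lr *= 0.5
                    stale = 0
        self.params = best_state
        return self

    def predict_logits(self, x, pooled: bool = False) -> np.ndarray:
        xp = x if pooled else self._pool_input(x)
        logits, _ = self._forward(np.asarray(xp, dtype=np.float64))
        return logits


def train_image_classifier(crops: np.ndarray, labels: np.ndarray,
                           organoid_keys, split: SplitPlan,
                           meta: pd.DataFrame, net: TinyConvNet | None = None,
                           task: str = "outcome", seed: int = 0,
                           epochs: int = 30, shuffle_labels: bool = False,
                           augment=default_augment) -> PredictionRun:
    """Train an image classifier on one fold; optional shuffled-label twin.

    ``crops`` is (N, H, W) from :func:`prepare_cnn_input`; ``meta`` aligns
    row-wise with META columns; ``organoid_keys`` holds (experiment, well)
    per row.  ``shuffle_labels=True`` trains the baseline twin: training
    labels are permuted at the organoid level before fitting.
    """
    keys = list(organoid_keys)
    tr = np.array([k in split.train_organoids for k in keys])
    va = np.array([k in split.validation_organoids for k in keys])
    te = np.array([meta.iloc[i]["experiment_id"] == split.test_experiment
                   for i in range(len(meta))])
    y = np.asarray(labels)
    classes = np.unique(y[tr])
    if len(classes) < 2:
        raise ValueError("single-class training fold")
    y_train = y.copy()
    if shuffle_labels:
        rng = np.random.default_rng([seed, 37])
        train_orgs = sorted(set(k for k, t in zip(keys, tr) if t))
        perm = rng.permutation(len(train_orgs))
        first = {o: y[[i for i, k in enumerate(keys) if k == o][0]]
                 for o in train_orgs}
        remap = {o: first[train_orgs[j]] for o, j in zip(train_orgs, perm)}
        for i, k in enumerate(keys):
            if tr[i]:
                y_train[i] = remap[k]
    cls_index = {c: j for j, c in enumerate(classes)}
    y_idx = np.array([cls_index.get(c, 0) for c in y_train])
    w = class_weights(y_train[tr], classes)

    net = net or TinyConvNet(n_classes=len(classes), seed=seed)
    net.fit(crops[tr], y_idx[tr], crops[va], y_idx[va], w,
            epochs=epochs, seed=seed, augment=augment)

    eval_mask = va | te
    logits = net.predict_logits(crops[eval_mask])
    proba = np.exp(logits - logits.max(axis=1, keepdims=True))
    proba /= proba.sum(axis=1, keepdims=True)
    pred = classes[np.argmax(proba, axis=1)]
    out = meta.loc[eval_mask, META].copy().reset_index(drop=True)
    out["subset"] = np.where(te[eval_mask], "test", "validation")
    out["y_true"] = y[eval_mask]
    out["y_pred"] = pred
    for j, c in enumerate(classes):
        out[f"p_{c}"] = proba[:, j]
    model_id = ("baseline:" if shuffle_labels else "") + "TinyConvNet"
    run = PredictionRun(task=task, fold=split, model_id=model_id,
                        classes=classes, predictions=out)
    run.best_validation_f1 = _best_per_loop_f1(out, "validation")
    run.net = net  # type: ignore[attr-defined]
    return run


# ---------------------------------------------------------------------------
# calibration / ensembling / evaluation

def temperature_calibrate(logits: np.ndarray, labels: np.ndarray) -> float:
    """Scalar temperature T > 0 minimising validation cross-entropy.

    Softmax probabilities are computed from logits / T; calibration is a
    monotone transform, so argmax predictions are unchanged.
    """
    logits = np.asarray(logits, dtype=np.float64)
    y = np.asarray(labels)
    if logits.ndim != 2:
        raise ValueError("logits must be (n, n_classes)")
    if np.allclose(logits, logits[:, :1]):
        raise ValueError("degenerate logits: all classes identical")

    def nll(log_t: float) -> float:
        z = logits / np.exp(log_t)
        z = z - z.max(axis=1, keepdims=True)
        logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
        return -float(logp[np.arange(len(y)), y].mean())

    res = optimize.minimize_scalar(nll, bounds=(-4.0, 4.0), method="bounded",
                                   options={"xatol": 1e-6})
    return float(np.exp(res.x))


def ensemble_predict(runs: list[PredictionRun],
                     weights: list[float] | None = None) -> PredictionRun:
    """Probability-weighted ensemble: w_i = best validation F1 of model i."""
    if not runs:
        raise ValueError("empty run list")
    classes = runs[0].classes
    for r in runs[1:]:
        if not np.array_equal(r.classes, classes):
            raise ValueError("mismatched class sets")
        if len(r.predictions) != len(runs[0].predictions):
            raise ValueError("runs must share evaluation rows")
    if weights is None:
        weights = [r.best_validation_f1 for r in runs]
    weights = np.asarray(weights, dtype=np.float64)
    if weights.sum() <= 0:
        raise ValueError("non-positive total ensemble weight")
    proba = sum(w * r.proba() for w, r in zip(weights, runs)) / weights.sum()
    out = runs[0].predictions[META + ["subset", "y_true"]].copy()
    out["y_pred"] = classes[np.argmax(proba, axis=1)]
    for j, c in enumerate(classes):
        out[f"p_{c}"] = proba[:, j]
    run = PredictionRun(task=runs[0].task, fold=runs[0].fold,
                        model_id="ensemble(" + ",".join(r.model_id for r in runs) + ")",
                        classes=classes, predictions=out)
    run.best_validation_f1 = _best_per_loop_f1(out, "validation")
    return run


def f1_over_time(run: PredictionRun, subset: str = "test") -> pd.DataFrame:
    """Weighted-F1 per loop on the named evaluation subset."""
    rows = run.predictions[run.predictions["subset"] == subset]
    recs = []
    for loop, grp in rows.groupby("loop"):
        recs.append(dict(loop=int(loop),
                         f1=float(f1_score(grp["y_true"], grp["y_pred"],
                                           average="weighted", zero_division=0)),
                         n=len(grp)))
    return pd.DataFrame(recs).sort_values("loop").reset_index(drop=True)


def f1_by_bin_distance(run: PredictionRun, distances: pd.Series,
                       n_strata: int = 5, subset: str = "test") -> pd.DataFrame:
    """Weighted F1 stratified by normalised bin-centre distance.

    ``distances`` maps (experiment_id, well_id) -> distance in [0, 1].
    Samples are cut into ``n_strata`` equal-width distance strata; empty
    strata are omitted.  Strata partition all scored samples.
    """
    rows = run.predictions[run.predictions["subset"] == subset].copy()
    d = np.array([distances.loc[k] for k in _organoid_keys(rows)])
    edges = np.linspace(0.0, 1.0, n_strata + 1)
    stratum = np.clip(np.searchsorted(edges, d, side="right") - 1, 0, n_strata - 1)
    rows["stratum"] = stratum
    recs = []
    for s, grp in rows.groupby("stratum"):
        recs.append(dict(
            stratum=int(s), d_lo=float(edges[s]), d_hi=float(edges[s + 1]),
            f1=float(f1_score(grp["y_true"], grp["y_pred"],
                              average="weighted", zero_division=0)),
            n=len(grp)))
    return pd.DataFrame(recs)


def normalized_auc(curve: pd.DataFrame) -> float:
    """Time-normalised trapezoidal AUC of an F1 curve (= time-averaged F1)."""
    loops = curve["loop"].to_numpy(dtype=np.float64)
    f1 = curve["f1"].to_numpy(dtype=np.float64)
    if len(loops) == 1:
        return float(f1[0])
    span = loops[-1] - loops[0]
    return float(np.trapezoid(f1, loops) / span)


def compare_classifiers(curves: dict, alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise method comparison via per-experiment AUCs.

    ``curves`` maps method -> {experiment -> F1-curve frame}.  Per-experiment
    time-normalised AUCs are compared for each method pair with a paired
    Wilcoxon signed-rank test (Pratt zero handling); Holm-Bonferroni adjusts
    across pairs.  Experiments missing from either method are dropped with a
    warning.
    """
    methods = sorted(curves)
    if len(methods) < 2:
        raise ValueError("need >= 2 methods")
    aucs = {m: {e: normalized_auc(c) for e, c in curves[m].items()}
            for m in methods}
    recs = []
    for i, a in enumerate(methods):
        for b in methods[i + 1:]:
            shared = sorted(set(aucs[a]) & set(aucs[b]))
            dropped = (set(aucs[a]) | set(aucs[b])) - set(shared)
            if dropped:
                warnings.warn(f"dropping unpaired experiments {sorted(dropped)} "
                              f"for {a} vs {b}", stacklevel=2)
            xa = np.array([aucs[a][e] for e in shared])
            xb = np.array([aucs[b][e] for e in shared])
            if np.allclose(xa, xb):
                p = 1.0
            else:
                p = float(stats.wilcoxon(xa, xb, zero_method="pratt").pvalue)
            recs.append(dict(method_a=a, method_b=b, n_experiments=len(shared),
                             mean_auc_a=float(xa.mean()), mean_auc_b=float(xb.mean()),
                             p_raw=p))
    table = pd.DataFrame(recs)
    reject, p_adj, _, _ = multipletests(table["p_raw"], alpha=alpha, method="holm")
    table["p_holm"] = p_adj
    table["significant"] = reject
    return table


def morphology_cluster_targets(final_features: pd.DataFrame,
                               n_components: int = 15, n_clusters: int = 4,
                               seed: int = 0) -> pd.Series:
    """Final-loop morphology clusters used as a 4-class prediction target.

    Features are z-scaled, projected to ``n_components`` principal
    components and k-means clustered (seeded, 10 restarts).  Returns labels
    indexed by (experiment_id, well_id).
    """
    feat_cols = [c for c in final_features.columns if c not in META]
    if len(final_features) < n_clusters:
        raise ValueError("fewer organoids than clusters")
    x = final_features[feat_cols].to_numpy(dtype=np.float64)
    keep = x.std(axis=0) > 0
    x = StandardScaler().fit_transform(x[:, keep])
    ncomp = min(n_components, x.shape[1], x.shape[0])
    pcs = PCA(n_components=ncomp, svd_solver="full").fit_transform(x)
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed).fit(pcs)
    idx = pd.MultiIndex.from_arrays(
        [final_features["experiment_id"], final_features["well_id"]])
    return pd.Series(km.labels_, index=idx, name="morphology_cluster")
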