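"""Attention-weighted deletion classifier and risk-feature selection.

The model scores each sample's binary deletion vector x (length m) as

    r = sum_j x_j * W_j * E_j          (an e-dimensional embedding sum)
    p = softmax(MLP(r))                (2 classes: cancer / non-cancer)

where W is a learned per-deletion scalar attention weight and E an m x e
embedding table.  After training with class-weighted binary cross-entropy,
deletions with strictly positive W are the cancer-risk-associated set.
The module also benchmarks the model against standard classifiers
(MLP, linear SVM, logistic regression, random forest) under stratified
k-fold cross-validation, and provides PCA projection and hierarchical
clustering of the selected deletions.

The network is small and tabular, so it is implemented directly in numpy
(forward pass, manual backprop, Adam); training is deterministic given the
seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)


@dataclass
class Hyperparams:
    embed_size: int = 32
    hidden: tuple[int, ...] = (64, 16)
    learning_rate: float = 1e-3
    epochs: int = 200
    batch_size: int = 32
    patience: int = 20          # early stopping on validation loss
    val_fraction: float = 0.1
    class_weighted: bool = True


@dataclass
class AttentionModel:
    W: np.ndarray                       # (m,) per-deletion attention weight
    E: np.ndarray                       # (m, e) embedding table
    layers: list[tuple[np.ndarray, np.ndarray]]   # [(weight, bias), ...]
    hyper: Hyperparams
    dsv_ids: list[str] = field(default_factory=list)
    history: dict = field(default_factory=dict)

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Class probabilities for rows of X; columns must match the model."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.W.shape[0]:
            raise ValueError(
                f"input has {X.shape[1]} deletions, model expects {self.W.shape[0]}"
            )
        probs, _ = _forward_pass(X, self.W, self.E, self.layers)
        return probs

    def predict_proba(self, X) -> np.ndarray:
        return self.forward(X)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


def _forward_pass(X, W, E, layers):
    """Returns (probabilities, cache for backprop)."""
    R = (X * W) @ E                      # n x e embedding sum
    acts = [R]
    h = R
    for k, (Wk, bk) in enumerate(layers):
        z = h @ Wk + bk
        h = z if k == len(layers) - 1 else np.maximum(z, 0.0)
        acts.append(h)
    probs = _softmax(acts[-1])
    return probs, (X, R, acts)


def _init_params(m: int, hyper: Hyperparams, rng: np.random.Generator):
    e = hyper.embed_size
    # W starts small-positive so "positive weight" is informative, not an
    # artifact of a symmetric initialisation; nothing constrains it after.
    W = rng.uniform(0.0, 0.1, size=m)
    E = rng.normal(0.0, 1.0 / np.sqrt(e), size=(m, e))
    sizes = (e, *hyper.hidden, 2)
    layers = []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        layers.append(
            (
                rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out)),
                np.zeros(fan_out),
            )
        )
    return W, E, layers


def _loss_and_grads(X, y, sw, W, E, layers):
    n = len(y)
    probs, (Xc, R, acts) = _forward_pass(X, W, E, layers)
    eps = 1e-12
    loss = -np.sum(sw * np.log(probs[np.arange(n), y] + eps)) / sw.sum()
    # backprop through softmax cross-entropy
    dz = probs.copy()
    dz[np.arange(n), y] -= 1.0
    dz *= (sw / sw.sum())[:, None]
    g_layers = [None] * len(layers)
    for k in range(len(layers) - 1, -1, -1):
        g_layers[k] = (acts[k].T @ dz, dz.sum(axis=0))
        if k > 0:
            dz = (dz @ layers[k][0].T) * (acts[k] > 0)
        else:
            dR = dz @ layers[0][0].T
    gW = ((dR @ E.T) * X).sum(axis=0)
    gE = (X * W).T @ dR
    return loss, probs, gW, gE, g_layers


def train_attention(
    carriers,
    labels,
    hyper: Hyperparams | None = None,
    seed: int = 0,
) -> AttentionModel:
    """Train the attention-weighted classifier with Adam on weighted
    cross-entropy.

    ``carriers`` is a :class:`~dsvpipe.preprocess.CarrierMatrix` or an
    (n x m) array; ``labels`` is 0/1 (1 = cancer) or a cohort-label vector.
    Class weights are inverse class frequencies.  Early stopping monitors a
    held-out validation split; the best-validation parameters are restored.
    """
    if hyper is None:
        hyper = Hyperparams()
    X, dsv_ids = _as_matrix(carriers)
    y = _as_labels(labels)
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    n, m = X.shape

    if hyper.class_weighted:
        freq = np.bincount(y, minlength=2) / n
        cw = 0.5 / freq
    else:
        cw = np.ones(2)
    perm = rng.permutation(n)
    n_val = max(1, int(round(hyper.val_fraction * n))) if hyper.val_fraction > 0 else 0
    val_idx, train_idx = perm[:n_val], perm[n_val:]

    W, E, layers = _init_params(m, hyper, rng)
    # Adam state
    params = [W, E] + [p for lay in layers for p in lay]
    ms = [np.zeros_like(p) for p in params]
    vs = [np.zeros_like(p) for p in params]
    b1, b2, eps, t = 0.9, 0.999, 1e-8, 0

    def val_loss():
        if n_val == 0:
            return np.nan
        probs, _ = _forward_pass(X[val_idx], W, E, layers)
        swv = cw[y[val_idx]]
        return float(
            -np.sum(swv * np.log(probs[np.arange(n_val), y[val_idx]] + 1e-12)) / swv.sum()
        )

    best = (np.inf, None)
    bad_epochs = 0
    train_hist, val_hist = [], []
    for epoch in range(hyper.epochs):
        order = rng.permutation(train_idx)
        ep_loss, n_batches = 0.0, 0
        for s in range(0, len(order), hyper.batch_size):
            idx = order[s : s + hyper.batch_size]
            loss, _, gW, gE, g_layers = _loss_and_grads(
                X[idx], y[idx], cw[y[idx]], W, E, layers
            )
            grads = [gW, gE] + [g for gl in g_layers for g in gl]
            t += 1
            for p, g, mm, vv in zip(params, grads, ms, vs):
                mm += (1 - b1) * (g - mm)
                vv += (1 - b2) * (g * g - vv)
                p -= hyper.learning_rate * (mm / (1 - b1**t)) / (
                    np.sqrt(vv / (1 - b2**t)) + eps
                )
            ep_loss += loss
            n_batches += 1
        train_hist.append(ep_loss / max(n_batches, 1))
        vl = val_loss()
        val_hist.append(vl)
        if n_val and vl < best[0] - 1e-6:
            best = (vl, [p.copy() for p in params])
            bad_epochs = 0
        elif n_val:
            bad_epochs += 1
            if bad_epochs >= hyper.patience:
                logger.info("early stopping at epoch %d", epoch)
                break
    if best[1] is not None:
        W, E = best[1][0], best[1][1]
        flat = best[1][2:]
        layers = [(flat[2 * k], flat[2 * k + 1]) for k in range(len(layers))]
    return AttentionModel(
        W=W,
        E=E,
        layers=layers,
        hyper=hyper,
        dsv_ids=dsv_ids,
        history={"train_loss": train_hist, "val_loss": val_hist},
    )


def select_positive_weight_dsvs(model: AttentionModel) -> list[str]:
    """Deletions with strictly positive attention weight, in column order."""
    ids = model.dsv_ids or [str(j) for j in range(len(model.W))]
    selected = [ids[j] for j in range(len(ids)) if model.W[j] > 0]
    if not selected:
        warnings.warn("no deletion has a positive attention weight")
    return selected


def _as_matrix(carriers) -> tuple[np.ndarray, list[str]]:
    if hasattr(carriers, "data") and isinstance(carriers.data, pd.DataFrame):
        return carriers.data.to_numpy(dtype=float), list(carriers.data.columns)
    X = np.asarray(carriers, dtype=float)
    return X, [str(j) for j in range(X.shape[1])]


def _as_labels(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "OU":
        return (arr == "cancer").astype(int)
    return arr.astype(int)


@dataclass
class CvReport:
    fold_metrics: pd.DataFrame    # model, fold, auc, sensitivity, specificity
    fold_assignments: np.ndarray
    seed: int

    @property
    def means(self) -> pd.DataFrame:
        return (
            self.fold_metrics.groupby("model")[["auc", "sensitivity", "specificity"]]
            .mean()
            .sort_index()
        )


DEFAULT_MODELS = ("attention", "mlp", "linear_svm", "logistic", "random_forest")


def _sklearn_model(name: str, seed: int):
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.linear_model import LogisticRegression
    from sklearn.neural_network import MLPClassifier
    from sklearn.svm import SVC

    if name == "mlp":
        return MLPClassifier(hidden_layer_sizes=(64, 16), max_iter=500, random_state=seed)
    if name == "linear_svm":
        return SVC(kernel="linear", random_state=seed)
    if name == "logistic":
        return LogisticRegression(max_iter=2000, random_state=seed)
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=200, random_state=seed)
    raise ValueError(f"unknown model {name!r}")


def crossvalidate(
    carriers,
    labels,
    models=DEFAULT_MODELS,
    k: int = 5,
    seed: int = 0,
    hyper: Hyperparams | None = None,
) -> CvReport:
    """Stratified k-fold benchmark: rank-based AUC plus sensitivity and
    specificity at the 0.5 probability cut-off ("cancer" positive)."""
    from sklearn.metrics import roc_auc_score
    from sklearn.model_selection import StratifiedKFold

    X, _ = _as_matrix(carriers)
    y = _as_labels(labels)
    if len(y) < k:
        raise ValueError("fewer samples than folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(y), dtype=int)
    rows = []
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        assignment[te] = fold
        if np.unique(y[tr]).size < 2 or np.unique(y[te]).size < 2:
            raise ValueError("a fold lost one of the classes")
        for name in models:
            if name == "attention":
                model = train_attention(X[tr], y[tr], hyper=hyper, seed=seed + fold)
                prob = model.forward(X[te])[:, 1]
            else:
                est = _sklearn_model(name, seed)
                est.fit(X[tr], y[tr])
                if hasattr(est, "predict_proba"):
                    prob = est.predict_proba(X[te])[:, 1]
                else:  # margin classifiers: squash the decision score
                    prob = 1 / (1 + np.exp(-est.decision_function(X[te])))
            pred = prob >= 0.5
            pos, neg = y[te] == 1, y[te] == 0
            rows.append(
                {
                    "model": name,
                    "fold": fold,
                    "auc": roc_auc_score(y[te], prob),
                    "sensitivity": float(pred[pos].mean()),
                    "specificity": float((~pred[neg]).mean()),
                }
            )
    return CvReport(fold_metrics=pd.DataFrame(rows), fold_assignments=assignment, seed=seed)


def pca_projection(carriers, n_components: int = 2) -> pd.DataFrame:
    """Project samples onto the top principal axes of the selected deletions."""
    from sklearn.decomposition import PCA

    X, _ = _as_matrix(carriers)
    if X.shape[1] < n_components:
        raise ValueError("need at least n_components deletions")
    if np.allclose(X.std(axis=0), 0):
        raise ValueError("zero-variance input: PCA undefined")
    pca = PCA(n_components=n_components)
    coords = pca.fit_transform(X)
    has_df = hasattr(carriers, "data") and isinstance(carriers.data, pd.DataFrame)
    index = carriers.data.index if has_df else pd.RangeIndex(len(X))
    return pd.DataFrame(
        coords, index=index, columns=[f"PC{i+1}" for i in range(n_components)]
    )


def cluster_dsvs(
    carriers,
    k: int = 2,
    metric: str = "jaccard",
    method: str = "average",
) -> tuple[np.ndarray, np.ndarray]:
    """Agglomerative clustering of deletion carrier profiles.

    Distances are computed between DSV columns (Jaccard on binary profiles
    by default), the dendrogram is cut at ``k`` clusters.  Returns
    (labels per DSV, scipy linkage matrix).
    """
    X, _ = _as_matrix(carriers)
    m = X.shape[1]
    if k > m:
        raise ValueError(f"k = {k} exceeds number of DSVs ({m})")
    if m == 1 or k == 1:
        return np.ones(m, dtype=int), np.empty((0, 4))
    profiles = X.T.astype(bool)
    with np.errstate(invalid="ignore"):
        d = pdist(profiles, metric=metric)
    d = np.nan_to_num(d, nan=0.0)  # all-zero profiles are mutually identical
    Z = linkage(d, method=method)
    return fcluster(Z, t=k, criterion="maxclust"), Z
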