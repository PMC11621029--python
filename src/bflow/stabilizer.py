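"""Classifier-in-the-middle cluster stabilization.

A supervised classifier is trained to imitate a reference clustering so
that new recordings receive consistent cluster labels without re-running
(or even having access to) the original clustering.  The default model
is a single-hidden-layer network (1,024 rectified-linear units, dropout
0.4, softmax output) trained for 30 epochs with batch size 512 under
categorical cross-entropy and RMSProp.  A multinomial-logistic variant
is provided for fast runs; the contract is simply "a probabilistic
multi-class model that transfers the clustering with high per-cluster
precision and recall", which is assessed by recording-level
cross-validation (no frame of a validation recording ever enters its
fold's training set).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import precision_recall_fscore_support
from sklearn.utils.validation import check_is_fitted

from bflow.clustering import BehaviorKMeans
from bflow.features import TemporalFeatureMatrix
from bflow.flow import LabelSequence


class LogisticClusterClassifier(BaseEstimator, ClassifierMixin):
    """Multinomial logistic regression over standardized feature rows.

    Lightweight stand-in with the same probabilistic contract as the
    network classifier; preferred when training time matters more than
    decision-boundary flexibility.
    """

    def __init__(self, C: float = 1.0, max_iter: int = 200,
                 random_state: int | None = 0):
        self.C = C
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y):
        self.model_ = LogisticRegression(
            C=self.C, max_iter=self.max_iter, random_state=self.random_state)
        self.model_.fit(np.asarray(X, dtype=float), np.asarray(y))
        self.classes_ = self.model_.classes_
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict_proba(np.asarray(X, dtype=float))

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]  # ties -> lowest class


class ClusterImitationClassifier(BaseEstimator, ClassifierMixin):
    """Single-hidden-layer softmax network imitating a reference clustering.

    Architecture: ``input -> dense(hidden_width, relu) -> dropout ->
    dense(n classes, softmax)``.  Trained with mini-batch RMSProp on
    categorical cross-entropy; data are shuffled each epoch.  Training is
    fully seeded and prediction is a pure function of (weights, input).

    Parameters
    ----------
    hidden_width : units in the hidden layer (default 1,024).
    dropout_rate : hidden-activation dropout during training (default 0.4).
    epochs, batch_size : training schedule (defaults 30 and 512).
    learning_rate, rho, eps : RMSProp parameters.
    random_state : seed for weight init, shuffling and dropout masks.
    """

    def __init__(self, hidden_width: int = 1024, dropout_rate: float = 0.4,
                 epochs: int = 30, batch_size: int = 512,
                 learning_rate: float = 1e-3, rho: float = 0.9,
                 eps: float = 1e-7, random_state: int | None = 0):
        self.hidden_width = hidden_width
        self.dropout_rate = dropout_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.rho = rho
        self.eps = eps
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        yi = np.searchsorted(self.classes_, y)
        n, d = X.shape
        k = len(self.classes_)
        rng = np.random.default_rng(self.random_state)

        # Glorot-uniform initialization
        lim1 = np.sqrt(6.0 / (d + self.hidden_width))
        W1 = rng.uniform(-lim1, lim1, size=(d, self.hidden_width))
        b1 = np.zeros(self.hidden_width)
        lim2 = np.sqrt(6.0 / (self.hidden_width + k))
        W2 = rng.uniform(-lim2, lim2, size=(self.hidden_width, k))
        b2 = np.zeros(k)
        cache = [np.zeros_like(p) for p in (W1, b1, W2, b2)]
        keep = 1.0 - self.dropout_rate
        self.loss_history_ = []

        for _ in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                xb, yb = X[idx], yi[idx]
                h_pre = xb @ W1 + b1
                h = np.maximum(h_pre, 0.0)
                if keep < 1.0:
                    mask = (rng.random(h.shape) < keep) / keep  # inverted dropout
                    h = h * mask
                logits = h @ W2 + b2
                logits -= logits.max(axis=1, keepdims=True)
                expl = np.exp(logits)
                proba = expl / expl.sum(axis=1, keepdims=True)
                m = len(idx)
                epoch_loss -= np.log(proba[np.arange(m), yb] + 1e-12).sum()

                dlogits = proba
                dlogits[np.arange(m), yb] -= 1.0
                dlogits /= m
                gW2 = h.T @ dlogits
                gb2 = dlogits.sum(axis=0)
                dh = dlogits @ W2.T
                if keep < 1.0:
                    dh = dh * mask
                dh[h_pre <= 0] = 0.0
                gW1 = xb.T @ dh
                gb1 = dh.sum(axis=0)

                params = (W1, b1, W2, b2)
                grads = (gW1, gb1, gW2, gb2)
                for p, g, c in zip(params, grads, cache):
                    c *= self.rho
                    c += (1 - self.rho) * g * g
                    p -= self.learning_rate * g / (np.sqrt(c) + self.eps)
            self.loss_history_.append(epoch_loss / n)

        self.W1_, self.b1_, self.W2_, self.b2_ = W1, b1, W2, b2
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "W1_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.W1_.shape[0]:
            raise ValueError(
                f"X has {X.shape[1]} columns, model expects {self.W1_.shape[0]}")
        h = np.maximum(X @ self.W1_ + self.b1_, 0.0)
        logits = h @ self.W2_ + self.b2_
        logits -= logits.max(axis=1, keepdims=True)
        expl = np.exp(logits)
        return expl / expl.sum(axis=1, keepdims=True)

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]  # ties -> lowest class


def train_classifier(X, labels, classifier=None, seed: int = 0):
    """Fit a cluster-imitation classifier on standardized feature rows."""
    if classifier is None:
        classifier = ClusterImitationClassifier(random_state=seed)
    else:
        classifier = clone(classifier)
        if "random_state" in classifier.get_params():
            classifier.set_params(random_state=seed)
    return classifier.fit(np.asarray(X, dtype=float), np.asarray(labels))


def apply_classifier(classifier, standardizer: BehaviorKMeans | None,
                     X: TemporalFeatureMatrix) -> LabelSequence:
    """Label every frame of an expanded matrix with the trained classifier.

    ``standardizer`` is the fitted clustering model whose persisted
    column statistics project the rows into training space; pass ``None``
    if rows are already standardized.
    """
    rows = X.values if standardizer is None else standardizer.transform(X.values)
    labels = classifier.predict(rows)
    return LabelSequence(recording_id=X.recording_id, labels=labels,
                         alphabet=classifier.classes_, fps=X.fps,
                         frame_offset=X.frame_offset)


@dataclass
class CVReport:
    """Per-fold, per-cluster precision/recall/F1 with fold manifests."""

    table: pd.DataFrame  # columns: fold, cluster, precision, recall, f1, support
    fold_membership: dict[int, list[str]] = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        """Fold-averaged and pooled-minimum metrics per cluster."""
        mean = self.table.groupby("cluster")[["precision", "recall", "f1"]].mean()
        mn = self.table.groupby("cluster")[["precision", "recall", "f1"]].min()
        return mean.join(mn, lsuffix="_mean", rsuffix="_min")

    @property
    def min_precision_recall(self) -> float:
        return float(self.table[["precision", "recall"]].min().min())


def crossvalidate(recordings: list[tuple[str, np.ndarray, np.ndarray]],
                  folds: int = 10, seed: int = 0,
                  classifier=None) -> CVReport:
    """Recording-level k-fold cross-validation of the cluster classifier.

    ``recordings`` is a list of ``(recording_id, X, labels)``.  Recordings
    (never frames) are shuffled and split sequentially into folds, so no
    frame of a validation recording appears in its fold's training set.
    Per-cluster precision, recall and F1 are computed on the pooled
    held-out frames of each fold; clusters absent from a fold's
    validation frames get recall (and precision, if never predicted) of 0
    with support 0.
    """
    if folds > len(recordings):
        raise ValueError(f"{folds} folds but only {len(recordings)} recordings")
    if classifier is None:
        classifier = LogisticClusterClassifier()
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(recordings))
    fold_ids = np.array_split(order, folds)
    classes = np.unique(np.concatenate([r[2] for r in recordings]))

    rows = []
    membership: dict[int, list[str]] = {}
    for f, val_idx in enumerate(fold_ids):
        val = [recordings[i] for i in val_idx]
        train = [recordings[i] for i in order if i not in set(val_idx)]
        membership[f] = [r[0] for r in val]
        Xtr = np.vstack([r[1] for r in train])
        ytr = np.concatenate([r[2] for r in train])
        model = train_classifier(Xtr, ytr, classifier=classifier, seed=seed + f)
        Xva = np.vstack([r[1] for r in val])
        yva = np.concatenate([r[2] for r in val])
        pred = model.predict(Xva)
        prec, rec, f1, support = precision_recall_fscore_support(
            yva, pred, labels=classes, zero_division=0)
        for c, p_, r_, f_, s_ in zip(classes, prec, rec, f1, support):
            rows.append({"fold": f, "cluster": c, "precision": p_,
                         "recall": r_, "f1": f_, "support": int(s_)})
    return CVReport(table=pd.DataFrame(rows), fold_membership=membership)
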