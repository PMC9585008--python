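"""Window-level predictors: multi-feature logistic regression and a parallel
one-dimensional convolutional network.

Both models map one 12-h window of IBW-normalized urine output (plus, for
the logistic model, simple covariates) to the probability that an oliguric
AKI stage 2/3 episode begins within the following 24 h.

They are written as scikit-learn estimators (``fit`` / ``predict_proba``,
``get_params``, fitted attributes with a trailing underscore) so they
compose with sklearn pipelines and model selection.  The convolutional
network is a deliberately small numpy implementation — three parallel valid
convolution branches with kernel sizes 3, 6 and 12 over the 12-value urine
sequence, ReLU, global max pooling, one hidden dense layer and a sigmoid
output (~1,000 parameters) — trained with Adam on class-weighted binary
cross-entropy, with early stopping on a patient-level validation split so
no patient contributes windows to both sides of the split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "FEATURE_NAMES",
    "AGE_ORDINALS",
    "extract_features",
    "feature_matrix",
    "LogisticWindowClassifier",
    "ConvNetSpec",
    "ParallelConv1DClassifier",
    "fit_logistic",
    "predict_logistic",
    "fit_convnet",
    "predict_convnet",
]

AGE_ORDINALS = {"18-39": 0, "40-49": 1, "50-59": 2, "60-69": 3, "70-79": 4, "80+": 5}

FEATURE_NAMES = (
    "uo_min",
    "uo_max",
    "uo_mean",
    "uo_last",
    "uo_slope",
    "hours_below_0.5",
    "hours_below_0.3",
    "scr_now",
    "scr_ratio",
    "age_ordinal",
    "sex_male",
)

_WINDOW_H = 12
_SLOPE_X = np.arange(_WINDOW_H, dtype=float)
_SLOPE_X_C = _SLOPE_X - _SLOPE_X.mean()
_SLOPE_DEN = float((_SLOPE_X_C**2).sum())


def extract_features(
    uo_window: np.ndarray,
    scr_now: float,
    scr_ratio: float,
    age_group: str | int,
    sex: str,
) -> np.ndarray:
    """Deterministic summary features of one fully observed 12-h window."""
    w = np.asarray(uo_window, dtype=float)
    if w.shape != (_WINDOW_H,) or np.isnan(w).any():
        raise ValueError("uo_window must be 12 fully observed values")
    for name, v in (("scr_now", scr_now), ("scr_ratio", scr_ratio)):
        if v is None or np.isnan(v):
            raise ValueError(f"missing covariate {name}")
    age = AGE_ORDINALS[age_group] if isinstance(age_group, str) else int(age_group)
    slope = float((_SLOPE_X_C * (w - w.mean())).sum() / _SLOPE_DEN)
    return np.array(
        [
            w.min(),
            w.max(),
            w.mean(),
            w[-1],
            slope,
            float((w < 0.5).sum()),
            float((w < 0.3).sum()),
            float(scr_now),
            float(scr_ratio),
            float(age),
            1.0 if sex == "male" else 0.0,
        ]
    )


def feature_matrix(windows: pd.DataFrame) -> np.ndarray:
    """Vectorized :func:`extract_features` over a windows table."""
    uo = windows[[f"uo_h{i + 1}" for i in range(_WINDOW_H)]].to_numpy(dtype=float)
    if np.isnan(uo).any():
        raise ValueError("windows contain missing urine bins")
    slope = (uo - uo.mean(axis=1, keepdims=True)) @ _SLOPE_X_C / _SLOPE_DEN
    age = windows["age_group"].map(AGE_ORDINALS).to_numpy(dtype=float)
    return np.column_stack(
        [
            uo.min(axis=1),
            uo.max(axis=1),
            uo.mean(axis=1),
            uo[:, -1],
            slope,
            (uo < 0.5).sum(axis=1),
            (uo < 0.3).sum(axis=1),
            windows["scr_now"].to_numpy(dtype=float),
            windows["scr_ratio"].to_numpy(dtype=float),
            age,
            (windows["sex"] == "male").to_numpy(dtype=float),
        ]
    )


def uo_matrix(windows: pd.DataFrame) -> np.ndarray:
    """The raw 12-value urine sequences of a windows table."""
    return windows[[f"uo_h{i + 1}" for i in range(_WINDOW_H)]].to_numpy(dtype=float)


class LogisticWindowClassifier(BaseEstimator, ClassifierMixin):
    """Maximum-likelihood logistic regression on standardized features.

    Features are centered and scaled with constants learned at fit time and
    reapplied identically at predict time.  The fit is unpenalized; if the
    optimizer fails to converge (the symptom of perfect separation) the model
    is refit with a vanishingly small L2 penalty and a warning is issued.

    Attributes set by :meth:`fit`: ``coef_`` (per-feature coefficients on the
    standardized scale), ``intercept_``, ``scaler_``, ``classes_``.
    """

    def __init__(self, max_iter: int = 100, tol: float = 1e-8):
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError(f"need both classes present, got classes {classes}")
        self.scaler_ = StandardScaler().fit(X)
        Z = self.scaler_.transform(X)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            lr = LogisticRegression(
                C=np.inf, solver="lbfgs", max_iter=self.max_iter, tol=self.tol
            ).fit(Z, y)
            # perfect separation: training scores of the classes don't overlap
            # (the unpenalized MLE diverges there)
            z = lr.decision_function(Z)
            separated = z[y == lr.classes_[1]].min() > z[y == lr.classes_[0]].max()
        if separated or any(issubclass(w.category, ConvergenceWarning) for w in caught):
            warnings.warn(
                "unpenalized fit did not converge (possible perfect "
                "separation); refitting with a tiny L2 penalty",
                stacklevel=2,
            )
            lr = LogisticRegression(
                C=1e6, solver="lbfgs", max_iter=10 * self.max_iter
            ).fit(Z, y)
        self.lr_ = lr
        self.classes_ = lr.classes_
        self.coef_ = lr.coef_[0]
        self.intercept_ = float(lr.intercept_[0])
        return self

    def decision_function(self, X):
        check_is_fitted(self, "lr_")
        return self.lr_.decision_function(self.scaler_.transform(np.asarray(X, float)))

    def predict_proba(self, X):
        check_is_fitted(self, "lr_")
        return self.lr_.predict_proba(self.scaler_.transform(np.asarray(X, float)))

    def predict(self, X):
        check_is_fitted(self, "lr_")
        return self.lr_.predict(self.scaler_.transform(np.asarray(X, float)))

    def score_windows(self, X) -> np.ndarray:
        """Event probability per window (column of the positive class)."""
        return self.predict_proba(X)[:, 1]


@dataclass(frozen=True)
class ConvNetSpec:
    """Architecture and training configuration of the convolutional model."""

    kernel_sizes: tuple[int, ...] = (3, 6, 12)
    n_filters: int = 8
    hidden: int = 16
    epochs: int = 60
    batch_size: int = 128
    learning_rate: float = 3e-3
    class_weighted: bool = True
    val_fraction: float = 0.15
    patience: int = 8
    min_positive_windows: int = 50
    seed: int = 0


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.params = params
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + eps)


class ParallelConv1DClassifier(BaseEstimator, ClassifierMixin):
    """Parallel-branch 1D convolutional classifier over 12-h urine windows.

    Each branch convolves the standardized sequence with ``n_filters``
    kernels of one size (valid padding), applies ReLU and global max
    pooling; pooled branch outputs are concatenated and passed through one
    hidden ReLU layer to a sigmoid unit.  Training minimizes class-weighted
    binary cross-entropy with Adam; early stopping monitors AUC on a
    patient-level validation split (pass ``groups`` to :meth:`fit`).  All
    randomness flows from ``spec.seed``: a fixed seed reproduces weights and
    predictions bit for bit on one CPU thread.
    """

    def __init__(self, spec: ConvNetSpec | None = None):
        self.spec = spec

    # -- forward / backward ------------------------------------------------
    def _forward(self, X, params, want_cache=False):
        ks = self._spec().kernel_sizes
        idx_per_branch, pooled, caches = [], [], []
        pi = 0
        for k in ks:
            W, b = params[pi], params[pi + 1]
            pi += 2
            cols = np.lib.stride_tricks.sliding_window_view(X, k, axis=1)  # (n,L,k)
            z = cols @ W.T + b  # (n,L,F)
            a = np.maximum(z, 0.0)
            am = a.argmax(axis=1)  # (n,F)
            p = np.take_along_axis(a, am[:, None, :], axis=1)[:, 0, :]
            pooled.append(p)
            caches.append((cols, z, am))
        h0 = np.concatenate(pooled, axis=1)  # (n, B*F)
        W1, b1, w2, b2 = params[pi], params[pi + 1], params[pi + 2], params[pi + 3]
        z1 = h0 @ W1.T + b1
        h1 = np.maximum(z1, 0.0)
        logit = h1 @ w2 + b2[0]
        if not want_cache:
            return logit
        return logit, (caches, h0, z1, h1)

    def _backward(self, X, dlogit, cache, params):
        spec = self._spec()
        ks = spec.kernel_sizes
        F = spec.n_filters
        caches, h0, z1, h1 = cache
        pi = 2 * len(ks)
        W1, w2 = params[pi], params[pi + 2]
        grads = [None] * len(params)
        grads[pi + 3] = np.array([dlogit.sum()])
        grads[pi + 2] = h1.T @ dlogit
        dh1 = np.outer(dlogit, w2)
        dz1 = dh1 * (z1 > 0)
        grads[pi] = dz1.T @ h0
        grads[pi + 1] = dz1.sum(axis=0)
        dh0 = dz1 @ W1
        for bi, k in enumerate(ks):
            cols, z, am = caches[bi]
            dp = dh0[:, bi * F : (bi + 1) * F]  # (n,F)
            dz = np.zeros_like(z)
            np.put_along_axis(dz, am[:, None, :], dp[:, None, :], axis=1)
            dz *= z > 0
            grads[2 * bi] = np.einsum("nlf,nlk->fk", dz, cols)
            grads[2 * bi + 1] = dz.sum(axis=(0, 1))
        return grads

    def _spec(self) -> ConvNetSpec:
        return self.spec if self.spec is not None else ConvNetSpec()

    # -- estimator API -----------------------------------------------------
    def fit(self, X, y, groups=None):
        spec = self._spec()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != _WINDOW_H:
            raise ValueError(f"X must be (n, {_WINDOW_H}) urine windows")
        if np.unique(y).size != 2:
            raise ValueError("need both classes present")
        n_pos = int(y.sum())
        if n_pos < spec.min_positive_windows:
            raise ValueError(
                f"only {n_pos} positive windows (< {spec.min_positive_windows}); "
                "increase the cohort size or prevalence"
            )
        rng = np.random.Generator(np.random.PCG64(spec.seed))

        # patient-level validation split for early stopping
        if groups is None:
            groups = np.arange(len(y))
        groups = np.asarray(groups)
        uniq = np.unique(groups)
        val_groups = set(
            rng.choice(uniq, size=max(1, int(round(spec.val_fraction * uniq.size))), replace=False)
        )
        val_mask = np.array([g in val_groups for g in groups])
        if y[~val_mask].sum() == 0 or y[val_mask].sum() == 0:
            # degenerate split: fall back to stratified window-level split
            pos_idx = np.flatnonzero(y == 1)
            neg_idx = np.flatnonzero(y == 0)
            val_mask = np.zeros(len(y), bool)
            val_mask[rng.choice(pos_idx, max(1, len(pos_idx) // 6), replace=False)] = True
            val_mask[rng.choice(neg_idx, max(1, len(neg_idx) // 6), replace=False)] = True
        Xtr, ytr = X[~val_mask], y[~val_mask]
        Xva, yva = X[val_mask], y[val_mask]

        self.center_ = Xtr.mean(axis=0)
        self.scale_ = Xtr.std(axis=0)
        self.scale_[self.scale_ == 0] = 1.0
        Ztr = (Xtr - self.center_) / self.scale_
        Zva = (Xva - self.center_) / self.scale_

        if spec.class_weighted:
            w_pos = len(ytr) / (2.0 * ytr.sum())
            w_neg = len(ytr) / (2.0 * (len(ytr) - ytr.sum()))
        else:
            w_pos = w_neg = 1.0
        wtr = np.where(ytr == 1, w_pos, w_neg)

        F, H = spec.n_filters, spec.hidden
        params: list[np.ndarray] = []
        for k in spec.kernel_sizes:
            params += [rng.normal(0, np.sqrt(2.0 / k), size=(F, k)), np.zeros(F)]
        nb = len(spec.kernel_sizes) * F
        params += [
            rng.normal(0, np.sqrt(2.0 / nb), size=(H, nb)),
            np.zeros(H),
            rng.normal(0, np.sqrt(1.0 / H), size=H),
            np.zeros(1),
        ]
        opt = _Adam(params, spec.learning_rate)

        best_auc, best_params, since_best = -np.inf, None, 0
        history = []
        n = len(ytr)
        for epoch in range(spec.epochs):
            order = rng.permutation(n)
            for start in range(0, n, spec.batch_size):
                sel = order[start : start + spec.batch_size]
                xb, yb, wb = Ztr[sel], ytr[sel], wtr[sel]
                logit, cache = self._forward(xb, params, want_cache=True)
                p = _sigmoid(logit)
                dlogit = wb * (p - yb) / wb.sum()
                grads = self._backward(xb, dlogit, cache, params)
                opt.step(grads)
            val_auc = roc_auc_score(yva, _sigmoid(self._forward(Zva, params)))
            history.append(val_auc)
            if val_auc > best_auc + 1e-4:
                best_auc, since_best = val_auc, 0
                best_params = [p.copy() for p in params]
            else:
                since_best += 1
                if since_best >= spec.patience:
                    break
        self.params_ = best_params if best_params is not None else params
        self.val_auc_ = float(best_auc)
        self.history_ = history
        self.classes_ = np.array([0, 1])
        self.n_parameters_ = int(sum(p.size for p in self.params_))
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "params_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != _WINDOW_H:
            raise ValueError(f"windows must have length {_WINDOW_H}")
        Z = (X - self.center_) / self.scale_
        p1 = _sigmoid(self._forward(Z, self.params_))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def score_windows(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1]


# -- thin functional wrappers over the estimators ---------------------------


def fit_logistic(features, labels, **kwargs) -> LogisticWindowClassifier:
    return LogisticWindowClassifier(**kwargs).fit(features, labels)


def predict_logistic(model: LogisticWindowClassifier, features) -> np.ndarray:
    return model.score_windows(features)


def fit_convnet(windows, labels, spec: ConvNetSpec | None = None, groups=None):
    return ParallelConv1DClassifier(spec).fit(windows, labels, groups=groups)


def predict_convnet(model: ParallelConv1DClassifier, windows) -> np.ndarray:
    return model.score_windows(windows)


# -- portable persistence ----------------------------------------------------

_FORMAT_VERSION = 1


def save_model(model, path) -> None:
    """Serialize a fitted model (weights, spec, standardization) to JSON."""
    import json
    from dataclasses import asdict
    from pathlib import Path

    if isinstance(model, LogisticWindowClassifier):
        payload = {
            "format_version": _FORMAT_VERSION,
            "kind": "logistic",
            "coef": model.coef_.tolist(),
            "intercept": model.intercept_,
            "center": model.scaler_.mean_.tolist(),
            "scale": model.scaler_.scale_.tolist(),
            "feature_names": list(FEATURE_NAMES),
        }
    elif isinstance(model, ParallelConv1DClassifier):
        payload = {
            "format_version": _FORMAT_VERSION,
            "kind": "convnet",
            "spec": asdict(model._spec()),
            "params": [p.tolist() for p in model.params_],
            "center": model.center_.tolist(),
            "scale": model.scale_.tolist(),
        }
    else:
        raise TypeError(f"cannot serialize {type(model).__name__}")
    Path(path).write_text(json.dumps(payload))


def load_model(path):
    """Inverse of :func:`save_model`; returns a ready-to-predict estimator."""
    import json
    from pathlib import Path

    payload = json.loads(Path(path).read_text())
    if payload.get("format_version") != _FORMAT_VERSION:
        raise ValueError(f"unsupported model file version: {payload.get('format_version')}")
    if payload["kind"] == "logistic":
        model = LogisticWindowClassifier()
        lr = LogisticRegression()
        lr.classes_ = np.array([0, 1])
        lr.coef_ = np.array([payload["coef"]])
        lr.intercept_ = np.array([payload["intercept"]])
        scaler = StandardScaler()
        scaler.mean_ = np.array(payload["center"])
        scaler.scale_ = np.array(payload["scale"])
        scaler.var_ = scaler.scale_**2
        scaler.n_features_in_ = scaler.mean_.size
        model.lr_, model.scaler_ = lr, scaler
        model.coef_ = lr.coef_[0]
        model.intercept_ = float(lr.intercept_[0])
        model.classes_ = lr.classes_
        return model
    if payload["kind"] == "convnet":
        spec = ConvNetSpec(**{**payload["spec"], "kernel_sizes": tuple(payload["spec"]["kernel_sizes"])})
        model = ParallelConv1DClassifier(spec)
        model.params_ = [np.array(p) for p in payload["params"]]
        model.center_ = np.array(payload["center"])
        model.scale_ = np.array(payload["scale"])
        model.classes_ = np.array([0, 1])
        return model
    raise ValueError(f"unknown model kind {payload['kind']!r}")
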