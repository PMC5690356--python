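"""Single-hidden-layer neural network for 3-class PA intensity prediction.

The architecture is fixed by the study design: 15 percentile-feature inputs,
one hidden layer of 5 logistic-sigmoid units, 3 softmax outputs (SB, LPA,
MVPA), biases on both layers and no skip-layer connections — 16×5 + 6×3 = 98
free weights.  The network outputs a probability in [0, 1] for each intensity
category; the predicted category is the one with probability closest to one
(argmax), with exact ties broken toward the lower-ordinal class.

Training minimizes multinomial cross-entropy with L2 weight decay by
full-batch L-BFGS from seeded uniform(−0.5, 0.5) initial weights, with
independent seeded restarts keeping the lowest final loss.  Features are
z-score standardized inside the model using training-fold statistics only.

The estimator follows the scikit-learn protocol (``fit`` / ``predict`` /
``predict_proba``, ``get_params`` / ``set_params``, trailing-underscore
fitted attributes) and composes with sklearn pipelines and model selection;
all network math is implemented here.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import scipy.optimize
from sklearn.base import BaseEstimator, ClassifierMixin

from ._rng import substream_seed
from .annotation import IntensityCategory
from .errors import DegenerateTrainingError
from .features import FEATURE_COLUMNS

logger = logging.getLogger(__name__)

N_CLASSES = 3
CLASS_ORDER = (IntensityCategory.SB, IntensityCategory.LPA, IntensityCategory.MVPA)

MODEL_FORMAT_VERSION = 1


def _sigmoid(z: np.ndarray) -> np.ndarray:
    # numerically stable logistic
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


class IntensityNet(BaseEstimator, ClassifierMixin):
    """15-5-3 neural network classifier for PA intensity categories.

    Parameters
    ----------
    hidden_units : int, default 5
        Number of logistic hidden units (the study architecture uses 5).
    alpha : float, default 1e-3
        L2 weight-decay coefficient on non-bias weights.
    restarts : int, default 5
        Independent seeded weight initializations; the fit with the lowest
        final training loss is kept.
    max_iter : int, default 500
        Maximum L-BFGS iterations per restart.
    tol : float, default 1e-8
        Relative-loss-change convergence tolerance.
    random_state : int, default 0
        Root seed; restart seeds are derived deterministically from it.

    Attributes
    ----------
    coef_hidden_ : ndarray of shape (n_features + 1, hidden_units)
        Input→hidden weights, bias in row 0.
    coef_output_ : ndarray of shape (hidden_units + 1, 3)
        Hidden→output weights, bias in row 0.
    scaler_mean_, scaler_scale_ : ndarray of shape (n_features,)
        Training-data standardization parameters (zero-variance features get
        scale 1 with a logged warning).
    classes_ : ndarray
        Always ``[SB, LPA, MVPA]`` as integers 0, 1, 2.
    loss_ : float
        Final (best-restart) regularized training loss.
    train_meta_ : dict
        Seed, restarts, per-restart losses, chosen restart.
    """

    def __init__(
        self,
        hidden_units: int = 5,
        alpha: float = 1e-3,
        restarts: int = 5,
        max_iter: int = 500,
        tol: float = 1e-8,
        random_state: int = 0,
    ):
        self.hidden_units = hidden_units
        self.alpha = alpha
        self.restarts = restarts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    # -- parameter packing ---------------------------------------------------

    def _shapes(self, n_features: int) -> tuple[tuple[int, int], tuple[int, int]]:
        return (n_features + 1, self.hidden_units), (self.hidden_units + 1, N_CLASSES)

    def _unpack(self, w: np.ndarray, n_features: int):
        s1, s2 = self._shapes(n_features)
        k = s1[0] * s1[1]
        return w[:k].reshape(s1), w[k:].reshape(s2)

    @property
    def n_parameters_(self) -> int:
        """Total free weights, e.g. (15+1)×5 + (5+1)×3 = 98."""
        return self.coef_hidden_.size + self.coef_output_.size

    # -- loss and gradient ---------------------------------------------------

    def _loss_grad(self, w, X, Y):
        """Regularized cross-entropy and its gradient (flat), full batch."""
        n, d = X.shape
        W1, W2 = self._unpack(w, d)
        Xb = np.hstack([np.ones((n, 1)), X])
        H = _sigmoid(Xb @ W1)
        Hb = np.hstack([np.ones((n, 1)), H])
        P = _softmax(Hb @ W2)
        eps = 1e-12
        ce = -np.sum(Y * np.log(P + eps)) / n
        reg = 0.5 * self.alpha * (np.sum(W1[1:] ** 2) + np.sum(W2[1:] ** 2))
        dZ2 = (P - Y) / n
        gW2 = Hb.T @ dZ2
        gW2[1:] += self.alpha * W2[1:]
        dH = dZ2 @ W2[1:].T
        dZ1 = dH * H * (1.0 - H)
        gW1 = Xb.T @ dZ1
        gW1[1:] += self.alpha * W1[1:]
        return ce + reg, np.concatenate([gW1.ravel(), gW2.ravel()])

    # -- estimator API -------------------------------------------------------

    def fit(self, X, y):
        """Fit the network on feature rows X and intensity labels y.

        y must contain only SB/LPA/MVPA (0/1/2) — never TRANSITION — and at
        least two distinct classes.
        """
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        y = np.asarray([int(v) for v in np.asarray(y).ravel()])
        if len(y) != X.shape[0]:
            raise ValueError("X and y length mismatch")
        if np.any((y < 0) | (y > 2)):
            raise ValueError(
                "labels must be SB/LPA/MVPA (0/1/2); TRANSITION windows must "
                "be stripped before training"
            )
        present = np.unique(y)
        if present.size < 2:
            raise DegenerateTrainingError(
                f"training set contains a single class ({present.tolist()}); "
                "need at least two of SB/LPA/MVPA"
            )
        self.classes_ = np.array([int(c) for c in CLASS_ORDER])
        self.n_features_in_ = X.shape[1]

        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        zero = scale == 0
        if np.any(zero):
            logger.warning(
                "%d feature(s) have zero training variance; using scale 1",
                int(zero.sum()),
            )
            scale = np.where(zero, 1.0, scale)
        self.scaler_mean_, self.scaler_scale_ = mean, scale
        Xs = (X - mean) / scale
        Y = np.zeros((len(y), N_CLASSES))
        Y[np.arange(len(y)), y] = 1.0

        s1, s2 = self._shapes(X.shape[1])
        n_w = s1[0] * s1[1] + s2[0] * s2[1]
        best = None
        losses = []
        for r in range(self.restarts):
            rng = np.random.default_rng(
                substream_seed(self.random_state, "init", r)
            )
            w0 = rng.uniform(-0.5, 0.5, size=n_w)
            res = scipy.optimize.minimize(
                self._loss_grad,
                w0,
                args=(Xs, Y),
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": self.max_iter, "ftol": self.tol,
                         "gtol": 1e-10},
            )
            losses.append(float(res.fun))
            if best is None or res.fun < best[1]:
                best = (res.x, float(res.fun), r)
        w, loss, chosen = best
        self.coef_hidden_, self.coef_output_ = (
            a.copy() for a in self._unpack(w, X.shape[1])
        )
        self.loss_ = loss
        self.train_meta_ = {
            "seed": int(self.random_state),
            "restarts": int(self.restarts),
            "restart_losses": losses,
            "chosen_restart": int(chosen),
            "final_loss": loss,
        }
        self.feature_names_in_ = np.asarray(FEATURE_COLUMNS) if X.shape[1] == 15 else None
        return self

    def _check_fitted_X(self, X) -> np.ndarray:
        if not hasattr(self, "coef_hidden_"):
            raise RuntimeError("IntensityNet is not fitted")
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected shape (n, {self.n_features_in_}), got {X.shape}"
            )
        return X

    def predict_proba(self, X) -> np.ndarray:
        """Per-window probabilities of (SB, LPA, MVPA); each row sums to 1."""
        X = self._check_fitted_X(X)
        Xs = (X - self.scaler_mean_) / self.scaler_scale_
        Xb = np.hstack([np.ones((len(Xs), 1)), Xs])
        H = _sigmoid(Xb @ self.coef_hidden_)
        Hb = np.hstack([np.ones((len(H), 1)), H])
        return _softmax(Hb @ self.coef_output_)

    def predict(self, X) -> np.ndarray:
        """Predicted intensity category per window: the class whose
        probability is closest to one; exact ties go to the lower ordinal."""
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]

    # -- persistence ---------------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> dict:
        """Serialize the fitted model (weights, standardizer, ordering) to a
        versioned JSON document; fully reproducible prediction from file."""
        if not hasattr(self, "coef_hidden_"):
            raise RuntimeError("cannot serialize an unfitted model")
        doc = {
            "format_version": MODEL_FORMAT_VERSION,
            "architecture": {
                "n_inputs": int(self.n_features_in_),
                "hidden_units": int(self.hidden_units),
                "n_outputs": N_CLASSES,
                "hidden_activation": "logistic",
                "output_activation": "softmax",
                "skip_layer_connections": False,
            },
            "class_order": [c.name for c in CLASS_ORDER],
            "feature_order": list(FEATURE_COLUMNS)
            if self.n_features_in_ == 15
            else [f"f{i}" for i in range(self.n_features_in_)],
            "hyperparameters": self.get_params(),
            "standardizer": {
                "mean": self.scaler_mean_.tolist(),
                "scale": self.scaler_scale_.tolist(),
            },
            "weights": {
                "hidden": self.coef_hidden_.tolist(),
                "output": self.coef_output_.tolist(),
            },
            "train_meta": self.train_meta_,
        }
        if path is not None:
            Path(path).write_text(json.dumps(doc, indent=1))
        return doc

    @classmethod
    def from_json(cls, source: str | Path | dict) -> "IntensityNet":
        if not isinstance(source, dict):
            source = json.loads(Path(source).read_text())
        if source.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"unsupported model format_version {source.get('format_version')}"
            )
        model = cls(**source["hyperparameters"])
        model.coef_hidden_ = np.asarray(source["weights"]["hidden"], dtype=float)
        model.coef_output_ = np.asarray(source["weights"]["output"], dtype=float)
        model.scaler_mean_ = np.asarray(source["standardizer"]["mean"], dtype=float)
        model.scaler_scale_ = np.asarray(source["standardizer"]["scale"], dtype=float)
        model.n_features_in_ = model.coef_hidden_.shape[0] - 1
        model.classes_ = np.array([int(c) for c in CLASS_ORDER])
        model.loss_ = source["train_meta"].get("final_loss", float("nan"))
        model.train_meta_ = source["train_meta"]
        return model


# ---------------------------------------------------------------------------
# thin functional wrappers
# ---------------------------------------------------------------------------

def train_ann(features, labels, hyper: dict | None = None) -> IntensityNet:
    """Train an :class:`IntensityNet` (functional wrapper over ``fit``)."""
    return IntensityNet(**(hyper or {})).fit(features, labels)


def predict_proba(model: IntensityNet, features) -> np.ndarray:
    return model.predict_proba(features)


def predict_category(model: IntensityNet, features) -> list[IntensityCategory]:
    return [IntensityCategory(int(c)) for c in model.predict(features)]
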