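"""Component and consensus regressors.

Two epsilon-SVRs with RBF kernels K(u, v) = exp(-gamma * ||u - v||^2):

* the signature component maps the flattened distance-pattern signature plus
  the pharmacophore change vector to ddG (kcal/mol);
* the consensus regressor maps the 13-feature vector — signature-component
  prediction, calibrated substitution score, 3-state secondary-structure
  one-hot, 8-component pharmacophore change — to the final ddG.

The dual problem is solved by libsvm's sequential-minimal-optimisation
solver (via scikit-learn), which honours the box and equality constraints
of the standard formulation; this module owns feature standardisation
(fitted on training data only), the cross-validated hyperparameter search
and a JSON-serialisable kernel-expansion form of the fitted model, so a
saved model reproduces its predictions without any pickled state.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from sklearn.model_selection import KFold
from sklearn.svm import SVR

from .config import SvrConfig
from .environment import SS_CLASSES
from .pharmacophore import N_CLASSES

FEATURE_WIDTH = 2 + len(SS_CLASSES) + N_CLASSES  # 13


class NotFittedError(RuntimeError):
    pass


@dataclass
class SVRModel:
    """Epsilon-SVR with RBF kernel plus per-feature standardisation."""
    C: float = 10.0
    gamma: float = 0.1
    epsilon: float = 0.1
    mean_: np.ndarray | None = field(default=None, repr=False)
    scale_: np.ndarray | None = field(default=None, repr=False)
    support_vectors_: np.ndarray | None = field(default=None, repr=False)
    dual_coef_: np.ndarray | None = field(default=None, repr=False)  # alpha - alpha*
    intercept_: float | None = None

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0 or self.epsilon <= 0:
            raise ValueError("C, gamma and epsilon must all be positive")

    @property
    def is_fitted(self) -> bool:
        return self.support_vectors_ is not None

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean_) / self.scale_

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SVRModel":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        self.mean_ = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
        self.scale_ = scale
        Z = self._standardize(X)
        svr = SVR(kernel="rbf", C=self.C, gamma=self.gamma, epsilon=self.epsilon,
                  tol=1e-4)
        svr.fit(Z, y)
        self.support_vectors_ = svr.support_vectors_.copy()
        self.dual_coef_ = svr.dual_coef_.ravel().copy()
        self.intercept_ = float(svr.intercept_[0])
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not self.is_fitted:
            raise NotFittedError("SVR model has not been fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Z = self._standardize(X)
        d2 = ((Z[:, None, :] - self.support_vectors_[None, :, :]) ** 2).sum(axis=2)
        K = np.exp(-self.gamma * d2)
        return K @ self.dual_coef_ + self.intercept_

    # -- diagnostics -------------------------------------------------------
    def dual_feasibility(self) -> dict[str, float]:
        """Constraint residuals of the fitted dual solution."""
        if not self.is_fitted:
            raise NotFittedError("SVR model has not been fitted")
        return {
            "sum_dual": float(abs(self.dual_coef_.sum())),
            "box_violation": float(np.maximum(np.abs(self.dual_coef_) - self.C, 0.0).max()),
        }

    # -- persistence -------------------------------------------------------
    def to_dict(self) -> dict:
        if not self.is_fitted:
            raise NotFittedError("cannot serialize an unfitted model")
        return {
            "C": self.C, "gamma": self.gamma, "epsilon": self.epsilon,
            "mean": self.mean_.tolist(), "scale": self.scale_.tolist(),
            "support_vectors": self.support_vectors_.tolist(),
            "dual_coef": self.dual_coef_.tolist(),
            "intercept": self.intercept_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SVRModel":
        m = cls(C=d["C"], gamma=d["gamma"], epsilon=d["epsilon"])
        m.mean_ = np.asarray(d["mean"], dtype=float)
        m.scale_ = np.asarray(d["scale"], dtype=float)
        m.support_vectors_ = np.asarray(d["support_vectors"], dtype=float)
        m.dual_coef_ = np.asarray(d["dual_coef"], dtype=float)
        m.intercept_ = float(d["intercept"])
        return m


def _cv_pearson(X: np.ndarray, y: np.ndarray, C: float, gamma: float,
                epsilon: float, folds: int, seed: int) -> float:
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    preds = np.empty_like(y)
    for train_idx, test_idx in kf.split(X):
        m = SVRModel(C=C, gamma=gamma, epsilon=epsilon).fit(X[train_idx], y[train_idx])
        preds[test_idx] = m.predict(X[test_idx])
    if np.std(preds) == 0 or np.std(y) == 0:
        return -1.0
    return float(np.corrcoef(preds, y)[0, 1])


def grid_search_svr(X: np.ndarray, y: np.ndarray, cfg: SvrConfig | None = None
                    ) -> tuple[SVRModel, dict]:
    """K-fold cross-validated grid search by Pearson r; returns the model
    refitted on all data with the winning hyperparameters."""
    cfg = cfg or SvrConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    best: tuple[float, tuple[float, float, float]] | None = None
    for C, gamma, epsilon in product(cfg.c_grid, cfg.gamma_grid, cfg.epsilon_grid):
        score = _cv_pearson(X, y, C, gamma, epsilon, cfg.cv_folds, cfg.cv_seed)
        if best is None or score > best[0]:
            best = (score, (C, gamma, epsilon))
    score, (C, gamma, epsilon) = best
    model = SVRModel(C=C, gamma=gamma, epsilon=epsilon).fit(X, y)
    return model, {"cv_pearson_r": score, "C": C, "gamma": gamma, "epsilon": epsilon}


def train_mcsm_component(signatures: np.ndarray, y: np.ndarray,
                         hyperparams: dict | None = None,
                         svr_cfg: SvrConfig | None = None) -> SVRModel:
    """Fit the signature-component SVR on flattened signatures (+ change
    vectors) against experimental ddG.  With explicit ``hyperparams``
    ({'C','gamma','epsilon'}) no search is run; otherwise a cross-validated
    grid search selects them."""
    signatures = np.asarray(signatures, dtype=float)
    y = np.asarray(y, dtype=float)
    if signatures.ndim != 2:
        raise ValueError("signature matrix must be 2-dimensional")
    if len(signatures) != len(y):
        raise ValueError("inconsistent numbers of signatures and targets")
    if len(set(map(len, signatures))) > 1:
        raise ValueError("inconsistent signature widths")
    if len(y) < 20:
        raise ValueError("need at least 20 training mutations")
    if hyperparams is not None:
        return SVRModel(C=hyperparams["C"], gamma=hyperparams["gamma"],
                        epsilon=hyperparams["epsilon"]).fit(signatures, y)
    model, _info = grid_search_svr(signatures, y, svr_cfg)
    return model


def assemble_features(mcsm_pred: float, sdm_calibrated: float, ss_class: str,
                      pharm_change: np.ndarray) -> np.ndarray:
    """Fixed-order 13-vector: [mcsm, sdm, helix, strand, coil, 8 x change]."""
    for name, value in (("mcsm_pred", mcsm_pred), ("sdm_calibrated", sdm_calibrated),
                        ("ss_class", ss_class), ("pharm_change", pharm_change)):
        if value is None:
            raise ValueError(f"missing feature component: {name}")
    if ss_class not in SS_CLASSES:
        raise ValueError(f"unknown secondary-structure class {ss_class!r}")
    pharm_change = np.asarray(pharm_change, dtype=float)
    if pharm_change.shape != (N_CLASSES,):
        raise ValueError(f"pharmacophore change vector must have length {N_CLASSES}")
    onehot = np.zeros(len(SS_CLASSES))
    onehot[SS_CLASSES.index(ss_class)] = 1.0
    return np.concatenate([[mcsm_pred, sdm_calibrated], onehot, pharm_change])


def unpack_features(v: np.ndarray) -> tuple[float, float, str, np.ndarray]:
    """Inverse of :func:`assemble_features`."""
    v = np.asarray(v, dtype=float)
    if v.shape != (FEATURE_WIDTH,):
        raise ValueError(f"feature vector must have length {FEATURE_WIDTH}")
    onehot = v[2:2 + len(SS_CLASSES)]
    if not np.isclose(onehot.sum(), 1.0):
        raise ValueError("secondary-structure one-hot must sum to 1")
    ss_class = SS_CLASSES[int(np.argmax(onehot))]
    return float(v[0]), float(v[1]), ss_class, v[2 + len(SS_CLASSES):]


def train_consensus(features: np.ndarray, y: np.ndarray, C: float | None = None,
                    gamma: float | None = None, epsilon: float | None = None,
                    svr_cfg: SvrConfig | None = None) -> SVRModel:
    """Fit the consensus SVR on assembled 13-feature vectors.

    Explicit (C, gamma, epsilon) bypass the search; otherwise hyperparameters
    come from the k-fold cross-validated grid."""
    features = np.asarray(features, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) < 20:
        raise ValueError("need at least 20 training mutations")
    if features.shape[1] != FEATURE_WIDTH:
        raise ValueError(f"expected feature width {FEATURE_WIDTH}, got {features.shape[1]}")
    if C is not None or gamma is not None or epsilon is not None:
        if None in (C, gamma, epsilon):
            raise ValueError("specify all of C, gamma, epsilon or none")
        return SVRModel(C=C, gamma=gamma, epsilon=epsilon).fit(features, y)
    model, _info = grid_search_svr(features, y, svr_cfg)
    return model


def predict_consensus(model: SVRModel, features: np.ndarray) -> np.ndarray:
    """Evaluate the consensus kernel expansion; deterministic."""
    return model.predict(features)
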