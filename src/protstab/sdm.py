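"""Environment-specific substitution scoring and its RSA-driven calibration.

The statistical-potential component scores a mutation by comparing amino
acid propensities conditioned on the local structural environment (the
folded state) with environment-free background propensities (the unfolded
state):

    raw = scale * [ ln P(mut|env) - ln P(wt|env) - (ln Pbg(mut) - ln Pbg(wt)) ]

Environments form a 9-letter alphabet: 3 secondary-structure states
(helix / strand / coil) crossed with 3 burial states from relative solvent
accessibility (buried rsa < 0.07, intermediate 0.07 <= rsa < 0.25, exposed
rsa >= 0.25).  Propensity tables (ESSTs) are estimated from
environment-labelled residue observations with additive pseudocounts; a
loader for user-supplied tables is provided.

The raw score is calibrated against experimental ddG with an M5-style model
tree over {raw score, RSA}: a binary regression tree with least-squares
linear models at the leaves, splits chosen to maximise the reduction in
leaf-model residual SD, and bottom-up pruning based on leave-one-out error.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .config import SdmConfig
from .environment import EnvironmentFeatures
from .structure_io import STANDARD_AA

SS_STATES = ("helix", "strand", "coil")
BURIAL_STATES = ("buried", "intermediate", "exposed")
N_ENVIRONMENTS = len(SS_STATES) * len(BURIAL_STATES)
AA_INDEX = {aa: i for i, aa in enumerate(STANDARD_AA)}

TREE_FEATURES = ("raw", "rsa")


class NotFittedError(RuntimeError):
    pass


@dataclass(frozen=True)
class EnvironmentClass:
    ss_class: str
    burial: str

    @property
    def index(self) -> int:
        return SS_STATES.index(self.ss_class) * len(BURIAL_STATES) + BURIAL_STATES.index(self.burial)

    def __str__(self) -> str:
        return f"{self.ss_class}:{self.burial}"


def environment_class(env: EnvironmentFeatures, rsa_buried: float = 0.07,
                      rsa_exposed: float = 0.25) -> EnvironmentClass:
    """Map (secondary structure, RSA) to one of the 9 environment classes.

    Burial boundaries are inclusive upward: rsa equal to a threshold falls
    in the less-buried class.
    """
    if env.ss_class not in SS_STATES:
        raise ValueError(f"unknown secondary-structure class {env.ss_class!r}")
    if env.rsa < rsa_buried:
        burial = "buried"
    elif env.rsa < rsa_exposed:
        burial = "intermediate"
    else:
        burial = "exposed"
    return EnvironmentClass(env.ss_class, burial)


@dataclass
class ESST:
    """Environment-specific substitution table: P(aa | env) plus background."""
    table: np.ndarray        # (9, 20) rows sum to 1
    background: np.ndarray   # (20,) sums to 1
    pseudocount: float

    def p(self, aa: str, env: EnvironmentClass) -> float:
        return float(self.table[env.index, AA_INDEX[aa]])

    def p_background(self, aa: str) -> float:
        return float(self.background[AA_INDEX[aa]])

    @classmethod
    def from_counts(cls, counts: np.ndarray, pseudocount: float) -> "ESST":
        if pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        counts = np.asarray(counts, dtype=float)
        if counts.shape != (N_ENVIRONMENTS, len(STANDARD_AA)):
            raise ValueError(f"counts must have shape (9, 20), got {counts.shape}")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        smoothed = counts + pseudocount
        table = smoothed / smoothed.sum(axis=1, keepdims=True)
        bg = counts.sum(axis=0) + pseudocount
        background = bg / bg.sum()
        return cls(table=table, background=background, pseudocount=pseudocount)

    def to_frame(self) -> pd.DataFrame:
        envs = [f"{ss}:{b}" for ss in SS_STATES for b in BURIAL_STATES]
        rows = [{"env": env, "aa": aa, "probability": self.table[i, j]}
                for i, env in enumerate(envs)
                for j, aa in enumerate(STANDARD_AA)]
        return pd.DataFrame(rows)


def build_esst(observations: pd.DataFrame, pseudocount: float = 1.0) -> ESST:
    """Estimate an ESST from environment-labelled residue observations.

    ``observations`` needs columns ``aa``, ``ss``, ``burial`` (one row per
    observed residue; the TSV interchange format 'seq_id pos aa ss burial'
    read with pandas works directly).
    """
    if observations is None or len(observations) == 0:
        raise ValueError("no observations to estimate an ESST from")
    counts = np.zeros((N_ENVIRONMENTS, len(STANDARD_AA)))
    for _idx, row in observations.iterrows():
        aa = row["aa"]
        if aa not in AA_INDEX:
            continue
        env = EnvironmentClass(row["ss"], row["burial"])
        counts[env.index, AA_INDEX[aa]] += 1
    return ESST.from_counts(counts, pseudocount)


def load_esst(path: str, pseudocount: float = 1.0) -> ESST:
    """Load a user-supplied table in the TSV format 'env aa probability'
    with env written as 'ss:burial'."""
    df = pd.read_csv(path, sep="\t")
    table = np.zeros((N_ENVIRONMENTS, len(STANDARD_AA)))
    for _idx, row in df.iterrows():
        ss, burial = str(row["env"]).split(":")
        env = EnvironmentClass(ss, burial)
        table[env.index, AA_INDEX[row["aa"]]] = row["probability"]
    if not np.allclose(table.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("ESST rows must sum to 1")
    background = table.mean(axis=0)
    background = background / background.sum()
    return ESST(table=table, background=background, pseudocount=pseudocount)


def sdm_raw_score(esst: ESST, wt: str, mut: str, env: EnvironmentClass,
                  scale: float = 1.0) -> float:
    """Log-odds stability score: folded-state (environment-conditional)
    propensity ratio minus unfolded-state (background) ratio, in kcal/mol
    per ``scale`` log-unit.  Antisymmetric in (wt, mut); zero for wt == mut."""
    return scale * (
        np.log(esst.p(mut, env)) - np.log(esst.p(wt, env))
        - (np.log(esst.p_background(mut)) - np.log(esst.p_background(wt)))
    )


# ---------------------------------------------------------------------------
# M5-style model tree

@dataclass
class _Node:
    # internal node
    feature: int | None = None        # index into TREE_FEATURES
    threshold: float | None = None
    left: "_Node | None" = None
    right: "_Node | None" = None
    # leaf
    coef: np.ndarray | None = None    # (3,) intercept + coefficients over features

    @property
    def is_leaf(self) -> bool:
        return self.coef is not None


def _fit_linear(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Least squares y ~ 1 + X; returns (coef, leave-one-out MSE).

    LOO residuals come from the hat-matrix identity e_i / (1 - h_ii); a
    leverage at 1 (interpolating point) falls back to the plain residual.
    """
    A = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    try:
        H = A @ np.linalg.pinv(A.T @ A) @ A.T
        h = np.clip(np.diag(H), 0.0, 1.0 - 1e-8)
        loo = resid / (1.0 - h)
    except np.linalg.LinAlgError:
        loo = resid
    return coef, float(np.mean(loo ** 2))


def _constant_leaf(y: np.ndarray) -> _Node:
    return _Node(coef=np.array([float(np.mean(y)), 0.0, 0.0]))


def _residual_sd(X: np.ndarray, y: np.ndarray) -> float:
    A = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(np.std(y - A @ coef))


_MAX_SPLIT_CANDIDATES = 32  # per feature; quantile-thinned for large nodes


def _best_split(X: np.ndarray, y: np.ndarray, min_leaf: int) -> tuple[int, float, float] | None:
    """Split maximising the reduction in leaf-model residual SD.

    Split quality is judged with the linear models the leaves will actually
    carry (weighted residual SD of a least-squares fit in each child versus
    the parent's) — judging by target SD alone cannot see a split that
    changes the slope rather than the level.  None if no admissible split.
    """
    n = len(y)
    sd_parent = _residual_sd(X, y)
    best: tuple[int, float, float] | None = None
    for f in range(X.shape[1]):
        order = np.argsort(X[:, f], kind="stable")
        xs = X[order, f]
        positions = [i for i in range(min_leaf, n - min_leaf + 1) if xs[i - 1] != xs[i]]
        if len(positions) > _MAX_SPLIT_CANDIDATES:
            idx = np.linspace(0, len(positions) - 1, _MAX_SPLIT_CANDIDATES).astype(int)
            positions = [positions[i] for i in idx]
        for i in positions:
            thr = 0.5 * (xs[i - 1] + xs[i])
            mask = X[:, f] <= thr
            sd_l = _residual_sd(X[mask], y[mask])
            sd_r = _residual_sd(X[~mask], y[~mask])
            reduction = sd_parent - (mask.sum() / n) * sd_l - ((~mask).sum() / n) * sd_r
            if best is None or reduction > best[2]:
                best = (f, thr, reduction)
    return best


def _grow(X: np.ndarray, y: np.ndarray, depth: int, min_leaf: int,
          max_depth: int, sd_stop_abs: float) -> _Node:
    if (depth >= max_depth or len(y) < 2 * min_leaf or np.std(y) == 0
            or _residual_sd(X, y) <= 1e-12):
        coef, _ = _fit_linear(X, y)
        return _Node(coef=coef)
    split = _best_split(X, y, min_leaf)
    if split is None or split[2] < sd_stop_abs:
        coef, _ = _fit_linear(X, y)
        return _Node(coef=coef)
    f, thr, _red = split
    mask = X[:, f] <= thr
    node = _Node(feature=f, threshold=thr)
    node.left = _grow(X[mask], y[mask], depth + 1, min_leaf, max_depth, sd_stop_abs)
    node.right = _grow(X[~mask], y[~mask], depth + 1, min_leaf, max_depth, sd_stop_abs)
    return node


def _prune(node: _Node, X: np.ndarray, y: np.ndarray) -> _Node:
    """Merge a pair of leaves back into their parent when the merged linear
    model's leave-one-out error is not worse than the subtree's."""
    if node.is_leaf:
        return node
    mask = X[:, node.feature] <= node.threshold
    node.left = _prune(node.left, X[mask], y[mask])
    node.right = _prune(node.right, X[~mask], y[~mask])
    if node.left.is_leaf and node.right.is_leaf:
        coef_merged, loo_merged = _fit_linear(X, y)
        _cl, loo_l = _fit_linear(X[mask], y[mask])
        _cr, loo_r = _fit_linear(X[~mask], y[~mask])
        n = len(y)
        loo_subtree = (mask.sum() * loo_l + (~mask).sum() * loo_r) / n
        if loo_merged <= loo_subtree * (1.0 + 1e-9) + 1e-12:
            return _Node(coef=coef_merged)
    return node


@dataclass
class ModelTree:
    """Piecewise-linear calibration tree over (raw score, RSA)."""
    min_leaf: int = 20
    max_depth: int = 4
    sd_stop: float = 0.05
    root: _Node | None = field(default=None, repr=False)

    @property
    def is_fitted(self) -> bool:
        return self.root is not None

    def fit(self, X: Sequence[Sequence[float]], y: Sequence[float]) -> "ModelTree":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(TREE_FEATURES):
            raise ValueError(f"X must be (n, {len(TREE_FEATURES)}) over {TREE_FEATURES}")
        if len(y) != len(X):
            raise ValueError("X and y length mismatch")
        if np.std(y) == 0:
            self.root = _constant_leaf(y)
            return self
        if len(y) < 2 * self.min_leaf:
            self.root = _constant_leaf(y)
            return self
        sd_stop_abs = self.sd_stop * float(np.std(y))
        root = _grow(X, y, 0, self.min_leaf, self.max_depth, sd_stop_abs)
        self.root = _prune(root, X, y)
        return self

    def predict_one(self, raw: float, rsa: float) -> float:
        if self.root is None:
            raise NotFittedError("model tree has not been fitted")
        node = self.root
        x = (raw, rsa)
        while not node.is_leaf:
            node = node.left if x[node.feature] <= node.threshold else node.right
        return float(node.coef[0] + node.coef[1] * raw + node.coef[2] * rsa)

    def predict(self, X: Sequence[Sequence[float]]) -> np.ndarray:
        return np.array([self.predict_one(raw, rsa) for raw, rsa in np.asarray(X, dtype=float)])

    # -- persistence -------------------------------------------------------
    def to_dict(self) -> dict:
        def enc(n: _Node) -> dict:
            if n.is_leaf:
                return {"coef": [float(c) for c in n.coef]}
            return {"feature": int(n.feature), "threshold": float(n.threshold),
                    "left": enc(n.left), "right": enc(n.right)}
        if self.root is None:
            raise NotFittedError("cannot serialize an unfitted tree")
        return {"min_leaf": self.min_leaf, "max_depth": self.max_depth,
                "sd_stop": self.sd_stop, "root": enc(self.root)}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelTree":
        def dec(nd: dict) -> _Node:
            if "coef" in nd:
                return _Node(coef=np.asarray(nd["coef"], dtype=float))
            return _Node(feature=nd["feature"], threshold=nd["threshold"],
                         left=dec(nd["left"]), right=dec(nd["right"]))
        return cls(min_leaf=d["min_leaf"], max_depth=d["max_depth"],
                   sd_stop=d["sd_stop"], root=dec(d["root"]))


def fit_model_tree(X: Sequence[Sequence[float]], y: Sequence[float],
                   min_leaf: int = 20, max_depth: int = 4,
                   sd_stop: float = 0.05) -> ModelTree:
    """Fit the RSA calibration tree on columns (raw score, RSA) against ddG."""
    return ModelTree(min_leaf=min_leaf, max_depth=max_depth, sd_stop=sd_stop).fit(X, y)


def calibrate(tree: ModelTree, raw: float, rsa: float) -> float:
    """Route (raw, rsa) to its leaf and evaluate the leaf's linear model."""
    return tree.predict_one(raw, rsa)


def default_sdm_config_tree(cfg: SdmConfig) -> ModelTree:
    return ModelTree(min_leaf=cfg.tree_min_leaf, max_depth=cfg.tree_max_depth,
                     sd_stop=cfg.tree_sd_stop)
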