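"""Evaluation metrics and data-splitting utilities.

Conventions: Pearson's product-moment correlation r; the "standard error"
sigma is the sample standard deviation of the residuals (pred - obs) with
n-1 denominator, the convention of the stability-prediction literature;
outlier removal discards the fraction of points with the largest absolute
residual (default 10%, floor rounding) and re-computes both metrics on the
remainder.  The position-level splitter keeps all mutations that share a
(structure, chain, position) key on the same side of a train/test split, so
a test set is blind at the position level.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class EvalReport:
    n: int
    r: float
    sigma: float
    r_90: float
    sigma_90: float
    removed_ids: list[int] = field(default_factory=list)

    def to_text(self) -> str:
        lines = [
            "# sigma = sample SD of residuals (pred - obs), n-1 denominator",
            f"n\t{self.n}",
            f"pearson_r\t{self.r:.4f}",
            f"sigma_kcal_mol\t{self.sigma:.4f}",
            f"pearson_r_after_outlier_removal\t{self.r_90:.4f}",
            f"sigma_after_outlier_removal\t{self.sigma_90:.4f}",
            f"removed_indices\t{','.join(map(str, self.removed_ids))}",
        ]
        return "\n".join(lines) + "\n"


def pearson_r(x, y) -> float:
    """Product-moment correlation; undefined for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("length mismatch")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def standard_error(pred, obs) -> float:
    """Sample standard deviation of residuals (pred - obs), kcal/mol."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if len(pred) != len(obs):
        raise ValueError("length mismatch")
    if len(pred) < 2:
        raise ValueError("need at least 2 points")
    return float(np.std(pred - obs, ddof=1))


def outlier_removal_eval(pred, obs, frac: float = 0.1,
                         count_mode: str = "floor") -> EvalReport:
    """Metrics before and after removing the ``frac`` worst-predicted points.

    Removes the floor(frac * n) points (``count_mode='round'`` uses banker's
    rounding instead) with the largest absolute residual, ties broken stably
    by input order, then recomputes r and sigma on the remainder.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if not 0.0 < frac < 1.0:
        raise ValueError("outlier fraction must be in (0, 1)")
    n = len(pred)
    if n < 10:
        raise ValueError("need at least 10 points for outlier-removal evaluation")
    if count_mode == "floor":
        k = math.floor(frac * n)
    elif count_mode == "round":
        k = round(frac * n)
    else:
        raise ValueError(f"unknown count_mode {count_mode!r}")
    resid = np.abs(pred - obs)
    # stable: sort by (-|resid|, index); take the k largest
    order = sorted(range(n), key=lambda i: (-resid[i], i))
    removed = sorted(order[:k])
    keep = np.ones(n, dtype=bool)
    keep[removed] = False
    return EvalReport(
        n=n,
        r=pearson_r(pred, obs),
        sigma=standard_error(pred, obs),
        r_90=pearson_r(pred[keep], obs[keep]),
        sigma_90=standard_error(pred[keep], obs[keep]),
        removed_ids=removed,
    )


def position_level_split(position_keys, test_frac: float = 0.25, seed: int = 0
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Split row indices so that no (structure, chain, position) key occurs
    in both partitions.  Returns (train_idx, test_idx)."""
    if not 0.0 < test_frac < 1.0:
        raise ValueError("test_frac must be in (0, 1)")
    keys = list(position_keys)
    unique = sorted(set(keys), key=str)
    rng = np.random.default_rng(seed)
    rng.shuffle(unique)
    n_test = max(1, int(round(test_frac * len(unique))))
    test_keys = set(unique[:n_test])
    test_idx = np.array([i for i, k in enumerate(keys) if k in test_keys], dtype=int)
    train_idx = np.array([i for i, k in enumerate(keys) if k not in test_keys], dtype=int)
    return train_idx, test_idx


def position_overlap(train_keys, test_keys) -> set:
    """Shared (structure, chain, position) keys between two partitions."""
    return set(train_keys) & set(test_keys)
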