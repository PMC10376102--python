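"""Model training, chain-level cross-validation and comparison metrics.

The predictor is a gradient-boosted tree regressor (LightGBM).  One
model is trained per angle (dphi, dpsi).  Cross-validation partitions
whole chains into folds, so residues of one chain never span train and
test.  Accuracy is summarised by the mean absolute error (MAE) and the
Pearson correlation coefficient (PCC) of pooled out-of-fold
predictions within each fold, averaged across folds, and by the
combined objective objfit = 1 - MAE + PCC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
from lightgbm import LGBMRegressor

__all__ = [
    "RegressorConfig",
    "EvalReport",
    "ImprovementRow",
    "mae",
    "pcc",
    "chain_level_folds",
    "make_regressor",
    "cross_validate",
    "improvement_table",
    "average_improvement",
    "window_sweep",
    "pool_chains",
]


@dataclass
class RegressorConfig:
    """Gradient-boosted regressor settings.

    Defaults are the tuned optimum for the full torsion-fluctuation
    task; tests and sweeps pass smaller configurations.
    """

    learning_rate: float = 0.014
    n_estimators: int = 2561
    max_depth: int = 19
    num_leaves: int = 380
    max_bin: int = 138
    feature_fraction: float = 0.52
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_estimators <= 0 or self.max_depth == 0 or self.num_leaves <= 1:
            raise ValueError("counts must be positive (num_leaves >= 2)")
        if not 0 < self.feature_fraction <= 1:
            raise ValueError("feature_fraction must be in (0, 1]")

    @classmethod
    def small(cls, seed: int = 0, n_estimators: int = 200, learning_rate: float = 0.1):
        """A compact configuration for simulations and sweeps."""
        return cls(
            learning_rate=learning_rate,
            n_estimators=n_estimators,
            max_depth=6,
            num_leaves=31,
            max_bin=255,
            feature_fraction=1.0,
            seed=seed,
        )


@dataclass
class EvalReport:
    """Chain-level cross-validation summary."""

    fold_mae: list[float]
    fold_pcc: list[float]
    mae: float
    pcc: float
    objfit: float
    fold_assignment: dict[str, int]
    k: int

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ImprovementRow:
    """Percent improvements of a new method over a baseline."""

    mae_pct: float
    pcc_pct: float
    average_pct: float


def mae(x, y) -> float:
    """Mean absolute error (1/N) * sum |x_i - y_i|."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size == 0:
        raise ValueError("predictions and labels must be equal-length and non-empty")
    return float(np.mean(np.abs(x - y)))


def pcc(x, y) -> float:
    """Sample Pearson correlation coefficient.

    r = sum (x_i - xbar)(y_i - ybar) / sqrt( sum (x_i - xbar)^2 * sum (y_i - ybar)^2 )
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length vectors of size >= 2")
    dx = x - x.mean()
    dy = y - y.mean()
    denom = np.sqrt(np.sum(dx**2) * np.sum(dy**2))
    if denom == 0:
        raise ValueError("correlation undefined: zero variance")
    return float(np.sum(dx * dy) / denom)


def chain_level_folds(chain_ids, k: int = 10, seed: int = 0) -> dict[str, int]:
    """Shuffle unique chains by seed and partition into k near-equal folds.

    Returns {chain_id: fold}; every residue of a chain inherits its
    chain's fold.
    """
    unique = list(dict.fromkeys(chain_ids))  # preserve first-seen order
    if len(unique) < k:
        raise ValueError(f"need at least k={k} chains, got {len(unique)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(unique))
    assignment: dict[str, int] = {}
    for pos, idx in enumerate(order):
        assignment[unique[idx]] = pos % k
    return assignment


def make_regressor(rc: RegressorConfig) -> LGBMRegressor:
    return LGBMRegressor(
        learning_rate=rc.learning_rate,
        n_estimators=rc.n_estimators,
        max_depth=rc.max_depth,
        num_leaves=rc.num_leaves,
        max_bin=rc.max_bin,
        colsample_bytree=rc.feature_fraction,
        random_state=rc.seed,
        deterministic=True,
        force_row_wise=True,
        n_jobs=1,
        verbose=-1,
    )


def cross_validate(X, y, chain_ids, rc: RegressorConfig, k: int = 10) -> EvalReport:
    """Chain-level k-fold CV of the boosted regressor.

    Per fold, the model is fit on all training-chain residues and
    evaluated on the pooled test-chain residues; fold metrics are then
    averaged and objfit computed from the aggregate MAE/PCC.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    chain_ids = np.asarray(chain_ids)
    if not (X.shape[0] == y.size == chain_ids.size):
        raise ValueError("X, y and chain_ids must be row-aligned")
    assignment = chain_level_folds(chain_ids, k=k, seed=rc.seed)
    folds = np.array([assignment[c] for c in chain_ids])
    fold_mae, fold_pcc = [], []
    for f in range(k):
        test = folds == f
        train = ~test
        assert not np.any(test & train), "a row cannot be in both train and test"
        model = make_regressor(rc)
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message=".*feature names.*")
            model.fit(X[train], y[train])
            pred = model.predict(X[test])
        fold_mae.append(mae(pred, y[test]))
        fold_pcc.append(pcc(pred, y[test]))
    agg_mae = float(np.mean(fold_mae))
    agg_pcc = float(np.mean(fold_pcc))
    return EvalReport(
        fold_mae=fold_mae,
        fold_pcc=fold_pcc,
        mae=agg_mae,
        pcc=agg_pcc,
        objfit=1.0 - agg_mae + agg_pcc,
        fold_assignment=assignment,
        k=k,
    )


def average_improvement(mae_pct: float, pcc_pct: float) -> float:
    """Mean of the two per-metric percent improvements."""
    return (mae_pct + pcc_pct) / 2.0


def improvement_table(new_mae, new_pcc, base_mae, base_pcc) -> ImprovementRow:
    """Percent improvements over a baseline (MAE: lower is better)."""
    if base_mae == 0 or base_pcc == 0:
        raise ZeroDivisionError("baseline metrics must be nonzero")
    mae_pct = (base_mae - new_mae) / base_mae * 100.0
    pcc_pct = (new_pcc - base_pcc) / base_pcc * 100.0
    return ImprovementRow(mae_pct, pcc_pct, average_improvement(mae_pct, pcc_pct))


def pool_chains(features: dict, labels: dict):
    """Stack per-chain (L, D) feature arrays and (L,) labels into pooled
    X, y, chain_ids arrays (row-aligned)."""
    Xs, ys, cids = [], [], []
    for cid in features:
        Xs.append(np.asarray(features[cid], dtype=float))
        ys.append(np.asarray(labels[cid], dtype=float))
        cids.extend([cid] * len(ys[-1]))
    return np.vstack(Xs), np.concatenate(ys), np.asarray(cids)


def window_sweep(features: dict, labels: dict, rc: RegressorConfig, ws_list, k: int = 10):
    """Evaluate a set of odd window sizes and return (best_ws, {ws: objfit}).

    Windowing is applied per chain (windows never cross chain
    boundaries) before pooling for chain-level CV.
    """
    from .features import window  # local import to avoid cycle

    scores: dict[int, float] = {}
    for ws in ws_list:
        wf = {cid: window(m, ws).values for cid, m in features.items()}
        X, y, cids = pool_chains(wf, labels)
        scores[ws] = cross_validate(X, y, cids, rc, k=k).objfit
    best = max(scores, key=scores.get)
    return best, scores
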