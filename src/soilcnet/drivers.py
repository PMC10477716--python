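"""Driver attribution for cumulative carbon mineralization.

Two complementary attributions:

* :func:`rf_importance` — a regression random forest with out-of-bag (OOB)
  permutation importance (%IncMSE) and rfPermute-style significance: each
  predictor's p-value comes from refitting the forest with that predictor's
  values permuted, and the whole-model p-value from refitting with the
  response permuted.
* :func:`variance_partition` — variance partitioning of the response
  between two predictor blocks (e.g. DOC characteristics vs microbial
  network complexity) into unique, shared and residual fractions. For a
  univariate response the constrained-ordination R^2 reduces to linear-model
  R^2; a multivariate response uses the redundancy-analysis trace R^2.
* :func:`within_category_share` — per-predictor share of a block's
  explained variance, both as standalone-R^2 proportions and as averaged
  sequential (LMG/hierarchical) contributions.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn import config_context as sklearn_config_context
from sklearn.tree import DecisionTreeRegressor

from ._utils import MAX_SEED


# ---------------------------------------------------------------- forests


class _OOBForest:
    """Bagged regression trees with explicit bootstrap/OOB bookkeeping.

    randomForest-style defaults: trees see max_features = p/3 candidate
    predictors per split and are grown to purity.
    """

    def __init__(self, n_trees: int, seed: int):
        self.n_trees = n_trees
        self.seed = seed
        self.trees: list[DecisionTreeRegressor] = []
        self.oob_masks: list[np.ndarray] = []

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_OOBForest":
        n, p = X.shape
        rng = np.random.default_rng(self.seed)
        mf = max(1, p // 3)
        X32 = np.ascontiguousarray(X, dtype=np.float32)
        y64 = np.ascontiguousarray(y, dtype=np.float64)
        self.trees, self.oob_masks = [], []
        # Inputs are prepared once above; skip sklearn's per-fit validation
        # (dominant cost when fitting thousands of small trees).
        with sklearn_config_context(
            assume_finite=True, skip_parameter_validation=True
        ):
            for _ in range(self.n_trees):
                idx = rng.integers(0, n, size=n)
                oob = np.ones(n, dtype=bool)
                oob[idx] = False
                tree = DecisionTreeRegressor(
                    max_features=mf, random_state=int(rng.integers(MAX_SEED))
                )
                tree.fit(X32[idx], y64[idx], check_input=False)
                self.trees.append(tree)
                self.oob_masks.append(oob)
        return self

    @staticmethod
    def _predict(tree: DecisionTreeRegressor, X: np.ndarray) -> np.ndarray:
        # Bypass sklearn input validation (hot loop over many small arrays).
        return tree.tree_.predict(
            np.ascontiguousarray(X, dtype=np.float32)
        ).ravel()

    def oob_predictions(self, X: np.ndarray) -> np.ndarray:
        n = X.shape[0]
        pred_sum = np.zeros(n)
        pred_cnt = np.zeros(n)
        for tree, oob in zip(self.trees, self.oob_masks):
            if oob.any():
                pred_sum[oob] += self._predict(tree, X[oob])
                pred_cnt[oob] += 1
        out = np.full(n, np.nan)
        ok = pred_cnt > 0
        out[ok] = pred_sum[ok] / pred_cnt[ok]
        return out

    def oob_r2(self, X: np.ndarray, y: np.ndarray) -> float:
        pred = self.oob_predictions(X)
        ok = np.isfinite(pred)
        ss_res = float(np.sum((y[ok] - pred[ok]) ** 2))
        ss_tot = float(np.sum((y[ok] - y[ok].mean()) ** 2))
        return 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan

    def oob_importance(
        self, X: np.ndarray, y: np.ndarray, seed: int, only_predictor: int | None = None
    ) -> dict:
        """Per-predictor OOB permutation importance.

        For each tree, the OOB MSE increase after permuting one predictor's
        OOB values; reported raw (mean increase), normalized by its standard
        error across trees (the classical scaled %IncMSE), and as a percent
        of the baseline OOB MSE. ``only_predictor`` restricts the work to a
        single column (used by the null refits).
        """
        rng = np.random.default_rng(seed)
        p = X.shape[1]
        cols = range(p) if only_predictor is None else [only_predictor]
        d = np.zeros((len(self.trees), p))
        base = np.zeros(len(self.trees))
        for t, (tree, oob) in enumerate(zip(self.trees, self.oob_masks)):
            if not oob.any():
                continue
            Xo, yo = X[oob], y[oob]
            err = float(np.mean((yo - self._predict(tree, Xo)) ** 2))
            base[t] = err
            for j in cols:
                Xp = Xo.copy()
                Xp[:, j] = rng.permutation(Xp[:, j])
                d[t, j] = float(np.mean((yo - self._predict(tree, Xp)) ** 2)) - err
        mean_d = d.mean(axis=0)
        sd_d = d.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(sd_d > 0, mean_d / (sd_d / math.sqrt(len(self.trees))), 0.0)
        base_mse = base.mean() if base.mean() > 0 else np.nan
        return {
            "raw": mean_d,
            "scaled": z,
            "inc_mse_pct": 100.0 * mean_d / base_mse,
        }


@dataclass
class RFImportanceResult:
    importance: pd.DataFrame  # per predictor: inc_mse_pct, raw, scaled, p_perm
    model_p: float
    oob_r2: float
    n_trees: int
    n_permutations: int


def rf_importance(
    table: pd.DataFrame,
    response: str = "cum",
    n_trees: int = 500,
    n_permutations: int = 99,
    seed: int = 0,
    compute_model_p: bool = True,
) -> RFImportanceResult:
    """Random-forest importance of mineralization predictors with
    permutation significance.

    ``table`` holds the response column and predictor columns. Per-predictor
    p-values refit the forest ``n_permutations`` times with that predictor's
    values permuted and compare the null raw importances with the observed
    one; the model p-value refits with the response permuted and compares
    OOB R^2. All randomness is derived from ``seed``.
    """
    if response not in table.columns:
        raise ValueError(f"response column {response!r} missing")
    predictors = [c for c in table.columns if c != response]
    if len(predictors) < 2:
        raise ValueError("need >= 2 predictors")
    if len(table) < 10:
        raise ValueError("need >= 10 samples")
    y = table[response].to_numpy(float)
    if np.std(y) == 0:
        raise ValueError("constant response")
    if table[predictors].isna().any().any() or np.isnan(y).any():
        raise ValueError("missing values in driver table")
    if n_permutations < 20:
        warnings.warn(
            "fewer than 20 permutations gives coarse p-value granularity", stacklevel=2
        )
    X = table[predictors].to_numpy(float)
    rng = np.random.default_rng(seed)

    forest = _OOBForest(n_trees, seed=int(rng.integers(MAX_SEED))).fit(X, y)
    obs = forest.oob_importance(X, y, seed=int(rng.integers(MAX_SEED)))
    obs_raw = obs["raw"]
    r2 = forest.oob_r2(X, y)

    p_perm = np.ones(len(predictors))
    for j in range(len(predictors)):
        hits = 0
        for _ in range(n_permutations):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            f0 = _OOBForest(n_trees, seed=int(rng.integers(MAX_SEED))).fit(Xp, y)
            null_raw = f0.oob_importance(
                Xp, y, seed=int(rng.integers(MAX_SEED)), only_predictor=j
            )["raw"][j]
            if null_raw >= obs_raw[j]:
                hits += 1
        p_perm[j] = (1 + hits) / (n_permutations + 1)

    model_p = np.nan
    if compute_model_p:
        hits = 0
        for _ in range(n_permutations):
            yp = rng.permutation(y)
            f0 = _OOBForest(n_trees, seed=int(rng.integers(MAX_SEED))).fit(X, yp)
            if f0.oob_r2(X, yp) >= r2:
                hits += 1
        model_p = (1 + hits) / (n_permutations + 1)

    imp = pd.DataFrame(
        {
            "inc_mse_pct": obs["inc_mse_pct"],
            "importance_raw": obs_raw,
            "importance_scaled": obs["scaled"],
            "p_perm": p_perm,
        },
        index=pd.Index(predictors, name="predictor"),
    ).sort_values("importance_raw", ascending=False)
    return RFImportanceResult(
        importance=imp,
        model_p=float(model_p),
        oob_r2=float(r2),
        n_trees=n_trees,
        n_permutations=n_permutations,
    )


# ---------------------------------------------------------------- VPA


@dataclass
class VPAResult:
    unique_x1: float
    unique_x2: float
    shared: float
    residual: float
    r2_x1: float
    r2_x2: float
    r2_both: float
    suppression: bool  # shared < 0 (a suppressor relationship)

    def fractions(self) -> dict:
        return {
            "unique_x1": self.unique_x1,
            "unique_x2": self.unique_x2,
            "shared": self.shared,
            "residual": self.residual,
        }


def _block_r2(Y: np.ndarray, X: np.ndarray, adjusted: bool = False) -> float:
    """Trace R^2 of a (possibly multivariate) centered response on a block.

    Equals linear-regression R^2 for a single response column and the
    redundancy-analysis trace statistic for a response matrix.
    """
    n = Y.shape[0]
    Yc = Y - Y.mean(axis=0)
    design = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(design, Yc, rcond=None)
    resid = Yc - design @ beta
    ss_tot = float(np.sum(Yc**2))
    if ss_tot == 0:
        raise ValueError("response has zero variance")
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    if adjusted:
        p = X.shape[1]
        if n - p - 1 <= 0:
            raise ValueError("not enough residual df for adjusted R^2")
        r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    return r2


def _as_2d(a) -> np.ndarray:
    arr = np.asarray(a, dtype=float)
    return arr[:, None] if arr.ndim == 1 else arr


def variance_partition(
    response,
    X1,
    X2,
    adjusted: bool = False,
) -> VPAResult:
    """Partition response variance between two predictor blocks.

    unique_X1 = R^2(X1+X2) - R^2(X2); unique_X2 symmetric;
    shared = R^2(X1) + R^2(X2) - R^2(X1+X2); residual = 1 - R^2(X1+X2).
    The four fractions sum to 1 exactly. A negative shared fraction
    (suppression) is reported with a flag rather than truncated.
    """
    Y, X1, X2 = _as_2d(response), _as_2d(X1), _as_2d(X2)
    if X1.shape[1] == 0 or X2.shape[1] == 0:
        raise ValueError("predictor blocks must be non-empty")
    if not (Y.shape[0] == X1.shape[0] == X2.shape[0]):
        raise ValueError("response and blocks must have aligned samples")
    n = Y.shape[0]
    if X1.shape[1] + X2.shape[1] >= n:
        raise ValueError("predictors >= samples: partition unidentifiable")
    r2_1 = _block_r2(Y, X1, adjusted)
    r2_2 = _block_r2(Y, X2, adjusted)
    r2_12 = _block_r2(Y, np.column_stack([X1, X2]), adjusted)
    unique1 = r2_12 - r2_2
    unique2 = r2_12 - r2_1
    shared = r2_1 + r2_2 - r2_12
    return VPAResult(
        unique_x1=unique1,
        unique_x2=unique2,
        shared=shared,
        residual=1.0 - r2_12,
        r2_x1=r2_1,
        r2_x2=r2_2,
        r2_both=r2_12,
        suppression=bool(shared < 0),
    )


def within_category_share(response, block: pd.DataFrame) -> pd.DataFrame:
    """Per-predictor share of a block's explained response variance.

    Two decompositions are reported side by side: standalone shares
    (R^2 of each predictor alone over their sum) and hierarchical (LMG)
    shares (sequential R^2 increments averaged over all predictor
    orderings, normalized by the block R^2).
    """
    if block.shape[1] < 1:
        raise ValueError("block must contain >= 1 predictor")
    Y = _as_2d(response)
    cols = list(block.columns)
    X = block.to_numpy(float)
    p = len(cols)
    r2_alone = np.array([_block_r2(Y, X[:, [j]]) for j in range(p)])
    total_alone = r2_alone.sum()
    if total_alone <= 0:
        raise ValueError("block explains no variance; shares undefined")

    # All-subsets R^2 for the LMG decomposition.
    r2_sub: dict[frozenset, float] = {frozenset(): 0.0}
    for size in range(1, p + 1):
        for subset in itertools.combinations(range(p), size):
            r2_sub[frozenset(subset)] = _block_r2(Y, X[:, list(subset)])
    lmg = np.zeros(p)
    for j in range(p):
        others = [k for k in range(p) if k != j]
        for size in range(0, p):
            w = math.factorial(size) * math.factorial(p - size - 1) / math.factorial(p)
            for subset in itertools.combinations(others, size):
                s = frozenset(subset)
                lmg[j] += w * (r2_sub[s | {j}] - r2_sub[s])
    r2_full = r2_sub[frozenset(range(p))]
    return pd.DataFrame(
        {
            "r2_alone": r2_alone,
            "share_standalone_pct": 100.0 * r2_alone / total_alone,
            "lmg": lmg,
            "share_hierarchical_pct": 100.0 * lmg / r2_full if r2_full > 0 else np.nan,
        },
        index=pd.Index(cols, name="predictor"),
    )
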