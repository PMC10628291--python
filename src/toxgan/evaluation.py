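"""Similarity metrics, the background-control distribution, rank-sum
comparison, per-endpoint error summaries, and the per-endpoint regression
baseline harness.

Cosine similarity and RMSE are computed between the generated mean profile
G-bar and the real mean profile R-bar of a condition, in natural units (the
RMSE magnitudes are only meaningful unscaled). The null reference — the
background control — is the same pair of metrics computed between the real
mean profiles of every unordered pair of treatment conditions: a model is
informative only if it sits above (cosine) / below (RMSE) that background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import StudyDataset, condition_mean_profile
from .panel import EndpointPanel

logger = logging.getLogger(__name__)


def cosine_similarity(g: np.ndarray, r: np.ndarray) -> float:
    """sum(g_i r_i) / (||g|| ||r||) on natural-unit mean profiles."""
    g = np.asarray(g, dtype=float)
    r = np.asarray(r, dtype=float)
    if g.shape != r.shape:
        raise ValueError("profile length mismatch")
    ng, nr = np.linalg.norm(g), np.linalg.norm(r)
    if ng == 0.0 or nr == 0.0:
        raise ValueError("zero-norm profile; lab profiles are strictly positive")
    return float(np.dot(g, r) / (ng * nr))


def rmse(g: np.ndarray, r: np.ndarray) -> float:
    """sqrt(mean((g_i - r_i)^2)) over the panel."""
    g = np.asarray(g, dtype=float)
    r = np.asarray(r, dtype=float)
    if g.shape != r.shape:
        raise ValueError("profile length mismatch")
    return float(np.sqrt(np.mean((g - r) ** 2)))


@dataclass
class BackgroundControl:
    """Pairwise metrics between real mean profiles of all condition pairs."""

    cosines: np.ndarray
    rmses: np.ndarray

    @property
    def n_pairs(self) -> int:
        return self.cosines.size

    @property
    def median_cosine(self) -> float:
        return float(np.median(self.cosines))

    @property
    def median_rmse(self) -> float:
        return float(np.median(self.rmses))


def background_control_distribution(dataset: StudyDataset) -> BackgroundControl:
    """Metrics between the real mean profiles of every unordered pair of
    treatment conditions: C(n, 2) pairs for n conditions."""
    conds = dataset.conditions
    if len(conds) < 2:
        raise ValueError("need >= 2 treatment conditions for a background control")
    means = [condition_mean_profile(dataset, c) for c in conds]
    cosines, rmses = [], []
    for i, j in combinations(range(len(means)), 2):
        cosines.append(cosine_similarity(means[i], means[j]))
        rmses.append(rmse(means[i], means[j]))
    return BackgroundControl(cosines=np.array(cosines), rmses=np.array(rmses))


def compare_to_background(
    model_metrics: np.ndarray, background: np.ndarray
) -> dict[str, float]:
    """Two-tailed Wilcoxon rank-sum test of the model's per-condition metric
    distribution against the background control, no multiplicity adjustment.

    Exact enumeration when the smaller sample has <= 8 observations and the
    pooled data are tie-free; tie-corrected normal approximation otherwise.
    Returns {"W": rank-sum statistic of the first sample, "p": p value}.
    """
    x = np.asarray(model_metrics, dtype=float)
    y = np.asarray(background, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty metric vectors")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    W = float(ranks[: x.size].sum())
    if np.all(pooled == pooled[0]):
        logger.warning("compare_to_background: constant pooled data, p = 1")
        return {"W": W, "p": 1.0}
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(x.size, y.size) <= 8 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return {"W": W, "p": float(res.pvalue)}


@dataclass
class EvalReport:
    """Per-condition metrics plus their comparison to the background."""

    per_condition: pd.DataFrame  # columns: condition key fields, cosine, rmse
    background: BackgroundControl
    cosine_test: dict[str, float]
    rmse_test: dict[str, float]

    @property
    def median_cosine(self) -> float:
        return float(self.per_condition["cosine"].median())

    @property
    def median_rmse(self) -> float:
        return float(self.per_condition["rmse"].median())


def evaluate_generated(
    generated: dict[tuple, np.ndarray],
    dataset: StudyDataset,
    background: BackgroundControl | None = None,
) -> EvalReport:
    """Score generated mean profiles (keyed by condition key) against the
    dataset's real condition means and the background control."""
    conds = {c.key: c for c in dataset.conditions}
    rows = []
    for key, g_bar in generated.items():
        if key not in conds:
            raise KeyError(f"generated profile for unknown condition {key}")
        r_bar = condition_mean_profile(dataset, conds[key])
        rows.append(
            {
                "compound_id": key[0],
                "dose_level": key[1],
                "time_days": key[2],
                "cosine": cosine_similarity(g_bar, r_bar),
                "rmse": rmse(g_bar, r_bar),
            }
        )
    per_condition = pd.DataFrame(rows)
    if background is None:
        background = background_control_distribution(dataset)
    return EvalReport(
        per_condition=per_condition,
        background=background,
        cosine_test=compare_to_background(per_condition["cosine"].to_numpy(), background.cosines),
        rmse_test=compare_to_background(per_condition["rmse"].to_numpy(), background.rmses),
    )


def per_endpoint_errors(
    generated_means: np.ndarray,
    real_means: np.ndarray,
    panel: EndpointPanel,
) -> pd.DataFrame:
    """Per-endpoint prediction-error summary across aligned conditions:
    Pearson correlation plus error quantiles. Correlation is reported as
    missing below 3 conditions or for constant columns."""
    G = np.asarray(generated_means, dtype=float)
    R = np.asarray(real_means, dtype=float)
    if G.shape != R.shape:
        raise ValueError("generated/real condition tables must align")
    rows = []
    for i, ep in enumerate(panel):
        err = G[:, i] - R[:, i]
        if G.shape[0] >= 3 and np.std(G[:, i]) > 0 and np.std(R[:, i]) > 0:
            corr = float(stats.pearsonr(G[:, i], R[:, i]).statistic)
        else:
            corr = float("nan")
        rows.append(
            {
                "code": ep.code,
                "pearson_r": corr,
                "mean_error": float(err.mean()),
                "median_abs_error": float(np.median(np.abs(err))),
                "q25_error": float(np.quantile(err, 0.25)),
                "q75_error": float(np.quantile(err, 0.75)),
                "rmse": float(np.sqrt(np.mean(err**2))),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# regression baseline harness
# ---------------------------------------------------------------------------

#: the 12 baseline regressor families, by config token
REGRESSOR_FAMILIES = (
    "knn",
    "decision_tree",
    "extra_trees",
    "random_forest",
    "svr",
    "linear_svr",
    "sgd",
    "adaboost",
    "gradient_boosting",
    "ard",
    "gaussian_process",
    "mlp",
)


def _make_regressor(family: str, seed: int):
    from sklearn import ensemble, gaussian_process, linear_model, neighbors, neural_network, svm, tree

    if family == "knn":
        return neighbors.KNeighborsRegressor(), {"n_neighbors": [3, 5]}
    if family == "decision_tree":
        return tree.DecisionTreeRegressor(random_state=seed), {"max_depth": [3, None]}
    if family == "extra_trees":
        return ensemble.ExtraTreesRegressor(n_estimators=50, random_state=seed), {
            "max_depth": [3, None]
        }
    if family == "random_forest":
        return ensemble.RandomForestRegressor(n_estimators=50, random_state=seed), {
            "max_depth": [3, None]
        }
    if family == "svr":
        return svm.SVR(), {"C": [1.0, 10.0]}
    if family == "linear_svr":
        return svm.LinearSVR(random_state=seed, max_iter=5000, dual="auto"), {"C": [1.0, 10.0]}
    if family == "sgd":
        return linear_model.SGDRegressor(random_state=seed), {"alpha": [1e-4, 1e-2]}
    if family == "adaboost":
        return ensemble.AdaBoostRegressor(random_state=seed), {"n_estimators": [25, 50]}
    if family == "gradient_boosting":
        return ensemble.GradientBoostingRegressor(random_state=seed), {"n_estimators": [25, 50]}
    if family == "ard":
        return linear_model.ARDRegression(), {"alpha_1": [1e-6, 1e-4]}
    if family == "gaussian_process":
        return gaussian_process.GaussianProcessRegressor(random_state=seed), {
            "alpha": [1e-10, 1e-2]
        }
    if family == "mlp":
        return neural_network.MLPRegressor(
            hidden_layer_sizes=(32,), max_iter=1500, random_state=seed
        ), {"alpha": [1e-4, 1e-2]}
    raise ValueError(f"unknown regressor family {family!r}")


def baseline_regression_mse(
    train: tuple[np.ndarray, np.ndarray],
    test: tuple[np.ndarray, np.ndarray],
    families: Sequence[str] = REGRESSOR_FAMILIES,
    endpoint_codes: Sequence[str] | None = None,
    cv_folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """One conventional structure-activity regression per endpoint per
    family, on the same feature construction the GAN conditions on
    (descriptors + dose + time): hyperparameters by k-fold CV on the
    training set, MSE on the test set. Returns an endpoint x family table.
    """
    from sklearn.model_selection import GridSearchCV
    from sklearn.preprocessing import StandardScaler

    X_tr, Y_tr = train
    X_te, Y_te = test
    Y_tr = np.atleast_2d(np.asarray(Y_tr, float))
    Y_te = np.atleast_2d(np.asarray(Y_te, float))
    n_endpoints = Y_tr.shape[1]
    codes = list(endpoint_codes) if endpoint_codes is not None else [str(i) for i in range(n_endpoints)]

    xsc = StandardScaler().fit(X_tr)
    Xs_tr, Xs_te = xsc.transform(X_tr), xsc.transform(X_te)

    out = np.empty((n_endpoints, len(families)))
    for fi, fam in enumerate(families):
        for ei in range(n_endpoints):
            est, grid = _make_regressor(fam, seed)
            y = Y_tr[:, ei]
            if np.std(y) == 0:
                # constant target: predict the constant
                pred = np.full(Y_te.shape[0], y[0])
            else:
                search = GridSearchCV(est, grid, cv=cv_folds, scoring="neg_mean_squared_error")
                search.fit(Xs_tr, y)
                pred = search.best_estimator_.predict(Xs_te)
            out[ei, fi] = float(np.mean((pred - Y_te[:, ei]) ** 2))
    return pd.DataFrame(out, index=codes, columns=list(families))
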