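"""Regression protocol for nodal influence prediction and its evaluation.

The task: given the network and the simulated spreading influence of a
small random fraction q of nodes (the training set S_q), predict the
influence of the remaining nodes (S_{1-q}) from topological features —
either an iterative metric set {M(1)..M(K)} or the 7 classic
centralities.  A Random Forest regressor is the default model; a ridge
variant (with feature standardization) is available.  Prediction quality
on the test set is summarized by three measures, averaged over
independent re-samplings of S_q:

* r^2 — fraction of influence variance explained,
  ``1 - sum (y - yhat)^2 / sum (y - ybar)^2``;
* Kendall's tau-b — rank agreement with tie correction,
  ``(n_c - n_d) / sqrt((n_c + n_d + T)(n_c + n_d + U))``;
* recognition rate — overlap of the predicted and true top-f% node
  lists within the test set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import kendalltau as _scipy_kendalltau

from .graph import UndirectedGraph
from .sir import InfluenceTable


@dataclass
class ExperimentConfig:
    """Protocol parameters for one prediction experiment."""

    q: float = 0.10                    # training fraction
    realizations: int = 50             # random re-samplings of S_q
    K: int = 4                         # max order of the iterative metric set
    f_percent: float = 10.0            # top-fraction for the recognition rate
    regressor: str = "random_forest"   # or "ridge"
    n_estimators: int = 100            # random-forest size
    rng_seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.q < 1.0:
            raise ValueError("q must lie in (0, 1)")
        if self.realizations < 1 or self.K < 1:
            raise ValueError("realizations and K must be >= 1")
        if not 0.0 < self.f_percent < 100.0:
            raise ValueError("f_percent must lie in (0, 100)")
        if self.regressor not in ("random_forest", "ridge"):
            raise ValueError(f"unknown regressor {self.regressor!r}")


@dataclass
class EvaluationReport:
    """Per-realization measures plus their mean and std."""

    per_realization: pd.DataFrame  # columns: realization, r2, kendall, recognition
    metric_name: str = ""
    K: int | None = None
    effective_rate: float | None = None
    graph_id: str = ""

    @property
    def mean(self) -> pd.Series:
        return self.per_realization[["r2", "kendall", "recognition"]].mean()

    @property
    def std(self) -> pd.Series:
        return self.per_realization[["r2", "kendall", "recognition"]].std()

    def to_csv(self, path) -> None:
        df = self.per_realization.copy()
        agg = pd.DataFrame([
            {"realization": "mean", **self.mean.to_dict()},
            {"realization": "std", **self.std.to_dict()},
        ])
        pd.concat([df, agg], ignore_index=True).to_csv(path, index=False)


# -- split -------------------------------------------------------------


def split_nodes(n: int, q: float, rng: np.random.Generator
                ) -> tuple[np.ndarray, np.ndarray]:
    """Uniform random disjoint split into S_q (size round(qN)) and S_{1-q}."""
    if int(np.floor(q * n)) < 2:
        raise ValueError(f"q={q} leaves fewer than 2 training nodes for N={n}")
    m = int(round(q * n))
    perm = rng.permutation(n)
    return np.sort(perm[:m]), np.sort(perm[m:])


# -- evaluation measures ----------------------------------------------


def r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    """Proportion of variance in y explained by yhat; can be negative."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if len(y) != len(yhat) or len(y) < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise ValueError("r^2 undefined: zero variance in y")
    return 1.0 - float(((y - yhat) ** 2).sum()) / ss_tot


def kendall_tau(a: np.ndarray, b: np.ndarray) -> float:
    """Kendall's tau-b: (n_c - n_d)/sqrt((n_c+n_d+T)(n_c+n_d+U))."""
    a = np.asarray(a)
    b = np.asarray(b)
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    if (a == a[0]).all() or (b == b[0]).all():
        raise ValueError("kendall tau-b undefined for an all-tied vector")
    return float(_scipy_kendalltau(a, b).statistic)


def top_nodes(values: np.ndarray, m: int) -> np.ndarray:
    """Indices of the m largest values; boundary ties broken by index."""
    order = np.lexsort((np.arange(len(values)), -np.asarray(values, float)))
    return order[:m]


def recognition_rate(s_hat: np.ndarray, s: np.ndarray,
                     f_percent: float = 10.0) -> float:
    """Overlap fraction of the top-f% lists of predicted and true influence."""
    s_hat = np.asarray(s_hat)
    s = np.asarray(s)
    if len(s) == 0:
        raise ValueError("empty test set")
    if len(s_hat) != len(s):
        raise ValueError("length mismatch")
    m = int(np.ceil(f_percent / 100.0 * len(s)))
    shared = np.intersect1d(top_nodes(s_hat, m), top_nodes(s, m))
    return len(shared) / m


# -- model fitting -----------------------------------------------------


def _make_regressor(name: str, seed: int, n_estimators: int = 100):
    if name == "random_forest":
        from sklearn.ensemble import RandomForestRegressor

        return RandomForestRegressor(n_estimators=n_estimators,
                                     random_state=seed, n_jobs=1)
    from sklearn.linear_model import Ridge
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler

    return make_pipeline(StandardScaler(), Ridge(random_state=seed))


def fit_and_predict(features: np.ndarray, influence: np.ndarray,
                    train: np.ndarray, test: np.ndarray,
                    regressor: str = "random_forest", seed: int = 0,
                    n_estimators: int = 100) -> np.ndarray:
    """Train on S_q rows only; return predicted influence on S_{1-q}."""
    features = np.asarray(features, dtype=float)
    influence = np.asarray(influence, dtype=float)
    if features.shape[0] != len(influence):
        raise ValueError("features are not row-aligned with the influence vector")
    if not np.isfinite(features).all():
        raise ValueError("features contain missing or non-finite values")
    y_train = influence[train]
    if (y_train == y_train[0]).all():
        warnings.warn("constant influence on the training set; "
                      "predicting the constant", stacklevel=2)
        return np.full(len(test), y_train[0])
    model = _make_regressor(regressor, seed, n_estimators)
    model.fit(features[train], y_train)
    return model.predict(features[test])


def evaluate_split(features: np.ndarray, influence: np.ndarray,
                   train: np.ndarray, test: np.ndarray,
                   cfg: ExperimentConfig, seed: int) -> dict:
    """One split -> the three test-set measures."""
    yhat = fit_and_predict(features, influence, train, test,
                           regressor=cfg.regressor, seed=seed,
                           n_estimators=cfg.n_estimators)
    y = np.asarray(influence, dtype=float)[test]
    return {
        "r2": r_squared(y, yhat),
        "kendall": kendall_tau(yhat, y),
        "recognition": recognition_rate(yhat, y, cfg.f_percent),
    }


def run_experiment(features: np.ndarray,
                   influence: InfluenceTable | np.ndarray,
                   cfg: ExperimentConfig,
                   metric_name: str = "",
                   graph_id: str = "") -> EvaluationReport:
    """The full protocol: repeat split -> fit -> evaluate, then aggregate.

    The influence ground truth is fixed; only the sampling of the
    training set S_q and the regressor seed vary across realizations.
    """
    if isinstance(influence, InfluenceTable):
        rate = influence.effective_rate
        influence = influence.influence
    else:
        rate = None
    influence = np.asarray(influence, dtype=float)
    n = len(influence)
    if np.asarray(features).shape[0] != n:
        raise ValueError("features are not row-aligned with the influence vector")
    seeds = np.random.SeedSequence(cfg.rng_seed).generate_state(
        cfg.realizations, np.uint32) >> 1
    rows = []
    for r, s in enumerate(seeds):
        rng = np.random.default_rng(int(s))
        train, test = split_nodes(n, cfg.q, rng)
        rows.append({"realization": r,
                     **evaluate_split(features, influence, train, test,
                                      cfg, int(s))})
    return EvaluationReport(per_realization=pd.DataFrame(rows),
                            metric_name=metric_name, K=cfg.K,
                            effective_rate=rate, graph_id=graph_id)
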