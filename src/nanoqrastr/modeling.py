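"""Best-subset multiple linear regression and the QSAR validation battery.

The modeling layer is deliberately plain ordinary least squares: the
datasets this tool targets are small (n of order 16-35, 3-4 descriptors),
where regularised or latent-variable models are neither needed nor
conventional.  What matters instead is the validation battery that the
QSAR field requires before a model is trusted:

* internal: R^2, adjusted R^2, leave-one-out Q^2 (1 - PRESS/SS), computed
  both by explicit refits and by the hat-matrix shortcut e_i/(1 - h_ii)
  (the two must agree; disagreement indicates a numerical problem);
* external: Q^2_F1 (test residuals against the training mean) and Q^2_F2
  (against the test mean), RMSEP;
* the Golbraikh-Tropsha criteria on observed-vs-predicted pairs;
* Y-randomization: refitting after seeded permutations of the response,
  reporting mean permuted R^2 and Q^2.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "LinearModel",
    "ValidationReport",
    "SingularDesignError",
    "fit_mlr",
    "q2_loo",
    "loo_residuals",
    "external_metrics",
    "external_metrics_from_predictions",
    "golbraikh_tropsha",
    "GT_THRESHOLDS",
    "best_subset",
    "y_randomization",
    "pca_rank_split",
    "validate_model",
]


class SingularDesignError(ValueError):
    """Design matrix is rank deficient; names the collinear columns."""


@dataclass
class LinearModel:
    """Intercept + named coefficients of a fitted (or published) MLR model."""

    intercept: float
    coef: dict[str, float]
    intercept_se: float | None = None
    coef_se: dict[str, float] = field(default_factory=dict)
    n_train: int | None = None
    x_mean: dict[str, float] = field(default_factory=dict)
    x_sd: dict[str, float] = field(default_factory=dict)
    y_mean_train: float | None = None
    y_sd_train: float | None = None
    see: float | None = None  # standard error of estimate

    @property
    def descriptors(self) -> list[str]:
        return list(self.coef)

    def predict(self, X) -> np.ndarray:
        """Evaluate the linear equation on a DataFrame / dict of columns."""
        if isinstance(X, dict):
            X = pd.DataFrame(X)
        yhat = np.full(len(X), self.intercept, dtype=float)
        for name, b in self.coef.items():
            if name not in X.columns:
                raise KeyError(f"descriptor {name!r} missing from input")
            yhat += b * X[name].to_numpy(dtype=float)
        return yhat

    def to_json(self, path=None) -> str:
        payload = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, source: str) -> "LinearModel":
        data = json.loads(source)
        return cls(**data)


@dataclass
class ValidationReport:
    """Bundle of fit, cross-validation, external, GT and Y-rand metrics."""

    r2: float | None = None
    r2_adj: float | None = None
    q2_loo: float | None = None
    press: float | None = None
    see: float | None = None
    q2_f1: float | None = None
    q2_f2: float | None = None
    r2_test: float | None = None
    rmsep: float | None = None
    gt: dict | None = None
    yrand: dict | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def _design(X: pd.DataFrame) -> np.ndarray:
    return sm.add_constant(X.to_numpy(dtype=float), has_constant="add")


def _check_rank(X: pd.DataFrame) -> None:
    A = _design(X)
    if np.linalg.matrix_rank(A) < A.shape[1]:
        # identify columns whose removal restores full rank
        bad = []
        for j, name in enumerate(X.columns):
            sub = np.delete(A, j + 1, axis=1)
            if np.linalg.matrix_rank(sub) == sub.shape[1]:
                bad.append(name)
        raise SingularDesignError(
            f"design is rank deficient; collinear columns: {bad or list(X.columns)}"
        )


def fit_mlr(X: pd.DataFrame, y) -> LinearModel:
    """Ordinary least squares of ``y`` on the named descriptor columns.

    Requires n > p + 1 and a full-rank design; coefficient standard errors
    come from the unbiased residual variance.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    n, p = len(X), X.shape[1]
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (got n={n}, p={p})")
    _check_rank(X)
    res = sm.OLS(y, _design(X)).fit()
    names = list(X.columns)
    return LinearModel(
        intercept=float(res.params[0]),
        coef=dict(zip(names, map(float, res.params[1:]))),
        intercept_se=float(res.bse[0]),
        coef_se=dict(zip(names, map(float, res.bse[1:]))),
        n_train=n,
        x_mean={c: float(X[c].mean()) for c in names},
        x_sd={c: float(X[c].std(ddof=1)) for c in names},
        y_mean_train=float(y.mean()),
        y_sd_train=float(np.std(y, ddof=1)),
        see=float(np.sqrt(res.ssr / res.df_resid)),
    )


def _r2(y, yhat) -> float:
    y = np.asarray(y, float)
    ss = ((y - y.mean()) ** 2).sum()
    return 1.0 - ((y - yhat) ** 2).sum() / ss


def q2_loo(X: pd.DataFrame, y, method: str = "both") -> tuple[float, float]:
    """Leave-one-out Q^2 and PRESS.

    ``method`` is ``"hat"`` (the e_i/(1-h_ii) identity), ``"refit"``
    (explicit n refits) or ``"both"`` (default; the two routes are computed
    and must agree to 1e-8 relative).  The denominator uses the
    full-training mean, the standard QSAR convention.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    n, p = len(X), X.shape[1]
    if n <= p + 2:
        raise ValueError(f"need n > p + 2 for LOO (got n={n}, p={p})")
    _check_rank(X)
    A = _design(X)

    press_hat = press_refit = None
    if method in ("hat", "both"):
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        e = y - A @ beta
        H = A @ np.linalg.solve(A.T @ A, A.T)
        h = np.diag(H)
        press_hat = float(((e / (1.0 - h)) ** 2).sum())
    if method in ("refit", "both"):
        press_refit = 0.0
        for i in range(n):
            mask = np.arange(n) != i
            Ai, yi = A[mask], y[mask]
            if np.linalg.matrix_rank(Ai) < Ai.shape[1]:
                raise SingularDesignError(
                    f"leave-out design singular when removing row {i}"
                )
            bi, *_ = np.linalg.lstsq(Ai, yi, rcond=None)
            press_refit += float((y[i] - A[i] @ bi) ** 2)
    if method == "both":
        if not np.isclose(press_hat, press_refit, rtol=1e-8):
            raise AssertionError(
                f"PRESS routes disagree: hat={press_hat}, refit={press_refit}"
            )
    press = press_hat if press_hat is not None else press_refit
    ss = float(((y - y.mean()) ** 2).sum())
    return 1.0 - press / ss, press


def loo_residuals(X: pd.DataFrame, y) -> np.ndarray:
    """Leave-one-out prediction residuals via the hat-matrix identity."""
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    _check_rank(X)
    A = _design(X)
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    e = y - A @ beta
    h = np.einsum("ij,ji->i", A, np.linalg.solve(A.T @ A, A.T))
    return e / (1.0 - h)


def external_metrics(
    model: LinearModel, X_test: pd.DataFrame, y_test
) -> dict[str, float]:
    """Q^2_F1, Q^2_F2, R^2_test and RMSEP for an external set."""
    if model.y_mean_train is None:
        raise ValueError("model lacks training response mean")
    return external_metrics_from_predictions(
        y_test, model.predict(X_test), model.y_mean_train
    )


def external_metrics_from_predictions(
    y_test, y_pred, y_mean_train: float
) -> dict[str, float]:
    """External predictivity metrics from raw prediction vectors.

    Q^2_F1 centers the denominator on the training mean, Q^2_F2 on the
    test mean; since the test mean minimises the centered sum of squares,
    Q^2_F2 <= Q^2_F1 always.
    """
    y = np.asarray(y_test, dtype=float)
    yhat = np.asarray(y_pred, dtype=float)
    if len(y) == 0:
        raise ValueError("empty test set")
    ssres = float(((y - yhat) ** 2).sum())
    ss_train_centered = float(((y - y_mean_train) ** 2).sum())
    ss_test_centered = float(((y - y.mean()) ** 2).sum())
    if ss_test_centered == 0:
        raise ValueError("zero test-response variance: Q2_F2 undefined")
    if len(y) > 1 and np.var(yhat) > 0:
        r = np.corrcoef(y, yhat)[0, 1]
    else:
        r = np.nan
    return {
        "q2_f1": 1.0 - ssres / ss_train_centered,
        "q2_f2": 1.0 - ssres / ss_test_centered,
        "r2_test": float(r ** 2),
        "rmsep": float(np.sqrt(ssres / len(y))),
    }


#: literature-default thresholds for the Golbraikh-Tropsha battery
GT_THRESHOLDS = {
    "r2_min": 0.6,
    "r0_gap_max": 0.1,
    "k_low": 0.85,
    "k_high": 1.15,
    "r0_diff_max": 0.3,
}


def golbraikh_tropsha(y_obs, y_pred, thresholds: dict | None = None) -> dict:
    """Golbraikh-Tropsha predictivity checks on observed/predicted pairs.

    Returns r^2, the through-origin r0^2 and r0'^2 (both regression
    directions), the through-origin slopes k and k', and pass flags.
    Anti-correlated predictions fail regardless of r^2 magnitude.
    """
    th = {**GT_THRESHOLDS, **(thresholds or {})}
    y = np.asarray(y_obs, dtype=float)
    p = np.asarray(y_pred, dtype=float)
    if len(y) < 3:
        raise ValueError("need >= 3 observation/prediction pairs")
    if np.var(y) == 0 or np.var(p) == 0:
        raise ValueError("zero variance in observations or predictions")
    r = float(np.corrcoef(y, p)[0, 1])
    r2 = r * r
    k = float((y * p).sum() / (p * p).sum())     # obs on pred, origin
    k_prime = float((y * p).sum() / (y * y).sum())  # pred on obs, origin
    r02 = 1.0 - float(((y - k * p) ** 2).sum() / ((y - y.mean()) ** 2).sum())
    r02_prime = 1.0 - float(
        ((p - k_prime * y) ** 2).sum() / ((p - p.mean()) ** 2).sum()
    )
    gap = (r2 - r02) / r2
    gap_prime = (r2 - r02_prime) / r2
    flags = {
        "positive_correlation": r > 0,
        "r2_ok": r2 > th["r2_min"],
        "r0_gap_ok": gap < th["r0_gap_max"] or gap_prime < th["r0_gap_max"],
        "slope_ok": (th["k_low"] <= k <= th["k_high"])
        or (th["k_low"] <= k_prime <= th["k_high"]),
        "r0_diff_ok": abs(r02 - r02_prime) < th["r0_diff_max"],
    }
    return {
        "r2": r2, "r02": r02, "r02_prime": r02_prime,
        "k": k, "k_prime": k_prime,
        "r0_gap": gap, "r0_gap_prime": gap_prime,
        "flags": flags, "all_pass": all(flags.values()),
        "thresholds": "literature defaults" if thresholds is None else "custom",
    }


def best_subset(
    X_all: pd.DataFrame,
    y,
    subset_size: int,
    max_intercorr: float = 0.90,
    criterion: str = "q2",
    top: int | None = None,
) -> list[dict]:
    """Exhaustive best-subset search over descriptor combinations.

    Every C(p, m) subset is enumerated; subsets with any pairwise
    |Pearson r| above ``max_intercorr`` are discarded; survivors are
    ranked by LOO Q^2 (ties by higher R^2, then lexicographic descriptor
    names), or by LOO mean absolute error when ``criterion="mae"``.
    """
    X_all = pd.DataFrame(X_all)
    y = np.asarray(y, dtype=float)
    if subset_size > 5:
        raise ValueError("subset_size > 5 not supported (combinatorial guard)")
    usable = [c for c in X_all.columns if X_all[c].std(ddof=1) > 0]
    if len(usable) < subset_size:
        raise ValueError(
            f"only {len(usable)} non-constant columns for subset_size="
            f"{subset_size}"
        )
    corr = X_all[usable].corr().abs()
    results = []
    for combo in itertools.combinations(sorted(usable), subset_size):
        if any(
            corr.loc[a, b] > max_intercorr
            for a, b in itertools.combinations(combo, 2)
        ):
            continue
        Xs = X_all[list(combo)]
        try:
            model = fit_mlr(Xs, y)
            loo_res = loo_residuals(Xs, y)
        except (SingularDesignError, ValueError):
            continue
        press = float((loo_res ** 2).sum())
        q2 = 1.0 - press / float(((y - y.mean()) ** 2).sum())
        r2 = _r2(y, model.predict(Xs))
        results.append({
            "descriptors": list(combo), "model": model,
            "q2_loo": q2, "press": press, "r2": r2,
            "loo_mae": float(np.abs(loo_res).mean()),
        })
    if not results:
        raise ValueError(
            f"no descriptor subset survives max_intercorr={max_intercorr}"
        )
    if criterion == "q2":
        results.sort(key=lambda r: (-r["q2_loo"], -r["r2"], r["descriptors"]))
    elif criterion == "mae":
        results.sort(key=lambda r: (r["loo_mae"], -r["r2"], r["descriptors"]))
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    return results[:top] if top else results


def y_randomization(
    X: pd.DataFrame, y, n_iter: int = 100, seed: int = 0
) -> dict:
    """Refit after seeded permutations of the response (chance-correlation check).

    Means below 0.5 for both permuted R^2 and permuted Q^2 indicate the
    original model is unlikely to be a chance correlation.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    r2s, q2s = [], []
    for _ in range(n_iter):
        yp = rng.permutation(y)
        model = fit_mlr(X, yp)
        r2s.append(_r2(yp, model.predict(X)))
        q2s.append(q2_loo(X, yp, method="hat")[0])
    return {
        "n_iter": n_iter, "seed": seed,
        "r2_values": r2s, "q2_values": q2s,
        "mean_r2": float(np.mean(r2s)), "mean_q2": float(np.mean(q2s)),
        "not_chance": float(np.mean(r2s)) < 0.5 and float(np.mean(q2s)) < 0.5,
    }


def pca_rank_split(
    X: pd.DataFrame, test_fraction: float = 1 / 3
) -> tuple[list, list]:
    """Train/test split by rank along the first principal component.

    Columns are standardized, compounds are scored on PC1, sorted, and
    every ceil(1/test_fraction)-th compound in rank order goes to the test
    set, giving uniform coverage of the score range.  Deterministic and
    invariant to input row order.
    """
    from sklearn.decomposition import PCA

    X = pd.DataFrame(X)
    if len(X) < 5:
        raise ValueError("need at least 5 compounds to split")
    sd = X.std(ddof=1)
    usable = sd.index[sd > 0]
    if len(usable) == 0:
        raise ValueError("degenerate covariance: all columns constant")
    Z = (X[usable] - X[usable].mean()) / sd[usable]
    scores = PCA(n_components=1).fit_transform(Z.to_numpy(dtype=float))[:, 0]
    # sign convention so row order cannot flip the component
    load_ref = np.argmax(np.abs(np.corrcoef(Z.to_numpy().T, scores)[-1, :-1]))
    if np.corrcoef(Z.to_numpy()[:, load_ref], scores)[0, 1] < 0:
        scores = -scores
    order = sorted(range(len(X)), key=lambda i: (scores[i], str(X.index[i])))
    step = int(np.ceil(1.0 / test_fraction))
    test_pos = set(range(step - 1, len(X), step))
    test = [X.index[order[j]] for j in sorted(test_pos)]
    train = [X.index[order[j]] for j in range(len(X)) if j not in test_pos]
    return train, test


def validate_model(
    X_train: pd.DataFrame,
    y_train,
    X_test: pd.DataFrame | None = None,
    y_test=None,
    n_yrand: int = 100,
    seed: int = 0,
) -> tuple[LinearModel, ValidationReport]:
    """Fit and run the full validation battery in one call."""
    model = fit_mlr(X_train, y_train)
    y = np.asarray(y_train, dtype=float)
    yhat = model.predict(X_train)
    n, p = len(y), len(model.coef)
    r2 = _r2(y, yhat)
    q2, press = q2_loo(X_train, y_train)
    report = ValidationReport(
        r2=r2,
        r2_adj=1.0 - (1.0 - r2) * (n - 1) / (n - p - 1),
        q2_loo=q2,
        press=press,
        see=model.see,
        yrand=y_randomization(X_train, y_train, n_iter=n_yrand, seed=seed),
    )
    if X_test is not None and y_test is not None:
        ext = external_metrics(model, X_test, y_test)
        report.q2_f1 = ext["q2_f1"]
        report.q2_f2 = ext["q2_f2"]
        report.r2_test = ext["r2_test"]
        report.rmsep = ext["rmsep"]
        report.gt = golbraikh_tropsha(y_test, model.predict(X_test))
    return model, report
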