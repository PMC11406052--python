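"""Applicability-domain analysis and prediction-reliability grading.

Three complementary views of whether a prediction can be trusted:

* leverage / Williams: h_q = x_q (X'X)^-1 x_q' with the intercept column,
  against the conventional critical value h* = 3 p'/n (p' = number of
  model parameters including the intercept); residuals standardized by the
  training SEE, outliers flagged at |standardized residual| > 3;
* descriptor standardization: a query is outside the domain when its
  largest |z| (training mean/SD scaling) exceeds 3 AND the corrected rule
  mean|z| + 1.28 * SD(|z|) also exceeds 3; a single extreme descriptor in
  an otherwise central compound does not eject it;
* a three-criterion reliability grade for external queries: (1) the mean
  absolute LOO error over the query's 10 most similar training compounds,
  (2) the standardization-AD verdict, (3) proximity of the prediction to
  the training response mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .modeling import LinearModel, loo_residuals
from .rastr import SimilarityConfig, Standardizer, similarity

__all__ = [
    "ADReport",
    "ReliabilityRecord",
    "leverage_ad",
    "standardization_ad",
    "prediction_reliability",
    "williams_table",
]


@dataclass
class ADReport:
    """Leverage-AD result, ready for a Williams plot."""

    h_train: pd.Series
    h_query: pd.Series | None
    h_star: float
    std_residuals_train: pd.Series
    std_residuals_query: pd.Series | None
    leverage_out_train: pd.Series
    leverage_out_query: pd.Series | None
    response_outlier_train: pd.Series

    def williams_table(self) -> pd.DataFrame:
        """CSV-ready table: compound, set, leverage, std residual, h*, flag."""
        rows = []
        for name in self.h_train.index:
            rows.append({
                "compound": name, "set": "train",
                "leverage": self.h_train[name],
                "std_residual": self.std_residuals_train[name],
                "h_star": self.h_star,
                "flag": "out" if self.leverage_out_train[name] else "in",
            })
        if self.h_query is not None:
            for name in self.h_query.index:
                sr = (
                    self.std_residuals_query[name]
                    if self.std_residuals_query is not None
                    else np.nan
                )
                rows.append({
                    "compound": name, "set": "query",
                    "leverage": self.h_query[name],
                    "std_residual": sr,
                    "h_star": self.h_star,
                    "flag": "out" if self.leverage_out_query[name] else "in",
                })
        return pd.DataFrame(rows)


@dataclass
class ReliabilityRecord:
    """Composite three-criterion reliability verdict for one query."""

    query: str
    neighbor_mae: float
    neighbor_mae_pass: bool
    standardization_in_ad: bool
    mean_proximity: float
    mean_proximity_pass: bool
    grade: str
    fallback_all_train: bool = False
    details: dict = field(default_factory=dict)


def _leverages(A_train: np.ndarray, A_query: np.ndarray) -> np.ndarray:
    XtX_inv = np.linalg.inv(A_train.T @ A_train)
    return np.einsum("ij,jk,ik->i", A_query, XtX_inv, A_query)


def leverage_ad(
    model: LinearModel,
    X_train: pd.DataFrame,
    y_train,
    X_query: pd.DataFrame | None = None,
    y_query=None,
) -> ADReport:
    """Leverage-based AD with h* = 3 p'/n and SEE-standardized residuals."""
    cols = model.descriptors
    Xt = pd.DataFrame(X_train)[cols]
    A = np.column_stack([np.ones(len(Xt)), Xt.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise np.linalg.LinAlgError("singular X'X in leverage computation")
    n, p_prime = A.shape
    h_star = 3.0 * p_prime / n
    h_train = pd.Series(_leverages(A, A), index=Xt.index)

    see = model.see if model.see else 1.0
    resid = np.asarray(y_train, dtype=float) - model.predict(Xt)
    sr_train = pd.Series(resid / see, index=Xt.index)

    h_query = sr_query = lev_out_q = None
    if X_query is not None:
        Xq = pd.DataFrame(X_query)[cols]
        Aq = np.column_stack([np.ones(len(Xq)), Xq.to_numpy(dtype=float)])
        h_query = pd.Series(_leverages(A, Aq), index=Xq.index)
        lev_out_q = h_query > h_star
        if y_query is not None:
            rq = np.asarray(y_query, dtype=float) - model.predict(Xq)
            sr_query = pd.Series(rq / see, index=Xq.index)
    return ADReport(
        h_train=h_train,
        h_query=h_query,
        h_star=h_star,
        std_residuals_train=sr_train,
        std_residuals_query=sr_query,
        leverage_out_train=h_train > h_star,
        leverage_out_query=lev_out_q,
        response_outlier_train=sr_train.abs() > 3,
    )


def standardization_ad(
    X_train: pd.DataFrame,
    x_query,
    z_max: float = 3.0,
    z_corr: float = 3.0,
) -> bool:
    """Two-step standardization AD verdict: True = inside the domain.

    Outside only when max|z| strictly exceeds ``z_max`` and the corrected
    statistic mean|z| + 1.28*SD(|z|) exceeds ``z_corr``.
    """
    Xt = pd.DataFrame(X_train)
    std = Standardizer.fit(Xt)
    if isinstance(x_query, (pd.Series, dict)):
        x_query = pd.DataFrame([x_query])
    z = np.abs(std.transform(pd.DataFrame(x_query)))[0]
    if z.max() <= z_max:
        return True
    corrected = z.mean() + 1.28 * (z.std(ddof=1) if len(z) > 1 else 0.0)
    return corrected <= z_corr


def prediction_reliability(
    model: LinearModel,
    X_train: pd.DataFrame,
    y_train,
    X_query: pd.DataFrame,
    config: SimilarityConfig | None = None,
    mae_factor: float = 1.5,
    proximity_sd_mult: float = 2.0,
) -> list[ReliabilityRecord]:
    """Three-criterion reliability grade for each external query compound.

    Grades: ``good`` when all three criteria pass; ``moderate`` when the
    standardization-AD criterion passes and exactly one of the other two
    fails; ``unreliable`` otherwise (a query outside the standardization AD
    can never grade better than unreliable).
    """
    config = config or SimilarityConfig()
    cols = model.descriptors
    Xt = pd.DataFrame(X_train)[cols]
    Xq = pd.DataFrame(X_query)[cols]
    y = np.asarray(y_train, dtype=float)
    n = len(Xt)

    loo_abs = np.abs(loo_residuals(Xt, y))
    overall_mae = float(loo_abs.mean())
    std = Standardizer.fit(Xt)
    Zt, Zq = std.transform(Xt), std.transform(Xq)

    k = min(10, n)
    fallback = n < 10
    records = []
    for i, name in enumerate(Xq.index):
        s = similarity(Zq[i], Zt, config)
        top = np.argsort(-s, kind="stable")[:k]
        neighbor_mae = float(loo_abs[top].mean())
        c1 = neighbor_mae <= mae_factor * overall_mae
        c2 = standardization_ad(Xt, Xq.iloc[[i]])
        yhat = float(model.predict(Xq.iloc[[i]])[0])
        prox = abs(yhat - (model.y_mean_train or y.mean()))
        sd_y = model.y_sd_train or float(np.std(y, ddof=1))
        c3 = prox <= proximity_sd_mult * sd_y
        if c2 and c1 and c3:
            grade = "good"
        elif c2 and (c1 or c3):
            grade = "moderate"
        else:
            grade = "unreliable"
        records.append(ReliabilityRecord(
            query=str(name),
            neighbor_mae=neighbor_mae,
            neighbor_mae_pass=c1,
            standardization_in_ad=c2,
            mean_proximity=prox,
            mean_proximity_pass=c3,
            grade=grade,
            fallback_all_train=fallback,
            details={"prediction": yhat, "overall_loo_mae": overall_mae},
        ))
    return records


def williams_table(report: ADReport) -> pd.DataFrame:
    """Functional alias for :meth:`ADReport.williams_table`."""
    return report.williams_table()
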