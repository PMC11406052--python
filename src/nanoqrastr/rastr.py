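"""Similarity and error-based read-across (RASTR) descriptors.

For each query compound, the k most similar training ("source") compounds
are found under a kernel similarity computed on standardized modeling
descriptors, and 15 descriptors summarising the similarity profile and the
response spread of those neighbours are emitted.  Column names carry a
kernel suffix, e.g. ``SE(LK)`` for the Laplacian kernel.

Definitions (tool-compatible; the originating read-across software does not
publish closed forms):

* distance: Euclidean on standardized features; laplacian kernel
  s = exp(-gamma*d), gaussian s = exp(-gamma*d^2); default gamma = 1/p.
* RA_pred: similarity-weighted mean of neighbour responses.
* SD_Activity: similarity-weighted SD of neighbour responses about RA_pred;
  SE = SD_Activity/sqrt(k); CVact = SD_Activity/|RA_pred|.
* AvgSim / SD_Similarity / CVsim: mean, sample SD and coefficient of
  variation of neighbour similarities.
* positive/negative neighbour classes split at the training-mean response;
  MaxPos/MaxNeg are the top similarity per class (0 for an empty class),
  AbsDiff = |MaxPos - MaxNeg|, gm = +1 if MaxPos >= MaxNeg else -1
  (Banerjee-Roy concordance coefficient), gmAvgSim = gm*AvgSim,
  gmSD_Similarity = gm*SD_Similarity, PosAvgSim/NegAvgSim are per-class
  mean similarities.

Training compounds are featurised leave-self-out: a training row never
appears in its own source pool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimilarityConfig",
    "Standardizer",
    "RASTR_NAMES",
    "KERNEL_SUFFIX",
    "similarity",
    "rastr_descriptors",
    "rastr_table",
    "InsufficientNeighborsError",
]

RASTR_NAMES = (
    "SD_Activity", "SE", "CVact", "MaxPos", "MaxNeg", "AbsDiff",
    "AvgSim", "SD_Similarity", "CVsim", "gm", "gmAvgSim",
    "gmSD_Similarity", "PosAvgSim", "NegAvgSim", "RA_pred",
)

KERNEL_SUFFIX = {"laplacian": "LK", "gaussian": "GK"}


class InsufficientNeighborsError(ValueError):
    """Fewer than two source compounds survive the similarity floor."""


@dataclass
class SimilarityConfig:
    kernel: str = "laplacian"
    gamma: float | None = None  # None -> 1/p at fit time
    n_close: int = 10
    sim_floor: float = 0.0

    def __post_init__(self) -> None:
        if self.kernel not in KERNEL_SUFFIX:
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.n_close < 2:
            raise ValueError("n_close must be >= 2")
        if self.sim_floor < 0:
            raise ValueError("sim_floor must be >= 0")

    @property
    def suffix(self) -> str:
        return KERNEL_SUFFIX[self.kernel]


@dataclass
class Standardizer:
    """Per-feature mean/SD learned from the training descriptor matrix."""

    mean: pd.Series = field(default_factory=pd.Series)
    sd: pd.Series = field(default_factory=pd.Series)

    @classmethod
    def fit(cls, train: pd.DataFrame) -> "Standardizer":
        if len(train) < 2:
            raise ValueError("need >= 2 training rows to standardize")
        sd = train.std(ddof=1)
        constant = sd.index[sd == 0].tolist()
        if constant:
            raise ValueError(
                f"constant feature(s) cannot be standardized: {constant}"
            )
        return cls(mean=train.mean(), sd=sd)

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.mean.index if c not in X.columns]
        if missing:
            raise ValueError(f"query lacks fitted features {missing}")
        Z = (X[self.mean.index] - self.mean) / self.sd
        return Z.to_numpy(dtype=float)


def similarity(
    query_row: np.ndarray, source_rows: np.ndarray, config: SimilarityConfig
) -> np.ndarray:
    """Kernel similarities in (0, 1] between one query and each source row."""
    q = np.asarray(query_row, dtype=float).ravel()
    S = np.atleast_2d(np.asarray(source_rows, dtype=float))
    if S.shape[1] != q.shape[0]:
        raise ValueError(
            f"feature mismatch: query has {q.shape[0]}, sources {S.shape[1]}"
        )
    gamma = config.gamma if config.gamma is not None else 1.0 / q.shape[0]
    d = np.sqrt(((S - q) ** 2).sum(axis=1))
    if config.kernel == "laplacian":
        return np.exp(-gamma * d)
    return np.exp(-gamma * d * d)


def _weighted_sd(y: np.ndarray, w: np.ndarray, center: float) -> float:
    """Similarity-weighted SD about ``center`` (frequency-weight convention)."""
    wsum = w.sum()
    return math.sqrt(float((w * (y - center) ** 2).sum() / wsum))


def rastr_descriptors(
    query_row: np.ndarray,
    source_X: np.ndarray,
    source_y: np.ndarray,
    config: SimilarityConfig,
    y_mean_train: float | None = None,
) -> dict[str, float]:
    """The 15 read-across descriptors for one (standardized) query row.

    ``y_mean_train`` is the response mean defining the positive/negative
    neighbour split; defaults to the mean of ``source_y``.
    """
    y = np.asarray(source_y, dtype=float)
    s_all = similarity(query_row, source_X, config)
    keep = np.flatnonzero(s_all >= config.sim_floor)
    if keep.size < 2:
        raise InsufficientNeighborsError(
            f"only {keep.size} source compounds at sim_floor="
            f"{config.sim_floor}"
        )
    k = min(config.n_close, keep.size)
    # top-k by similarity; ties broken by source index order (stable sort
    # on descending similarity keeps the lower index first)
    order = keep[np.argsort(-s_all[keep], kind="stable")][:k]
    s, yk = s_all[order], y[order]
    if y_mean_train is None:
        y_mean_train = float(y.mean())

    ra_pred = float((s * yk).sum() / s.sum())
    sd_act = _weighted_sd(yk, s, ra_pred)
    se = sd_act / math.sqrt(k)
    cvact = sd_act / abs(ra_pred) if ra_pred != 0 else math.inf
    avg_sim = float(s.mean())
    sd_sim = float(np.std(s, ddof=1))
    cvsim = sd_sim / avg_sim

    pos = s[yk > y_mean_train]
    neg = s[yk <= y_mean_train]
    max_pos = float(pos.max()) if pos.size else 0.0
    max_neg = float(neg.max()) if neg.size else 0.0
    gm = 1.0 if max_pos >= max_neg else -1.0
    return {
        "SD_Activity": sd_act,
        "SE": se,
        "CVact": cvact,
        "MaxPos": max_pos,
        "MaxNeg": max_neg,
        "AbsDiff": abs(max_pos - max_neg),
        "AvgSim": avg_sim,
        "SD_Similarity": sd_sim,
        "CVsim": cvsim,
        "gm": gm,
        "gmAvgSim": gm * avg_sim,
        "gmSD_Similarity": gm * sd_sim,
        "PosAvgSim": float(pos.mean()) if pos.size else 0.0,
        "NegAvgSim": float(neg.mean()) if neg.size else 0.0,
        "RA_pred": ra_pred,
    }


def rastr_table(
    train_X: pd.DataFrame,
    train_y: pd.Series,
    test_X: pd.DataFrame | None = None,
    config: SimilarityConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """RASTR descriptor tables for a training set and an optional test set.

    Training rows are computed leave-self-out; test rows see the full
    training pool.  Columns are suffixed with the kernel tag, e.g.
    ``SE(LK)``.
    """
    config = config or SimilarityConfig()
    std = Standardizer.fit(train_X)
    Zt = std.transform(train_X)
    y = np.asarray(train_y, dtype=float)
    y_mean = float(y.mean())
    cols = [f"{n}({config.suffix})" for n in RASTR_NAMES]

    def _rows(Z, pool_of):
        out, errors = [], {}
        for i in range(Z.shape[0]):
            pool = pool_of(i)
            try:
                r = rastr_descriptors(
                    Z[i], Zt[pool], y[pool], config, y_mean_train=y_mean
                )
                out.append([r[n] for n in RASTR_NAMES])
            except Exception as e:  # propagate with compound identifier
                errors[i] = e
        if errors:
            raise ValueError(f"RASTR failures at rows {errors}")
        return out

    mask = np.arange(len(y))
    train_rows = _rows(Zt, lambda i: mask != i)
    train_tab = pd.DataFrame(train_rows, index=train_X.index, columns=cols)
    test_tab = None
    if test_X is not None:
        Zq = std.transform(test_X)
        test_rows = _rows(Zq, lambda i: slice(None))
        test_tab = pd.DataFrame(test_rows, index=test_X.index, columns=cols)
    return train_tab, test_tab
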