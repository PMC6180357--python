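"""Synthetic data generation, normalisation, splitting and CSV I/O.

Two dataset shapes are emulated: a genomic-style table of binary covariates
(the scale of interest is ~1581 records x ~103 columns) and a
financial-style table of continuous covariates min-max normalised to
[0, 1] (~20,000 records x ~32 columns).  Labels are drawn from the logistic
model itself, so the Bayes-optimal classifier is known by construction.
"""

from __future__ import annotations

import warnings
from typing import Literal

import numpy as np
import pandas as pd

from .sfh import Dataset, ModelVector, sigmoid

__all__ = [
    "minmax_normalize",
    "gen_synthetic",
    "draw_beta",
    "train_test_split",
    "load_csv",
    "save_csv",
]

#: Published shapes of the two study datasets (records, covariates).
GENOMIC_SHAPE = (1581, 103)
FINANCIAL_SHAPE = (20000, 32)


def minmax_normalize(X: np.ndarray) -> np.ndarray:
    """Columnwise (x - x_min) / (x_max - x_min); rejects constant columns."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-d array")
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    flat = np.flatnonzero(hi == lo)
    if flat.size:
        raise ValueError(
            f"column {int(flat[0])} is constant and cannot be min-max normalised"
        )
    return (X - lo) / (hi - lo)


def draw_beta(
    d: int, rng: np.random.Generator, scale: float = 1.0, center: bool = True
) -> ModelVector:
    """Draw a ground-truth coefficient vector with N(0, scale^2) covariate
    weights.  With ``center`` the intercept is set to -sum(beta_j)/2 so the
    logits are centred for covariates with mean ~1/2 and classes stay
    roughly balanced."""
    b = rng.normal(0.0, scale, size=d + 1)
    if center:
        b[0] = -0.5 * b[1:].sum()
    return ModelVector(b)


def gen_synthetic(
    N: int,
    d: int,
    kind: Literal["binary", "continuous"],
    beta_true: ModelVector,
    seed: int,
) -> Dataset:
    """Synthetic dataset in one of the two study shapes.

    kind="binary": covariate j is Bernoulli(p_j) with p_j drawn once per
    column from Uniform[0.1, 0.5].  kind="continuous": Uniform[0, 1].
    Labels are +1 with probability sigma(beta_true^T x).  Deterministic
    under ``seed``.
    """
    if N < 1 or d < 1:
        raise ValueError("N >= 1 and d >= 1 required")
    if len(beta_true) != d + 1:
        raise ValueError("beta_true must have d+1 entries")
    rng = np.random.default_rng(seed)
    if kind == "binary":
        p = rng.uniform(0.1, 0.5, size=d)
        cov = (rng.random((N, d)) < p).astype(float)
    elif kind == "continuous":
        cov = rng.random((N, d))
    else:
        raise ValueError(f"unknown covariate kind {kind!r}")
    data = Dataset.from_covariates(cov, np.ones(N))
    probs = sigmoid(data.X @ beta_true.beta)
    y = np.where(rng.random(N) < probs, 1.0, -1.0)
    return Dataset(data.X, y)


def train_test_split(
    data: Dataset, n_train: int, shuffle_seed: int | None = None
) -> tuple[Dataset, Dataset]:
    """First ``n_train`` rows train, the rest test; an optional shuffle seed
    permutes the rows first."""
    if not 1 <= n_train < data.N:
        raise ValueError("need 1 <= n_train < N")
    idx = np.arange(data.N)
    if shuffle_seed is not None:
        np.random.default_rng(shuffle_seed).shuffle(idx)
    tr, te = idx[:n_train], idx[n_train:]
    return (
        Dataset(data.X[tr], data.y[tr]),
        Dataset(data.X[te], data.y[te]),
    )


def load_csv(path) -> tuple[Dataset, list[str]]:
    """Read a dataset from CSV: header row, label column named "y" with
    values in {-1, +1} ({0, 1} is accepted and remapped with a warning).
    The intercept column is added internally.  Returns (dataset, covariate
    names)."""
    df = pd.read_csv(path)
    if "y" not in df.columns:
        raise ValueError(f"{path}: no label column named 'y'")
    y = df["y"].to_numpy(dtype=float)
    vals = set(np.unique(y).tolist())
    if vals <= {0.0, 1.0}:
        warnings.warn(
            f"{path}: labels in {{0,1}} remapped to {{-1,+1}}", stacklevel=2
        )
        y = 2.0 * y - 1.0
    elif not vals <= {-1.0, 1.0}:
        raise ValueError(f"{path}: labels must lie in {{-1,+1}} (or {{0,1}})")
    names = [c for c in df.columns if c != "y"]
    if not names:
        raise ValueError(f"{path}: no covariate columns")
    return Dataset.from_covariates(df[names].to_numpy(dtype=float), y), names


def save_csv(data: Dataset, path, names: list[str] | None = None) -> None:
    """Write covariates (without the internal intercept) and the label."""
    if names is None:
        names = [f"x{j}" for j in range(1, data.d + 1)]
    if len(names) != data.d:
        raise ValueError("one name per covariate required")
    df = pd.DataFrame(data.X[:, 1:], columns=names)
    df["y"] = data.y.astype(int)
    df.to_csv(path, index=False)
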