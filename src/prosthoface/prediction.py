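"""Elastic prediction model: PCA shape statistics + back-propagation network.

The displacement of the 29 perioral feature points between the edentulous
and the denture-wearing face is an 87-dimensional field; across a patient
cohort these fields occupy a low-dimensional subspace, captured by PCA
(sample covariance, n-1 normalization).  A small back-propagation network —
87 inputs (the flattened pre-operative template), one sigmoidal hidden
layer of 20 nodes, linear outputs — regresses the PCA scores of the
displacement field from the pre-operative template geometry; decoding
through the PCA basis yields the predicted 29-point displacement field that
drives the Laplacian deformation.

Inputs and targets are z-standardized with training statistics; training is
full-batch gradient descent with momentum under a fixed seed, so fitted
models are exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SKPCA

from .errors import DivergenceError, ParameterError
from .geometry import FeatureTemplate

__all__ = [
    "PCAModel",
    "BPNetwork",
    "fit_pca",
    "train_bp",
    "predict_field",
    "hidden_layer_sweep",
]

FIELD_DIM = 87  # 29 template points x 3 coordinates


def as_field_matrix(fields) -> np.ndarray:
    """Stack a list of (29, 3) displacement fields into an (n, 87) matrix."""
    rows = [np.asarray(f, dtype=np.float64).reshape(-1) for f in fields]
    x = np.vstack(rows)
    if x.shape[1] != FIELD_DIM:
        raise ParameterError(f"displacement fields must flatten to {FIELD_DIM} values")
    if not np.all(np.isfinite(x)):
        raise ParameterError("non-finite displacement field")
    return x


@dataclass
class PCAModel:
    """Mean + orthonormal component basis of template-displacement fields."""

    mean: np.ndarray                 # (87,)
    components: np.ndarray           # (k, 87), rows orthonormal
    explained_variance: np.ndarray   # (k,), non-increasing
    total_variance: float

    @property
    def k(self) -> int:
        return int(self.components.shape[0])

    def encode(self, flat_fields: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(flat_fields, dtype=np.float64))
        return (x - self.mean) @ self.components.T

    def decode(self, scores: np.ndarray) -> np.ndarray:
        s = np.atleast_2d(np.asarray(scores, dtype=np.float64))
        if s.shape[1] != self.k:
            raise ParameterError(f"expected {self.k} scores, got {s.shape[1]}")
        return self.mean + s @ self.components

    def to_dict(self) -> dict:
        return {
            "mean": self.mean.tolist(),
            "components": self.components.tolist(),
            "explained_variance": self.explained_variance.tolist(),
            "total_variance": self.total_variance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PCAModel":
        return cls(
            np.asarray(d["mean"], dtype=np.float64),
            np.asarray(d["components"], dtype=np.float64).reshape(-1, FIELD_DIM),
            np.asarray(d["explained_variance"], dtype=np.float64),
            float(d["total_variance"]),
        )


def fit_pca(fields, variance_kept: float = 0.95) -> PCAModel:
    """Fit the PCA displacement-field model.

    ``k`` is the smallest component count whose cumulative explained
    variance reaches ``variance_kept``; a cohort with (numerically) zero
    total variance yields k = 0.  Component signs follow a deterministic
    convention: the largest-magnitude entry of each component is positive.
    """
    x = as_field_matrix(fields)
    n = x.shape[0]
    if n < 2:
        raise ParameterError(f"PCA needs >= 2 displacement fields, got {n}")
    if not 0 < variance_kept <= 1:
        raise ParameterError("variance_kept must be in (0, 1]")
    mean = x.mean(axis=0)
    total = float(((x - mean) ** 2).sum() / (n - 1))
    if total < 1e-12:
        return PCAModel(mean, np.zeros((0, FIELD_DIM)), np.zeros(0), total)
    pca = _SKPCA(n_components=min(n - 1, FIELD_DIM), svd_solver="full")
    pca.fit(x)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, variance_kept - 1e-12) + 1)
    k = min(k, pca.components_.shape[0])
    comp = pca.components_[:k].copy()
    for row in comp:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    return PCAModel(mean, comp, pca.explained_variance_[:k].copy(), total)


# ----------------------------------------------------------------- network
def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60.0, 60.0)))


@dataclass
class BPNetwork:
    """One-hidden-layer back-propagation regressor (sigmoid -> linear)."""

    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: np.ndarray
    y_std: np.ndarray
    seed: int = 0
    final_mse: float = np.nan
    hyper: dict = field(default_factory=dict)

    @property
    def hidden(self) -> int:
        return int(self.w1.shape[1])

    @property
    def output_dim(self) -> int:
        return int(self.w2.shape[1])

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Forward pass on raw (unstandardized) inputs; raw-scale outputs."""
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        if x.shape[1] != self.w1.shape[0]:
            raise ParameterError(
                f"expected {self.w1.shape[0]} inputs, got {x.shape[1]}"
            )
        xs = (x - self.x_mean) / self.x_std
        h = _sigmoid(xs @ self.w1 + self.b1)
        ys = h @ self.w2 + self.b2
        return ys * self.y_std + self.y_mean

    def to_dict(self) -> dict:
        return {
            "w1": self.w1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": self.b2.tolist(),
            "x_mean": self.x_mean.tolist(),
            "x_std": self.x_std.tolist(),
            "y_mean": self.y_mean.tolist(),
            "y_std": self.y_std.tolist(),
            "seed": self.seed,
            "final_mse": self.final_mse,
            "hyper": self.hyper,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BPNetwork":
        arr = lambda k: np.asarray(d[k], dtype=np.float64)
        return cls(
            arr("w1"), arr("b1"), arr("w2"), arr("b2"),
            arr("x_mean"), arr("x_std"), arr("y_mean"), arr("y_std"),
            int(d.get("seed", 0)), float(d.get("final_mse", np.nan)),
            dict(d.get("hyper", {})),
        )


def train_bp(
    inputs,
    targets,
    hidden: int = 20,
    seed: int = 0,
    learning_rate: float = 0.01,
    epochs: int = 5000,
    momentum: float = 0.9,
) -> BPNetwork:
    """Train the back-propagation network.

    Full-batch gradient descent with classical momentum on z-standardized
    inputs and targets; deterministic given ``seed``.  Raises
    :class:`DivergenceError` (naming the epoch) if the loss goes
    non-finite.
    """
    x = np.atleast_2d(np.asarray(inputs, dtype=np.float64))
    y = np.asarray(targets, dtype=np.float64)
    y = y.reshape(x.shape[0], -1)
    n = x.shape[0]
    if n < 4:
        raise ParameterError(f"training needs >= 4 samples, got {n}")
    if hidden < 1:
        raise ParameterError("need at least one hidden node")

    x_mean, x_std = x.mean(axis=0), x.std(axis=0)
    x_std = np.where(x_std < 1e-12, 1.0, x_std)
    y_mean, y_std = y.mean(axis=0), y.std(axis=0)
    y_std = np.where(y_std < 1e-12, 1.0, y_std)
    xs = (x - x_mean) / x_std
    ys = (y - y_mean) / y_std

    rng = np.random.default_rng(seed)
    d_in, d_out = x.shape[1], y.shape[1]
    w1 = rng.normal(0.0, 1.0 / np.sqrt(d_in), size=(d_in, hidden))
    b1 = np.zeros(hidden)
    w2 = rng.normal(0.0, 1.0 / np.sqrt(hidden), size=(hidden, d_out))
    b2 = np.zeros(d_out)
    vw1 = np.zeros_like(w1)
    vb1 = np.zeros_like(b1)
    vw2 = np.zeros_like(w2)
    vb2 = np.zeros_like(b2)

    mse = 0.0
    for epoch in range(int(epochs)):
        h = _sigmoid(xs @ w1 + b1)
        out = h @ w2 + b2
        err = out - ys
        mse = float(np.mean(err**2)) if d_out else 0.0
        if not np.isfinite(mse):
            raise DivergenceError("training loss is non-finite", epoch=epoch)
        g_out = 2.0 * err / max(n * max(d_out, 1), 1)
        gw2 = h.T @ g_out
        gb2 = g_out.sum(axis=0)
        g_h = (g_out @ w2.T) * h * (1.0 - h)
        gw1 = xs.T @ g_h
        gb1 = g_h.sum(axis=0)
        vw1 = momentum * vw1 - learning_rate * gw1
        vb1 = momentum * vb1 - learning_rate * gb1
        vw2 = momentum * vw2 - learning_rate * gw2
        vb2 = momentum * vb2 - learning_rate * gb2
        w1 += vw1
        b1 += vb1
        w2 += vw2
        b2 += vb2

    return BPNetwork(
        w1, b1, w2, b2, x_mean, x_std, y_mean, y_std,
        seed=int(seed), final_mse=mse,
        hyper={
            "hidden": hidden,
            "learning_rate": learning_rate,
            "epochs": int(epochs),
            "momentum": momentum,
        },
    )


def predict_field(pca: PCAModel, net: BPNetwork, preop_template: FeatureTemplate) -> np.ndarray:
    """Predicted (29, 3) displacement field for a pre-operative template.

    Standardize -> network forward pass -> PCA decode.  With k = 0 (a
    variance-free cohort) the prediction is the mean field regardless of
    the input.
    """
    if pca.k == 0:
        return pca.mean.reshape(-1, 3).copy()
    if net.output_dim != pca.k:
        raise ParameterError(
            f"network predicts {net.output_dim} scores but PCA keeps {pca.k}"
        )
    scores = net.predict(preop_template.flatten()[None, :])
    return pca.decode(scores)[0].reshape(-1, 3)


def hidden_layer_sweep(
    inputs,
    targets,
    candidate_counts,
    seed: int = 0,
    validation_fraction: float = 0.25,
    **train_kwargs,
) -> pd.DataFrame:
    """Validation error for each candidate hidden-layer size.

    One shared seeded train/validation split; one network per candidate
    trained with the same seed.  Returns a table (hidden, train_mse,
    validation_rmse) with the arg-min marked in ``best``.
    """
    candidates = list(candidate_counts)
    if not candidates:
        raise ParameterError("no candidate hidden-layer sizes given")
    x = np.atleast_2d(np.asarray(inputs, dtype=np.float64))
    y = np.asarray(targets, dtype=np.float64).reshape(x.shape[0], -1)
    n = x.shape[0]
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_val = max(1, int(round(validation_fraction * n)))
    val, train = perm[:n_val], perm[n_val:]
    rows = []
    for hside in candidates:
        net = train_bp(x[train], y[train], hidden=int(hside), seed=seed, **train_kwargs)
        pred = net.predict(x[val])
        rmse = float(np.sqrt(np.mean((pred - y[val]) ** 2)))
        rows.append({"hidden": int(hside), "train_mse": net.final_mse, "validation_rmse": rmse})
    table = pd.DataFrame(rows)
    table["best"] = table["validation_rmse"] == table["validation_rmse"].min()
    return table
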