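"""Principal component analysis of the 13-variable feature table.

The thirteen howl variables mix units (Hz, seconds, counts, dimensionless
ratios), so the default is correlation-matrix PCA: each variable is centred
and divided by its sample standard deviation before the eigendecomposition.
Covariance-matrix PCA is available for matching analyses that worked on raw
scales.  Components are retained by the ">5% of variance" rule: every
component whose variance share strictly exceeds the threshold is kept.

The eigendecomposition itself is done here (symmetric eigensolver on the
13x13 correlation/covariance matrix) so that centring, scaling, ordering and
the deterministic sign convention are all explicit and serialisable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .exceptions import HowlIdError, SchemaError
from .features import FEATURE_NAMES

_SERIAL_VERSION = 1


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Force each column's largest-magnitude entry positive (first on ties)."""
    out = vectors.copy()
    for j in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, j])))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


@dataclass
class PCAModel:
    """A fitted PCA: centring/scaling plus orthonormal loadings.

    ``variance_fraction`` holds the proportion of (standardised) variance per
    component, non-increasing and summing to one.
    """

    feature_names: tuple[str, ...]
    centers: np.ndarray
    scales: np.ndarray
    loadings: np.ndarray  # p x p, columns are components
    variance_fraction: np.ndarray
    scale_mode: str = "correlation"

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    # -- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "format": "howlid-pca",
            "version": _SERIAL_VERSION,
            "feature_names": list(self.feature_names),
            "centers": self.centers.tolist(),
            "scales": self.scales.tolist(),
            "loadings": self.loadings.tolist(),
            "variance_fraction": self.variance_fraction.tolist(),
            "scale_mode": self.scale_mode,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PCAModel":
        if d.get("format") != "howlid-pca":
            raise HowlIdError("not a serialised PCA model")
        return cls(
            feature_names=tuple(d["feature_names"]),
            centers=np.array(d["centers"], dtype=float),
            scales=np.array(d["scales"], dtype=float),
            loadings=np.array(d["loadings"], dtype=float),
            variance_fraction=np.array(d["variance_fraction"], dtype=float),
            scale_mode=d["scale_mode"],
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "PCAModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _feature_matrix(
    table: pd.DataFrame, feature_names: Sequence[str]
) -> np.ndarray:
    missing = [c for c in feature_names if c not in table.columns]
    if missing:
        raise SchemaError(f"feature table lacks columns: {missing}")
    return table[list(feature_names)].to_numpy(dtype=float)


def fit_pca(
    table: pd.DataFrame,
    scale_mode: str = "correlation",
    feature_names: Sequence[str] = FEATURE_NAMES,
) -> PCAModel:
    """Fit PCA on a feature table.

    ``scale_mode="correlation"`` (default) standardises every variable to
    unit sample variance; ``"covariance"`` only centres.  A constant column
    under correlation scaling is an error, because it cannot be standardised.
    """
    if scale_mode not in ("correlation", "covariance"):
        raise ValueError(f"unknown scale_mode {scale_mode!r}")
    X = _feature_matrix(table, feature_names)
    n, p = X.shape
    if n < 2:
        raise HowlIdError(f"PCA needs at least 2 rows, got {n}")

    centers = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    if scale_mode == "correlation":
        constant = [feature_names[j] for j in range(p) if sds[j] < 1e-12]
        if constant:
            raise HowlIdError(
                "constant column(s) under correlation scaling: "
                f"{constant}; drop them or use covariance scaling"
            )
        scales = sds
    else:
        scales = np.ones(p)

    Z = (X - centers) / scales
    C = Z.T @ Z / (n - 1)
    eigvals, eigvecs = scipy.linalg.eigh(C)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    loadings = _fix_signs(eigvecs[:, order])
    return PCAModel(
        feature_names=tuple(feature_names),
        centers=centers,
        scales=scales,
        loadings=loadings,
        variance_fraction=eigvals / eigvals.sum(),
        scale_mode=scale_mode,
    )


def select_components(
    model_or_fractions: PCAModel | Sequence[float] | np.ndarray,
    threshold: float = 0.05,
) -> np.ndarray:
    """Indices of components whose variance fraction strictly exceeds the
    threshold, in decreasing-variance order.

    Accepts either a fitted :class:`PCAModel` or a bare vector of variance
    fractions (summing to one).
    """
    if isinstance(model_or_fractions, PCAModel):
        fractions = model_or_fractions.variance_fraction
    else:
        fractions = np.asarray(model_or_fractions, dtype=float)
    selected = [
        int(i)
        for i in np.argsort(-fractions, kind="stable")
        if fractions[i] > threshold
    ]
    if not selected:
        raise HowlIdError(
            f"no component exceeds a variance fraction of {threshold}; "
            "lower the threshold"
        )
    return np.array(selected, dtype=int)


def project(
    model: PCAModel,
    table: pd.DataFrame,
    components: Sequence[int] | np.ndarray | None = None,
) -> pd.DataFrame:
    """Project howls (training or novel) onto the selected components.

    Returns a DataFrame of scores indexed like ``table`` with columns
    ``PC1``, ``PC2``, ... named after the 1-based component numbers.
    """
    X = _feature_matrix(table, model.feature_names)
    Z = (X - model.centers) / model.scales
    if components is None:
        components = np.arange(model.n_features)
    components = np.asarray(components, dtype=int)
    scores = Z @ model.loadings[:, components]
    cols = [f"PC{i + 1}" for i in components]
    return pd.DataFrame(scores, index=table.index, columns=cols)
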