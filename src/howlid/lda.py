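"""Linear discriminant functions on retained principal-component scores.

Given labelled training howls in PC space, this module fits the linear
combinations that best separate individuals: the generalised eigenproblem
``Sb v = λ Sw v`` with ``Sw`` the pooled within-class covariance and ``Sb``
the between-class covariance of the class means.  Discriminant vectors are
normalised so that the within-class variance of every LD score is one (the
convention of classical DFA software), which makes Euclidean distance in LD
space the within-class Mahalanobis distance.  The same fitted "equation" is
then applied to project any howl — training or novel — into LD space, which
is what makes unknown-individual clustering possible downstream.

Classification uses the standard Gaussian linear rule: nearest class centre
in full LD space, shifted by log prior.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .exceptions import HowlIdError, SchemaError

logger = logging.getLogger(__name__)

_SERIAL_VERSION = 1


@dataclass
class LDAModel:
    """A fitted set of linear discriminant functions.

    ``scaling`` maps centred PC coordinates to LD coordinates; its columns
    are the discriminant vectors, each with unit pooled within-class
    variance and the largest-magnitude coefficient forced positive.
    ``discriminant_proportion`` is each LD's share of the between-class
    separation (eigenvalue over eigenvalue sum).
    """

    pc_columns: tuple[str, ...]
    class_labels: tuple[str, ...]
    class_means: np.ndarray  # K x p, in PC space
    grand_mean: np.ndarray  # p,
    scaling: np.ndarray  # p x r
    eigenvalues: np.ndarray  # r,
    discriminant_proportion: np.ndarray  # r,
    priors: np.ndarray  # K,

    @property
    def n_discriminants(self) -> int:
        return self.scaling.shape[1]

    @property
    def class_centers_ld(self) -> np.ndarray:
        """Class means projected into full LD space (K x r)."""
        return (self.class_means - self.grand_mean) @ self.scaling

    # -- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "format": "howlid-lda",
            "version": _SERIAL_VERSION,
            "pc_columns": list(self.pc_columns),
            "class_labels": list(self.class_labels),
            "class_means": self.class_means.tolist(),
            "grand_mean": self.grand_mean.tolist(),
            "scaling": self.scaling.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "discriminant_proportion": self.discriminant_proportion.tolist(),
            "priors": self.priors.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LDAModel":
        if d.get("format") != "howlid-lda":
            raise HowlIdError("not a serialised LDA model")
        return cls(
            pc_columns=tuple(d["pc_columns"]),
            class_labels=tuple(d["class_labels"]),
            class_means=np.array(d["class_means"], dtype=float),
            grand_mean=np.array(d["grand_mean"], dtype=float),
            scaling=np.array(d["scaling"], dtype=float),
            eigenvalues=np.array(d["eigenvalues"], dtype=float),
            discriminant_proportion=np.array(
                d["discriminant_proportion"], dtype=float
            ),
            priors=np.array(d["priors"], dtype=float),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "LDAModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _check_columns(model: LDAModel, scores: pd.DataFrame) -> np.ndarray:
    if tuple(scores.columns) != model.pc_columns:
        raise SchemaError(
            f"score columns {tuple(scores.columns)} do not match the "
            f"model's retained PCs {model.pc_columns}"
        )
    return scores.to_numpy(dtype=float)


def fit_lda(
    scores: pd.DataFrame,
    labels: Sequence[str],
    priors: str = "proportional",
    ridge: float = 1e-8,
) -> LDAModel:
    """Fit linear discriminant functions on labelled PC scores.

    Parameters
    ----------
    scores
        Training howls' retained-PC coordinates (rows = howls).
    labels
        Individual identity per row.
    priors
        ``"proportional"`` (training class frequencies, default) or
        ``"uniform"``.
    ridge
        Relative Tikhonov term added to the pooled within-class covariance
        when it is near-singular.

    Raises
    ------
    HowlIdError
        With fewer than two classes, or when any individual has fewer than
        two howls (its within-class scatter would be undefined).
    """
    X = scores.to_numpy(dtype=float)
    labels = np.asarray(labels, dtype=object)
    if len(labels) != len(X):
        raise HowlIdError(
            f"{len(labels)} labels for {len(X)} score rows"
        )
    class_labels = tuple(sorted(set(labels)))
    K = len(class_labels)
    n, p = X.shape
    if K < 2:
        raise HowlIdError(f"discriminant analysis needs >= 2 classes, got {K}")
    counts = {c: int(np.sum(labels == c)) for c in class_labels}
    singletons = [c for c, m in counts.items() if m < 2]
    if singletons:
        raise HowlIdError(
            f"individual(s) with fewer than 2 howls: {singletons}"
        )
    if n < K + p:
        logger.warning(
            "only %d rows for %d classes in %d dimensions; pooled "
            "within-class covariance is regularised",
            n,
            K,
            p,
        )

    grand_mean = X.mean(axis=0)
    means = np.vstack([X[labels == c].mean(axis=0) for c in class_labels])
    n_k = np.array([counts[c] for c in class_labels], dtype=float)

    Sw = np.zeros((p, p))
    for c, m in zip(class_labels, means):
        D = X[labels == c] - m
        Sw += D.T @ D
    Sw /= n - K
    Sb = (means - grand_mean).T @ (n_k[:, None] * (means - grand_mean)) / (n - K)

    Sw_reg = Sw + ridge * (np.trace(Sw) / p + 1e-30) * np.eye(p)
    eigvals, eigvecs = scipy.linalg.eigh(Sb, Sw_reg)
    order = np.argsort(eigvals)[::-1]
    r = min(K - 1, p)
    eigvals = np.clip(eigvals[order][:r], 0.0, None)
    scaling = eigvecs[:, order][:, :r]  # eigh: v.T @ Sw_reg @ v = I
    for j in range(r):
        i = int(np.argmax(np.abs(scaling[:, j])))
        if scaling[i, j] < 0:
            scaling[:, j] = -scaling[:, j]

    if priors == "proportional":
        pri = n_k / n
    elif priors == "uniform":
        pri = np.full(K, 1.0 / K)
    else:
        raise ValueError(f"unknown priors {priors!r}")

    total = eigvals.sum()
    proportion = eigvals / total if total > 0 else np.full(r, 1.0 / r)
    return LDAModel(
        pc_columns=tuple(scores.columns),
        class_labels=class_labels,
        class_means=means,
        grand_mean=grand_mean,
        scaling=scaling,
        eigenvalues=eigvals,
        discriminant_proportion=proportion,
        priors=pri,
    )


def project_ld(
    model: LDAModel, scores: pd.DataFrame, n_lds: int = 2
) -> pd.DataFrame:
    """Project howls into LD space using the fitted discriminant functions.

    Works identically for training and novel howls; the pooled training
    mean maps to the origin.  Returns columns ``LD1``..``LDn``.
    """
    if n_lds < 1 or n_lds > model.n_discriminants:
        raise HowlIdError(
            f"n_lds={n_lds} outside 1..{model.n_discriminants}"
        )
    X = _check_columns(model, scores)
    Z = (X - model.grand_mean) @ model.scaling[:, :n_lds]
    return pd.DataFrame(
        Z, index=scores.index, columns=[f"LD{j + 1}" for j in range(n_lds)]
    )


def classify(model: LDAModel, scores: pd.DataFrame) -> pd.Series:
    """Assign each howl to the nearest class centre in full LD space.

    The rule is the Gaussian linear discriminant: minimise squared Euclidean
    distance in (within-class-whitened) LD space minus twice the log prior.
    Exact ties go to the lexicographically first class label and are logged.
    """
    X = _check_columns(model, scores)
    Z = (X - model.grand_mean) @ model.scaling
    centers = model.class_centers_ld
    d2 = ((Z[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    disc = -0.5 * d2 + np.log(model.priors)[None, :]
    best = np.argmax(disc, axis=1)  # first maximum = lexicographically first
    near_tie = (
        np.sort(disc, axis=1)[:, -1] - np.sort(disc, axis=1)[:, -2]
    ) < 1e-12
    if np.any(near_tie):
        logger.warning(
            "%d howl(s) equidistant between classes; tie broken to the "
            "lexicographically first label",
            int(near_tie.sum()),
        )
    labels = [model.class_labels[i] for i in best]
    return pd.Series(labels, index=scores.index, name="predicted_label")
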