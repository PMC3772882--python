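"""Least-squares linear discriminant for two-class problems.

A linear discriminant function ``y(x) = w0 + w . x`` is fitted by ordinary
least squares against the class labels (coded -1/+1 by default).  With this
coding the least-squares weight vector is, up to scale, the Fisher
discriminant direction, so the scalar ``y`` ("weight sum") is the usual LDA
projection.  The conventional LDA decision rule thresholds ``y`` at the
midpoint of the two label codes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "AugmentedWeights",
    "LabelVector",
    "encode_labels",
    "fit_least_squares",
    "project",
    "lda_predict",
]

DEFAULT_CODING: tuple[float, float] = (-1.0, 1.0)


@dataclass(frozen=True)
class LabelVector:
    """Numeric label codes plus the class-name-to-code mapping that made them.

    ``classes[0]`` is coded ``coding[0]`` and ``classes[1]`` is ``coding[1]``.
    """

    codes: np.ndarray
    classes: tuple[str, str]
    coding: tuple[float, float] = DEFAULT_CODING

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes, dtype=float)
        object.__setattr__(self, "codes", codes)
        if self.coding[0] == self.coding[1]:
            raise ValueError("label codes must be distinct")

    @property
    def threshold(self) -> float:
        """Midpoint of the two codes — the conventional LDA boundary."""
        return 0.5 * (self.coding[0] + self.coding[1])

    def decode(self, codes: np.ndarray) -> np.ndarray:
        """Map numeric codes back to class names."""
        codes = np.asarray(codes, dtype=float)
        names = np.empty(codes.shape, dtype=object)
        names[codes == self.coding[0]] = self.classes[0]
        names[codes == self.coding[1]] = self.classes[1]
        return names.astype(str)


@dataclass(frozen=True)
class AugmentedWeights:
    """Fitted affine projection: bias ``w0`` plus weight vector ``w``."""

    bias: float
    weights: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        w = np.atleast_1d(np.asarray(self.weights, dtype=float))
        object.__setattr__(self, "weights", w)
        if not np.isfinite(self.bias) or not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite")

    @property
    def n_features(self) -> int:
        return self.weights.shape[0]


def encode_labels(
    class_ids: Sequence[str],
    coding: tuple[float, float] = DEFAULT_CODING,
    classes: tuple[str, str] | None = None,
) -> LabelVector:
    """Code a binary class-name sequence numerically.

    Classes are ordered by first appearance unless ``classes`` fixes the
    order explicitly; the first class gets ``coding[0]``, the second
    ``coding[1]``.

    Raises
    ------
    ValueError
        ``"single-class input"`` if only one class occurs,
        ``"not binary"`` if more than two occur.
    """
    ids = np.asarray([str(c) for c in class_ids], dtype=object)
    seen = list(dict.fromkeys(ids))  # unique, first-appearance order
    if len(seen) < 2:
        raise ValueError("single-class input")
    if len(seen) > 2:
        raise ValueError("not binary")
    if classes is None:
        classes = (seen[0], seen[1])
    elif sorted(classes) != sorted(seen):
        raise ValueError(f"classes {classes} do not match labels present {seen}")
    codes = np.where(ids == classes[0], coding[0], coding[1]).astype(float)
    return LabelVector(codes=codes, classes=(str(classes[0]), str(classes[1])), coding=coding)


def fit_least_squares(
    X: np.ndarray,
    t: LabelVector | np.ndarray,
    ridge: float = 0.0,
    allow_rank_deficient: bool = True,
) -> AugmentedWeights:
    """Fit the discriminant by least squares on the augmented design.

    A dummy input of 1 is prepended to every sample and the augmented
    weight vector minimizing ``||A W - t||^2`` is returned.  Rank-deficient
    designs fall back to the minimum-norm (pseudo-inverse) solution unless
    ``allow_rank_deficient`` is False.  ``ridge`` adds an L2 penalty on the
    non-bias weights for numerically fragile feature sets (default 0: plain
    least squares).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    codes = t.codes if isinstance(t, LabelVector) else np.asarray(t, dtype=float)
    if X.shape[0] != codes.shape[0]:
        raise ValueError("feature matrix and labels disagree in sample count")
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains non-finite entries")
    if np.unique(codes).size < 2:
        raise ValueError("single-class input")

    A = np.column_stack([np.ones(X.shape[0]), X])
    if ridge > 0.0:
        # normal equations with penalty on w only, never on the bias
        penalty = np.eye(A.shape[1]) * ridge
        penalty[0, 0] = 0.0
        W = np.linalg.solve(A.T @ A + penalty, A.T @ codes)
    else:
        W, _, rank, _ = np.linalg.lstsq(A, codes, rcond=None)
        if rank < A.shape[1] and not allow_rank_deficient:
            raise ValueError("rank-deficient design")
    return AugmentedWeights(bias=float(W[0]), weights=W[1:])


def project(w: AugmentedWeights, X: np.ndarray) -> np.ndarray:
    """Weight sums ``y_i = w0 + w . x_i`` for every row of ``X``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != w.n_features:
        raise ValueError("feature dimension mismatch")
    return w.bias + X @ w.weights


def lda_predict(
    scores: np.ndarray, coding: tuple[float, float] = DEFAULT_CODING
) -> np.ndarray:
    """Conventional LDA rule: threshold the weight sum at the code midpoint.

    Scores above the midpoint of the two label codes (0 for the default
    -1/+1 coding) take the second code; scores at or below it take the
    first.  The tie at the exact threshold goes to the first class.
    """
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    threshold = 0.5 * (coding[0] + coding[1])
    return np.where(scores > threshold, coding[1], coding[0])
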