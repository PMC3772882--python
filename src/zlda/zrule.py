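"""The z-score decision rule on top of the least-squares discriminant.

Conventional LDA thresholds the projected weight sum at the midpoint of the
label codes, which is only optimal when the two classes share a covariance.
Here each class's training weight sums are summarized by a Gaussian
(mu_i, sigma_i) and a new sample is assigned to the class whose projected
distribution it sits closest to in z-score units:

    z_i = |y - mu_i| / sigma_i,      assign to argmin_i z_i.

Between the two class means the rule flips exactly once, at

    b = (sigma2 * mu1 + sigma1 * mu2) / (sigma1 + sigma2),

a boundary pulled toward the class with the smaller projected SD.  When the
SDs are equal, b is the midpoint of the means and the rule coincides with
conventional LDA.  Note the z-equality locus has a second crossing in the
far tail on the small-sigma side (|y - mu| grows faster in that class's
units), so the literal z-rule — not a single threshold at b — is what
``zlda_predict`` applies; ``zlda_boundary`` exposes b as a diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .lslda import (
    DEFAULT_CODING,
    AugmentedWeights,
    LabelVector,
    encode_labels,
    fit_least_squares,
    project,
)

__all__ = [
    "ScoreDistribution",
    "ZldaModel",
    "estimate_score_distributions",
    "zscore",
    "zlda_predict",
    "zlda_boundary",
    "classification_confidence",
    "fit_zlda",
]


@dataclass(frozen=True)
class ScoreDistribution:
    """Gaussian summary (mean, SD, count) of one class's training weight sums."""

    mu: float
    sigma: float
    n: int

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if self.n < 1:
            raise ValueError("n must be positive")


@dataclass(frozen=True)
class ZldaModel:
    """Fitted Z-LDA classifier: projection plus the two score distributions."""

    weights: AugmentedWeights
    dist1: ScoreDistribution
    dist2: ScoreDistribution
    coding: tuple[float, float] = DEFAULT_CODING
    classes: tuple[str, str] = ("1", "2")

    def __post_init__(self) -> None:
        if self.dist1.sigma <= 0 or self.dist2.sigma <= 0:
            raise ValueError("degenerate class distribution")
        if self.dist1.mu == self.dist2.mu:
            raise ValueError("class score means coincide; projection is uninformative")

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Class names for the rows of a feature matrix."""
        scores = project(self.weights, X)
        codes = zlda_predict(scores, self)
        label = LabelVector(
            codes=np.asarray(self.coding), classes=self.classes, coding=self.coding
        )
        return label.decode(codes)


def estimate_score_distributions(
    scores: np.ndarray,
    labels: LabelVector,
    ddof: int = 1,
    sigma_floor: float = 0.0,
) -> tuple[ScoreDistribution, ScoreDistribution]:
    """Per-class mean and SD of the training weight sums.

    The SD uses the sample (n-1) denominator by default (``ddof=0`` gives
    the population form).  A zero class SD normally raises, so constant
    features fail loudly; setting ``sigma_floor`` > 0 instead clips the SD
    from below for callers who prefer a floor to an error.
    """
    scores = np.asarray(scores, dtype=float)
    out = []
    for code in labels.coding:
        cls = scores[labels.codes == code]
        if cls.size < 2:
            raise ValueError("insufficient samples for SD")
        sigma = float(np.std(cls, ddof=ddof))
        if sigma <= 0.0:
            if sigma_floor > 0.0:
                sigma = sigma_floor
            else:
                raise ValueError("degenerate class distribution")
        out.append(ScoreDistribution(mu=float(np.mean(cls)), sigma=sigma, n=cls.size))
    return out[0], out[1]


def zscore(y: float | np.ndarray, dist: ScoreDistribution) -> float | np.ndarray:
    """Distance of a weight sum from a class mean in units of the class SD."""
    if dist.sigma <= 0:
        raise ValueError("degenerate class distribution")
    z = np.abs(np.asarray(y, dtype=float) - dist.mu) / dist.sigma
    return float(z) if np.isscalar(y) else z


def zlda_predict(scores: np.ndarray, model: ZldaModel) -> np.ndarray:
    """Assign each score to the class with the smaller z-score.

    Ties (z1 == z2) go to the first class.  Applied literally, so the far
    tail on the small-sigma side belongs to the large-sigma class.
    """
    scores = np.asarray(scores, dtype=float)
    z1 = zscore(scores, model.dist1)
    z2 = zscore(scores, model.dist2)
    return np.where(z1 <= z2, model.coding[0], model.coding[1])


def zlda_boundary(model: ZldaModel) -> float:
    """SD-weighted boundary between the class means (diagnostic value).

    ``b = (sigma2*mu1 + sigma1*mu2) / (sigma1 + sigma2)`` — the unique
    z-equality point strictly between mu1 and mu2, equal to their midpoint
    when the SDs agree.
    """
    s1, s2 = model.dist1.sigma, model.dist2.sigma
    if s1 + s2 <= 0:
        raise ValueError("degenerate")
    return (s2 * model.dist1.mu + s1 * model.dist2.mu) / (s1 + s2)


def classification_confidence(
    y: float | np.ndarray, model: ZldaModel
) -> tuple[np.ndarray, np.ndarray]:
    """Relative per-class reliabilities derived from the z-scores.

    Each class's standard-normal density at its z-score, normalized to sum
    to one: ``r_i = phi(z_i) / (phi(z1) + phi(z2))``.  A heuristic reading
    of "how reliable is this assignment", not a calibrated posterior.
    """
    z1 = np.asarray(zscore(y, model.dist1), dtype=float)
    z2 = np.asarray(zscore(y, model.dist2), dtype=float)
    # shared phi normalization cancels; subtract the max exponent for stability
    e = np.stack([-0.5 * z1**2, -0.5 * z2**2])
    e -= e.max(axis=0)
    d = np.exp(e)
    r1, r2 = d[0] / d.sum(axis=0), d[1] / d.sum(axis=0)
    if np.isscalar(y):
        return float(r1), float(r2)
    return r1, r2


def fit_zlda(
    X: np.ndarray,
    class_ids: Sequence[str],
    coding: tuple[float, float] = DEFAULT_CODING,
    classes: tuple[str, str] | None = None,
    ddof: int = 1,
    sigma_floor: float = 0.0,
    ridge: float = 0.0,
) -> ZldaModel:
    """Fit the full Z-LDA model: least-squares projection + score Gaussians."""
    labels = encode_labels(class_ids, coding=coding, classes=classes)
    weights = fit_least_squares(X, labels, ridge=ridge)
    scores = project(weights, X)
    dist1, dist2 = estimate_score_distributions(
        scores, labels, ddof=ddof, sigma_floor=sigma_floor
    )
    return ZldaModel(
        weights=weights, dist1=dist1, dist2=dist2, coding=coding, classes=labels.classes
    )
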