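"""EEG front-end: artifact rejection, band-pass filtering, CSP, log-variance.

Common spatial patterns (CSP) finds spatial filters w that maximize the
variance of the filtered signal under one motor-imagery task while
minimizing it under the other.  With trace-normalized per-trial covariances
averaged within class (C1, C2), the filters solve the generalized
eigenproblem C1 w = lambda (C1 + C2) w; eigenvalue lambda_k is the class-1
fraction of the filtered variance, so filters at both ends of the spectrum
are the discriminative ones.  Band power of each filtered "surrogate
channel" — the log of its variance — is the classification feature.

A seeded synthetic trial generator (latent sources with class-dependent
variances mixed into channels plus sensor noise) makes the whole pipeline
testable without recorded EEG.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, signal

__all__ = [
    "TrialArray",
    "SpatialFilterBank",
    "SynthEEGConfig",
    "reject_artifacts",
    "bandpass_filter",
    "fit_csp",
    "select_filter_pairs",
    "log_variance_features",
    "generate_synthetic_trials",
]


@dataclass(frozen=True)
class TrialArray:
    """Segmented multichannel EEG: trials x channels x samples, in microvolts."""

    data: np.ndarray = field(repr=False)
    fs: float
    labels: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        labels = np.asarray(self.labels)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "labels", labels)
        if data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if data.shape[1] < 2:
            raise ValueError("need at least two channels")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if labels.shape[0] != data.shape[0]:
            raise ValueError("one label per trial required")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class SpatialFilterBank:
    """CSP solution: one spatial filter per row, eigenvalues sorted descending.

    ``eigenvalues[k]`` is the class-1 variance fraction of filter k (the
    class-2 fraction is its complement).
    """

    filters: np.ndarray = field(repr=False)
    eigenvalues: np.ndarray
    classes: tuple[str, str] = ("1", "2")

    def __post_init__(self) -> None:
        ev = np.asarray(self.eigenvalues, dtype=float)
        object.__setattr__(self, "eigenvalues", ev)
        object.__setattr__(self, "filters", np.asarray(self.filters, dtype=float))
        if np.any(np.diff(ev) > 1e-12):
            raise ValueError("eigenvalues must be sorted descending")


def reject_artifacts(trials: TrialArray, threshold: float = 300.0) -> TrialArray:
    """Drop trials whose peak absolute amplitude exceeds ``threshold`` (µV).

    Large excursions in scalp EEG are dominated by ocular and movement
    artifacts, not brain activity; 300 µV is the conventional cut.  Trial
    order is preserved.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    keep = np.max(np.abs(trials.data), axis=(1, 2)) <= threshold
    if not np.any(keep):
        raise ValueError("no trials survive rejection")
    return TrialArray(data=trials.data[keep], fs=trials.fs, labels=trials.labels[keep])


def bandpass_filter(
    trials: TrialArray, band: tuple[float, float], order: int = 4
) -> TrialArray:
    """Zero-phase Butterworth band-pass applied per channel.

    The filter runs forward and backward (``sosfiltfilt``), so the passband
    is phase-neutral and variance-based features see no group delay.
    """
    lo, hi = band
    nyq = trials.fs / 2.0
    if not (0.0 < lo < hi < nyq):
        raise ValueError("band outside Nyquist range")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=trials.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, trials.data, axis=-1)
    return TrialArray(data=filtered, fs=trials.fs, labels=trials.labels)


def _class_covariances(
    trials: TrialArray, classes: tuple[str, str] | None = None
) -> tuple[np.ndarray, np.ndarray, tuple[str, str]]:
    present = list(dict.fromkeys(trials.labels.tolist()))
    if len(present) < 2:
        raise ValueError("single-class input")
    if len(present) > 2:
        raise ValueError("not binary")
    if classes is None:
        classes = present
    elif sorted(classes) != sorted(present):
        raise ValueError(f"classes {classes} do not match labels present {present}")
    covs = []
    for cls in classes:
        acc = np.zeros((trials.n_channels, trials.n_channels))
        members = trials.data[trials.labels == cls]
        for X in members:
            Xc = X - X.mean(axis=1, keepdims=True)
            C = Xc @ Xc.T
            tr = np.trace(C)
            if tr <= 0:
                raise ValueError("singular covariance (enable shrinkage)")
            acc += C / tr
        covs.append(acc / len(members))
    return covs[0], covs[1], (str(classes[0]), str(classes[1]))


def fit_csp(
    trials: TrialArray,
    shrinkage: float = 0.0,
    classes: tuple[str, str] | None = None,
) -> SpatialFilterBank:
    """Fit CSP spatial filters from labelled trials.

    Per-trial covariances are trace-normalized and averaged within class;
    the filters jointly diagonalize the two class means, with eigenvalue
    lambda_k = w_k' C1 w_k under the normalization w_k' (C1 + C2) w_k = 1.
    ``classes`` fixes which label plays class 1 (default: first appearance);
    swapping it mirrors the spectrum.  ``shrinkage`` in [0, 1] blends each
    class covariance toward a scaled identity (Ledoit-style scalar target)
    for rank-deficient data.
    """
    if not 0.0 <= shrinkage <= 1.0:
        raise ValueError("shrinkage must lie in [0, 1]")
    C1, C2, classes = _class_covariances(trials, classes=classes)
    if shrinkage > 0.0:
        nc = trials.n_channels
        C1 = (1 - shrinkage) * C1 + shrinkage * np.eye(nc) * np.trace(C1) / nc
        C2 = (1 - shrinkage) * C2 + shrinkage * np.eye(nc) * np.trace(C2) / nc
    composite = C1 + C2
    # generalized symmetric eigenproblem; fails on singular composite
    min_eig = np.min(linalg.eigvalsh(composite))
    if min_eig <= 1e-10 * np.trace(composite):
        raise ValueError("singular covariance (enable shrinkage)")
    eigenvalues, eigenvectors = linalg.eigh(C1, composite)
    order = np.argsort(eigenvalues)[::-1]
    return SpatialFilterBank(
        filters=eigenvectors[:, order].T,
        eigenvalues=np.clip(eigenvalues[order], 0.0, 1.0),
        classes=classes,
    )


def select_filter_pairs(bank: SpatialFilterBank, n_pairs: int = 3) -> np.ndarray:
    """The ``n_pairs`` most discriminative filters from each end of the spectrum.

    Filters with eigenvalues far from 0.5 in either direction carry the
    class-variance contrast; the default 3 pairs yields 6 surrogate channels.
    """
    n_filters = bank.filters.shape[0]
    if n_pairs < 1 or 2 * n_pairs > n_filters:
        raise ValueError(
            f"n_pairs must satisfy 1 <= 2*n_pairs <= {n_filters} filters"
        )
    idx = list(range(n_pairs)) + list(range(n_filters - n_pairs, n_filters))
    return bank.filters[idx]


def log_variance_features(trials: TrialArray, filters: np.ndarray) -> np.ndarray:
    """Log band-power features: log variance of each spatially filtered trial.

    Returns a trials x filters matrix; the variance is the population form
    over samples.
    """
    filters = np.atleast_2d(np.asarray(filters, dtype=float))
    if filters.size == 0:
        raise ValueError("filters must be nonempty")
    if filters.shape[1] != trials.n_channels:
        raise ValueError("feature dimension mismatch")
    projected = np.einsum("fc,tcs->tfs", filters, trials.data)
    variances = projected.var(axis=-1)
    if np.any(variances <= 0):
        raise ValueError("log of zero variance")
    return np.log(variances)


@dataclass(frozen=True)
class SynthEEGConfig:
    """Generator settings for synthetic motor-imagery-like trials.

    Latent sources with class-dependent variances are mixed into channels
    through a fixed random orthogonal matrix, scaled to microvolt range,
    with additive white sensor noise.  The defaults give two discriminative
    sources with a 4:1 variance flip between classes against a unit-variance
    background, roughly emulating lateralized sensorimotor band power.
    """

    n_channels: int = 15
    n_samples: int = 500
    n_trials_per_class: int = 100
    fs: float = 250.0
    class1_source_vars: tuple[float, ...] = (4.0, 1.0)
    class2_source_vars: tuple[float, ...] = (1.0, 4.0)
    n_background: int | None = None  # defaults to n_channels - n_sources
    amplitude_uv: float = 10.0
    noise_sd_uv: float = 1.0
    mixing_seed: int = 0
    class_names: tuple[str, str] = ("left", "right")

    def __post_init__(self) -> None:
        if len(self.class1_source_vars) != len(self.class2_source_vars):
            raise ValueError("per-class source variance tuples must align")
        if min(self.class1_source_vars) <= 0 or min(self.class2_source_vars) <= 0:
            raise ValueError("source variances must be positive")
        n_bg = self.n_background
        n_src = len(self.class1_source_vars)
        if n_bg is None:
            n_bg = self.n_channels - n_src
        if n_bg < 0 or n_src + n_bg > self.n_channels:
            raise ValueError("more sources than channels")

    @property
    def n_sources(self) -> int:
        n_bg = self.n_background
        if n_bg is None:
            n_bg = self.n_channels - len(self.class1_source_vars)
        return len(self.class1_source_vars) + n_bg


def generate_synthetic_trials(
    cfg: SynthEEGConfig, seed: int | np.random.SeedSequence
) -> TrialArray:
    """Draw a seeded synthetic trial set (class-1 trials first, then class-2)."""
    mix_rng = np.random.default_rng(cfg.mixing_seed)
    # fixed orthonormal mixing, independent of the trial-noise seed
    A = linalg.qr(mix_rng.standard_normal((cfg.n_channels, cfg.n_channels)))[0]
    A = A[:, : cfg.n_sources]

    rng = np.random.default_rng(seed)
    n_disc = len(cfg.class1_source_vars)
    n_bg = cfg.n_sources - n_disc
    trials, labels = [], []
    for name, disc_vars in (
        (cfg.class_names[0], cfg.class1_source_vars),
        (cfg.class_names[1], cfg.class2_source_vars),
    ):
        sd = np.sqrt(np.concatenate([np.asarray(disc_vars, float), np.ones(n_bg)]))
        for _ in range(cfg.n_trials_per_class):
            sources = rng.standard_normal((cfg.n_sources, cfg.n_samples)) * sd[:, None]
            x = cfg.amplitude_uv * (A @ sources)
            x += rng.standard_normal(x.shape) * cfg.noise_sd_uv
            trials.append(x)
            labels.append(name)
    return TrialArray(data=np.asarray(trials), fs=cfg.fs, labels=np.asarray(labels))
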