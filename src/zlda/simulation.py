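"""Monte-Carlo comparison of LDA and Z-LDA on heteroscedastic 2-D Gaussians.

Two bivariate Gaussian classes are drawn with means (-1, -0.6) and (1, 0.6)
and per-dimension SD 0.3; heteroscedasticity is introduced by adding a
constant ``sd_delta`` to each component of the class-2 SD, sweeping delta
from 0.0 to 0.9.  (Measured as the norm of the SD-difference vector the
levels are delta * sqrt(2).)  For each level, fresh train and test sets of
100 samples per class are generated, both classifiers are fitted on the
train set, test accuracy is recorded, and the draw is repeated 100 times;
a paired t-test compares the per-repetition accuracy vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .lslda import encode_labels, fit_least_squares, lda_predict, project
from .zrule import estimate_score_distributions, zlda_predict, ZldaModel

__all__ = [
    "SimulationConfig",
    "DEFAULT_LEVELS",
    "generate_gaussian_2class",
    "run_single_repetition",
    "run_study",
    "paired_t_test",
]

DEFAULT_LEVELS: tuple[float, ...] = tuple(np.round(np.arange(0.0, 1.0, 0.1), 10))

CLASS1, CLASS2 = "class1", "class2"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the two-Gaussian comparison (defaults as above)."""

    mean1: tuple[float, ...] = (-1.0, -0.6)
    mean2: tuple[float, ...] = (1.0, 0.6)
    sd1: tuple[float, ...] = (0.3, 0.3)
    sd2: tuple[float, ...] = (0.3, 0.3)
    sd_delta: float = 0.0
    n_per_class_train: int = 100
    n_per_class_test: int = 100
    n_reps: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd_delta < 0:
            raise ValueError("sd_delta must be nonnegative")
        if min(self.n_per_class_train, self.n_per_class_test, self.n_reps) < 1:
            raise ValueError("sample and repetition counts must be positive")
        if min(self.sd1) <= 0 or min(self.sd2) <= 0:
            raise ValueError("SDs must be strictly positive")

    @property
    def class2_sd(self) -> np.ndarray:
        return np.asarray(self.sd2, dtype=float) + self.sd_delta


def generate_gaussian_2class(
    cfg: SimulationConfig,
    seed: int | tuple | np.random.SeedSequence | np.random.Generator,
    n_per_class: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one labelled dataset: class-1 rows first, then class-2.

    Per-dimension independent Gaussians; deterministic given the seed.
    ``n_per_class`` defaults to the training-set size in ``cfg``.
    """
    rng = np.random.default_rng(seed)
    n = cfg.n_per_class_train if n_per_class is None else int(n_per_class)
    if n < 1:
        raise ValueError("n_per_class must be positive")
    X1 = rng.normal(cfg.mean1, cfg.sd1, size=(n, len(cfg.mean1)))
    X2 = rng.normal(cfg.mean2, cfg.class2_sd, size=(n, len(cfg.mean2)))
    X = np.vstack([X1, X2])
    labels = np.array([CLASS1] * n + [CLASS2] * n)
    return X, labels


def run_single_repetition(
    cfg: SimulationConfig,
    seed: int | tuple | np.random.SeedSequence,
) -> tuple[float, float]:
    """One train/test draw; returns (LDA accuracy %, Z-LDA accuracy %).

    The seed may be an int or an entropy tuple such as
    ``(master_seed, level_index, repetition)``, so any repetition of a study
    is reproducible in isolation.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    train_ss, test_ss = ss.spawn(2)
    Xtr, ids_tr = generate_gaussian_2class(cfg, train_ss, cfg.n_per_class_train)
    Xte, ids_te = generate_gaussian_2class(cfg, test_ss, cfg.n_per_class_test)

    labels_tr = encode_labels(ids_tr, classes=(CLASS1, CLASS2))
    weights = fit_least_squares(Xtr, labels_tr)
    scores_tr = project(weights, Xtr)
    scores_te = project(weights, Xte)
    truth = encode_labels(ids_te, classes=(CLASS1, CLASS2)).codes

    acc_lda = 100.0 * np.mean(lda_predict(scores_te) == truth)

    d1, d2 = estimate_score_distributions(scores_tr, labels_tr)
    model = ZldaModel(weights=weights, dist1=d1, dist2=d2, classes=(CLASS1, CLASS2))
    acc_zlda = 100.0 * np.mean(zlda_predict(scores_te, model) == truth)
    return float(acc_lda), float(acc_zlda)


def run_study(
    cfg: SimulationConfig | None = None,
    levels: tuple[float, ...] = DEFAULT_LEVELS,
) -> pd.DataFrame:
    """Full accuracy comparison across SD-difference levels.

    Returns one row per level with mean and SD (over repetitions) of each
    classifier's accuracy in percent, plus the paired-t statistic and
    two-sided p-value of the per-repetition accuracy differences.  A level
    where every repetition ties exactly (typically level 0) reports NaN for
    t and p.
    """
    if cfg is None:
        cfg = SimulationConfig()
    if len(levels) == 0:
        raise ValueError("levels must be nonempty")
    rows = []
    for li, delta in enumerate(levels):
        level_cfg = replace(cfg, sd_delta=float(delta))
        accs = np.array(
            [
                run_single_repetition(level_cfg, (cfg.seed, li, rep))
                for rep in range(cfg.n_reps)
            ]
        )
        lda_acc, zlda_acc = accs[:, 0], accs[:, 1]
        try:
            t, p = paired_t_test(zlda_acc, lda_acc)
        except ValueError:
            t, p = np.nan, np.nan
        rows.append(
            {
                "level": float(delta),
                "lda_mean": lda_acc.mean(),
                "lda_sd": lda_acc.std(ddof=1) if cfg.n_reps > 1 else 0.0,
                "zlda_mean": zlda_acc.mean(),
                "zlda_sd": zlda_acc.std(ddof=1) if cfg.n_reps > 1 else 0.0,
                "t": t,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def paired_t_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided paired t-test on the differences a - b (df = n - 1).

    Raises ``"degenerate t"`` when the differences have zero variance
    (including a == b exactly), where the statistic is undefined.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length vectors")
    if a.size < 2:
        raise ValueError("need at least two pairs")
    diff = a - b
    if np.std(diff, ddof=1) == 0.0:
        raise ValueError("degenerate t")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)
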