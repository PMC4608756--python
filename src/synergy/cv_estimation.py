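"""Estimation of per-muscle coefficients of variation from EMG summaries.

Signal-dependent noise predicts a linear relation between the mean and the
standard deviation of a muscle's EMG across force conditions; the slope of
that line is the muscle's coefficient of variation ``alpha``.  In practice
``alpha`` is estimated by regressing the SD of the EMG envelope on its mean
over a battery of isometric force conditions (directions x magnitudes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["ForceTaskSummary", "CVEstimate", "estimate_cv", "synth_force_task"]


@dataclass(frozen=True)
class ForceTaskSummary:
    """(mean, SD) EMG pairs for one muscle across force conditions."""

    pairs: np.ndarray  # (m, 2) columns: mean, sd
    muscle_label: str = ""

    def __post_init__(self) -> None:
        pairs = np.atleast_2d(np.asarray(self.pairs, dtype=float))
        object.__setattr__(self, "pairs", pairs)
        if pairs.shape[0] < 3 or pairs.shape[1] != 2:
            raise ValueError("need at least 3 (mean, sd) pairs")
        if np.any(pairs[:, 0] <= 0):
            raise ValueError("mean EMG values must be > 0")
        if np.any(pairs[:, 1] < 0):
            raise ValueError("EMG SDs must be >= 0")

    @property
    def means(self) -> np.ndarray:
        return self.pairs[:, 0]

    @property
    def sds(self) -> np.ndarray:
        return self.pairs[:, 1]


@dataclass(frozen=True)
class CVEstimate:
    """Fitted SDN slope for one muscle.

    ``alpha`` is the regression slope of SD on mean; ``correlation`` is the
    Pearson correlation of the raw (mean, SD) points.
    """

    alpha: float
    correlation: float
    n_points: int
    intercept: float
    muscle_label: str = ""


def estimate_cv(
    summary: ForceTaskSummary, through_origin: bool = False
) -> CVEstimate:
    """Estimate a muscle's coefficient of variation by linear regression.

    Ordinary least squares of SD on mean: ``sd = intercept + alpha * mean``.
    With ``through_origin=True`` the intercept is forced to zero (the pure
    SDN model), and ``alpha = sum(mean*sd) / sum(mean**2)``.  The Pearson
    correlation is always computed on the raw pairs.
    """
    x, y = summary.means, summary.sds
    if np.ptp(x) == 0:
        raise ValueError("all means identical: slope undefined")
    if np.ptp(y) == 0:
        correlation = 0.0  # flat SD carries no linear association
    else:
        correlation = float(stats.pearsonr(x, y).statistic)
    if through_origin:
        alpha = float(np.dot(x, y) / np.dot(x, x))
        intercept = 0.0
    else:
        fit = stats.linregress(x, y)
        alpha, intercept = float(fit.slope), float(fit.intercept)
    return CVEstimate(
        alpha=alpha,
        correlation=correlation,
        n_points=x.size,
        intercept=intercept,
        muscle_label=summary.muscle_label,
    )


def synth_force_task(
    alpha_true: float,
    magnitudes=(5.0, 10.0, 15.0),
    n_directions: int = 16,
    noise_sd: float = 0.005,
    seed: int | np.random.Generator = 0,
    muscle_label: str = "",
) -> ForceTaskSummary:
    """Generate a synthetic isometric-force-battery EMG summary.

    Emulates a task in which a muscle is engaged at ``n_directions`` force
    directions and ``len(magnitudes)`` force magnitudes.  The muscle's mean
    EMG follows cosine direction tuning (floored at a small baseline) and
    scales with magnitude; the SD is ``alpha_true * mean`` plus additive
    Gaussian noise, so a regression of SD on mean should recover
    ``alpha_true``.
    """
    if alpha_true < 0:
        raise ValueError("alpha_true must be >= 0")
    rng = np.random.default_rng(seed)
    directions = np.linspace(0.0, 2.0 * np.pi, n_directions, endpoint=False)
    pref = rng.uniform(0.0, 2.0 * np.pi)
    # engagement in (0, 1]: half-rectified cosine tuning with a 0.05 floor
    engagement = np.maximum(np.cos(directions - pref), 0.0) * 0.95 + 0.05
    mags = np.asarray(magnitudes, dtype=float)
    # mean MVC-normalized EMG ~ engagement * magnitude, scaled into [0, ~0.6]
    means = (engagement[:, None] * mags[None, :] / mags.max() * 0.6).ravel()
    sds = alpha_true * means + rng.normal(0.0, noise_sd, means.size)
    sds = np.abs(sds)
    return ForceTaskSummary(
        np.column_stack([means, sds]), muscle_label=muscle_label
    )
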