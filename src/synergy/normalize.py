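"""Transformation of SDN muscle tensions into signal-independent commands.

Signal-dependent noise gives each mixture component a spread proportional
to its mean (``alpha_i * mu_k``), so muscles at high activation look
intrinsically more variable.  To compare variability across muscles on an
equal footing, each component's spread is rescaled to a single common
standard deviation ``beta`` while keeping its mean fixed:

    T_hat = T + sum_k gamma_k (T - mu_k) (beta / (alpha_i mu_k) - 1)

where ``gamma_k`` are the converged EM responsibilities.  The transformed
values are interpreted as the motor-command sample: what the trials would
have looked like had every muscle carried the same signal-independent
noise.  ``beta`` is the mean of ``alpha_i * mu_k`` over all muscles and
components, so the transform is overall scale-preserving.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Sequence

import numpy as np

from .mixture import SDNMixtureFit
from .plant import TrialSet

__all__ = ["NormalizedTrialSet", "compute_beta", "normalize_trialset"]


@dataclass(frozen=True)
class NormalizedTrialSet:
    """Motor-command estimates: tensions with SDN spread equalized to beta."""

    commands: np.ndarray  # (N, n), same shape as the source tensions
    beta: float
    source: TrialSet | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "commands", np.atleast_2d(np.asarray(self.commands, float))
        )
        if self.beta <= 0:
            raise ValueError("beta must be > 0")


def compute_beta(
    fits: Sequence[SDNMixtureFit], pi_weighted: bool = False
) -> float:
    """Common signal-independent spread: mean of ``alpha_i * mu_k``.

    By default every (muscle, component) pair contributes equally; with
    ``pi_weighted=True`` each muscle's components are weighted by their
    mixing proportions instead.
    """
    if len(fits) == 0:
        raise ValueError("need at least one mixture fit")
    if pi_weighted:
        per_muscle = [float(f.mixing @ (f.alpha * f.means)) for f in fits]
        return float(np.mean(per_muscle))
    products = np.concatenate([f.alpha * f.means for f in fits])
    return float(products.mean())


def normalize_trialset(
    trials: TrialSet,
    fits: Sequence[SDNMixtureFit],
    beta: float | None = None,
) -> NormalizedTrialSet:
    """Rescale each muscle's per-component spread to the common beta.

    ``fits[i]`` must be the converged mixture for column ``i`` of
    ``trials``, with responsibilities computed on these exact trials.
    Component means are unchanged; the responsibility-weighted spread of
    each component becomes ``beta`` (up to the soft-assignment overlap
    between components).  When ``alpha_i * mu_k == beta`` for every
    component the transform is the identity.
    """
    if len(fits) != trials.n_muscles:
        raise ValueError("need one mixture fit per muscle column")
    if beta is None:
        beta = compute_beta(fits)
    if beta <= 0:
        raise ValueError("beta must be > 0")
    T = trials.tensions
    out = np.empty_like(T)
    for i, fit in enumerate(fits):
        if fit.responsibilities.shape != (trials.n_trials, fit.K):
            raise ValueError(
                f"fit {i}: responsibilities shape "
                f"{fit.responsibilities.shape} does not match trials"
            )
        col = T[:, i]
        scale = beta / (fit.alpha * fit.means) - 1.0  # (K,)
        shift = (fit.responsibilities * (col[:, None] - fit.means[None, :])) @ scale
        out[:, i] = col + shift
    return NormalizedTrialSet(out, beta=float(beta), source=trials)
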