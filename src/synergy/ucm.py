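"""Uncontrolled-manifold (UCM) variance decomposition and synergy indices.

A redundant task maps ``n`` motor elements to a ``d``-dimensional
performance variable through a matrix ``A``.  Element combinations inside
the null space of ``A`` (the UCM) leave the performance variable unchanged.
Trial-to-trial deviations from the mean element vector are split into a
component parallel to the UCM and its orthogonal complement; their
per-dimension variances ``V_UCM`` and ``V_ORT`` quantify how much of the
variability is task-irrelevant versus task-affecting.

The raw synergy index is ``dV = (V_UCM - V_ORT) / V_TOT`` with ``V_TOT``
the total variance per element dimension.  It is bounded in
``[-n/d, n/(n-d)]`` and not Gaussian, so inference uses its Fisher
Z-transform ``dV* = ln((dV + n/d) / (n/(n-d) - dV))``, whose
no-coordination reference (``V_UCM = V_ORT``) depends only on ``(n, d)``
and equals ``ln 7 ~= 1.95`` for eight elements and a scalar performance
variable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import null_space

__all__ = [
    "UCMResult",
    "null_basis",
    "ucm_decompose",
    "delta_v",
    "fisher_z",
    "inverse_fisher_z",
    "no_coordination_value",
    "ratio_of_change",
]


@dataclass(frozen=True)
class UCMResult:
    """Variance decomposition of one trial set relative to a task map."""

    v_ucm: float
    v_ort: float
    v_tot: float
    delta_v: float
    delta_v_star: float
    n: int
    d: int
    basis: np.ndarray  # (n, n-d) orthonormal null-space vectors

    def __post_init__(self) -> None:
        object.__setattr__(self, "basis", np.asarray(self.basis, dtype=float))


def null_basis(A: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the null space of a full-row-rank ``(d, n)`` map.

    Returns an ``(n, n-d)`` matrix whose columns are mutually orthonormal
    and annihilated by ``A``.  The sign convention fixes each column's
    first nonzero-magnitude coordinate to be positive, making the basis
    deterministic up to the underlying SVD.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    d, n = A.shape
    if n <= d:
        raise ValueError("need more elements than performance dimensions")
    if np.linalg.matrix_rank(A) < d:
        raise ValueError("task map must have full row rank")
    E = null_space(A)
    if E.shape[1] != n - d:
        raise ValueError("unexpected null-space dimension")
    for j in range(E.shape[1]):
        col = E[:, j]
        lead = col[np.abs(col) > 1e-12][0]
        if lead < 0:
            E[:, j] = -col
    return E


def ucm_decompose(
    trials: np.ndarray, A: np.ndarray, ddof: int = 0
) -> UCMResult:
    """Decompose trial-to-trial variance into UCM and orthogonal parts.

    Each trial's deviation from the column-mean vector is projected onto
    the null-space basis of ``A``; ``v_ucm`` is the mean squared parallel
    deviation per UCM dimension, ``v_ort`` the mean squared residual per
    orthogonal dimension, and ``v_tot`` the mean squared deviation per
    element dimension.  ``ddof=0`` (population convention) divides by the
    number of trials; ``ddof=1`` uses N-1.
    """
    T = np.atleast_2d(np.asarray(trials, dtype=float))
    N, n = T.shape
    if N < 2:
        raise ValueError("need at least 2 trials")
    A = np.atleast_2d(np.asarray(A, dtype=float))
    d = A.shape[0]
    if A.shape[1] != n:
        raise ValueError("task map columns must match trial columns")
    E = null_basis(A)
    dev = T - T.mean(axis=0)
    par = (dev @ E) @ E.T
    ort = dev - par
    denom = N - ddof
    v_ucm = float(np.sum(par**2) / denom / (n - d))
    v_ort = float(np.sum(ort**2) / denom / d)
    v_tot = float(np.sum(dev**2) / denom / n)
    dv = delta_v(v_ucm, v_ort, v_tot)
    dvs = fisher_z(dv, n, d)
    return UCMResult(
        v_ucm=v_ucm,
        v_ort=v_ort,
        v_tot=v_tot,
        delta_v=dv,
        delta_v_star=dvs,
        n=n,
        d=d,
        basis=E,
    )


def delta_v(v_ucm: float, v_ort: float, v_tot: float) -> float:
    """Raw synergy index ``(V_UCM - V_ORT) / V_TOT``."""
    if v_tot <= 0:
        raise ValueError("v_tot must be > 0 (degenerate trial set)")
    return (v_ucm - v_ort) / v_tot


def fisher_z(dv: float, n: int, d: int) -> float:
    """Fisher Z-transform of the synergy index for an (n, d) task.

    ``dV* = ln((dV + n/d) / (n/(n-d) - dV))``; strictly increasing on the
    open interval ``(-n/d, n/(n-d))``.  At a bound the transform diverges:
    signed infinity is returned with a warning rather than clipping.
    """
    lo, hi = -n / d, n / (n - d)
    if dv <= lo or dv >= hi:
        warnings.warn(
            f"delta_v={dv} at or beyond its bounds ({lo}, {hi}); "
            "Fisher Z is infinite",
            RuntimeWarning,
            stacklevel=2,
        )
        return float(np.inf if dv >= hi else -np.inf)
    return float(np.log((dv + n / d) / (n / (n - d) - dv)))


def inverse_fisher_z(dv_star: float, n: int, d: int) -> float:
    """Invert the Fisher Z transform back to the raw index."""
    ez = np.exp(dv_star)
    return float((ez * n / (n - d) - n / d) / (1.0 + ez))


def no_coordination_value(n: int, d: int) -> float:
    """Fisher-Z index when V_UCM = V_ORT: ``ln((n/d) / (n/(n-d)))``."""
    return fisher_z(0.0, n, d)


def ratio_of_change(
    pre_measured: float,
    post_measured: float,
    pre_normalized: float,
    post_normalized: float,
) -> float:
    """Percent of the measured synergy change explained by command change.

    ``100 * (post_norm - pre_norm) / (post_meas - pre_meas)``; 100% means
    the change in the measured index is fully accounted for by the change
    in the normalized (motor-command) index.
    """
    d_meas = post_measured - pre_measured
    if d_meas == 0:
        raise ValueError("measured index did not change; ratio undefined")
    return 100.0 * (post_normalized - pre_normalized) / d_meas
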