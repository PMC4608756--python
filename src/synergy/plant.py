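"""Musculoskeletal plant model and signal-dependent-noise (SDN) simulation.

The plant is an isometric muscle-to-torque map: ``n`` muscle tensions ``T``
produce a ``d``-dimensional joint torque ``tau = A @ T`` through a constant
transformation matrix ``A`` of moment arms.  Each muscle's trial-to-trial
tension variability follows signal-dependent noise: for a commanded input
``e_i`` the realized tension is

    T_i = e_i + e_i * alpha_i * N(0, 1)

so the standard deviation scales linearly with the mean, with per-muscle
coefficient of variation ``alpha_i``.

Also provided: the visual-feedback torque distortion used in tracking
experiments, half-sine target trajectories, and the time-outside-margin
tracking score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MusclePlant",
    "InputVector",
    "TrialSet",
    "TorqueSet",
    "FeedbackConfig",
    "TrackingScore",
    "default_plant",
    "simulate_tensions",
    "compute_torque",
    "feedback_torque",
    "make_target_trajectory",
    "target_segments",
    "time_out_of_margin",
    "UNCOORDINATED_INPUT",
    "COORDINATED_INPUTS",
    "table1_input",
]


@dataclass(frozen=True)
class MusclePlant:
    """Constant isometric plant: torque map plus per-muscle noise levels.

    Parameters
    ----------
    torque_map
        ``(d, n)`` matrix ``A`` mapping muscle tensions to joint torques,
        in N·m per unit tension.  Must have full row rank with ``n > d``.
    cv
        Length-``n`` vector of coefficients of variation ``alpha_i >= 0``
        (SDN slope of each muscle).
    muscle_labels
        ``n`` muscle names.
    """

    torque_map: np.ndarray
    cv: np.ndarray
    muscle_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        A = np.atleast_2d(np.asarray(self.torque_map, dtype=float))
        cv = np.asarray(self.cv, dtype=float).ravel()
        object.__setattr__(self, "torque_map", A)
        object.__setattr__(self, "cv", cv)
        object.__setattr__(self, "muscle_labels", tuple(self.muscle_labels))
        d, n = A.shape
        if not (n > d >= 1):
            raise ValueError(f"need n > d >= 1, got A of shape {A.shape}")
        if np.linalg.matrix_rank(A) < d:
            raise ValueError("torque map must have full row rank")
        if cv.shape != (n,):
            raise ValueError("cv length must match number of muscles")
        if np.any(cv < 0):
            raise ValueError("coefficients of variation must be >= 0")
        if len(self.muscle_labels) != n:
            raise ValueError("muscle_labels length must match number of muscles")

    @property
    def n_muscles(self) -> int:
        return self.torque_map.shape[1]

    @property
    def n_torques(self) -> int:
        return self.torque_map.shape[0]


@dataclass(frozen=True)
class InputVector:
    """Commanded tensions ``e`` (one per muscle), all non-negative."""

    e: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        e = np.asarray(self.e, dtype=float).ravel()
        object.__setattr__(self, "e", e)
        if np.any(e < 0):
            raise ValueError("commanded tensions must be >= 0")


@dataclass(frozen=True)
class TrialSet:
    """``(N, n)`` matrix of muscle tensions across ``N`` trials."""

    tensions: np.ndarray
    condition: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        T = np.atleast_2d(np.asarray(self.tensions, dtype=float))
        object.__setattr__(self, "tensions", T)
        if T.shape[0] < 2:
            raise ValueError("a trial set needs at least 2 trials")
        if not np.all(np.isfinite(T)):
            raise ValueError("tensions must be finite")

    @property
    def n_trials(self) -> int:
        return self.tensions.shape[0]

    @property
    def n_muscles(self) -> int:
        return self.tensions.shape[1]


@dataclass(frozen=True)
class TorqueSet:
    """``(N, d)`` torques produced by a trial set."""

    torques: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "torques", np.atleast_2d(np.asarray(self.torques, dtype=float))
        )


@dataclass(frozen=True)
class FeedbackConfig:
    """Tracking-task feedback: error-amplification gain and target margin."""

    gain: float
    target: np.ndarray = field(default_factory=lambda: np.zeros(0))
    margin: float = 0.3

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be > 0")
        if self.margin <= 0:
            raise ValueError("margin must be > 0")
        object.__setattr__(self, "target", np.asarray(self.target, dtype=float))


@dataclass(frozen=True)
class TrackingScore:
    """Seconds spent outside the tracking margin during one trial."""

    t_out: float
    trial_duration: float

    def __post_init__(self) -> None:
        if not (0 <= self.t_out <= self.trial_duration):
            raise ValueError("t_out must lie in [0, trial_duration]")


# ---------------------------------------------------------------------------
# Default demonstration plant
# ---------------------------------------------------------------------------

# Two-elbow, eight-muscle layout: muscles 1-4 act on the right elbow,
# 5-8 on the left; odd indices are flexors (+), even are extensors (-).
# The performance variable is the one-dimensional total elbow torque, so
# A is a single signed row of moment arms (N·m per unit tension).
# Magnitudes are fixed in [1, 3]; the two starred entries are chosen so
# that the three coordinated demonstration inputs below are exactly
# torque-equivalent, i.e. they lie on a single uncontrolled manifold.
_DEFAULT_MOMENT_ARMS = np.array(
    [
        2.0020833333333333,  # * right biarticular flexor
        -1.204,              # right biarticular extensor
        1.894,               # right monoarticular flexor
        -2.035,              # right monoarticular extensor
        2.8649166666666667,  # * left biarticular flexor
        -1.0,                # left biarticular extensor
        2.396,               # left monoarticular flexor
        -1.173,              # left monoarticular extensor
    ]
)

# Per-muscle coefficients of variation, drawn once (seeded) from the
# empirically observed range [0.082, 0.246] and frozen here.  The draw is
# heterogeneous across muscles (largest on the strongly activated,
# low-leverage left monoarticular extensor), which makes the SDN tension
# ellipsoid of the single demonstration input elongate along the UCM and
# hence produce a clearly positive apparent synergy of raw tensions.
_DEFAULT_CV = np.array(
    [0.1279, 0.1576, 0.102, 0.1677, 0.1491, 0.0937, 0.0982, 0.2438]
)

_DEFAULT_LABELS = (
    "r_bi_flex",
    "r_bi_ext",
    "r_mono_flex",
    "r_mono_ext",
    "l_bi_flex",
    "l_bi_ext",
    "l_mono_flex",
    "l_mono_ext",
)

# Demonstration inputs (commanded tensions per muscle): one unique
# uncoordinated combination, and three torque-equivalent coordinated
# combinations sharing the same total torque.
UNCOORDINATED_INPUT = InputVector(
    np.array([0.08, 0.01, 0.10, 0.09, 0.08, 0.01, 0.10, 0.29]),
    label="uncoordinated",
)

COORDINATED_INPUTS = (
    InputVector(
        np.array([0.03, 0.02, 0.06, 0.06, 0.15, 0.05, 0.13, 0.38]),
        label="coordinated-1",
    ),
    InputVector(
        np.array([0.08, 0.01, 0.10, 0.09, 0.08, 0.01, 0.10, 0.29]),
        label="coordinated-2",
    ),
    InputVector(
        np.array([0.15, 0.04, 0.15, 0.13, 0.03, 0.03, 0.08, 0.21]),
        label="coordinated-3",
    ),
)


def default_plant() -> MusclePlant:
    """Return the repository's fixed eight-muscle, one-torque demo plant."""
    return MusclePlant(
        torque_map=_DEFAULT_MOMENT_ARMS.reshape(1, -1),
        cv=_DEFAULT_CV.copy(),
        muscle_labels=_DEFAULT_LABELS,
    )


def table1_input(name: str) -> InputVector | tuple[InputVector, ...]:
    """Look up a demonstration input condition by name.

    ``"uncoordinated"`` returns the single input vector; ``"coordinated"``
    returns the tuple of three torque-equivalent input vectors.
    """
    if name == "uncoordinated":
        return UNCOORDINATED_INPUT
    if name == "coordinated":
        return COORDINATED_INPUTS
    raise KeyError(f"unknown input condition {name!r}")


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def simulate_tensions(
    plant: MusclePlant,
    input: InputVector,
    n_trials: int,
    seed: int | np.random.Generator,
    clip_negative: bool = False,
) -> TrialSet:
    """Draw ``n_trials`` SDN tension vectors for a single commanded input.

    Each trial row is an independent draw of ``T_i = e_i (1 + alpha_i Z)``
    with ``Z ~ N(0, 1)``, so column ``i`` has mean ``e_i`` and standard
    deviation ``e_i * alpha_i``.  Negative tensions are allowed by default
    (the additive Gaussian model permits them); ``clip_negative`` clips
    at zero.
    """
    if n_trials < 2:
        raise ValueError("n_trials must be >= 2")
    if input.e.shape[0] != plant.n_muscles:
        raise ValueError("input length does not match plant")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_trials, plant.n_muscles))
    T = input.e + input.e * plant.cv * z
    if clip_negative:
        T = np.clip(T, 0.0, None)
    seed_val = seed if isinstance(seed, int) else None
    return TrialSet(T, condition=input.label, seed=seed_val)


def compute_torque(plant: MusclePlant, trials: TrialSet) -> TorqueSet:
    """Map each trial's tensions through the plant: ``tau = A @ T`` per row."""
    if trials.n_muscles != plant.n_muscles:
        raise ValueError("trial columns do not match plant muscles")
    return TorqueSet(trials.tensions @ plant.torque_map.T)


def feedback_torque(tau_act, tau_d, gain: float):
    """Distorted torque shown as visual feedback.

    The displayed torque amplifies the signed squared error:
    ``tau_fb = tau_act + G * sign(tau_act - tau_d) * (tau_act - tau_d)**2``.
    Larger gains make the same physical error look bigger, raising task
    difficulty.  Accepts scalars or arrays (broadcast elementwise).
    """
    if gain < 0:
        raise ValueError("gain must be >= 0")
    err = np.asarray(tau_act, dtype=float) - np.asarray(tau_d, dtype=float)
    out = np.asarray(tau_act, dtype=float) + gain * np.sign(err) * err**2
    return out if out.ndim else float(out)


def target_segments(
    seed: int | np.random.Generator,
) -> list[tuple[float, float, bool]]:
    """Half-sine segment plan for one tracking-task target trajectory.

    Returns 14 ``(signed_amplitude, period, is_standard)`` tuples: 4
    standard segments (amplitude 3 N·m, period 4 s) and 10 random ones
    (amplitude ~ N(3, 1) N·m, period ~ N(4, 0.4) s), in seeded shuffled
    order.  Signs alternate between flexion (+) and extension (−) along
    the shuffled sequence.
    """
    rng = np.random.default_rng(seed)
    segments = [(3.0, 4.0, True)] * 4 + [
        (abs(rng.normal(3.0, 1.0)), abs(rng.normal(4.0, 0.4)), False)
        for _ in range(10)
    ]
    order = rng.permutation(len(segments))
    return [
        (segments[idx][0] * (1.0 if j % 2 == 0 else -1.0), segments[idx][1],
         segments[idx][2])
        for j, idx in enumerate(order)
    ]


def make_target_trajectory(
    seed: int | np.random.Generator, dt: float = 1.0 / 200.0
) -> np.ndarray:
    """Generate one tracking-task target trajectory of total torque.

    Concatenates the 14 half-sine segments of :func:`target_segments`,
    sampled at ``1/dt`` Hz.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    pieces = []
    for amp, period, _ in target_segments(seed):
        n_samp = max(int(round(period / dt)), 1)
        t = np.arange(n_samp) * dt
        pieces.append(amp * np.sin(np.pi * t / period))
    return np.concatenate(pieces)


def time_out_of_margin(
    actual: np.ndarray, target: np.ndarray, margin: float = 0.3, dt: float = 1.0 / 200.0
) -> TrackingScore:
    """Score a tracking trial: seconds where ``|actual - target| > margin``."""
    actual = np.asarray(actual, dtype=float)
    target = np.asarray(target, dtype=float)
    if actual.shape != target.shape:
        raise ValueError("actual and target trajectories must have equal length")
    outside = np.abs(actual - target) > margin
    return TrackingScore(
        t_out=float(np.count_nonzero(outside) * dt),
        trial_duration=float(actual.size * dt),
    )
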