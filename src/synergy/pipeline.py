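"""End-to-end experiment runners, EMG preprocessing and statistics helpers.

The core workflow chains the other modules: simulate (or load) a trial set,
fit each muscle's SDN-constrained mixture with BIC model selection,
transform the trials to signal-independent motor commands, and run the UCM
decomposition on both the measured and the normalized trials.  A session's
pair of synergy indices (measured vs. normalized) is the method's output;
sessions are repeated with independent seeds for statistical evaluation
against the no-coordination reference via a one-sample t-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from collections.abc import Sequence

import numpy as np
from scipy import signal as sp_signal
from scipy import stats

from .mixture import SDNMixtureFit, select_mixture
from .normalize import NormalizedTrialSet, compute_beta, normalize_trialset
from .plant import (
    COORDINATED_INPUTS,
    UNCOORDINATED_INPUT,
    InputVector,
    MusclePlant,
    TrialSet,
    simulate_tensions,
)
from .ucm import UCMResult, ucm_decompose

__all__ = [
    "ExperimentConfig",
    "SessionResult",
    "TTestResult",
    "preprocess_emg",
    "analyze_trialset",
    "run_simulation_experiment",
    "run_torque_task_analysis",
    "one_sample_t",
    "make_negative_synergy_input",
    "initial_feedback_gain",
    "update_feedback_gain",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExperimentConfig:
    """Configuration of a repeated-session simulation experiment.

    ``inputs`` pairs each commanded input with its trial count; all inputs
    of a session are pooled into a single trial set before analysis (e.g.
    three coordinated combinations x 100 trials = 300 pooled trials).
    """

    plant: MusclePlant
    inputs: tuple[tuple[InputVector, int], ...]
    n_sessions: int = 10
    seed: int = 0
    K_max: int = 5
    restarts: int = 5
    tol: float = 1e-8
    max_iter: int = 500
    clip_negative: bool = False
    # The SDN mixture requires strictly positive data; the additive
    # Gaussian noise model has a tiny sub-zero tail at weakly commanded
    # muscles, so simulated tensions are floored here before fitting.
    tension_floor: float = 1e-6
    condition: str = ""

    def __post_init__(self) -> None:
        if self.n_sessions < 1:
            raise ValueError("n_sessions must be >= 1")
        if any(n < 2 for _, n in self.inputs):
            raise ValueError("each input needs at least 2 trials")


@dataclass(frozen=True)
class SessionResult:
    """Measured and normalized UCM analyses of one session."""

    measured: UCMResult
    normalized: UCMResult
    fits: tuple[SDNMixtureFit, ...]
    beta: float
    session_seed: int
    normalized_trials: NormalizedTrialSet | None = None


@dataclass(frozen=True)
class TTestResult:
    """One-sample t-test of session values against a reference."""

    t_statistic: float
    degrees_of_freedom: int
    p_value: float
    reference_value: float


# ---------------------------------------------------------------------------
# EMG preprocessing
# ---------------------------------------------------------------------------


def preprocess_emg(
    signal: np.ndarray,
    sampling_rate: float,
    mvc_value: float,
    downsample: int = 10,
    cutoff_hz: float = 3.0,
    filter_order: int = 2,
    zero_phase: bool = True,
) -> np.ndarray:
    """Raw EMG to MVC-normalized envelope.

    Steps, in order: block-average downsampling (``downsample`` points per
    block, remainder truncated), full-wave rectification, low-pass
    Butterworth filtering at ``cutoff_hz`` (zero-phase by default), and
    division by the maximum-voluntary-contraction value.
    """
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be > 0")
    if mvc_value <= 0:
        raise ValueError("mvc_value must be > 0")
    x = np.asarray(signal, dtype=float).ravel()
    n_blocks = x.size // downsample
    x = x[: n_blocks * downsample].reshape(n_blocks, downsample).mean(axis=1)
    fs = sampling_rate / downsample
    x = np.abs(x)
    sos = sp_signal.butter(filter_order, cutoff_hz, fs=fs, output="sos")
    x = sp_signal.sosfiltfilt(sos, x) if zero_phase else sp_signal.sosfilt(sos, x)
    return x / mvc_value


# ---------------------------------------------------------------------------
# Session analysis
# ---------------------------------------------------------------------------


def analyze_trialset(
    trials: TrialSet,
    plant: MusclePlant,
    K_max: int = 5,
    restarts: int = 5,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
    keep_normalized: bool = False,
) -> SessionResult:
    """Run the full measured-vs-normalized analysis on one trial set.

    Per muscle column: BIC-selected SDN mixture fit.  Then the common
    spread ``beta`` is computed, the trials are transformed to
    signal-independent commands, and both the raw tensions and the
    commands are decomposed against the plant's UCM.
    """
    if trials.n_muscles != plant.n_muscles:
        raise ValueError("trial columns do not match plant muscles")
    rng = np.random.default_rng(seed)
    fits = []
    for i, label in enumerate(plant.muscle_labels):
        fit = select_mixture(
            trials.tensions[:, i],
            alpha=plant.cv[i],
            K_max=K_max,
            restarts=restarts,
            seed=rng.integers(2**31),
            tol=tol,
            max_iter=max_iter,
            muscle_label=label,
        )
        logger.debug("muscle %s: K=%d, BIC=%.2f", label, fit.K, fit.bic)
        fits.append(fit)
    beta = compute_beta(fits)
    logger.debug("beta=%.5f", beta)
    normalized = normalize_trialset(trials, fits, beta)
    measured_res = ucm_decompose(trials.tensions, plant.torque_map)
    normalized_res = ucm_decompose(normalized.commands, plant.torque_map)
    return SessionResult(
        measured=measured_res,
        normalized=normalized_res,
        fits=tuple(fits),
        beta=beta,
        session_seed=seed,
        normalized_trials=normalized if keep_normalized else None,
    )


def _simulate_session(
    config: ExperimentConfig, rng: np.random.Generator
) -> TrialSet:
    blocks = [
        simulate_tensions(
            config.plant,
            inp,
            n,
            seed=rng.integers(2**31),
            clip_negative=config.clip_negative,
        ).tensions
        for inp, n in config.inputs
    ]
    T = np.maximum(np.vstack(blocks), config.tension_floor)
    return TrialSet(T, condition=config.condition)


def run_simulation_experiment(config: ExperimentConfig) -> list[SessionResult]:
    """Run ``n_sessions`` independent simulate-fit-normalize-decompose runs.

    Deterministic given ``config.seed``: each session draws its trial and
    fitting seeds from one seeded stream.
    """
    rng = np.random.default_rng(config.seed)
    results = []
    for s in range(config.n_sessions):
        session_seed = int(rng.integers(2**31))
        srng = np.random.default_rng(session_seed)
        trials = _simulate_session(config, srng)
        res = analyze_trialset(
            trials,
            config.plant,
            K_max=config.K_max,
            restarts=config.restarts,
            seed=int(srng.integers(2**31)),
            tol=config.tol,
            max_iter=config.max_iter,
        )
        res = SessionResult(
            measured=res.measured,
            normalized=res.normalized,
            fits=res.fits,
            beta=res.beta,
            session_seed=session_seed,
        )
        logger.info(
            "session %d: measured dV*=%.3f, normalized dV*=%.3f, beta=%.4f",
            s,
            res.measured.delta_v_star,
            res.normalized.delta_v_star,
            res.beta,
        )
        results.append(res)
    return results


def run_torque_task_analysis(
    trials_csv, cv_json, plant_json, K_max: int = 5, restarts: int = 5, seed: int = 0
) -> SessionResult:
    """File-based single-session analysis of measured trial data.

    Loads a trial-set CSV, a per-muscle CV JSON and a plant JSON, aligns
    muscle columns by label, and runs :func:`analyze_trialset`.  The CV
    file, when given, overrides the plant's stored coefficients.
    """
    from . import io

    plant = io.load_plant(plant_json)
    trials = io.load_trialset(trials_csv, muscle_labels=plant.muscle_labels)
    if cv_json is not None:
        cv = io.load_cv(cv_json, muscle_labels=plant.muscle_labels)
        plant = MusclePlant(plant.torque_map, cv, plant.muscle_labels)
    return analyze_trialset(trials, plant, K_max=K_max, restarts=restarts, seed=seed)


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


def one_sample_t(values: Sequence[float], reference: float) -> TTestResult:
    """Two-sided one-sample t-test of session values against a reference."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    if np.ptp(v) == 0:
        raise ValueError("values have zero variance; t undefined")
    res = stats.ttest_1samp(v, reference)
    return TTestResult(
        t_statistic=float(res.statistic),
        degrees_of_freedom=int(v.size - 1),
        p_value=float(res.pvalue),
        reference_value=float(reference),
    )


# ---------------------------------------------------------------------------
# Negative-synergy demonstration input
# ---------------------------------------------------------------------------


def make_negative_synergy_input(
    plant: MusclePlant, dominant: float = 0.5, base: float = 0.02
) -> InputVector:
    """Construct a single (uncoordinated) input that yields negative synergy.

    Concentrates commanded tension on the muscle whose moment-arm column
    carries the largest leverage, so the SDN ellipsoid of the resulting
    tensions elongates along the row space of ``A`` — variability then
    loads onto the orthogonal (task-affecting) subspace and the measured
    synergy index falls below the no-coordination value.  The input is a
    single point, so the normalized index should return to no-coordination.
    """
    lever = np.linalg.norm(plant.torque_map, axis=0) * plant.cv
    j = int(np.argmax(lever))
    e = np.full(plant.n_muscles, base)
    e[j] = dominant
    return InputVector(e, label="negative-synergy")


# ---------------------------------------------------------------------------
# Tracking-task feedback-gain schedule
# ---------------------------------------------------------------------------

# (upper bound on best pre-test t_out in seconds, gain); better pre-test
# performance gets a higher gain so the task stays hard.
_GAIN_BANDS = ((0.5, 0.025), (1.0, 0.02), (5.0, 0.015), (np.inf, 0.01))


def initial_feedback_gain(lowest_pretest_t_out: float) -> float:
    """Feedback gain for the first learning block from pre-test performance."""
    if lowest_pretest_t_out < 0:
        raise ValueError("t_out must be >= 0")
    for bound, gain in _GAIN_BANDS:
        if lowest_pretest_t_out <= bound:
            return gain
    raise AssertionError("unreachable")


def update_feedback_gain(
    gain: float, best_t_out_block: float, best_t_out_previous: float
) -> float:
    """Raise the gain by 0.005 after a block improving the best t_out by 10%."""
    if best_t_out_block <= 0.9 * best_t_out_previous:
        return gain + 0.005
    return gain


def default_uncoordinated_config(
    plant: MusclePlant, seed: int = 0, n_sessions: int = 10, n_trials: int = 300
) -> ExperimentConfig:
    """Single unique input, ``n_trials`` trials per session."""
    return ExperimentConfig(
        plant=plant,
        inputs=((UNCOORDINATED_INPUT, n_trials),),
        n_sessions=n_sessions,
        seed=seed,
        condition="uncoordinated",
    )


def default_coordinated_config(
    plant: MusclePlant, seed: int = 0, n_sessions: int = 10, trials_per_input: int = 100
) -> ExperimentConfig:
    """Three torque-equivalent inputs, ``trials_per_input`` trials each."""
    return ExperimentConfig(
        plant=plant,
        inputs=tuple((inp, trials_per_input) for inp in COORDINATED_INPUTS),
        n_sessions=n_sessions,
        seed=seed,
        condition="coordinated",
    )
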