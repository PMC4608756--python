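"""File formats: plant JSON, trial-set CSV, CV JSON, fit JSON, result JSON.

All CSVs are comma-separated UTF-8 with a header row of muscle labels;
trial-set files may carry ``# key=value`` comment lines (condition, seed,
beta).  JSON results include a ``schema_version`` field.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .mixture import SDNMixtureFit
from .normalize import NormalizedTrialSet
from .plant import MusclePlant, TrialSet
from .ucm import UCMResult

SCHEMA_VERSION = 1

__all__ = [
    "save_plant",
    "load_plant",
    "save_trialset",
    "load_trialset",
    "save_normalized",
    "save_cv",
    "load_cv",
    "save_fits",
    "save_ucm_result",
]


def save_plant(plant: MusclePlant, path) -> None:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "torque_map": plant.torque_map.tolist(),
        "cv": plant.cv.tolist(),
        "muscle_labels": list(plant.muscle_labels),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_plant(path) -> MusclePlant:
    payload = json.loads(Path(path).read_text())
    return MusclePlant(
        torque_map=np.asarray(payload["torque_map"], dtype=float),
        cv=np.asarray(payload["cv"], dtype=float),
        muscle_labels=tuple(payload["muscle_labels"]),
    )


def _read_comment_meta(path) -> dict[str, str]:
    meta = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
    return meta


def save_trialset(trials: TrialSet, path, muscle_labels=None) -> None:
    n = trials.n_muscles
    labels = list(muscle_labels) if muscle_labels else [f"m{i+1}" for i in range(n)]
    with open(path, "w", encoding="utf-8") as fh:
        if trials.condition:
            fh.write(f"# condition={trials.condition}\n")
        if trials.seed is not None:
            fh.write(f"# seed={trials.seed}\n")
        pd.DataFrame(trials.tensions, columns=labels).to_csv(fh, index=False)


def load_trialset(path, muscle_labels=None) -> TrialSet:
    """Read a trial-set CSV; columns are aligned by header label if given."""
    meta = _read_comment_meta(path)
    df = pd.read_csv(path, comment="#")
    if muscle_labels is not None:
        missing = set(muscle_labels) - set(df.columns)
        if missing:
            raise ValueError(f"trial CSV missing muscle columns: {sorted(missing)}")
        df = df[list(muscle_labels)]
    seed = int(meta["seed"]) if "seed" in meta else None
    return TrialSet(df.to_numpy(float), condition=meta.get("condition", ""), seed=seed)


def save_normalized(norm: NormalizedTrialSet, path, muscle_labels=None) -> None:
    n = norm.commands.shape[1]
    labels = list(muscle_labels) if muscle_labels else [f"m{i+1}" for i in range(n)]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# beta={norm.beta!r}\n")
        if norm.source is not None and norm.source.condition:
            fh.write(f"# condition={norm.source.condition}\n")
        pd.DataFrame(norm.commands, columns=labels).to_csv(fh, index=False)


def save_cv(estimates, path) -> None:
    """Write per-muscle CV estimates as JSON keyed by muscle label."""
    payload = {"schema_version": SCHEMA_VERSION, "muscles": {}}
    for est in estimates:
        payload["muscles"][est.muscle_label] = {
            "alpha": est.alpha,
            "correlation": est.correlation,
            "n_points": est.n_points,
            "intercept": est.intercept,
        }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_cv(path, muscle_labels) -> np.ndarray:
    payload = json.loads(Path(path).read_text())
    muscles = payload["muscles"]
    missing = [m for m in muscle_labels if m not in muscles]
    if missing:
        raise ValueError(f"CV file missing muscles: {missing}")
    return np.array([muscles[m]["alpha"] for m in muscle_labels], dtype=float)


def save_fits(fits, path, responsibilities_csv=None) -> None:
    """Serialize per-muscle mixture fits; responsibilities go to a sidecar CSV."""
    payload = {"schema_version": SCHEMA_VERSION, "muscles": {}}
    for fit in fits:
        payload["muscles"][fit.muscle_label] = _fit_dict(fit)
    Path(path).write_text(json.dumps(payload, indent=2))
    if responsibilities_csv is not None:
        frames = []
        for fit in fits:
            cols = {
                f"{fit.muscle_label}_k{k+1}": fit.responsibilities[:, k]
                for k in range(fit.K)
            }
            frames.append(pd.DataFrame(cols))
        pd.concat(frames, axis=1).to_csv(responsibilities_csv, index=False)


def _fit_dict(fit: SDNMixtureFit) -> dict:
    return {
        "K": fit.K,
        "means": fit.means.tolist(),
        "mixing": fit.mixing.tolist(),
        "bic": fit.bic,
        "log_likelihood": fit.log_likelihood,
        "alpha": fit.alpha,
        "converged": fit.converged,
        "n_iterations": fit.n_iterations,
    }


def save_ucm_result(result: UCMResult, path) -> None:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "v_ucm": result.v_ucm,
        "v_ort": result.v_ort,
        "v_tot": result.v_tot,
        "delta_v": result.delta_v,
        "delta_v_star": result.delta_v_star,
        "n": result.n,
        "d": result.d,
    }
    Path(path).write_text(json.dumps(payload, indent=2))
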