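"""Checkpoint and cohort serialization.

A model checkpoint is a directory holding ``manifest.json`` (shapes,
activation, format version) and ``arrays.npz`` with the named numeric
arrays.  A cohort directory holds ``manifest.json``, ``patients.csv``,
``trajectories.csv`` (long format), optional ``truth_latents.csv``, and a
``truth_model/`` checkpoint subdirectory when ground truth is known.
Floats in CSV are written with 17 significant digits, which round-trips
float64 exactly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .dynamics import (
    ConditionLayout,
    EmissionModel,
    LatentDynamicsModel,
    PatientEmbedding,
    TensorBank,
    Trajectory,
)
from .tucker import TuckerFactors

FORMAT_VERSION = 1
FLOAT_FMT = "%.17g"


class SchemaError(ValueError):
    """A file set is missing, truncated, or carries an unknown format version."""


def _check_version(manifest: dict, path: Path) -> None:
    major = int(manifest.get("format_version", -1))
    if major != FORMAT_VERSION:
        raise SchemaError(
            f"{path}: format_version {manifest.get('format_version')!r} "
            f"not supported (expected {FORMAT_VERSION})"
        )


# ---------------------------------------------------------------- checkpoints


def save_checkpoint(model: LatentDynamicsModel, directory, extra: Optional[dict] = None
                    ) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    bank = model.dense_bank()
    arrays = {
        "prototypes": bank.prototypes,
        "bases_W": model.emission.bases_W,
        "bases_Sigma": model.emission.bases_Sigma,
    }
    factored = isinstance(model.bank, TuckerFactors)
    if factored:
        arrays["tucker_core"] = model.bank.core
        for n, u in enumerate(model.bank.factors):
            arrays[f"tucker_factor_{n}"] = u
    manifest = {
        "format_version": FORMAT_VERSION,
        "k": bank.k,
        "d": bank.d,
        "m": bank.m,
        "q": model.emission.q,
        "block_dims": list(model.layout.block_dims),
        "activation": model.activation,
        "factored": factored,
        "spectral_bound": bank.spectral_bound,
    }
    if extra:
        manifest.update(extra)
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    np.savez(directory / "arrays.npz", **arrays)
    return directory


def load_checkpoint(directory) -> LatentDynamicsModel:
    directory = Path(directory)
    mpath = directory / "manifest.json"
    apath = directory / "arrays.npz"
    if not mpath.exists() or not apath.exists():
        raise SchemaError(f"{directory}: checkpoint needs manifest.json and arrays.npz")
    manifest = json.loads(mpath.read_text())
    _check_version(manifest, mpath)
    with np.load(apath) as npz:
        arrays = {name: npz[name] for name in npz.files}
    bank = TensorBank(arrays["prototypes"], spectral_bound=manifest.get("spectral_bound"))
    if manifest.get("factored"):
        n_factors = sum(1 for name in arrays if name.startswith("tucker_factor_"))
        bank_obj: object = TuckerFactors(
            core=arrays["tucker_core"],
            factors=tuple(arrays[f"tucker_factor_{n}"] for n in range(n_factors)),
        )
    else:
        bank_obj = bank
    emission = EmissionModel(arrays["bases_W"], arrays["bases_Sigma"])
    layout = ConditionLayout(tuple(manifest["block_dims"]))
    model = LatentDynamicsModel(
        bank=bank_obj, emission=emission, layout=layout, activation=manifest["activation"]
    )
    for key, expected in (("k", model.k), ("d", model.d), ("m", model.m), ("q", model.q)):
        if int(manifest[key]) != expected:
            raise SchemaError(f"{directory}: manifest {key}={manifest[key]} but arrays give {expected}")
    return model


# -------------------------------------------------------------------- cohorts


def write_cohort(cohort, directory) -> Path:
    """Write a generated cohort losslessly; see :mod:`chronodyn.synth` for the type."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cfg = cohort.config
    manifest = {
        "format_version": FORMAT_VERSION,
        "config": cfg.to_dict(),
        "n_patients": len(cohort.trajectories),
        "has_truth": cohort.truth_model is not None,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))

    k = cohort.embeddings[0].k if cohort.embeddings else cfg.k
    patients = pd.DataFrame(
        {
            "patient_id": [tr.patient_id for tr in cohort.trajectories],
            **{f"z_{j + 1}": [z.z[j] for z in cohort.embeddings] for j in range(k)},
            "T": [tr.T for tr in cohort.trajectories],
        }
    )
    patients.to_csv(directory / "patients.csv", index=False, float_format=FLOAT_FMT)

    rows = []
    for tr in cohort.trajectories:
        for t in range(tr.T):
            rows.append(
                {
                    "patient_id": tr.patient_id,
                    "t": t + 1,
                    # no action precedes the first visit
                    "action": int(tr.actions[t - 1]) if t > 0 else -1,
                    **{f"obs_{i + 1}": tr.observations[t, i] for i in range(tr.observations.shape[1])},
                }
            )
    pd.DataFrame(rows).to_csv(directory / "trajectories.csv", index=False,
                              float_format=FLOAT_FMT)

    if cohort.trajectories and cohort.trajectories[0].latents is not None:
        rows = []
        for tr in cohort.trajectories:
            for t in range(tr.T):
                rows.append(
                    {
                        "patient_id": tr.patient_id,
                        "t": t + 1,
                        **{f"s_{i + 1}": tr.latents[t, i] for i in range(tr.latents.shape[1])},
                    }
                )
        pd.DataFrame(rows).to_csv(directory / "truth_latents.csv", index=False,
                                  float_format=FLOAT_FMT)

    if cohort.truth_model is not None:
        save_checkpoint(cohort.truth_model, directory / "truth_model")
    return directory


def read_cohort(directory):
    from .synth import Cohort, CohortConfig  # deferred to avoid an import cycle

    directory = Path(directory)
    mpath = directory / "manifest.json"
    if not mpath.exists():
        raise SchemaError(f"{directory}: missing manifest.json")
    manifest = json.loads(mpath.read_text())
    _check_version(manifest, mpath)
    config = CohortConfig.from_dict(manifest["config"])

    for name in ("patients.csv", "trajectories.csv"):
        if not (directory / name).exists():
            raise SchemaError(f"{directory}: missing {name}")
    patients = pd.read_csv(directory / "patients.csv", float_precision="round_trip")
    traj_tab = pd.read_csv(directory / "trajectories.csv", float_precision="round_trip")
    obs_cols = [c for c in traj_tab.columns if c.startswith("obs_")]
    z_cols = [c for c in patients.columns if c.startswith("z_")]

    lat_tab = None
    if (directory / "truth_latents.csv").exists():
        lat_tab = pd.read_csv(directory / "truth_latents.csv", float_precision="round_trip")
        lat_cols = [c for c in lat_tab.columns if c.startswith("s_")]

    embeddings, trajectories = [], []
    for _, row in patients.iterrows():
        pid = row["patient_id"]
        embeddings.append(PatientEmbedding(row[z_cols].to_numpy(dtype=float)))
        sub = traj_tab[traj_tab["patient_id"] == pid].sort_values("t")
        T = int(row["T"])
        if len(sub) != T:
            raise SchemaError(
                f"{directory}: trajectories.csv has {len(sub)} rows for patient "
                f"{pid}, expected T={T}"
            )
        obs = sub[obs_cols].to_numpy(dtype=float)
        actions = sub["action"].to_numpy(dtype=int)[1:]
        latents = None
        if lat_tab is not None:
            lsub = lat_tab[lat_tab["patient_id"] == pid].sort_values("t")
            if len(lsub) != T:
                raise SchemaError(f"{directory}: truth_latents.csv truncated for patient {pid}")
            latents = lsub[lat_cols].to_numpy(dtype=float)
        trajectories.append(
            Trajectory(actions=actions, observations=obs, latents=latents, patient_id=pid)
        )

    truth_model = None
    if manifest.get("has_truth") and (directory / "truth_model").exists():
        truth_model = load_checkpoint(directory / "truth_model")
    return Cohort(
        config=config,
        trajectories=trajectories,
        embeddings=embeddings,
        truth_model=truth_model,
    )
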