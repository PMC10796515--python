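"""CSV readers/writers for the tabular interchange schema.

patients.csv    patient_id, time_days, gtv_cm3 [, necrosis_cm3]
schedules.csv   patient_id, dose_time_days, dose_gy
particles.csv   log_lambda..log_phi0, weight, provenance [, patient_id]

The patient reader normalizes volumes to fold change of the first scan and
retains the raw initial volume in cm³.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .inference import PosteriorSamples, WeightedParticles
from .model import LOG_PARAM_NAMES, DoseSchedule
from .noise import NoiseParams, ObservationSet

__all__ = [
    "read_patients",
    "write_patients",
    "read_particles",
    "write_particles",
    "write_posterior_samples",
    "write_cohort",
]

PATIENT_COLUMNS = ("patient_id", "time_days", "gtv_cm3")
SCHEDULE_COLUMNS = ("patient_id", "dose_time_days", "dose_gy")


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")


def read_patients(patients_path, schedules_path) -> list[ObservationSet]:
    """Read a cohort from the patient/schedule CSV schema.

    Volumes are normalized to fold change of each patient's first scan (the
    raw initial cm³ is retained); schedules are joined by patient_id.
    """
    pdf = pd.read_csv(patients_path)
    sdf = pd.read_csv(schedules_path)
    _require_columns(pdf, PATIENT_COLUMNS, patients_path)
    _require_columns(sdf, SCHEDULE_COLUMNS, schedules_path)
    cohort = []
    for pid, grp in pdf.groupby("patient_id", sort=False):
        times = grp["time_days"].to_numpy(dtype=float)
        vols = grp["gtv_cm3"].to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0):
            raise ValueError(f"{patients_path}: times not sorted for patient {pid!r}")
        if vols[0] <= 0:
            raise ValueError(
                f"{patients_path}: non-positive initial volume for patient {pid!r}"
            )
        n_obs = None
        if "necrosis_cm3" in grp.columns and grp["necrosis_cm3"].notna().all():
            n_obs = grp["necrosis_cm3"].to_numpy(dtype=float) / vols[0]
        sched = sdf[sdf["patient_id"] == pid]
        dose_gy = float(sched["dose_gy"].iloc[0]) if len(sched) else 2.0
        cohort.append(
            ObservationSet(
                patient_id=str(pid),
                times=times,
                v_obs=vols / vols[0],
                schedule=DoseSchedule(
                    dose_times=np.sort(sched["dose_time_days"].to_numpy(dtype=float)),
                    dose_gy=dose_gy,
                ),
                initial_volume_cm3=float(vols[0]),
                n_obs=n_obs,
            )
        )
    return cohort


def write_patients(cohort, patients_path, schedules_path) -> None:
    """Write observation sets back to the CSV schema (volumes in cm³)."""
    prow, srow = [], []
    for obs in cohort:
        v0 = obs.initial_volume_cm3
        if not np.isfinite(v0):
            v0 = 1.0
        for k in range(obs.n):
            row = {
                "patient_id": obs.patient_id,
                "time_days": obs.times[k],
                "gtv_cm3": obs.v_obs[k] * v0,
            }
            if obs.n_obs is not None:
                row["necrosis_cm3"] = obs.n_obs[k] * v0
            prow.append(row)
        for t in obs.schedule.dose_times:
            srow.append(
                {
                    "patient_id": obs.patient_id,
                    "dose_time_days": t,
                    "dose_gy": obs.schedule.dose_gy,
                }
            )
    pd.DataFrame(prow).to_csv(patients_path, index=False)
    pd.DataFrame(srow).to_csv(schedules_path, index=False)


def write_particles(particles: WeightedParticles, path) -> None:
    df = pd.DataFrame(particles.thetas, columns=list(LOG_PARAM_NAMES))
    df["weight"] = particles.weights
    df["provenance"] = particles.provenance
    if particles.patient_ids is not None:
        df["patient_id"] = particles.patient_ids
    df.to_csv(path, index=False)


def read_particles(path) -> WeightedParticles:
    df = pd.read_csv(path)
    _require_columns(df, LOG_PARAM_NAMES + ("weight",), path)
    ids = df["patient_id"].to_numpy() if "patient_id" in df.columns else None
    w = df["weight"].to_numpy(dtype=float)
    return WeightedParticles(
        thetas=df[list(LOG_PARAM_NAMES)].to_numpy(dtype=float),
        weights=w / w.sum(),
        provenance=str(df["provenance"].iloc[0]) if "provenance" in df.columns else "pooled_posterior",
        patient_ids=ids,
    )


def write_posterior_samples(posteriors: list[PosteriorSamples], path) -> None:
    frames = []
    for post in posteriors:
        df = pd.DataFrame(post.draws[:, :6], columns=list(LOG_PARAM_NAMES))
        df["patient_id"] = post.patient_id
        df["chain"] = post.chain_id
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_cohort(cohort, outdir, noise: NoiseParams | None = None, seed=None) -> None:
    """Persist a synthetic cohort: CSVs plus a manifest with seeds/truths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_patients(
        [p.observations for p in cohort],
        outdir / "patients.csv",
        outdir / "schedules.csv",
    )
    manifest = {
        "seed": seed,
        "noise": None if noise is None else {"alpha1": noise.alpha1, "alpha2": noise.alpha2},
        "patients": [
            {
                "patient_id": p.patient_id,
                "seed": int(p.seed),
                "true_class": p.true_class.value,
                "theta_log": p.params.to_log().tolist(),
                "final_volume_true": p.final_volume_true,
            }
            for p in cohort
        ],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
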