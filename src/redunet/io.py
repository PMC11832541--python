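"""Plain-text serialization of pipeline inputs and outputs.

Timeseries travel as per-session TSV (one header row of region IDs, one
row per volume); subject tables and cognitive scores as CSV; redundancy
profiles as JSON; generator truth as YAML.  Numeric text uses full
``repr`` precision so a write-read round trip is bit-exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dynfc import RegionalTimeseries
from .redundancy import RedundancyProfile
from .synth import COGNITIVE_TESTS, SyntheticCohort

SUBJECT_COLUMNS = (
    "subject_id",
    "age",
    "sex",
    "site",
    "cortical_thickness",
    "gm_volume",
    "tiv",
    "brain_age",
    "max_displacement",
)


class SchemaError(ValueError):
    """An input table does not match its expected column schema."""


def write_timeseries(ts: RegionalTimeseries, path) -> None:
    df = pd.DataFrame(ts.values, columns=list(ts.region_ids))
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_timeseries(
    path,
    tr_seconds: float = 3.0,
    subject_id: str = "sub-01",
    session_id: str = "ses-01",
) -> RegionalTimeseries:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if df.shape[1] < 2:
        raise SchemaError(f"{path}: need at least 2 region columns")
    non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        raise SchemaError(f"{path}: non-numeric region column(s) {non_numeric}")
    return RegionalTimeseries(
        values=df.to_numpy(dtype=float),
        tr_seconds=tr_seconds,
        subject_id=subject_id,
        session_id=session_id,
        region_ids=tuple(df.columns),
    )


def write_subject_table(subjects: pd.DataFrame, path) -> None:
    subjects.to_csv(path, index=False, float_format="%.17g")


def read_subject_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in SUBJECT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing subject column(s) {missing}")
    numeric = [c for c in SUBJECT_COLUMNS if c != "subject_id"]
    bad = [c for c in numeric if not np.issubdtype(df[c].dtype, np.number)]
    if bad:
        raise SchemaError(f"{path}: non-numeric column(s) {bad}")
    if df[numeric].isna().any().any():
        cols = df[numeric].columns[df[numeric].isna().any()].tolist()
        raise SchemaError(f"{path}: missing values in column(s) {cols}")
    return df


def read_cognitive_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    if "subject_id" not in df.columns:
        raise SchemaError(f"{path}: missing 'subject_id' column")
    missing = [c for c in COGNITIVE_TESTS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing cognitive column(s) {missing}")
    return df


def write_profile(profile: RedundancyProfile, path) -> None:
    payload = {
        "subject_id": profile.subject_id,
        "session_ids": list(profile.session_ids),
        "labels": list(profile.labels),
        "d_one": list(profile.d_one),
        "d_two": list(profile.d_two),
        "bfr": profile.bfr,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_profile(path) -> RedundancyProfile:
    with open(path) as fh:
        raw = json.load(fh)
    return RedundancyProfile(
        labels=tuple(raw["labels"]),
        d_one=tuple(raw["d_one"]),
        d_two=tuple(raw["d_two"]),
        bfr=raw["bfr"],
        session_ids=tuple(raw.get("session_ids", ())),
        subject_id=raw.get("subject_id", ""),
    )


def write_cohort(cohort: SyntheticCohort, out_dir) -> Path:
    """Write a synthetic cohort: per-session TSVs, tables, truth YAML."""
    out = Path(out_dir)
    ts_dir = out / "timeseries"
    ts_dir.mkdir(parents=True, exist_ok=True)
    for (sid, ses), ts in cohort.timeseries.items():
        write_timeseries(ts, ts_dir / f"{sid}_{ses}.tsv")
    write_subject_table(cohort.subjects, out / "subjects.csv")
    cohort.cognitive_scores.to_csv(
        out / "cognitive_scores.csv", index=False, float_format="%.17g"
    )
    truth = cohort.truth
    payload = {
        "seed": truth.seed,
        "betas": list(truth.betas),
        "noise_sd": truth.noise_sd,
        "factor_sd": list(truth.factor_sd),
        "cog_noise_sd": truth.cog_noise_sd,
        "snr": truth.snr,
        "loadings": np.asarray(truth.loadings).tolist(),
        "state_sequences": {
            f"{sid}/{ses}": list(seq.labels)
            for (sid, ses), seq in truth.state_sequences.items()
        },
        "bfr_true": dict(truth.bfr_true),
    }
    with open(out / "truth.yaml", "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
    return out


def read_cohort_timeseries(ts_dir, tr_seconds: float = 3.0) -> dict:
    """Load every ``<subject>_<session>.tsv`` under a directory."""
    ts_dir = Path(ts_dir)
    out = {}
    for path in sorted(ts_dir.glob("*.tsv")):
        stem = path.stem
        if "_" not in stem:
            raise SchemaError(f"{path}: expected '<subject>_<session>.tsv'")
        sid, ses = stem.split("_", 1)
        out[(sid, ses)] = read_timeseries(
            path, tr_seconds=tr_seconds, subject_id=sid, session_id=ses
        )
    if not out:
        raise SchemaError(f"no timeseries TSV files under {ts_dir}")
    return out
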