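"""End-to-end pipeline: timeseries -> BFR -> PCA -> moderation models.

Stages run in a fixed order with a single configuration object; identical
config and inputs give identical outputs.  A run manifest records the
config snapshot, input digests and output paths so every output is
traceable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .cognition import CognitiveComponents, analyze_cognition
from .config import PipelineConfig
from .dynfc import RegionalTimeseries, build_stack, drop_initial_volumes
from .models import ModerationFit, exclude_by_motion, fit_moderation, normalize_gm_volume
from .redundancy import RedundancyProfile, bfr_score

logger = logging.getLogger(__name__)


class SubjectMismatchError(ValueError):
    """Subject IDs differ between the timeseries and subject tables."""


@dataclass
class PipelineResult:
    bfr_table: pd.DataFrame
    profiles: Mapping[str, RedundancyProfile]
    components: CognitiveComponents
    fits: Mapping[str, ModerationFit]
    manifest: dict


def compute_bfr_table(
    timeseries: Mapping[tuple[str, str], RegionalTimeseries],
    config: PipelineConfig,
) -> tuple[pd.DataFrame, dict[str, RedundancyProfile]]:
    """Per-subject BFR from raw session timeseries.

    Sessions are scrubbed of initial volumes, windowed, labeled, and
    concatenated in session order per subject.
    """
    grid = config.density_grid()
    by_subject: dict[str, list] = {}
    for (sid, ses), ts in sorted(timeseries.items()):
        by_subject.setdefault(sid, []).append(ts)
    profiles = {}
    rows = []
    for sid, sessions in by_subject.items():
        stacks = [
            build_stack(
                drop_initial_volumes(ts, config.drop_initial),
                window=config.window_volumes,
                step=config.step_volumes,
            )
            for ts in sessions
        ]
        profile = bfr_score(
            stacks, grid, rank_mode=config.rank_mode, mode=config.path_mode
        )
        profiles[sid] = profile
        rows.append(
            {"subject_id": sid, "bfr": profile.bfr, "n_windows": profile.n_windows}
        )
        logger.info("subject %s: bfr=%.3f over %d windows", sid, profile.bfr, profile.n_windows)
    return pd.DataFrame(rows), profiles


def assemble_records(
    subjects: pd.DataFrame,
    bfr_table: pd.DataFrame,
    components: CognitiveComponents,
) -> pd.DataFrame:
    """Merge subject measures, BFR and retained component scores."""
    records = subjects.merge(bfr_table[["subject_id", "bfr"]], on="subject_id")
    records["gm_volume_norm"] = normalize_gm_volume(
        records["gm_volume"].to_numpy(), records["tiv"].to_numpy()
    )
    scores = components.retained_scores.copy()
    scores.index.name = "subject_id"
    records = records.merge(scores.reset_index(), on="subject_id")
    return records


def run_pipeline(
    timeseries: Mapping[tuple[str, str], RegionalTimeseries],
    subjects: pd.DataFrame,
    cognitive_scores: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Execute every analysis stage on in-memory inputs.

    Applies the motion filter, computes per-subject BFR, runs the
    cognitive PCA with elbow selection, and fits the three moderation
    models on subjects present in every table.
    """
    config = config or PipelineConfig()
    ts_subjects = {sid for sid, _ in timeseries}
    tab_subjects = set(subjects["subject_id"])
    if not ts_subjects & tab_subjects:
        raise SubjectMismatchError(
            "no overlap between timeseries subjects and the subject table"
        )
    kept = exclude_by_motion(subjects, config.motion_threshold_mm)
    n_excluded = len(subjects) - len(kept)
    logger.info("motion filter: excluded %d of %d subjects", n_excluded, len(subjects))
    kept_ids = set(kept["subject_id"]) & ts_subjects
    ts_kept = {k: v for k, v in timeseries.items() if k[0] in kept_ids}
    bfr_table, profiles = compute_bfr_table(ts_kept, config)
    components = analyze_cognition(cognitive_scores)
    logger.info(
        "PCA: retained %d components (%s)",
        components.n_retained,
        ", ".join(components.domain_labels),
    )
    records = assemble_records(kept[kept["subject_id"].isin(kept_ids)], bfr_table, components)
    fits = {}
    for model_id in ("thickness", "gm_volume", "brain_age"):
        fits[model_id] = fit_moderation(
            records,
            model_id,
            include_chron_age=config.include_chron_age.get(model_id),
        )
    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "n_subjects_input": int(len(subjects)),
        "n_subjects_motion_excluded": int(n_excluded),
        "n_subjects_analyzed": int(len(records)),
        "n_regions": int(next(iter(ts_kept.values())).n_regions) if ts_kept else 0,
        "n_retained_components": int(components.n_retained),
        "domain_labels": list(components.domain_labels),
    }
    return PipelineResult(
        bfr_table=bfr_table,
        profiles=profiles,
        components=components,
        fits=fits,
        manifest=manifest,
    )


def write_results(result: PipelineResult, out_dir) -> Path:
    """Write BFR CSV, PCA outputs, model coefficient CSVs and manifest."""
    from .io import write_profile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.bfr_table.to_csv(out / "bfr.csv", index=False, float_format="%.17g")
    prof_dir = out / "profiles"
    prof_dir.mkdir(exist_ok=True)
    for sid, profile in result.profiles.items():
        write_profile(profile, prof_dir / f"{sid}.json")
    comps = result.components
    comps.loadings.to_csv(out / "pca_loadings.csv", float_format="%.17g")
    pd.DataFrame(
        {
            "component": comps.loadings.columns,
            "variance_fraction": comps.variance_fraction,
        }
    ).to_csv(out / "pca_scree.csv", index=False, float_format="%.17g")
    comps.scores.to_csv(out / "pca_scores.csv", float_format="%.17g")
    for model_id, fit in result.fits.items():
        fit.coefficients.to_csv(
            out / f"model_{model_id}_coefficients.csv", index=False, float_format="%.6g"
        )
        fit.fit.to_csv(out / f"model_{model_id}_fit.csv", index=False, float_format="%.6g")
    manifest = dict(result.manifest)
    manifest["outputs"] = sorted(str(p.relative_to(out)) for p in out.rglob("*") if p.is_file())
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return out


def digest_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
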