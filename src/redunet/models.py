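"""Moderation regressions and display subgroup splits.

Tests whether brain functional redundancy (BFR) modulates the association
between an age-related brain-change measure and cognitive performance.
For each brain-change definition (cortical thickness, TIV-normalized GM
volume, brain age) the retained cognitive components are regressed on the
brain change, BFR, their product, and site/sex covariates — chronological
age is added for the brain-age model by default (to absorb the known
chronological-age bias of brain-age predictions) and optionally for the
other two.  The multivariate fit is computed as per-outcome OLS on the
shared design, which yields point estimates identical to a joint
multivariate fit; predictors enter uncentered and p-values are two-sided
and uncorrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

BRAIN_CHANGE_COLUMNS: Mapping[str, str] = {
    "thickness": "cortical_thickness",
    "gm_volume": "gm_volume_norm",
    "brain_age": "brain_age",
}

MOTION_THRESHOLD_MM = 2.5

#: Condition-number ceiling above which the design is rejected as collinear.
_CONDITION_LIMIT = 1e10


@dataclass(frozen=True)
class ModerationFit:
    """Per-outcome coefficient tables and fit statistics for one model.

    ``coefficients`` has one row per (outcome, predictor) with beta, SE, t
    and two-sided p; ``fit`` has one row per outcome with residual SE, R²,
    adjusted R², F and the model p-value.  ``residual_covariance`` is the
    joint residual covariance across outcomes (reported for completeness;
    no multivariate test is computed).
    """

    model_id: str
    coefficients: pd.DataFrame
    fit: pd.DataFrame
    residual_covariance: pd.DataFrame
    interaction_name: str = ""
    n_obs: int = 0

    def coef(self, outcome: str, predictor: str) -> pd.Series:
        rows = self.coefficients
        m = (rows["outcome"] == outcome) & (rows["predictor"] == predictor)
        if not m.any():
            raise KeyError(f"no row for ({outcome}, {predictor})")
        return rows.loc[m].iloc[0]


def normalize_gm_volume(gm: float | np.ndarray, tiv: float | np.ndarray):
    """GM volume as a fraction of total intracranial volume.

    Corrects cortical gray-matter volume (mm^3) for head size; the result
    is a dimensionless ratio in (0, 1).
    """
    gm = np.asarray(gm, dtype=float)
    tiv = np.asarray(tiv, dtype=float)
    if np.any(gm <= 0) or np.any(tiv <= 0):
        raise ValueError("volumes must be positive")
    if np.any(gm >= tiv):
        raise ValueError("GM volume must be smaller than TIV")
    out = gm / tiv
    return float(out) if out.ndim == 0 else out


def exclude_by_motion(
    subjects: pd.DataFrame, threshold: float = MOTION_THRESHOLD_MM
) -> pd.DataFrame:
    """Keep subjects whose maximum displacement does not exceed threshold.

    The exclusion is strict (``> threshold`` removed), so values exactly at
    the threshold are retained.
    """
    if "max_displacement" not in subjects.columns:
        raise KeyError("subject table lacks a 'max_displacement' column")
    disp = subjects["max_displacement"]
    if disp.isna().any():
        bad = subjects.loc[disp.isna(), "subject_id"].tolist() \
            if "subject_id" in subjects.columns else disp.index[disp.isna()].tolist()
        raise ValueError(f"missing max_displacement for: {bad}")
    return subjects.loc[disp <= threshold].copy()


def _design_matrix(
    records: pd.DataFrame,
    bc_col: str,
    include_chron_age: bool,
    center: bool,
) -> pd.DataFrame:
    bc = records[bc_col].astype(float)
    bfr = records["bfr"].astype(float)
    if center:
        bc = bc - bc.mean()
        bfr = bfr - bfr.mean()
    design = pd.DataFrame(
        {
            "Intercept": 1.0,
            bc_col: bc,
            "bfr": bfr,
            f"{bc_col}:bfr": bc * bfr,
            "site": records["site"].astype(float),
            "sex": records["sex"].astype(float),
        },
        index=records.index,
    )
    if include_chron_age:
        design["age"] = records["age"].astype(float)
    return design


def fit_moderation(
    records: pd.DataFrame,
    brain_change: Literal["thickness", "gm_volume", "brain_age"],
    outcomes: Sequence[str] | None = None,
    include_chron_age: bool | None = None,
    center: bool = False,
) -> ModerationFit:
    """OLS moderation fit of each cognitive component on one brain change.

    ``records`` carries one row per subject with the brain-change columns
    (``cortical_thickness``, ``gm_volume_norm``, ``brain_age``), ``bfr``,
    ``site``, ``sex``, ``age`` and the outcome columns (by default every
    column named ``PC*``).  ``include_chron_age`` defaults to True only for
    the brain-age model; ``center`` mean-centers the moderated predictors
    before forming the product term (off by default, for numerical
    comparisons only — it changes the main-effect parameterization).
    """
    if brain_change not in BRAIN_CHANGE_COLUMNS:
        raise ValueError(f"unknown brain change {brain_change!r}")
    bc_col = BRAIN_CHANGE_COLUMNS[brain_change]
    if include_chron_age is None:
        include_chron_age = brain_change == "brain_age"
    if outcomes is None:
        outcomes = [c for c in records.columns if c.startswith("PC")]
    if not outcomes:
        raise ValueError("no outcome columns found")
    needed = [bc_col, "bfr", "site", "sex", *outcomes]
    if include_chron_age:
        needed.append("age")
    missing = [c for c in needed if c not in records.columns]
    if missing:
        raise KeyError(f"records lack columns: {missing}")
    if records[needed].isna().any().any():
        raise ValueError("missing values in model columns")
    design = _design_matrix(records, bc_col, include_chron_age, center)
    n, k = design.shape
    if n < k + 10:
        raise ValueError(f"need at least {k + 10} records for {k} predictors, got {n}")
    cond = np.linalg.cond(design.to_numpy())
    if cond > _CONDITION_LIMIT:
        raise ValueError(f"collinear design (condition number {cond:.2e})")
    coef_rows, fit_rows, resids = [], [], {}
    for outcome in outcomes:
        res = sm.OLS(records[outcome].astype(float), design).fit()
        for pred in design.columns:
            coef_rows.append(
                {
                    "outcome": outcome,
                    "predictor": pred,
                    "beta": res.params[pred],
                    "se": res.bse[pred],
                    "t": res.tvalues[pred],
                    "p": res.pvalues[pred],
                }
            )
        fit_rows.append(
            {
                "outcome": outcome,
                "resid_se": np.sqrt(res.mse_resid),
                "r_squared": res.rsquared,
                "adj_r_squared": res.rsquared_adj,
                "f_stat": res.fvalue,
                "model_p": res.f_pvalue,
            }
        )
        resids[outcome] = res.resid
    resid_df = pd.DataFrame(resids)
    dof = n - k
    resid_cov = resid_df.T @ resid_df / dof
    return ModerationFit(
        model_id=brain_change,
        coefficients=pd.DataFrame(coef_rows),
        fit=pd.DataFrame(fit_rows),
        residual_covariance=resid_cov,
        interaction_name=f"{bc_col}:bfr",
        n_obs=n,
    )


def mean_split(values: Sequence[float] | pd.Series) -> np.ndarray:
    """Assign 'high' to values at or above the mean, 'low' below it."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values to split")
    return np.where(v >= v.mean(), "high", "low")


def threshold_split(
    values: Sequence[float] | pd.Series,
    cut: float,
    brain_change: Sequence[float] | None = None,
    outcome: Sequence[float] | None = None,
) -> dict:
    """Split BFR values at a fixed cut; optionally report per-group slopes.

    Values below ``cut`` go to 'low', values at or above it to 'high'.
    When ``brain_change`` and ``outcome`` are given, the simple linear
    slope of outcome on brain change is fitted within each group.
    """
    v = np.asarray(values, dtype=float)
    if not (0.0 < cut < 1.0):
        raise ValueError("cut must lie strictly inside (0, 1)")
    if np.any((v < 0) | (v > 1)):
        raise ValueError("BFR values must lie in [0, 1]")
    groups = np.where(v < cut, "low", "high")
    out = {
        "groups": groups,
        "n_low": int((groups == "low").sum()),
        "n_high": int((groups == "high").sum()),
    }
    if brain_change is not None and outcome is not None:
        bc = np.asarray(brain_change, dtype=float)
        y = np.asarray(outcome, dtype=float)
        slopes = {}
        for g in ("low", "high"):
            m = groups == g
            if m.sum() >= 3:
                slopes[g] = float(np.polyfit(bc[m], y[m], 1)[0])
            else:
                slopes[g] = float("nan")
        out["slopes"] = slopes
    return out
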