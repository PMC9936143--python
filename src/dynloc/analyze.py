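"""Response screening and localization-performance metrics.

Quality control drops trials whose head movement does not match the
instruction: dynamic trials need at least 5° of rotation about the
instructed axis and at most 2° about the orthogonal one; static trials
may move at most a (configurable) 2° in total.

Three metrics are computed per subject × cue condition × rotation type:

* **LPE** — lateral precision error: sample SD of lateral response errors;
* **FBC rate** — percentage of front-back confusions among eligible
  trials (targets with |lateral| ≤ 60°); a response counts as confused
  when its polar angle crosses more than 10° past the front/back boundary
  (polar 90°/270°) into the hemifield opposite the target's;
* **PPE** — polar precision error: sample SD of wrapped polar errors,
  computed after removing confused trials so the two polar metrics stay
  independent.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .coords import wrap_degrees

__all__ = [
    "qc_filter",
    "classify_fbc",
    "alt_fbc_definition",
    "localization_errors",
    "compute_metrics",
    "FBC_PRESETS",
]

#: Named rule sets for the front-back confusion classifier:
#: (lateral exclusion limit in degrees, midline crossing allowance in degrees)
FBC_PRESETS = {
    "default": (60.0, 10.0),
    "middlebrooks": (30.0, 0.0),
}


def qc_filter(
    rt: pd.DataFrame,
    min_on_axis: float = 5.0,
    max_off_axis: float = 2.0,
    static_threshold: float = 2.0,
) -> tuple[pd.DataFrame, dict]:
    """Screen responses for head-movement outliers.

    Dynamic trials are kept iff the rotation about the instructed axis is
    at least ``min_on_axis`` degrees and the orthogonal-axis rotation at
    most ``max_off_axis`` degrees (both boundaries inclusive).  Static
    trials are kept iff total head movement is at most
    ``static_threshold`` degrees.  Returns the filtered table and a QC
    report with per-reason exclusion counts.
    """
    dyn = rt.rotation != "static"
    if dyn.any() and rt.loc[dyn, ["on_axis_rot_deg", "off_axis_rot_deg"]].isna().any().any():
        raise ValueError("dynamic rows without trajectory summaries")
    too_small = dyn & (rt.on_axis_rot_deg < min_on_axis)
    wrong_axis = dyn & (rt.off_axis_rot_deg > max_off_axis)
    static_moved = ~dyn & (rt.total_rot_deg > static_threshold)
    keep = ~(too_small | wrong_axis | static_moved)
    report = {
        "n_input": int(len(rt)),
        "n_kept": int(keep.sum()),
        "n_excluded_rotation_too_small": int(too_small.sum()),
        "n_excluded_wrong_axis": int((wrong_axis & ~too_small).sum()),
        "n_excluded_static_movement": int(static_moved.sum()),
        "min_on_axis_deg": min_on_axis,
        "max_off_axis_deg": max_off_axis,
        "static_threshold_deg": static_threshold,
    }
    return rt[keep].reset_index(drop=True), report


def _target_in_front(pol) -> np.ndarray:
    pol = np.asarray(pol, dtype=float)
    return (pol >= -90.0) & (pol <= 90.0)


def classify_fbc(
    target_lat_deg,
    target_pol_deg,
    response_pol_deg,
    lat_limit: float = 60.0,
    cross_allow: float = 10.0,
) -> np.ndarray:
    """Label responses as front-back confusions.

    Returns a float array: 1 for a confusion, 0 for the correct hemifield,
    NaN for excluded trials (|target lateral| > ``lat_limit``).  The
    front/back boundary is the frontal plane (polar 90°/270°); a response
    must cross it by more than ``cross_allow`` degrees into the hemifield
    opposite the target's to count as confused.
    """
    t_lat = np.asarray(target_lat_deg, dtype=float)
    t_pol = np.asarray(target_pol_deg, dtype=float)
    r_pol = np.asarray(response_pol_deg, dtype=float)
    front = _target_in_front(t_pol)
    # response lies > cross_allow past the boundary, in the back hemifield
    in_back_beyond = (r_pol > 90.0 + cross_allow) & (r_pol < 270.0 - cross_allow)
    # ... or in the front hemifield
    in_front_beyond = (r_pol > -90.0 + cross_allow) & (r_pol < 90.0 - cross_allow)
    fbc = np.where(front, in_back_beyond, in_front_beyond).astype(float)
    fbc = np.where(np.abs(t_lat) > lat_limit, np.nan, fbc)
    if fbc.ndim == 0:
        return float(fbc)
    return fbc


def alt_fbc_definition(
    target_lat_deg, target_pol_deg, response_pol_deg, preset: str = "middlebrooks"
) -> np.ndarray:
    """Front-back classification under a named alternative rule set."""
    if preset not in FBC_PRESETS:
        raise ValueError(f"unknown preset {preset!r}; know {sorted(FBC_PRESETS)}")
    lat_limit, cross_allow = FBC_PRESETS[preset]
    return classify_fbc(
        target_lat_deg, target_pol_deg, response_pol_deg, lat_limit, cross_allow
    )


def localization_errors(
    target_lat_deg, target_pol_deg, response_lat_deg, response_pol_deg
) -> tuple[np.ndarray, np.ndarray]:
    """Signed lateral and polar response errors in degrees.

    The polar error is the circular difference wrapped to (−180, 180].
    """
    lat_err = np.asarray(response_lat_deg, dtype=float) - np.asarray(
        target_lat_deg, dtype=float
    )
    diff = np.asarray(response_pol_deg, dtype=float) - np.asarray(
        target_pol_deg, dtype=float
    )
    pol_err = -wrap_degrees(-diff)  # wraps to (-180, 180]
    return lat_err, pol_err


def compute_metrics(
    rt: pd.DataFrame,
    group_by: tuple[str, ...] = ("subject_id", "cue_condition", "rotation"),
    lat_limit: float = 60.0,
    cross_allow: float = 10.0,
    fbc_classifier=None,
) -> pd.DataFrame:
    """Per-group LPE, PPE and FBC rate.

    ``fbc_classifier`` may override the default rule (same call signature
    as :func:`classify_fbc` minus the threshold arguments); swapping it
    changes FBC labeling and PPE eligibility but never the LPE.  Groups
    with fewer than two usable trials get NaN metrics rather than zeros.
    """
    rt = rt.copy()
    lat_err, pol_err = localization_errors(
        rt.target_lat_deg, rt.target_pol_deg, rt.response_lat_deg, rt.response_pol_deg
    )
    rt["_lat_err"] = lat_err
    rt["_pol_err"] = pol_err
    if fbc_classifier is None:
        rt["_fbc"] = classify_fbc(
            rt.target_lat_deg, rt.target_pol_deg, rt.response_pol_deg,
            lat_limit, cross_allow,
        )
    else:
        rt["_fbc"] = fbc_classifier(
            rt.target_lat_deg, rt.target_pol_deg, rt.response_pol_deg
        )

    def _one(group: pd.DataFrame) -> pd.Series:
        n = len(group)
        lpe = group._lat_err.std(ddof=1) if n >= 2 else np.nan
        eligible = group._fbc.notna()
        n_eligible = int(eligible.sum())
        fbc_rate = (
            100.0 * group._fbc[eligible].mean() if n_eligible >= 1 else np.nan
        )
        # PPE: drop confused trials; targets without an FBC label stay in
        ppe_rows = group[(group._fbc != 1.0) | ~eligible]
        ppe = ppe_rows._pol_err.std(ddof=1) if len(ppe_rows) >= 2 else np.nan
        return pd.Series(
            {
                "LPE_deg": lpe,
                "PPE_deg": ppe,
                "FBC_rate_pct": fbc_rate,
                "n_trials": n,
                "n_fbc_eligible": n_eligible,
            }
        )

    out = (
        rt.groupby(list(group_by), sort=True, observed=True)
        .apply(_one, include_groups=False)
        .reset_index()
    )
    out["n_trials"] = out.n_trials.astype(int)
    out["n_fbc_eligible"] = out.n_fbc_eligible.astype(int)
    return out
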