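"""Inferential stage: mixed-effects models and Tukey-adjusted contrasts.

Precision metrics (LPE/PPE, one value per subject × cue condition ×
rotation type) are analyzed with a linear mixed-effects model — cue,
rotation and their interaction as fixed effects (fit in cell-means form),
subject as a random intercept, REML.  Front-back confusions are analyzed
at the trial level with a mixed-effects logistic regression with the same
fixed/random structure; the likelihood is maximized with adaptive
Gauss–Hermite quadrature over the subject random intercept, using the
per-subject, per-cell binomial counts as sufficient statistics.

Follow-up comparisons are pairwise contrasts of estimated marginal (cell)
means, Tukey-adjusted per family, where a family collects all level pairs
within one grouping-factor level (e.g. all rotation pairs within one cue
condition), matching the structure of the study's contrast tables.

A simulation harness estimates the operating characteristics (empirical
type-I error under null generating parameters, power under the default
effects) of this analysis chain end to end.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm, studentized_range, t as t_dist

from .analyze import classify_fbc, compute_metrics, qc_filter

__all__ = [
    "CellMeansModel",
    "fit_precision_model",
    "fit_fbc_model",
    "marginal_contrasts",
    "simulation_harness",
]

CUE_ORDER = ("flat", "full", "frozen", "free_field")
ROTATION_ORDER = ("static", "yaw", "pitch")


def _sorted_cells(cells) -> list[tuple[str, str]]:
    return sorted(
        cells,
        key=lambda cr: (CUE_ORDER.index(cr[0]), ROTATION_ORDER.index(cr[1])),
    )


@dataclass
class CellMeansModel:
    """Fitted cell-means summary shared by both model families.

    estimates/cov live on the model's natural scale: degrees for the
    precision models, log-odds for the confusion model (``scale`` says
    which).  ``df`` is the degrees of freedom for Wald tests (inf → z).
    """

    metric: str
    scale: str
    cells: list[tuple[str, str]]
    estimates: np.ndarray
    cov: np.ndarray
    df: float
    converged: bool = True
    extra: dict = field(default_factory=dict)

    def cell_index(self, condition: str, rotation: str) -> int:
        return self.cells.index((condition, rotation))

    def cell_probabilities(self) -> dict:
        """Fitted marginal cell values (probabilities for the logit scale)."""
        if self.scale == "logit":
            return {
                c: float(1.0 / (1.0 + np.exp(-e)))
                for c, e in zip(self.cells, self.estimates)
            }
        return {c: float(e) for c, e in zip(self.cells, self.estimates)}


# ---------------------------------------------------------------------------
# linear mixed model for precision metrics

def fit_precision_model(mt: pd.DataFrame, metric: str = "LPE_deg") -> CellMeansModel:
    """Linear mixed-effects model for a precision metric.

    Cell-means parameterization (one fixed effect per cue × rotation cell,
    equivalent to condition + rotation + interaction) with a subject random
    intercept, REML; falls back to ML with a warning when the REML fit is
    singular or fails to converge.
    """
    import statsmodels.api as sm

    data = mt.dropna(subset=[metric])
    subjects = pd.unique(data.subject_id)
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects")
    cells = _sorted_cells(set(zip(data.cue_condition, data.rotation)))
    if len({c for c, _ in cells}) < 2 or len({r for _, r in cells}) < 2:
        raise ValueError("need at least 2 levels of both factors")
    col = pd.Series(list(zip(data.cue_condition, data.rotation)))
    exog = np.column_stack([(col == c).to_numpy(float) for c in cells])
    if np.linalg.matrix_rank(exog) < len(cells):
        raise ValueError("rank-deficient design: empty cells " +
                         str([c for c in cells if not (col == c).any()]))
    endog = data[metric].to_numpy()
    groups = data.subject_id.to_numpy()
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(endog, exog, groups=groups)
        try:
            fit = model.fit(reml=True)
            singular = not np.isfinite(np.asarray(fit.cov_re)).all()
        except Exception:
            fit, singular = None, True
        if fit is None or singular or not fit.converged:
            warnings.warn("REML fit singular or not converged; refitting by ML",
                          RuntimeWarning, stacklevel=2)
            fit = sm.MixedLM(endog, exog, groups=groups).fit(reml=False)
            converged = bool(fit.converged)
    k = len(cells)
    cov = np.asarray(fit.cov_params())[:k, :k]
    return CellMeansModel(
        metric=metric,
        scale="linear",
        cells=cells,
        estimates=np.asarray(fit.fe_params, dtype=float),
        cov=cov,
        df=float(len(endog) - k),
        converged=converged,
        extra={"subject_sd": float(np.sqrt(max(np.asarray(fit.cov_re)[0, 0], 0.0))),
               "resid_sd": float(np.sqrt(fit.scale))},
    )


# ---------------------------------------------------------------------------
# mixed-effects logistic regression (random subject intercept)

def _glmm_negll(theta, y, n, ghx, ghw):
    """Negative marginal log-likelihood of the random-intercept logistic
    model, adaptive Gauss–Hermite quadrature, vectorized over subjects.

    y, n: (S, C) successes and trial counts (n=0 marks empty cells).
    """
    beta, log_sigma = theta[:-1], theta[-1]
    sigma = np.exp(log_sigma)

    def l_and_derivs(b):
        # b: (S,) or (S, K); returns conditional log-lik and derivatives
        eta = beta[None, :, None] + b[:, None, :] if b.ndim == 2 else (
            beta[None, :] + b[:, None]
        )
        p = 1.0 / (1.0 + np.exp(-eta))
        if b.ndim == 2:
            yb = y[:, :, None]
            nb = n[:, :, None]
            axis = 1
        else:
            yb, nb, axis = y, n, 1
        ll = np.sum(yb * eta - nb * np.log1p(np.exp(eta)), axis=axis)
        d1 = np.sum(yb - nb * p, axis=axis)
        d2 = -np.sum(nb * p * (1.0 - p), axis=axis)
        return ll, d1, d2

    # posterior mode per subject by Newton iterations
    b = np.zeros(y.shape[0])
    for _ in range(25):
        ll, d1, d2 = l_and_derivs(b)
        g = d1 - b / sigma**2
        h = d2 - 1.0 / sigma**2
        step = g / h
        b = b - np.clip(step, -5.0, 5.0)
        if np.max(np.abs(step)) < 1e-10:
            break
    _, _, d2 = l_and_derivs(b)
    tau = 1.0 / np.sqrt(-(d2 - 1.0 / sigma**2))  # Laplace scale per subject

    nodes = b[:, None] + np.sqrt(2.0) * tau[:, None] * ghx[None, :]
    ll_nodes, _, _ = l_and_derivs(nodes)
    logint = (
        ll_nodes
        - 0.5 * nodes**2 / sigma**2
        + ghx[None, :] ** 2
        + np.log(ghw)[None, :]
    )
    m = logint.max(axis=1, keepdims=True)
    per_subject = (
        np.log(np.sum(np.exp(logint - m), axis=1))
        + m[:, 0]
        + np.log(np.sqrt(2.0) * tau)
        - 0.5 * np.log(2.0 * np.pi)
        - log_sigma
    )
    return -float(np.sum(per_subject))


def fit_fbc_model(
    rt: pd.DataFrame,
    lat_limit: float = 60.0,
    cross_allow: float = 10.0,
    n_quad: int = 15,
    label_col: str | None = None,
) -> CellMeansModel:
    """Mixed-effects logistic regression for front-back confusions.

    Takes a (QC-filtered) trial-level response table, labels eligible
    trials with :func:`classify_fbc`, and fits cell-means fixed effects
    with a subject random intercept by adaptive Gauss–Hermite maximum
    likelihood.  Cells with complete separation (all-0 or all-1) are
    flagged unstable in ``extra['unstable_cells']``.
    """
    rt = rt.copy()
    if label_col is not None:
        fbc = rt[label_col].to_numpy(dtype=float)
    else:
        fbc = classify_fbc(
            rt.target_lat_deg, rt.target_pol_deg, rt.response_pol_deg,
            lat_limit, cross_allow,
        )
    if not np.all(np.isin(fbc[~np.isnan(fbc)], (0.0, 1.0))):
        raise ValueError("FBC labels must be binary (0/1, NaN for ineligible)")
    rt["_fbc"] = fbc
    rt = rt[rt._fbc.notna()]
    cells = _sorted_cells(set(zip(rt.cue_condition, rt.rotation)))
    subjects = sorted(pd.unique(rt.subject_id))
    agg = (
        rt.groupby(["subject_id", "cue_condition", "rotation"], observed=True)._fbc
        .agg(["sum", "count"])
    )
    S, C = len(subjects), len(cells)
    y = np.zeros((S, C))
    n = np.zeros((S, C))
    for (sub, cond, rot), row in agg.iterrows():
        if (cond, rot) in cells:
            y[subjects.index(sub), cells.index((cond, rot))] = row["sum"]
            n[subjects.index(sub), cells.index((cond, rot))] = row["count"]

    totals_y, totals_n = y.sum(axis=0), n.sum(axis=0)
    unstable = [
        cells[i] for i in range(C)
        if totals_y[i] == 0 or totals_y[i] == totals_n[i]
    ]
    if unstable:
        warnings.warn(
            f"complete separation in cells {unstable}; their contrasts are "
            "unstable", RuntimeWarning, stacklevel=2,
        )
    # empirical-logit start values
    beta0 = np.log((totals_y + 0.5) / (totals_n - totals_y + 0.5))
    theta0 = np.concatenate([beta0, [np.log(0.3)]])
    ghx, ghw = np.polynomial.hermite.hermgauss(n_quad)

    res = minimize(
        _glmm_negll, theta0, args=(y, n, ghx, ghw), method="L-BFGS-B",
        bounds=[(-12.0, 12.0)] * C + [(np.log(1e-4), np.log(10.0))],
    )
    from statsmodels.tools.numdiff import approx_hess

    hess = approx_hess(res.x, _glmm_negll, args=(y, n, ghx, ghw))
    try:
        cov_all = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov_all = np.linalg.pinv(hess)
    return CellMeansModel(
        metric="FBC",
        scale="logit",
        cells=cells,
        estimates=res.x[:C],
        cov=cov_all[:C, :C],
        df=np.inf,
        converged=bool(res.success),
        extra={
            "subject_sd_logodds": float(np.exp(res.x[-1])),
            "unstable_cells": unstable,
            "counts": {"successes": y.sum(), "trials": n.sum()},
        },
    )


# ---------------------------------------------------------------------------
# marginal-mean contrasts with Tukey adjustment

def _tukey_p(t_stat: float, k: int, df: float) -> float:
    if k < 2:
        return np.nan
    if k == 2:
        # single pair: Tukey reduces to the unadjusted two-sided test
        return _unadj_p(t_stat, df)
    return float(studentized_range.sf(abs(t_stat) * np.sqrt(2.0), k, df))


def _unadj_p(t_stat: float, df: float) -> float:
    if np.isinf(df):
        return float(2.0 * norm.sf(abs(t_stat)))
    return float(2.0 * t_dist.sf(abs(t_stat), df))


def marginal_contrasts(
    model: CellMeansModel,
    scheme: str = "by_cue",
    adjust: bool = True,
    pvalues: bool = True,
) -> pd.DataFrame:
    """Pairwise contrasts of estimated marginal means.

    ``by_cue`` compares rotation types within each cue condition;
    ``by_rotation`` compares cue conditions within each rotation type.
    Each grouping level forms one Tukey family.  Estimates are on the
    model's natural scale (degrees, or log-odds for the confusion model).
    With ``pvalues=False`` the p/significance columns are left NaN (the
    Wald statistic, family size and df still allow threshold tests, which
    the simulation harness uses to avoid thousands of studentized-range
    integrations).
    """
    if scheme == "by_cue":
        group_of, level_of = (lambda c: c[0]), (lambda c: c[1])
        group_order, level_order = CUE_ORDER, ROTATION_ORDER
    elif scheme == "by_rotation":
        group_of, level_of = (lambda c: c[1]), (lambda c: c[0])
        group_order, level_order = ROTATION_ORDER, CUE_ORDER
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    rows = []
    groups = sorted({group_of(c) for c in model.cells}, key=group_order.index)
    for g in groups:
        levels = sorted(
            [level_of(c) for c in model.cells if group_of(c) == g],
            key=level_order.index,
        )
        k = len(levels)
        for la, lb in itertools.combinations(levels, 2):
            ca = (la, g) if scheme == "by_rotation" else (g, la)
            cb = (lb, g) if scheme == "by_rotation" else (g, lb)
            ia, ib = model.cell_index(*ca), model.cell_index(*cb)
            est = model.estimates[ia] - model.estimates[ib]
            se = np.sqrt(
                model.cov[ia, ia] + model.cov[ib, ib] - 2.0 * model.cov[ia, ib]
            )
            t_stat = est / se if se > 0 else np.nan
            if pvalues:
                p_unadj = _unadj_p(t_stat, model.df)
                p_adj = _tukey_p(t_stat, k, model.df) if adjust else p_unadj
            else:
                p_unadj = p_adj = np.nan
            rows.append(
                {
                    "metric": model.metric,
                    "grouping": g,
                    "contrast": f"{la}/{lb}",
                    "estimate": est,
                    "se": se,
                    "stat": t_stat,
                    "df": model.df,
                    "k_family": k,
                    "p_unadj": p_unadj,
                    "p_tukey": p_adj,
                    "sig_05": p_adj < 0.05 if pvalues else np.nan,
                    "sig_001": p_adj < 0.001 if pvalues else np.nan,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# operating-characteristics harness

_CRIT_CACHE: dict = {}


def _crit_unadj(df: float, alpha: float) -> float:
    key = ("t", round(float(df), 3), alpha)
    if key not in _CRIT_CACHE:
        _CRIT_CACHE[key] = (
            norm.ppf(1 - alpha / 2)
            if np.isinf(df)
            else t_dist.ppf(1 - alpha / 2, df)
        )
    return _CRIT_CACHE[key]


def _crit_tukey(k: int, df: float, alpha: float) -> float:
    if k < 2:
        return np.inf
    if k == 2:
        return _crit_unadj(df, alpha) * np.sqrt(2.0)
    key = ("q", int(k), round(float(df), 3), alpha)
    if key not in _CRIT_CACHE:
        _CRIT_CACHE[key] = studentized_range.ppf(
            1 - alpha, k, 1e7 if np.isinf(df) else df
        )
    return _CRIT_CACHE[key]


def _wilson_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    z = norm.ppf(0.5 + level / 2.0)
    p = k / n
    denom = 1.0 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return center - half, center + half


def analyze_and_test(responses: pd.DataFrame, pvalues: bool = True) -> pd.DataFrame:
    """One full pass of the analysis chain: QC → metrics → models →
    contrast tables for LPE, PPE and FBC (both grouping schemes)."""
    filtered, _ = qc_filter(responses)
    mt = compute_metrics(filtered)
    frames = []
    for metric in ("LPE_deg", "PPE_deg"):
        model = fit_precision_model(mt, metric)
        for scheme in ("by_cue", "by_rotation"):
            frames.append(
                marginal_contrasts(model, scheme, pvalues=pvalues).assign(scheme=scheme)
            )
    fbc = fit_fbc_model(filtered)
    for scheme in ("by_cue", "by_rotation"):
        frames.append(
            marginal_contrasts(fbc, scheme, pvalues=pvalues).assign(scheme=scheme)
        )
    return pd.concat(frames, ignore_index=True)


def simulation_harness(
    params=None,
    n_subjects: int = 7,
    n_replicates: int = 200,
    seed: int | np.random.SeedSequence = 0,
    alpha: float = 0.05,
    static_reps: int = 1,
    dynamic_reps: int = 1,
) -> pd.DataFrame:
    """Empirical rejection rates of the analysis chain by simulation.

    Repeatedly simulates a full experiment with the given generating
    parameters, runs QC → metrics → mixed models → contrasts, and tallies
    per-contrast rejection rates at ``alpha`` (unadjusted and
    Tukey-adjusted) with Wilson Monte-Carlo confidence intervals.  Run
    with :meth:`ListenerParams.null` parameters for type-I error, with
    effect-bearing parameters for power.
    """
    from .simulate import ListenerParams, simulate_experiment

    if params is None:
        params = ListenerParams()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    tallies: dict = {}
    for rep_seed in ss.spawn(n_replicates):
        responses, _ = simulate_experiment(
            n_subjects=n_subjects,
            params=params,
            seed=rep_seed,
            static_reps=static_reps,
            dynamic_reps=dynamic_reps,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = analyze_and_test(responses, pvalues=False)
        for _, row in table.iterrows():
            key = (row.metric, row.scheme, row.grouping, row.contrast)
            rec = tallies.setdefault(key, {"n": 0, "rej_unadj": 0, "rej_tukey": 0})
            rec["n"] += 1
            rec["rej_unadj"] += int(abs(row.stat) > _crit_unadj(row.df, alpha))
            rec["rej_tukey"] += int(
                abs(row.stat) * np.sqrt(2.0)
                > _crit_tukey(row.k_family, row.df, alpha)
            )

    rows = []
    for (metric, scheme, grouping, contrast), rec in tallies.items():
        lo_u, hi_u = _wilson_ci(rec["rej_unadj"], rec["n"])
        lo_t, hi_t = _wilson_ci(rec["rej_tukey"], rec["n"])
        rows.append(
            {
                "metric": metric,
                "scheme": scheme,
                "grouping": grouping,
                "contrast": contrast,
                "n_replicates": rec["n"],
                "reject_rate_unadj": rec["rej_unadj"] / rec["n"],
                "ci_unadj_lo": lo_u,
                "ci_unadj_hi": hi_u,
                "reject_rate_tukey": rec["rej_tukey"] / rec["n"],
                "ci_tukey_lo": lo_t,
                "ci_tukey_hi": hi_t,
            }
        )
    return pd.DataFrame(rows)
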