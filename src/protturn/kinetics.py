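"""Degradation-rate estimation from 14N fraction time courses.

The light fraction of a protein at steady state decays as
``Fraction14N(t) = exp(-kd * t)``, so ``ln(fraction)`` is linear in time with
slope ``-kd``. Estimation proceeds in two stages:

1. Per-peptide OLS of ln(fraction) on time within each condition; peptides
   with r^2 <= 0.65 or detected in fewer than six samples are discarded.
2. Per-protein linear mixed-effects fit pooling the kept peptides, with a
   random intercept per peptide absorbing ionization-efficiency offsets; the
   fixed time coefficient gives kd, and the half-life is ln(2)/kd.

Proteins whose rate is estimated with a Wald p-value below 0.20 carry the
``reported`` flag; records with non-positive slope estimates are kept but
flagged non-physical (long-lived or noise-dominated).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

LN2 = float(np.log(2.0))

R2_MIN_DEFAULT = 0.65
MIN_SAMPLES_DEFAULT = 6  # "detected in more than five samples"
KD_P_MAX_DEFAULT = 0.20
# Guard for pathological near-zero fractions before the log transform; far
# below any intensity ratio a real instrument can produce (a half-life of
# 0.8 d still gives fraction ~1e-12 at day 32), so genuine decay signal is
# never clipped.
FRACTION_FLOOR = 1e-12


def half_life(kd: float) -> float:
    """Half-life in days, t1/2 = ln(2)/kd. Raises for non-positive rates."""
    if kd <= 0:
        raise ValueError(f"half-life undefined for kd <= 0 (got {kd})")
    return LN2 / kd


def _prepare_log_fraction(fractions: pd.DataFrame) -> pd.DataFrame:
    """Attach ln(fraction), flooring tiny values to keep the log finite."""
    frac = fractions["fraction14N"].to_numpy(dtype=float)
    n_floored = int((frac < FRACTION_FLOOR).sum())
    if n_floored:
        logger.info("floored %d fractions below %g before log", n_floored, FRACTION_FLOOR)
    out = fractions.copy()
    out["log_fraction"] = np.log(np.maximum(frac, FRACTION_FLOOR))
    return out


def fit_peptide_ols(
    fractions: pd.DataFrame,
    samples: pd.DataFrame,
    r2_min: float = R2_MIN_DEFAULT,
    min_samples: int = MIN_SAMPLES_DEFAULT,
) -> pd.DataFrame:
    """Per-peptide, per-condition OLS of ln(fraction) on time (free intercept).

    Vectorized via the closed-form normal equations on group sums. Returns one
    row per (peptide, organ, oxygen) with slope, r_squared, n_samples and the
    ``passes_filter`` flag: r^2 strictly above ``r2_min`` and at least
    ``min_samples`` observations within the condition. Peptides observed at
    fewer than two distinct time points, or with zero variance in
    ln(fraction), fail the filter (r^2 undefined).
    """
    df = _prepare_log_fraction(fractions).merge(
        samples[["sample_id", "organ", "oxygen", "time_days"]],
        on="sample_id",
        how="left",
        validate="many_to_one",
    )
    df["_t"] = df["time_days"].to_numpy(dtype=float)
    df["_y"] = df["log_fraction"]
    df["_tt"] = df["_t"] ** 2
    df["_yy"] = df["_y"] ** 2
    df["_ty"] = df["_t"] * df["_y"]
    keys = ["peptide_id", "protein_id", "organ", "oxygen"]
    g = df.groupby(keys, sort=True)
    agg = g.agg(
        n=("_t", "size"),
        n_t=("_t", "nunique"),
        st=("_t", "sum"),
        sy=("_y", "sum"),
        stt=("_tt", "sum"),
        syy=("_yy", "sum"),
        sty=("_ty", "sum"),
    ).reset_index()

    n = agg["n"].to_numpy(dtype=float)
    sxx = agg["stt"] - agg["st"] ** 2 / n
    syy = agg["syy"] - agg["sy"] ** 2 / n
    sxy = agg["sty"] - agg["st"] * agg["sy"] / n
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(sxx > 0, sxy / sxx, np.nan)
        r2 = np.where((sxx > 0) & (syy > 0), sxy**2 / (sxx * syy), np.nan)
    # Guard rounding: r^2 of an exact fit can land at 1 + eps.
    r2 = np.clip(r2, 0.0, 1.0)

    fits = agg[keys + ["n"]].rename(columns={"n": "n_samples"}).copy()
    fits["slope"] = slope
    fits["r_squared"] = r2
    fits["passes_filter"] = (
        (fits["r_squared"] > r2_min).fillna(False)
        & (fits["n_samples"] >= min_samples)
        & (agg["n_t"] >= 2)
    )
    n_skipped = int((agg["n_t"] < 2).sum())
    if n_skipped:
        logger.info("%d peptide/condition fits skipped (<2 distinct time points)", n_skipped)
    logger.info(
        "peptide OLS: %d fits, %d pass filter (r2 > %g, n >= %d)",
        len(fits),
        int(fits["passes_filter"].sum()),
        r2_min,
        min_samples,
    )
    return fits


def filter_peptides(fits: pd.DataFrame) -> pd.DataFrame:
    """Kept (peptide, condition) rows — those whose ``passes_filter`` flag is set."""
    return fits.loc[fits["passes_filter"], ["peptide_id", "protein_id", "organ", "oxygen"]]


def _pooled_ols(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Closed-form OLS slope, its standard error and two-sided t-test p-value."""
    n = len(t)
    tbar, ybar = t.mean(), y.mean()
    sxx = float(((t - tbar) ** 2).sum())
    slope = float(((t - tbar) * (y - ybar)).sum() / sxx)
    resid = y - ybar - slope * (t - tbar)
    dof = n - 2
    if dof <= 0:
        return slope, np.nan, np.nan
    s2 = float((resid**2).sum()) / dof
    se = float(np.sqrt(s2 / sxx))
    if se == 0.0:
        return slope, 0.0, 0.0 if slope != 0 else 1.0
    pval = 2.0 * sps.t.sf(abs(slope) / se, dof)
    return slope, se, float(pval)


def _lmm_time_fit(sub: pd.DataFrame) -> tuple[float, float, float, bool]:
    """Random-intercept LMM of ln(fraction) on time; returns slope, se, p, converged."""
    import statsmodels.api as sm

    exog = sm.add_constant(sub["_t"].to_numpy())
    endog = sub["_y"].to_numpy()
    groups = sub["peptide_id"].to_numpy()
    # Conjugate gradient with a tight gradient tolerance: near-boundary
    # variance components make lbfgs path-dependent (it can collapse the
    # random-effect variance to zero), while cg reproduces the REML optimum
    # to ~1e-14 under infinitesimal input perturbations (loading rescales).
    for reml in (True, False):
        for method, opts in (
            ("cg", {"gtol": 1e-10}),
            ("lbfgs", {"pgtol": 1e-12, "factr": 10.0}),
        ):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model = sm.MixedLM(endog, exog, groups=groups)
                    res = model.fit(reml=reml, method=method, maxiter=500, **opts)
                if np.isfinite(res.params[1]) and np.isfinite(res.bse[1]) and res.bse[1] > 0:
                    return (
                        float(res.params[1]),
                        float(res.bse[1]),
                        float(res.pvalues[1]),
                        bool(res.converged),
                    )
            except (np.linalg.LinAlgError, ValueError):
                continue
    return np.nan, np.nan, np.nan, False


def fit_protein_lmm(
    protein_fractions: pd.DataFrame,
    kd_p_max: float = KD_P_MAX_DEFAULT,
) -> dict:
    """Fit one protein in one condition; expects columns peptide_id, _t, _y.

    With a single kept peptide (or a residual variance too small for the
    mixed model to be identified, or on convergence failure) the fit falls
    back to pooled OLS and ``fit_method`` records it. kd is minus the time
    coefficient; the ``reported`` flag applies the p < ``kd_p_max`` rule.
    """
    peptides = protein_fractions["peptide_id"].unique()
    t = protein_fractions["_t"].to_numpy(dtype=float)
    y = protein_fractions["_y"].to_numpy(dtype=float)

    fit_method = "lmm"
    converged = True
    single = len(peptides) == 1
    # A (near-)exact log-linear fit leaves no residual variance for the mixed
    # model; pooled OLS is then the same estimator and is exact.
    degenerate = False
    if not single:
        slope0, _, _ = _pooled_ols(t, y)
        resid = y - y.mean() - slope0 * (t - t.mean())
        degenerate = float(np.var(resid)) < 1e-12
    if single or degenerate:
        slope, se, pval = _pooled_ols(t, y)
        fit_method = "ols_fallback"
    else:
        slope, se, pval, converged = _lmm_time_fit(protein_fractions)
        if not np.isfinite(slope):
            slope, se, pval = _pooled_ols(t, y)
            fit_method = "ols_fallback"
            converged = False

    kd = -slope
    return {
        "kd": kd,
        "se_kd": se,
        "p_value": pval,
        "half_life_days": LN2 / kd if kd > 0 else np.nan,
        "nonphysical": kd <= 0,
        "n_peptides_used": len(peptides),
        "n_obs": len(protein_fractions),
        "fit_method": fit_method,
        "converged": converged,
        "reported": bool(np.isfinite(pval) and pval < kd_p_max),
    }


def fit_all_proteins(
    fractions: pd.DataFrame,
    samples: pd.DataFrame,
    kept: pd.DataFrame,
    kd_p_max: float = KD_P_MAX_DEFAULT,
) -> pd.DataFrame:
    """Per-protein, per-condition mixed-effects rate estimates.

    ``kept`` is the filtered peptide/condition table from
    :func:`filter_peptides`; proteins with no kept peptide in a condition are
    absent from the output (counted in the log).
    """
    df = _prepare_log_fraction(fractions).merge(
        samples[["sample_id", "organ", "oxygen", "time_days"]],
        on="sample_id",
        how="left",
        validate="many_to_one",
    )
    df["_t"] = df["time_days"].astype(float)
    df["_y"] = df["log_fraction"]
    keys = ["peptide_id", "organ", "oxygen"]
    df = df.merge(kept[keys].drop_duplicates(), on=keys, how="inner")

    n_candidates = fractions.groupby(["protein_id"]).ngroups
    records = []
    for (protein, organ, oxy), sub in df.groupby(["protein_id", "organ", "oxygen"], sort=True):
        if sub["_t"].nunique() < 2:
            continue
        rec = fit_protein_lmm(sub, kd_p_max=kd_p_max)
        rec.update({"protein_id": protein, "organ": organ, "oxygen": oxy})
        records.append(rec)
    out = pd.DataFrame(records)
    if not out.empty:
        out = out[
            [
                "protein_id",
                "organ",
                "oxygen",
                "kd",
                "se_kd",
                "p_value",
                "half_life_days",
                "nonphysical",
                "n_peptides_used",
                "n_obs",
                "fit_method",
                "converged",
                "reported",
            ]
        ]
    n_fallback = int((out["fit_method"] == "ols_fallback").sum()) if len(out) else 0
    logger.info(
        "protein fits: %d records from %d candidate proteins (%d OLS fallbacks)",
        len(out),
        n_candidates,
        n_fallback,
    )
    return out


def summarize_half_lives(
    records: pd.DataFrame,
    by: tuple[str, ...] = ("organ", "oxygen"),
    valid_range: tuple[float, float] = (0.5, 64.0),
) -> pd.DataFrame:
    """Median/IQR/count of half-lives per group, with an out-of-window count.

    Half-lives outside ``valid_range`` (default 0.5-64 days, roughly the
    range a 1-32 day labeling window can resolve) are counted but retained.
    """
    valid = records.dropna(subset=["half_life_days"])
    rows = []
    for key, grp in valid.groupby(list(by), sort=True):
        hl = grp["half_life_days"]
        if hl.empty:
            logger.warning("half-life summary: empty group %s omitted", key)
            continue
        key = key if isinstance(key, tuple) else (key,)
        rows.append(
            dict(zip(by, key))
            | {
                "median_days": float(hl.median()),
                "q1_days": float(hl.quantile(0.25)),
                "q3_days": float(hl.quantile(0.75)),
                "n": int(len(hl)),
                "n_out_of_range": int(
                    ((hl < valid_range[0]) | (hl > valid_range[1])).sum()
                ),
            }
        )
    return pd.DataFrame(rows)
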