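"""Differential turnover between oxygen tensions via the interaction model.

For each protein within one organ, ln(fraction) across two oxygen tensions is
modeled with fixed effects {oxygen indicator, time, oxygen x time} and a
random intercept per peptide. The time coefficient gives the reference-oxygen
rate (kd_ref = -b_time); the interaction coefficient is the slope difference,
so kd_alt = -(b_time + b_interaction), and its Wald test asks whether the two
degradation rates differ. p-values are Benjamini-Hochberg adjusted within one
organ x contrast family, and proteins are called faster/slower when the rate
fold change exceeds 1.3 with FDR below 0.05 (both strict).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

FC_THRESHOLD_DEFAULT = 1.3
FDR_THRESHOLD_DEFAULT = 0.05


def _interaction_design(sub: pd.DataFrame, oxy_ref: str) -> tuple[np.ndarray, np.ndarray]:
    oxy = (sub["oxygen"].to_numpy() != oxy_ref).astype(float)
    t = sub["_t"].to_numpy(dtype=float)
    exog = np.column_stack([np.ones_like(t), oxy, t, oxy * t])
    return exog, sub["_y"].to_numpy(dtype=float)


def _ols_interaction(exog: np.ndarray, endog: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closed-form OLS for the 4-column interaction design; Wald t p-values."""
    n, p = exog.shape
    xtx = exog.T @ exog
    beta = np.linalg.solve(xtx, exog.T @ endog)
    resid = endog - exog @ beta
    dof = n - p
    if dof <= 0:
        return beta, np.full(p, np.nan), np.full(p, np.nan)
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(xtx)
    se = np.sqrt(np.diag(cov))
    from scipy import stats as sps

    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = 2.0 * sps.t.sf(np.abs(tstat), dof)
    pvals = np.where(se > 0, pvals, np.where(beta == 0, 1.0, 0.0))
    return beta, se, pvals


def fit_interaction_lmm(sub: pd.DataFrame, oxy_ref: str, oxy_alt: str) -> dict:
    """Fit the oxygen x time interaction model for one protein in one organ.

    ``sub`` holds the kept-peptide fraction rows of both conditions with
    columns peptide_id, oxygen, _t (time) and _y (ln fraction). Falls back to
    pooled OLS with the same design when the mixed model is degenerate or
    fails to converge.
    """
    import statsmodels.api as sm

    exog, endog = _interaction_design(sub, oxy_ref)
    single = sub["peptide_id"].nunique() == 1

    beta0, _, _ = _ols_interaction(exog, endog)
    resid0 = endog - exog @ beta0
    degenerate = float(np.var(resid0)) < 1e-12

    fit_method = "lmm"
    converged = True
    beta = se = pvals = None
    if not (single or degenerate):
        # cg with tight gtol: stable at near-boundary variance components
        # (lbfgs is kept as fallback); see kinetics._lmm_time_fit.
        attempts = [
            (reml, method, opts)
            for reml in (True, False)
            for method, opts in (
                ("cg", {"gtol": 1e-10}),
                ("lbfgs", {"pgtol": 1e-12, "factr": 10.0}),
            )
        ]
        for reml, method, opts in attempts:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model = sm.MixedLM(endog, exog, groups=sub["peptide_id"].to_numpy())
                    res = model.fit(reml=reml, method=method, maxiter=500, **opts)
                if np.all(np.isfinite(res.params[:4])) and np.isfinite(res.bse[3]) and res.bse[3] > 0:
                    beta, se, pvals = res.params[:4], res.bse[:4], res.pvalues[:4]
                    converged = bool(res.converged)
                    break
            except (np.linalg.LinAlgError, ValueError):
                continue
    if beta is None:
        beta, se, pvals = _ols_interaction(exog, endog)
        fit_method = "ols_fallback"
        converged = not (single or degenerate)
        if single or degenerate:
            converged = True

    kd_ref = -float(beta[2])
    kd_alt = -float(beta[2] + beta[3])
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = float(beta[3] / se[3]) if se[3] > 0 else np.nan
    nonphysical = kd_ref <= 0 or kd_alt <= 0
    log2_fc = float(np.log2(kd_alt / kd_ref)) if not nonphysical else np.nan
    return {
        "oxy_ref": oxy_ref,
        "oxy_alt": oxy_alt,
        "kd_ref": kd_ref,
        "kd_alt": kd_alt,
        "log2_fc": log2_fc,
        "p_interaction": float(pvals[3]),
        "t_statistic": tstat,
        "nonphysical": nonphysical,
        "n_peptides_used": int(sub["peptide_id"].nunique()),
        "fit_method": fit_method,
        "converged": converged,
    }


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify(
    log2_fc,
    fdr,
    fc_threshold: float = FC_THRESHOLD_DEFAULT,
    fdr_threshold: float = FDR_THRESHOLD_DEFAULT,
) -> np.ndarray:
    """faster / slower / ns labels; both thresholds strict.

    faster: kd_alt exceeds kd_ref by more than ``fc_threshold``-fold at
    FDR below ``fdr_threshold``; slower is the mirror image.
    """
    log2_fc = np.asarray(log2_fc, dtype=float)
    fdr = np.asarray(fdr, dtype=float)
    log2_thr = np.log2(fc_threshold)
    sig = fdr < fdr_threshold
    out = np.full(log2_fc.shape, "ns", dtype=object)
    with np.errstate(invalid="ignore"):
        out[sig & (log2_fc > log2_thr)] = "faster"
        out[sig & (-log2_fc > log2_thr)] = "slower"
    return out


def run_differential(
    fractions: pd.DataFrame,
    samples: pd.DataFrame,
    peptide_fits: pd.DataFrame,
    oxy_ref: str,
    oxy_alt: str,
    organs=None,
    filter_mode: str = "any",
    fc_threshold: float = FC_THRESHOLD_DEFAULT,
    fdr_threshold: float = FDR_THRESHOLD_DEFAULT,
) -> pd.DataFrame:
    """Interaction fits for every protein, BH correction, and class labels.

    ``filter_mode`` controls peptide eligibility: "any" keeps peptides passing
    the r^2/n filter in at least one of the two conditions (default), "both"
    requires both. The BH family is all proteins within one organ x contrast.
    """
    from .kinetics import _prepare_log_fraction

    if filter_mode not in ("any", "both"):
        raise ValueError("filter_mode must be 'any' or 'both'")

    df = _prepare_log_fraction(fractions).merge(
        samples[["sample_id", "organ", "oxygen", "time_days"]],
        on="sample_id",
        how="left",
        validate="many_to_one",
    )
    df["_t"] = df["time_days"].astype(float)
    df["_y"] = df["log_fraction"]
    df = df.loc[df["oxygen"].isin([oxy_ref, oxy_alt])]
    if organs is not None:
        df = df.loc[df["organ"].isin(list(organs))]

    fits = peptide_fits.loc[peptide_fits["oxygen"].isin([oxy_ref, oxy_alt])]
    passes = (
        fits.groupby(["peptide_id", "organ"])["passes_filter"]
        .agg("any" if filter_mode == "any" else "all")
        .rename("eligible")
    )
    df = df.join(passes, on=["peptide_id", "organ"])
    df = df.loc[df["eligible"].fillna(False).astype(bool)]

    records = []
    n_skipped = 0
    for (organ, protein), sub in df.groupby(["organ", "protein_id"], sort=True):
        present = set(sub["oxygen"])
        if oxy_ref not in present or oxy_alt not in present:
            n_skipped += 1
            continue
        rec = fit_interaction_lmm(sub, oxy_ref, oxy_alt)
        rec.update({"protein_id": protein, "organ": organ})
        records.append(rec)
    if n_skipped:
        logger.info("differential: %d proteins skipped (one condition missing)", n_skipped)
    out = pd.DataFrame(records)
    if out.empty:
        logger.warning("differential: no testable proteins")
        return out

    out["contrast"] = f"{oxy_alt}-vs-{oxy_ref}"
    out["fdr"] = np.nan
    for organ, idx in out.groupby("organ").groups.items():
        out.loc[idx, "fdr"] = bh_adjust(out.loc[idx, "p_interaction"].to_numpy())
    out["class"] = classify(out["log2_fc"], out["fdr"], fc_threshold, fdr_threshold)
    out.loc[out["nonphysical"], "class"] = "ns"
    logger.info(
        "differential: %d proteins tested, %d significant calls",
        len(out),
        int((out["class"] != "ns").sum()),
    )
    cols = [
        "protein_id",
        "organ",
        "contrast",
        "oxy_ref",
        "oxy_alt",
        "kd_ref",
        "kd_alt",
        "log2_fc",
        "t_statistic",
        "p_interaction",
        "fdr",
        "class",
        "nonphysical",
        "n_peptides_used",
        "fit_method",
        "converged",
    ]
    return out[cols]


def summarize_fraction_significant(records: pd.DataFrame, by=("organ", "contrast")) -> pd.DataFrame:
    """Percent of tested proteins called faster or slower, per group."""
    rows = []
    for key, grp in records.groupby(list(by), sort=True):
        if grp.empty:
            continue
        key = key if isinstance(key, tuple) else (key,)
        n_sig = int((grp["class"] != "ns").sum())
        rows.append(
            dict(zip(by, key))
            | {
                "n_tested": len(grp),
                "n_faster": int((grp["class"] == "faster").sum()),
                "n_slower": int((grp["class"] == "slower").sum()),
                "percent_significant": 100.0 * n_sig / len(grp),
            }
        )
    return pd.DataFrame(rows)
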