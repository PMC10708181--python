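"""Ingestion and normalization: raw light-channel intensities -> 14N fractions.

Two corrections precede kinetic fitting. First, per-sample loading/acquisition
differences are removed by centering each sample on a panel of long-lived
proteins assumed to have fixed abundance over the labeling window. Second,
each peptide's normalized abundance is divided by its own baseline (day-0)
abundance, giving the fraction of the pre-pulse, light-isotope pool that
remains — the quantity that decays as exp(-kd * t).
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ABUNDANCE_COLUMNS = ("peptide_id", "protein_id", "sample_id", "abundance")
SAMPLE_COLUMNS = ("sample_id", "organ", "oxygen", "time_days", "replicate")

BASELINE_MODES = ("explicit_t0", "condition_t0", "fitted_intercept")


class SchemaError(ValueError):
    """A required column is missing or a table violates its contract."""


class ReferentialError(ValueError):
    """Cross-table references (e.g. sample ids) do not resolve."""


def _read_delimited(path, required: Sequence[str], label: str) -> pd.DataFrame:
    """Read a TSV/CSV (gzip ok), sniffing the delimiter, and check columns."""
    df = pd.read_csv(path, sep=None, engine="python", compression="infer")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{label} table {path} missing column(s): {missing}")
    return df


def read_tables(abundance_path, samples_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read abundance and sample-metadata tables and enforce their contracts.

    Rows with non-numeric or non-positive abundance are dropped (with a logged
    count); sample ids present in the abundance table but absent from the
    metadata raise a :class:`ReferentialError`.
    """
    abund = _read_delimited(abundance_path, ABUNDANCE_COLUMNS, "abundance")
    samples = _read_delimited(samples_path, SAMPLE_COLUMNS, "sample")

    abund = abund.loc[:, list(ABUNDANCE_COLUMNS)].copy()
    abund["abundance"] = pd.to_numeric(abund["abundance"], errors="coerce")
    n_in = len(abund)
    abund = abund.dropna(subset=["abundance"])
    abund = abund.loc[abund["abundance"] > 0]
    n_dropped = n_in - len(abund)
    if n_dropped:
        logger.warning(
            "dropped %d of %d abundance rows (non-numeric or non-positive)",
            n_dropped,
            n_in,
        )
    if abund.duplicated(["peptide_id", "sample_id"]).any():
        raise SchemaError("duplicate (peptide_id, sample_id) rows in abundance table")

    samples = samples.loc[:, list(SAMPLE_COLUMNS)].copy()
    samples["oxygen"] = samples["oxygen"].astype(str)
    samples["time_days"] = pd.to_numeric(samples["time_days"])
    if samples["sample_id"].duplicated().any():
        raise SchemaError("duplicate sample_id in sample table")
    if (samples["time_days"] < 0).any():
        raise SchemaError("time_days must be non-negative")

    unknown = set(abund["sample_id"]) - set(samples["sample_id"])
    if unknown:
        raise ReferentialError(
            f"abundance table references unknown sample id(s): {sorted(unknown)[:5]}"
        )
    return abund.reset_index(drop=True), samples.reset_index(drop=True)


def read_panel(path) -> list[str]:
    """Read the long-lived protein panel: one protein id per line."""
    with open(path) as fh:
        panel = [line.strip() for line in fh if line.strip() and not line.startswith("#")]
    if not panel:
        raise SchemaError(f"panel file {path} is empty")
    return panel


def compute_sample_factors(
    abund: pd.DataFrame,
    samples: pd.DataFrame,
    panel: Iterable[str],
    method: str = "geomean",
) -> pd.Series:
    """Per-sample scaling factors from the long-lived panel.

    The default ``geomean`` method fits the two-way additive model
    ``log(abundance) = peptide_effect + sample_effect`` over the panel rows by
    least squares and takes ``factor = exp(sample_effect)``, rescaled so the
    factors have geometric mean 1. On complete panel data this is exactly the
    geometric mean over panel peptides of (abundance / the peptide's
    geometric-mean abundance across samples); unlike that ratio form it stays
    *exactly* invariant when a sample is rescaled even if some panel peptides
    are missing in some samples. ``method="median"`` is a robust log-median
    centering variant (invariance only approximate under missingness).

    The panel is assumed to have fixed true abundance, so any common
    multiplicative shift of a sample is absorbed entirely into its factor.
    """
    if method not in ("geomean", "median"):
        raise ValueError("method must be 'geomean' or 'median'")
    panel = set(panel)
    sub = abund.loc[abund["protein_id"].isin(panel)].copy()
    sample_ids = samples["sample_id"].tolist()
    missing = set(sample_ids) - set(sub["sample_id"])
    if missing:
        raise ReferentialError(
            "no panel peptide observed in sample(s): " + ", ".join(sorted(missing))
        )
    sub["log_ab"] = np.log(sub["abundance"].to_numpy())
    if method == "geomean":
        pep_codes, _ = pd.factorize(sub["peptide_id"], sort=True)
        smp_index = pd.Index(sample_ids)
        smp_codes = smp_index.get_indexer(sub["sample_id"])
        n_pep, n_smp = pep_codes.max() + 1, len(smp_index)
        X = np.zeros((len(sub), n_pep + n_smp))
        X[np.arange(len(sub)), pep_codes] = 1.0
        X[np.arange(len(sub)), n_pep + smp_codes] = 1.0
        beta, *_ = np.linalg.lstsq(X, sub["log_ab"].to_numpy(), rcond=None)
        log_factor = pd.Series(beta[n_pep:], index=smp_index)
    else:
        sub["log_rel"] = sub["log_ab"] - sub.groupby("peptide_id")["log_ab"].transform(
            "median"
        )
        log_factor = sub.groupby("sample_id")["log_rel"].median()
    log_factor = log_factor - log_factor.mean()  # geometric mean of factors = 1
    factors = np.exp(log_factor).reindex(sample_ids)
    factors.name = "factor"
    logger.info(
        "sample factors from %d panel proteins (%d peptides): range %.3g-%.3g",
        sub["protein_id"].nunique(),
        sub["peptide_id"].nunique(),
        factors.min(),
        factors.max(),
    )
    return factors


def normalize(abund: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """Divide each abundance by its sample's factor."""
    missing = set(abund["sample_id"]) - set(factors.index)
    if missing:
        raise ReferentialError(f"factors missing for sample(s): {sorted(missing)[:5]}")
    out = abund.copy()
    out["abundance"] = out["abundance"].to_numpy() / factors.loc[
        out["sample_id"]
    ].to_numpy()
    return out


def compute_fraction(
    normalized: pd.DataFrame,
    samples: pd.DataFrame,
    baseline_mode: str = "condition_t0",
) -> pd.DataFrame:
    """Convert normalized abundances to 14N fractions via per-peptide baselines.

    baseline_mode
        ``condition_t0`` (default): baseline = mean of the peptide's day-0
        normalized abundances within each organ x oxygen condition, so
        conditions with different pre-labeling abundance are not mixed.
        ``explicit_t0``: one global day-0 baseline per peptide.
        ``fitted_intercept``: baseline = exp(intercept) of an OLS fit of
        log-abundance on time per peptide per condition — for datasets with
        no day-0 samples.

    Rows whose baseline cannot be formed are dropped with a logged count.
    Fractions above 1 (noise) are retained; truncation would bias early-time
    slopes.
    """
    if baseline_mode not in BASELINE_MODES:
        raise ValueError(f"baseline_mode must be one of {BASELINE_MODES}")
    merged = normalized.merge(
        samples[["sample_id", "organ", "oxygen", "time_days"]],
        on="sample_id",
        how="left",
        validate="many_to_one",
    )
    n_in = len(merged)

    if baseline_mode in ("explicit_t0", "condition_t0"):
        t0 = merged.loc[merged["time_days"] == 0]
        if t0.empty:
            raise ValueError(
                "no day-0 samples present; use baseline_mode='fitted_intercept'"
            )
        keys = ["peptide_id"] if baseline_mode == "explicit_t0" else [
            "peptide_id",
            "organ",
            "oxygen",
        ]
        baseline = t0.groupby(keys)["abundance"].mean().rename("baseline")
        merged = merged.join(baseline, on=keys)
    else:
        keys = ["peptide_id", "organ", "oxygen"]
        merged["_log_ab"] = np.log(merged["abundance"].to_numpy())
        grp = merged.groupby(keys)
        stats = grp.agg(
            n=("time_days", "size"),
            n_t=("time_days", "nunique"),
            mt=("time_days", "mean"),
            my=("_log_ab", "mean"),
        )
        # slope = cov(t, y) / var(t); intercept = mean(y) - slope * mean(t)
        cov = grp.apply(
            lambda g: np.cov(g["time_days"], g["_log_ab"], ddof=0)[0, 1],
            include_groups=False,
        )
        var = grp["time_days"].var(ddof=0)
        slope = cov / var.replace(0.0, np.nan)
        intercept = stats["my"] - slope * stats["mt"]
        intercept[stats["n_t"] < 2] = np.nan
        baseline = np.exp(intercept).rename("baseline")
        merged = merged.drop(columns="_log_ab").join(baseline, on=keys)

    merged = merged.dropna(subset=["baseline"])
    n_dropped = n_in - len(merged)
    if n_dropped:
        logger.info(
            "fraction: dropped %d of %d rows lacking a %s baseline",
            n_dropped,
            n_in,
            baseline_mode,
        )
    merged["fraction14N"] = merged["abundance"].to_numpy() / merged[
        "baseline"
    ].to_numpy()
    out = merged[
        ["peptide_id", "protein_id", "sample_id", "fraction14N"]
    ].reset_index(drop=True)
    logger.info("fraction table: %d rows (%d in, %d dropped)", len(out), n_in, n_dropped)
    return out


def fractions_from_raw(
    abund: pd.DataFrame,
    samples: pd.DataFrame,
    panel: Iterable[str],
    baseline_mode: str = "condition_t0",
    method: str = "geomean",
) -> pd.DataFrame:
    """Convenience pipeline: factors -> normalize -> fractions."""
    factors = compute_sample_factors(abund, samples, panel, method=method)
    return compute_fraction(normalize(abund, factors), samples, baseline_mode)
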