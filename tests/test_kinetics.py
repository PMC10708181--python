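"""Peptide OLS pre-filter and per-protein mixed-effects rate estimation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar

from protturn import (
    filter_peptides,
    fit_all_proteins,
    fit_peptide_ols,
    fit_protein_lmm,
    fractions_from_raw,
    half_life,
    summarize_half_lives,
)
from protturn.kinetics import LN2, _pooled_ols


def _samples(times, organ="lung", oxygen="21"):
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(len(times))],
            "organ": organ,
            "oxygen": oxygen,
            "time_days": times,
            "replicate": 1,
        }
    )


def _fractions(times, values, peptide="p1", protein="A"):
    return pd.DataFrame(
        {
            "peptide_id": peptide,
            "protein_id": protein,
            "sample_id": [f"s{i}" for i in range(len(times))],
            "fraction14N": values,
        }
    )


class TestPeptideOLS:
    def test_exact_exponential_gives_slope_and_unit_r2(self):
        t = np.array([0, 1, 2, 4, 8, 16, 32], dtype=float)
        fits = fit_peptide_ols(_fractions(t, np.exp(-0.2 * t)), _samples(t))
        row = fits.iloc[0]
        assert row["slope"] == pytest.approx(-0.2, rel=1e-12)
        assert row["r_squared"] == pytest.approx(1.0, abs=1e-12)
        assert row["n_samples"] == 7
        assert row["passes_filter"]

    def test_constant_fraction_fails_filter(self):
        t = np.array([0, 1, 2, 4, 8, 16, 32], dtype=float)
        fits = fit_peptide_ols(_fractions(t, np.ones(7)), _samples(t))
        row = fits.iloc[0]
        assert row["slope"] == 0.0
        assert np.isnan(row["r_squared"]) or row["r_squared"] == 0.0
        assert not row["passes_filter"]

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(3)
        t = np.repeat([0, 1, 2, 4, 8, 16, 32], 3).astype(float)
        y = np.exp(-0.15 * t + rng.normal(0, 0.1, t.size))
        fits = fit_peptide_ols(_fractions(t, y), _samples(t))
        # Oracle: direct normal-equation solve on ln(y).
        X = np.column_stack([np.ones_like(t), t])
        beta = np.linalg.solve(X.T @ X, X.T @ np.log(y))
        resid = np.log(y) - X @ beta
        r2 = 1 - (resid @ resid) / np.sum((np.log(y) - np.log(y).mean()) ** 2)
        assert fits.iloc[0]["slope"] == pytest.approx(beta[1], abs=1e-10)
        assert fits.iloc[0]["r_squared"] == pytest.approx(r2, abs=1e-10)

    def test_single_timepoint_fails_gracefully(self):
        t = np.array([4.0, 4.0, 4.0])
        fits = fit_peptide_ols(_fractions(t, [0.4, 0.5, 0.45]), _samples(t))
        assert not fits.iloc[0]["passes_filter"]


class TestFilterBoundaries:
    @pytest.mark.parametrize(
        "r2, n, kept",
        [
            (0.65, 6, False),  # r^2 must strictly exceed 0.65
            (0.66, 5, False),  # "more than five samples" means >= 6
            (0.66, 6, True),
            (0.99, 5, False),
            (0.64, 10, False),
        ],
    )
    def test_strict_thresholds(self, r2, n, kept):
        fits = pd.DataFrame(
            {
                "peptide_id": ["p"],
                "protein_id": ["A"],
                "organ": ["lung"],
                "oxygen": ["21"],
                "n_samples": [n],
                "slope": [-0.1],
                "r_squared": [r2],
            }
        )
        fits["passes_filter"] = (fits["r_squared"] > 0.65) & (fits["n_samples"] >= 6)
        assert bool(filter_peptides(fits).shape[0]) == kept

    def test_filter_applied_within_condition(self, noisy_dataset):
        cfg, ds = noisy_dataset
        fr = fractions_from_raw(ds["abundance"], ds["design"], ds["panel"]["protein_id"])
        fits = fit_peptide_ols(fr, ds["design"])
        assert fits.equals(fits)  # one row per peptide x condition
        assert not fits.duplicated(["peptide_id", "organ", "oxygen"]).any()
        assert (
            fits["passes_filter"]
            == ((fits["r_squared"] > 0.65).fillna(False) & (fits["n_samples"] >= 6))
        ).all()


def _lmm_input(times, peptide_series):
    rows = []
    for pep, y in peptide_series.items():
        for t, v in zip(times, y):
            rows.append({"peptide_id": pep, "_t": t, "_y": np.log(v)})
    return pd.DataFrame(rows)


def _profile_reml_slope(df):
    """Independent oracle: profile REML over the variance ratio.

    Random-intercept model y = a + b t + u_pep + e; for each ratio
    lambda = var(u)/var(e), GLS gives the fixed effects in closed form and
    the profiled REML criterion is maximized over lambda by 1-D search.
    """
    peps = df["peptide_id"].unique()
    Z = (df["peptide_id"].to_numpy()[:, None] == peps[None, :]).astype(float)
    X = np.column_stack([np.ones(len(df)), df["_t"].to_numpy()])
    y = df["_y"].to_numpy()
    n, p = X.shape

    def neg_reml(log_lam):
        lam = np.exp(log_lam)
        V = np.eye(n) + lam * Z @ Z.T
        Vi = np.linalg.inv(V)
        XtVX = X.T @ Vi @ X
        beta = np.linalg.solve(XtVX, X.T @ Vi @ y)
        r = y - X @ beta
        s2 = (r @ Vi @ r) / (n - p)
        _, ld_V = np.linalg.slogdet(V)
        _, ld_X = np.linalg.slogdet(XtVX)
        return 0.5 * (ld_V + (n - p) * np.log(s2) + ld_X)

    res = minimize_scalar(neg_reml, bounds=(-12, 8), method="bounded",
                          options={"xatol": 1e-10})
    lam = np.exp(res.x)
    V = np.eye(n) + lam * Z @ Z.T
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    return beta[1]


class TestProteinLMM:
    def test_single_peptide_reduces_to_ols(self):
        t = np.array([0, 1, 2, 4, 8, 16, 32], dtype=float)
        df = _lmm_input(t, {"p1": np.exp(-0.1 * t)})
        rec = fit_protein_lmm(df)
        assert rec["fit_method"] == "ols_fallback"
        assert rec["kd"] == pytest.approx(0.1, rel=1e-12)
        assert rec["half_life_days"] == pytest.approx(LN2 / 0.1, rel=1e-12)
        slope, _, _ = _pooled_ols(df["_t"].to_numpy(), df["_y"].to_numpy())
        assert rec["kd"] == -slope  # exact equality with closed-form OLS

    def test_identical_peptides_match_single_peptide_slope(self):
        t = np.array([0, 1, 2, 4, 8, 16, 32], dtype=float)
        series = np.exp(-0.25 * t)
        df = _lmm_input(t, {f"p{i}": series for i in range(3)})
        rec = fit_protein_lmm(df)
        assert rec["kd"] == pytest.approx(0.25, rel=1e-10)

    def test_matches_profile_likelihood_oracle(self):
        rng = np.random.default_rng(17)
        t = np.repeat([0, 1, 2, 4, 8, 16, 32], 2).astype(float)
        series = {}
        for i in range(3):
            offset = np.exp(rng.normal(0, 0.3))
            series[f"p{i}"] = offset * np.exp(-0.12 * t + rng.normal(0, 0.1, t.size))
        df = _lmm_input(t, series)
        rec = fit_protein_lmm(df)
        assert rec["fit_method"] == "lmm"
        oracle_slope = _profile_reml_slope(df)
        assert rec["kd"] == pytest.approx(-oracle_slope, rel=1e-4)

    def test_nonphysical_rate_flagged_not_dropped(self):
        t = np.array([0, 1, 2, 4, 8, 16, 32], dtype=float)
        df = _lmm_input(t, {"p1": np.exp(0.05 * t)})  # rising "fraction"
        rec = fit_protein_lmm(df)
        assert rec["nonphysical"]
        assert np.isnan(rec["half_life_days"])

    def test_reported_flag_follows_p_rule(self):
        t = np.array([0, 1, 2, 4, 8, 16, 32], dtype=float)
        rec = fit_protein_lmm(_lmm_input(t, {"p1": np.exp(-0.1 * t)}))
        assert rec["p_value"] < 0.20 and rec["reported"]


class TestHalfLife:
    def test_ln2_identity(self):
        assert half_life(LN2) == pytest.approx(1.0, rel=1e-12)
        assert half_life(LN2 / 3.9) == pytest.approx(3.9, rel=1e-12)

    @pytest.mark.parametrize("bad", [0.0, -0.1])
    def test_nonpositive_rate_rejected(self, bad):
        with pytest.raises(ValueError):
            half_life(bad)

    @settings(deadline=None, max_examples=50)
    @given(st.floats(min_value=1e-6, max_value=1e6))
    def test_involution_through_ln2(self, x):
        assert half_life(LN2 / x) == pytest.approx(x, rel=1e-9)


class TestSummaries:
    def test_median_of_three(self):
        records = pd.DataFrame(
            {
                "organ": "lung", "oxygen": "21",
                "half_life_days": [1.0, 2.0, 3.0],
            }
        )
        out = summarize_half_lives(records)
        assert out.iloc[0]["median_days"] == 2.0
        assert out.iloc[0]["n"] == 3

    def test_single_rate_simulation_recovers_median_exactly(self, noiseless_dataset):
        cfg, ds = noiseless_dataset
        fr = fractions_from_raw(ds["abundance"], ds["design"], ds["panel"]["protein_id"])
        fits = fit_peptide_ols(fr, ds["design"])
        rec = fit_all_proteins(fr, ds["design"], filter_peptides(fits))
        truth = ds["truth"].loc[~ds["truth"]["is_longlived"]]
        expected = np.median(LN2 / truth["true_kd"])
        out = summarize_half_lives(rec)
        assert out.iloc[0]["median_days"] == pytest.approx(expected, rel=1e-9)


class TestRecoveryProperties:
    def test_noiseless_recovery_and_monotonicity(self, noiseless_dataset):
        cfg, ds = noiseless_dataset
        fr = fractions_from_raw(ds["abundance"], ds["design"], ds["panel"]["protein_id"])
        fits = fit_peptide_ols(fr, ds["design"])
        rec = fit_all_proteins(fr, ds["design"], filter_peptides(fits))
        m = rec.merge(ds["truth"], on=["protein_id", "organ", "oxygen"])
        m = m.loc[~m["is_longlived"]]
        assert len(m) == cfg.n_proteins
        rel = np.abs(m["kd"] - m["true_kd"]) / m["true_kd"]
        assert rel.max() < 1e-8
        ordered = m.sort_values("true_kd")
        assert ordered["kd"].is_monotonic_increasing
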