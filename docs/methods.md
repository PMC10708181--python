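# Methods

## Kinetic model

A protein pool at steady-state abundance, degraded by a first-order process
and synthesized (after the diet switch) exclusively from heavy precursor,
has a light-isotope fraction

    F(t) = exp(−k_d · t),        t½ = ln(2) / k_d,

where k_d (per day) is the degradation rate constant. The model assumes
constant total abundance over the labeling window and zero-order synthesis;
proteins whose expression changes over the experiment (circadian, induced)
violate it and will show lack of fit rather than a biased rate. Taking logs
makes the problem linear: ln F(t) = −k_d·t (+ intercept), which is why every
estimator in the package is a linear model on ln(fraction).

## From intensities to fractions

**Panel normalization.** Light-channel peptide intensities carry per-sample
loading/acquisition factors. Each sample is centered on a panel of
long-lived proteins (half-life well beyond the study window) assumed to
have fixed abundance. The per-sample factor is obtained by least-squares
fitting of the two-way additive model

    log(abundance) = peptide_effect + sample_effect

over the panel rows, with factors rescaled to geometric mean 1. On complete
panel data this reduces exactly to the geometric mean over panel peptides of
(abundance / the peptide's geometric-mean abundance across samples). The
least-squares form is used because it remains *exactly* invariant to
rescaling any one sample even when some panel peptides are missing in some
samples, which the plain ratio-of-geomeans form is not. A robust log-median
variant (`method="median"`) is available; its invariance is only approximate
under missingness.

**Baseline division.** The normalized abundance of each peptide is divided
by its day-0 baseline to give the ¹⁴N fraction. The default scope is per
peptide per condition (`condition_t0`), so conditions with different
pre-labeling expression are not mixed; `explicit_t0` pools all day-0 samples
per peptide, and `fitted_intercept` extrapolates the baseline from the OLS
intercept of log-abundance on time for datasets without day-0 samples. The
data cannot tell which scope a given experiment warrants, so all three are
explicit options. Fractions above 1 (noise) are retained — truncation at 1
would bias early-time slopes downward. Peptides lacking any baseline are
dropped, never imputed, and all row drops are logged (rows in = rows out +
dropped).

## Rate estimation

**Per-peptide pre-filter.** Within each organ × oxygen condition, each
peptide's ln(fraction) is regressed on time by OLS (free intercept,
closed-form normal equations). Peptides are kept iff r² > 0.65 (strict) and
they are detected in more than five samples (n ≥ 6), counted within the
condition across all timepoints and replicates. Peptides with fewer than two
distinct timepoints or zero variance in ln(fraction) have undefined r² and
fail the filter.

**Per-protein mixed model.** Kept peptides of a protein are pooled in a
linear mixed-effects model: ln(fraction) ~ time with a random intercept per
peptide (ionization-efficiency offsets). k_d = −(time coefficient); the
p-value is the two-sided Wald test of the time coefficient; records with
p < 0.20 carry the `reported` flag. The free intercept absorbs residual
baseline mis-normalization; a through-origin fit is deliberately not the
default even though the model forces F(0) = 1. The random-effects structure
is intercept-only by default — the most identifiable choice at 6 labeled
timepoints × 4 replicates; the simulator can generate random slopes to study
the mis-specification.

Estimation is REML via conjugate gradient with gradient tolerance 1e-10
(falling back to tightened L-BFGS, then to maximum likelihood, then to
pooled OLS with `fit_method="ols_fallback"`). The tight, cg-based
optimization matters: with near-zero random-effect variance the REML surface
is flat at the boundary and looser optimizers are path-dependent — an
infinitesimal perturbation of the input (e.g. a pure loading rescale) could
move the estimate by ~1e-4. With cg the optimum is reproduced to ~1e-14.
Single-peptide proteins use pooled OLS directly (the mixed model is not
identified), as do proteins whose pooled-OLS residual variance is below
1e-12 (noiseless data; the mixed model adds nothing and its optimizer is
degenerate there). Fractions below 1e-12 are floored before the log with a
logged count — a guard against pathological zeros placed far below any
measurable intensity ratio so that genuine fast-decay signal (fraction
~1e-8 at day 32 for a 1.5-day half-life) is never clipped.

Proteins with non-positive estimated k_d are retained with `nonphysical=True`
and undefined half-life (long-lived or noise-dominated), never silently
dropped.

## Differential turnover

For one protein within one organ, both oxygen tensions are fit jointly:

    ln F = β₀ + β₁·oxy + β₂·t + β₃·(oxy·t) + u_peptide + ε,

with oxy an indicator for the non-reference tension and u a per-peptide
random intercept shared across the two conditions. Then k_ref = −β₂,
k_alt = −(β₂+β₃); β₃ is the slope difference, its Wald test the differential
p-value, and t = β₃/se(β₃) the ranking statistic. The fold change is taken
from this single joint model (ratio of implied rates) rather than from two
separate per-condition fits, for internal consistency; on balanced noiseless
data the two coincide exactly. A peptide is eligible if it passes the
r²/n filter in at least one of the two conditions (configurable to "both").

Benjamini–Hochberg adjustment is applied within one organ × contrast family
(matching per-organ volcano analyses; pooling organs would mix different
null behaviors). Classification: faster iff fold change > 1.3 and
FDR < 0.05, slower for the mirror case, both thresholds strict; proteins
with non-positive slope estimates are reported `ns` with a flag.

## Downstream analyses

**Sequence features.** From FASTA: amino-acid length; fraction of charged
residues (H, K, R, D, E); fractions of positive (H, K, R) and negative
(D, E) residues; mean hydropathy on the Kyte–Doolittle scale rescaled to
[0, 1] via (kd + 4.5)/9. Non-standard letters are ignored with a warning.
Externally predicted features (disorder fractions, charge-patterning
scores) are consumed from user-supplied tables only.

**Percentile-tail KS enrichment.** Proteins are ranked by k_d (baseline
mode, 5% tails) or by the interaction t-statistic (differential mode, 2%
tails). Each tail of size max(1, floor(f·n)) — ties broken by protein id so
the split is deterministic — is compared against *all other proteins* (the
tail is excluded from its own background) with the two-sided two-sample
Kolmogorov–Smirnov test; the direction is the sign of the mean shift.

**Complex summaries.** A two-column TSV dialect (complex metadata +
semicolon-separated subunit list) maps complexes to protein ids. Per
complex: subunits measured (present among differential records), counts of
significant/faster/slower subunits, and the linear fold-change range
(2^|log₂FC|) across significant subunits. Complexes with fewer than 4
measured subunits are excluded.

## Synthetic data generator

The generator emulates the pulse-labeling study design: organs lung, heart
and brain; oxygen tensions 8% (hypoxia), 21% (normoxia) and 60% (hyperoxia)
FiO₂; harvests at days 1, 2, 4, 8, 16, 32 plus explicit day-0 baseline
samples; 4 animals per cell. Explicit day-0 samples are generated because
the fraction computation needs a baseline, whatever its experimental source.

Per organ, half-lives are lognormal with configurable median (defaults
3.9 / 7.3 / 8.0 days for lung / heart / brain) and log-scale sigma 0.4 —
a spread that reproduces a broad but unimodal half-life density with an
interquartile ratio of about 1.7. A configurable fraction of proteins
(default 10%) has its rate multiplied or divided (random direction) by a
factor drawn from `effect_fc_range` in each non-reference oxygen tension.
Peptide counts per protein are uniform in 2–8 by default — the typical
per-protein peptide coverage of tissue DIA is not well pinned down, and
this range brackets "a few peptides for most proteins"; it is a documented
guess and easily overridden.

The forward model per measurement is

    abundance = baseline_peptide · loading_sample · exp(−k_d·t) · exp(ε),

with per-peptide lognormal baselines (ionization offsets, sigma 0.3 on the
log scale — mirroring the random-intercept structure the estimator
assumes), per-sample lognormal loading factors (sigma 0.1), and ε ~ N(0, σ)
with σ = sqrt(ln(1+cv²)) so the multiplicative noise has the configured
coefficient of variation (default 0.10, consistent with well-behaved DIA
quantification). Missingness (default 5%) is completely at random, never
removing day-0 rows so every peptide keeps a baseline; an
intensity-dependent censoring mode is available because DIA missingness is
in truth intensity-correlated, but MCAR is the default so recovery tests
stay interpretable. Noise is multiplicative lognormal throughout: MS
intensities are positive and roughly lognormal, and this keeps all
fractions positive by construction.

The long-lived normalization panel (10 proteins) has k_d = 0 by default —
idealized fixed abundance, which is precisely the assumption under which
such panels are used for normalization. A finite panel half-life (floor 60
days) can be configured to study the bias a slowly decaying panel induces
(it subtracts the panel rate from every estimated rate).

What the generator does **not** emulate: isotope-envelope shapes and
partial-labeling mass shifts, retention-time effects, interference between
co-eluting peptides, protein-level abundance drift (steady state is
assumed), and shared peptides between proteins. Recovery results on
synthetic data therefore show correctness of the estimators under the
model's own assumptions, not robustness to these real-data pathologies.

## Validation regimes and problem sizes

The test suite and `scripts/acceptance.py` validate the pipeline end-to-end
at desk scale: exact inversion on noiseless data (100 proteins × 3
conditions; every rate recovered to < 1e-8 relative), parameter recovery at
10% noise with 5 peptides (median rate error < 10%, per-organ median
half-lives within 5% of the configured 3.9/7.3/8.0 days), null calibration
(no true effects: raw interaction p < 0.05 for ~5% of proteins, BH +
fold-change calls ≤ 1%), and power (true two-fold shifts: ≥ 80% detected,
every significant call in the true direction). The acceptance script uses
150–300 proteins per regime, sizes at which the measured quantities are
stable to a few percent while the full run stays around a minute.

## Known limitations

- Rates outside roughly ln2/64–ln2/0.5 per day are poorly constrained by a
  1–32 day window; the half-life summary counts (but keeps) such records.
- The Wald p-values from the mixed model are asymptotic; with very few
  peptides and timepoints they are approximate (the null-calibration test
  bounds the practical consequence).
- BH is applied assuming (approximately) independent or positively
  dependent tests across proteins; strong co-regulation violates this.
- The loading-invariance guarantee is exact in real arithmetic and holds to
  ~1e-14 in floating point; bit-identity under arbitrary real rescales is
  not attainable.
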