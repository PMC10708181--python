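# protturn

Protein turnover kinetics from pulsed metabolic isotope-labeling (SILAM)
proteomics: per-protein degradation rates and half-lives, differential
turnover between conditions, and downstream biophysical-feature and
protein-complex analyses — with a fully specified synthetic-data generator
for validation.

## The problem

In a whole-animal pulse-labeling experiment, animals are switched at day 0
to a heavy-isotope (¹⁵N) diet. Newly synthesized protein incorporates ¹⁵N,
so the light (¹⁴N) fraction of each protein reflects the pre-pulse pool and,
at steady-state abundance, decays by first-order degradation:

    Fraction₁₄N(t) = exp(−k_d · t),      t½ = ln(2) / k_d

Mass spectrometry quantifies the light channel of many peptides per protein
across tissues, oxygen tensions and harvest times. Estimating k_d per
protein, and asking whether k_d differs between conditions, requires:

1. **Normalization** — each sample is centered on a panel of long-lived
   proteins assumed to have fixed abundance, absorbing loading and
   acquisition differences; each peptide is then divided by its day-0
   baseline to give the ¹⁴N fraction.
2. **Quality filtering** — per-peptide OLS of ln(fraction) on time within
   each condition; only peptides with r² > 0.65 detected in more than five
   samples enter the protein-level fit.
3. **Mixed-effects rate estimation** — per protein and condition,
   ln(fraction) ~ time with a random intercept per peptide; k_d is minus the
   time coefficient, estimates with Wald p < 0.20 carry the `reported` flag.
4. **Differential turnover** — per protein, a joint model with fixed effects
   {oxygen, time, oxygen:time} and peptide random intercepts; the
   interaction coefficient is the slope (rate) difference. Benjamini-Hochberg
   FDR within each organ × contrast; proteins with rate fold change > 1.3
   and FDR < 0.05 are called faster/slower.
5. **Downstream** — Kolmogorov–Smirnov enrichment of sequence features
   (length, charge fractions, Kyte–Doolittle hydropathy) in the percentile
   tails of the k_d or t-statistic ranking, and per-complex summaries of
   differential calls for complexes with ≥ 4 measured subunits.

The synthetic generator emulates the study design (3 organs × 8/21/60% FiO₂
× harvests at days 0–32 × 4 animals) with known ground-truth rates,
per-peptide random intercepts, per-sample loading factors, multiplicative
lognormal noise and missingness, so every stage can be validated by
parameter recovery.

## Worked example

```python
import protturn as pt

cfg = pt.SimulationConfig(
    organs=["lung"], oxygen_levels=["8", "21"], n_proteins=50,
    peptides_per_protein=(5, 5), frac_affected=0.3,
    effect_fc_range=(2.0, 2.0), seed=7,
)
ds = pt.simulate_dataset(cfg)
fractions = pt.fractions_from_raw(
    ds["abundance"], ds["design"], ds["panel"]["protein_id"]
)
fits = pt.fit_peptide_ols(fractions, ds["design"])
rates = pt.fit_all_proteins(fractions, ds["design"], pt.filter_peptides(fits))
print(pt.summarize_half_lives(rates))
diff = pt.run_differential(fractions, ds["design"], fits,
                           oxy_ref="21", oxy_alt="8")
print(pt.summarize_fraction_significant(diff))
```

Output:

```
  organ oxygen  median_days   q1_days   q3_days   n  n_out_of_range
0  lung     21     3.849076  3.270783  5.066400  50               0
1  lung      8     3.754121  2.503435  6.187169  50               0
  organ contrast  n_tested  n_faster  n_slower  percent_significant
0  lung  8-vs-21        50         8         8                 32.0
```

The recovered normoxic median half-life (3.85 d) tracks the configured lung
median of 3.9 d. This seed shifts 16 of the 50 proteins two-fold (random
direction) under hypoxia; all 16 are called significant (8 faster, 8
slower), each in the true direction.

The same pipeline is available as subcommands of the `protturn` console
script (`simulate`, `fit`, `diff`, `enrich`, `complexes`), each taking
`--config`, `--seed`, `--out-dir` and threshold overrides, writing TSVs plus
the resolved configuration and an audit log.

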