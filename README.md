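# vwmstats

Computational core of a visual working-memory training analysis: mixture-model
estimation of the **quantity** (capacity) and **quality** (precision) of
working-memory representations from continuous-reproduction errors, plus the
full statistical pipeline of a two-group pre/post training study, exercised
end-to-end on synthetic data.

## What it implements

- **`vwmstats.circular`** — angle wrapping into (−π, π], the von Mises
  density, and the κ ↔ circular-SD conversion. Precision is defined as
  `1 / SD` with SD in **degrees**.
- **`vwmstats.smm`** — the standard mixture model
  `P(x) = (1−g)·vonMises(x; 0, κ) + g/(2π)`: log-likelihood, bounded
  multi-start maximum-likelihood fitting (8 deterministic starts in
  (logit g, log κ) space), and the derived quantities `Pm = 1 − g`,
  capacity `K = Pm · N`, and precision `SD⁻¹`.
- **`vwmstats.change_detection`** — Pashler's whole-display capacity
  estimate `k = (H − FA)/(1 − FA) · N` (clamped to [0, N] by default, raw
  value retained).
- **`vwmstats.robust`** — Yuen's independent and paired trimmed-mean t-tests
  (20% trimming; paired df = h − 1), the Algina–Keselman–Penfield robust
  effect size δ_t, Yates-corrected 2×2 chi-square, a two-way mixed ANOVA,
  a two-within-factor repeated-measures ANOVA, and both generalized (η²G)
  and partial (η²p) eta-squared.
- **`vwmstats.bayes`** — the default JZS t-test Bayes factor (Cauchy prior,
  r = 0.707, adaptive quadrature), the Gunel–Dickey contingency-table Bayes
  factor (Poisson sampling plan by default, independent-multinomial
  available; closed form in gamma functions), a clearly-tagged BIC
  approximation for ANOVA-effect Bayes factors, and categorical evidence
  labels. **Note:** exact multivariate-Cauchy g-prior ANOVA Bayes factors
  are deliberately out of scope; the BIC stand-in is tagged `bic_approx`.
- **`vwmstats.simulate`** — synthetic study generator: two groups
  (30 + 34 participants), pre/post testing (120 test + 20 practice trials
  per task at set size 4; 16 for visual search), four training sessions of
  360 trials (120 per set size ∈ {2, 4, 6} reproduction / {8, 16, 24}
  search), with recall errors drawn from the mixture model at configurable
  per-cell (g, κ), a whole-display change-detection generator, and a
  visual-search generator. Scenario builders: `null_config`,
  `quality_gain_config`.
- **`vwmstats.pipeline`** — exclusions (extra-trial, RT, omission rules),
  per-cell estimation, response-density chi-square comparisons (8 bins of
  45° anchored at 0), and `run_full_analysis` producing a machine-readable
  report (baseline comparisons, training ANOVAs, pre/post mixed ANOVAs,
  follow-up robust tests, density comparisons), every statistic carrying a
  method tag.

## CLI

```bash
# generate a synthetic study (scenarios: null, quality_gain)
vwmstats simulate --scenario quality_gain --seed 1 --out trials.csv

# per-cell estimates only
vwmstats fit --trials trials.csv --out cells.csv

# full analysis report (JSON + CSV tables)
vwmstats analyze --trials trials.csv --report report_dir
```

Simulation/analysis settings can be given as YAML or JSON via `--config`
(keys mirror `StudySimConfig`, `FitConfig`, and `ExclusionConfig` fields).

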