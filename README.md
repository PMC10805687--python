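# survrank

Survival-model benchmarking and ensemble feature ranking for right-censored
clinical tables, built around the kind of small tabular cohorts that come out
of electronic health records — the motivating application is overall-survival
prediction in glioblastoma multiforme, where three public cohorts (Lammer,
n=60; Shieh, n=84; Berendsen, n=647) mix clinical covariates (age, Karnofsky
performance status, extent of surgery, radiation dose) with molecular markers
(MGMT promoter methylation, cytosolic HSP70 expression).

The package is for biostatisticians and clinical-ML researchers who want to
(a) compare survival learners under a repeated random-split protocol, and
(b) obtain a stable feature-importance ranking from noisy permutation
importances.

## What it computes

**Models.** Three learners behind one `predict_risk` / `predict_survival`
contract:

* **Cox proportional hazards** — hazard h(t | x) = h₀(t) · exp(xᵀβ); β is
  estimated by Newton–Raphson on the Breslow partial log-likelihood, the
  baseline cumulative hazard H₀ by the Breslow estimator.
* **Random survival forest** — bagged binary survival trees; each node split
  maximises the two-sample log-rank statistic (O − E)²/V over `mtry` random
  candidate features, leaves hold Nelson–Aalen cumulative hazards
  Ĥ(t) = Σ_{tᵢ ≤ t} dᵢ/nᵢ, the ensemble cumulative hazard is the tree mean,
  and the risk score its sum over the training event-time grid.
* **DeepSurv-style network** — a feed-forward net whose single linear output
  estimates the log-risk; trained full-batch on the negative Cox partial
  log-likelihood of the output scores.

**Metrics.** Harrell's concordance index
C = (concordant pairs + ½·risk ties) / comparable pairs, where a pair is
comparable when the earlier observed time belongs to a subject with an
observed event and the times differ (1 = perfect, 0.5 = chance, 0 = perfectly
inverted); and the IPCW (integrated) Brier score

BS(t) = n⁻¹ Σᵢ [ 1{Tᵢ ≤ t, eᵢ=1} Ŝᵢ(t)² / G(Tᵢ⁻) + 1{Tᵢ > t} (1−Ŝᵢ(t))² / G(t) ],

with G the Kaplan–Meier estimate of the censoring distribution; the IBS is
the trapezoidal integral of BS(t) over the observed event-time window,
normalised by its length (0 is perfect).

**Ranking.** The core analysis: 100 runs, each with a fresh random split
(three equal training / ranking / evaluation parts by default); a random
survival forest is fit on the training part and each feature column is
permuted exactly once on the ranking part, recording the concordance loss
ΔC = C_full − C_permuted; within a run features are ranked by descending ΔC,
and the per-run ranks are merged by Borda's count (the average rank ± sd over
runs; lower = more important). A univariate screen (chi-square for coded
features, two-sided Mann–Whitney U for numeric ones, significance at
p < 0.005) complements the multivariate ranking.

**Synthetic cohorts.** Because the real cohorts live on FigShare, the package
ships a generator for right-censored cohorts with known ground truth:
covariates from declared marginals, event times from a Weibull
proportional-hazards model T = λ(−ln U / exp(xᵀβ))^{1/k}, independent
exponential or administrative censoring (the exponential rate can be solved
numerically to hit a target event fraction). Presets `lammer_like`,
`shieh_like` and `berendsen_like` reproduce each cohort's published marginal
characteristics and death rates.

## Worked example

```python
import survrank as sr

table = sr.generate(sr.preset("berendsen_like", n=300, seed=7))

cfg = sr.ExperimentConfig(n_runs=20, master_seed=7,
                          model_params={"rsf": {"n_trees": 50},
                                        "deepsurv": {"epochs": 200}})
print(sr.repeated_split_benchmark(table, cfg).summary().to_string(index=False))

ranking = sr.run_ranking(table, rsf_params={"n_trees": 50}, n_runs=20,
                         master_seed=7)
print(ranking.to_frame().to_string(index=False))
```

prints

```
   model  c_index_mean  c_index_sd  ibs_mean   ibs_sd  n_runs_completed  n_failures
     cox      0.652992    0.031856  0.115857 0.008734                20           0
     rsf      0.619864    0.027086  0.138416 0.007946                20           0
deepsurv      0.638494    0.023646  0.120878 0.008217                20           0
 rank            feature  average_borda_score     sd
    1 Adjuvant treatment                  1.5 0.6708
    2                Age                  2.0 1.0000
    3         SVZ status                  3.3 1.1000
    4   Biopsy debulking                  3.7 0.8426
    5                KPS                  4.5 0.7416
```

All three models score well above chance (C ≈ 0.62–0.65) on this synthetic
cohort, and the Borda ranking recovers the generator's planted effect-size
order: adjuvant treatment (the largest |β|) ranks first with the smallest
average Borda score, KPS (the smallest |β|) last.

The same pipeline is available from a shell:

```bash
survrank simulate  --preset berendsen_like --n 300 --seed 7 --out cohort.csv
survrank benchmark --input cohort.csv --schema berendsen --runs 100 --seed 7 --outdir out/
survrank rank      --input cohort.csv --schema berendsen --runs 100 --seed 7 --out ranking.csv
survrank univariate --input cohort.csv --schema berendsen --out univariate.csv
```

Every command writes a JSON manifest (configuration, seeds, package version)
so any result replays exactly.

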