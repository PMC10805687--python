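# Methods

This note documents the statistical procedures implemented in `survrank`,
the conventions chosen where several exist in the literature, the defaults
and what they mean, and what the synthetic-data generator does and does not
emulate.

## Data model

The unit of data flow is the `SurvivalTable`: an n × p numeric covariate
matrix, a strictly positive survival time in months, and an event indicator
(1 = death observed, 0 = right-censored). Construction rejects missing
values, non-positive times and non-binary events, so all cleaning happens in
`read_cohort` under an explicit policy: `drop_rows` (complete-case, the
default — the conservative choice when the provenance of missing codes is
unknown) or `impute_mode` (per-column mode). Rows with missing or
non-positive outcome are always dropped. Every load produces a `LoadReport`
(rows read / dropped / imputed, per-column missing counts) that is logged
and attached to the table.

Schema presets encode the three glioblastoma cohorts' covariate definitions
and codings (e.g. sex male = 1, extent of surgery 0 = biopsy / 1 = resection,
adjuvant treatment as a 0–2 rank, KPS dichotomised at 70). Header matching is
case-insensitive and whitespace-stripped with an optional rename map, and the
delimiter is sniffed, because public CSV exports rarely match published
tables verbatim.

## Estimators and metrics

**Kaplan–Meier / Nelson–Aalen.** Standard product-limit and cumulative-hazard
estimators over distinct event times; step functions are right-continuous,
with an explicit `left_limit` evaluation used by the IPCW weights.

**Concordance index.** A pair (i, j) is comparable iff the earlier observed
time belongs to a subject with an observed event and the two times differ.
Pairs with exactly tied times are *never* comparable — the strict reading of
the definition. Harrell's classical estimator (and scikit-survival) instead
counts an event-vs-censored pair at a tied time as comparable, so on data
with many coincident times the two conventions can differ by ~0.01; with
continuous times they agree to machine precision (verified to 1e-8 in the
test suite, and to 1e-3 on mildly tied fixtures). Tied risk predictions
always credit 0.5. Zero comparable pairs raises an error rather than
returning 0.5 silently. Risk orientation is global: higher risk = earlier
expected event (the RSF and network scores are built to satisfy this), which
avoids silent 1 − C inversions.

**IPCW Brier score.** Graf's estimator with weights from the Kaplan–Meier
estimate of the censoring distribution (event indicator flipped). Weights
for subjects whose event occurred by the evaluation time use the left limit
G(T⁻), the standard convention that avoids a subject down-weighting itself.
Subjects censored before the evaluation time contribute zero. A required
weight of zero raises with advice to shrink the time window. The *integrated*
Brier score is the trapezoidal integral over the grid of distinct observed
event times inside the window, normalised by window length; the default
window spans the observed event times, truncated where G reaches zero. In
heavily censored tails the IPCW weights can exceed 1, so the score is not
formally bounded by 1 in finite samples; under the light-censoring regimes
used here it stays well inside [0, 1].

## Models

**Cox proportional hazards.** Breslow partial likelihood (Breslow tie
handling throughout the package; Efron-based implementations will differ
slightly on heavily tied data), maximised by Newton–Raphson with
step-halving. Covariates are standardised internally for conditioning and
the coefficients mapped back. Convergence: gradient max-norm < 1e-8
(standardised scale) within 100 iterations; runaway coefficients
(|β| > 50 standardised, the signature of complete separation) raise with
advice to refit with the optional ridge penalty. The baseline cumulative
hazard is the Breslow estimator at x = 0; predicted survival is
S(t | x) = exp(−H₀(t)·exp(xᵀβ)).

**Random survival forest.** Trees are grown on bootstrap samples (switchable
off). At each node, `mtry` features are drawn without replacement and every
admissible midpoint threshold (both daughters ≥ `min_leaf` subjects, boundary
values distinct) is scored by the squared standardised log-rank statistic
(O − E)²/V, computed for all thresholds of a feature in one vectorised pass
over the node's event table. Ties in the statistic break to the lowest
feature index, then the lowest threshold, making the forest fully
deterministic given its seed. Nodes stop splitting when too small, eventless,
at `max_depth`, or when no split has positive variance. Leaves store
Nelson–Aalen cumulative hazards evaluated on the grid of distinct training
event times; the ensemble CHF is the pointwise tree mean; the scalar risk is
the CHF summed over that grid (so a uniformly higher hazard ranks as higher
risk), and predicted survival is exp(−CHF). Defaults: 100 trees,
mtry = ⌈√p⌉, min_leaf = 3, unlimited depth — explicit, overridable constants.

**DeepSurv-style network.** A feed-forward net (default one hidden layer of
32 ReLU units) whose single linear output estimates the log-risk. The loss is
the event-normalised negative Breslow partial log-likelihood of the output
scores plus an L2 penalty (default 1e-4) on the weights. Training is
full-batch gradient descent — cohorts of this size do not need minibatching,
and removing it removes batching nondeterminism — with a backtracking rule
(halve the step while the loss would increase), so the recorded trajectory is
non-increasing by construction and the fit is bit-reproducible from its seed.
`hidden_sizes=()` degenerates to a linear score trained by gradient descent
and recovers the Cox coefficient direction (verified to < 0.05 rad at
n = 2000). The architecture and schedule are this package's documented
defaults, not a claim about any particular external implementation.

## Benchmark protocol

Per run: a seeded shuffle, a split — 70/30 train/test by default, or three
equal parts (train / rank / evaluation; the benchmark then fits on the first
and scores on the last) — identical splits shared by all models within a run,
C-index and IBS on the held-out part, and population mean ± sd over runs.
Both split schemes exist because both appear in practice for this kind of
analysis; manifests always record which was used, along with the realised
partition sizes (floor sizes for leading parts, remainder to the last). A
model failing in a run (e.g. no comparable pairs in a degenerate split) is
logged and dropped for that model only.

Child randomness is derived as `SeedSequence([master_seed, run])`, spawned
further per stage (split / model fits / permutations), so every experiment is
replayable bit-for-bit from one integer.

## Ranking protocol

The ranking uses the random survival forest only: its splits capture
non-linear effects while the fitted object remains inspectable. Each feature
is permuted exactly once per run — a deliberately literal, noisy estimate
whose variance is absorbed by the 100-run Borda aggregation. Ranks within a
run are 1..p by descending ΔC with exact ties averaged (average ranks keep
Borda sums comparable across runs); the Borda score is the average rank over
runs, reported with the population sd, sorted ascending. A constant feature,
or one the model provably ignores, has ΔC = 0 exactly.

The univariate screen targets the binary event status (a chi-square test
needs a categorical target; using the status rather than the time is the
documented choice): chi-square without continuity correction for coded
features, two-sided Mann–Whitney U for numeric ones — exact enumeration when
both groups have ≤ 20 subjects and no ties, tie-corrected normal
approximation otherwise — flagged at p < 0.005. Degenerate layouts (an empty
contingency margin, a constant feature) are reported as non-significant with
a warning rather than failing the screen.

Post-baseline covariates (progression status, PFS) are kept in the cohort
schemas to mirror the deposited files; `SurvivalTable.drop_features` removes
them when a strictly baseline analysis is wanted.

## Synthetic cohorts

The generator draws covariates independently per declared marginal
(truncated normal, Bernoulli, categorical), event times by inverse transform
from a Weibull proportional-hazards model, and censoring independently of
covariates (matching the IPCW assumption) from an exponential distribution
or a fixed administrative horizon. `censoring_rate_for_event_fraction`
solves for the exponential rate that yields a target expected event fraction
by Gauss–Legendre quadrature of P(T ≤ C | x) averaged over a Monte-Carlo
covariate sample, with Brent root-finding.

The three presets match the published cohorts' sample sizes, numeric
marginals (mean/sd/range as truncated normals), category prevalences among
observed levels, and death rates (60.00%, 96.43%, 86.82%). The log-hazard
effect sizes are **synthetic constants of this package** — the real effect
sizes are unknown — chosen so the features reported as most predictive in
each cohort carry the largest |β|; they are configurable per preset. The
baseline Weibull scales give median survival near 12–16 months at the
covariate origin, a realistic scale for this disease; the printed survival
summary row for two of the cohorts is internally inconsistent in the source
material, so no attempt is made to match it. Not emulated: joint covariate
correlations (marginals are independent), covariate-dependent censoring, and
any non-proportional-hazards structure. Passing tests on these cohorts
therefore demonstrate correctness of the machinery and recoverability of
planted PH effects — not performance claims about the real datasets.

## Numerical and testing notes

* All sd's reported over runs are population sd (ddof = 0); within-cohort
  descriptive sd's are sample sd (ddof = 1), matching the conventions of the
  tables they mirror.
* The acceptance-style checks run at explicit problem sizes chosen for the
  package's test suite: Cox recovery at n = 2000; ranking recovery on an
  n = 600 cohort with β = (1.5, 0.75, 0, 0) over 20 master seeds × 100 runs
  with a 16-tree, depth-4 forest (the planted signal is strong, so a small
  forest suffices and the Borda aggregation removes the per-run noise); null
  calibration on an n = 300 covariate-independent cohort over 100 runs.
* Known limitations: no competing risks, no time-varying covariates, no
  Efron tie handling, no Uno's C or time-dependent AUC, no hyperparameter
  search. The forest does not implement out-of-bag estimates; all evaluation
  is by explicit held-out splits.
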