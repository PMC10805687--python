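"""Ensemble feature ranking for censored survival data.

The ranking protocol: repeat ``n_runs`` times with fresh random splits —
shuffle the cohort, partition it (by default into three equal parts:
training / ranking / evaluation), fit a random survival forest on the
training part, and on the ranking part permute each feature column exactly
once and record the concordance-index loss dC = C_full - C_permuted. Within
each run features are ranked by descending dC (rank 1 = largest loss, exact
ties averaged); the per-run ranks are then merged by Borda's count — the
average rank over runs, reported with its (population) standard deviation
and sorted ascending, so lower average Borda score = more important.

The forest is the ranking model because its splits capture non-linear
feature effects while remaining inspectable; a single permutation per
feature per run is noisy, but the noise is absorbed by the cross-run Borda
aggregation.

A univariate screen complements the multivariate ranking: each coded feature
is tested against the event status by a chi-square contingency test (no
continuity correction) and each numeric feature by a two-sided Mann–Whitney
U test between the event groups, flagged significant at p < 0.005.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .clinical_io import SurvivalTable
from .metrics import concordance_index
from .models import DEFAULT_RSF_PARAMS, fit_rsf, predict_risk

logger = logging.getLogger(__name__)

__all__ = [
    "RunRanking",
    "FeatureRanking",
    "UnivariateResult",
    "permutation_importance",
    "rank_within_run",
    "borda_merge",
    "run_ranking",
    "univariate_screen",
    "SIGNIFICANCE_LEVEL",
]

SIGNIFICANCE_LEVEL = 0.005


@dataclass(frozen=True)
class RunRanking:
    """One run's concordance losses and the ranks they induce."""

    run_id: int
    features: tuple[str, ...]
    delta_c: np.ndarray       # C_full - C_permuted, per feature
    ranks: np.ndarray         # 1 = largest loss; exact ties averaged


@dataclass(frozen=True)
class FeatureRanking:
    """Borda-merged ranking: per-feature average rank +/- sd over runs."""

    features: tuple[str, ...]          # sorted ascending by average score
    average_score: np.ndarray
    sd: np.ndarray
    n_runs: int
    per_run: list[RunRanking] = field(default_factory=list, repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.features) + 1),
                "feature": self.features,
                "average_borda_score": np.round(self.average_score, 4),
                "sd": np.round(self.sd, 4),
            }
        )


@dataclass(frozen=True)
class UnivariateResult:
    feature: str
    test: str                 # "chi_square" | "mann_whitney_u"
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < SIGNIFICANCE_LEVEL


def permutation_importance(model, eval_table: SurvivalTable, seed=0):
    """Concordance loss per feature from a single seeded permutation each.

    The baseline C-index is computed once on the untouched evaluation table;
    each feature's column is then permuted exactly once (all other columns
    untouched) and dC = C_baseline - C_permuted recorded. A feature the model
    ignores, or a constant feature, yields dC = 0 exactly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = eval_table.X
    baseline = concordance_index(
        eval_table.time, eval_table.event, predict_risk(model, X)
    ).value
    delta = np.zeros(len(eval_table.features))
    for j, name in enumerate(eval_table.feature_names):
        perm = rng.permutation(len(X))
        col = X[name].to_numpy()
        if np.all(col[perm] == col):
            continue  # identity in effect (e.g. constant feature): dC = 0
        X_perm = X.copy()
        X_perm[name] = col[perm]
        c_perm = concordance_index(
            eval_table.time, eval_table.event, predict_risk(model, X_perm)
        ).value
        delta[j] = baseline - c_perm
    return delta


def rank_within_run(delta_c, features=None, run_id: int = 0) -> RunRanking:
    """Ranks 1..p by descending concordance loss; exact ties averaged."""
    delta_c = np.asarray(delta_c, dtype=float)
    if np.any(~np.isfinite(delta_c)):
        raise ValueError("concordance losses must be finite")
    ranks = stats.rankdata(-delta_c, method="average")
    if features is None:
        features = tuple(f"f{i}" for i in range(delta_c.size))
    return RunRanking(run_id=run_id, features=tuple(features),
                      delta_c=delta_c, ranks=ranks)


def borda_merge(rankings: list[RunRanking]) -> FeatureRanking:
    """Average the per-run ranks (Borda's count) and sort ascending.

    The reported spread is the population standard deviation over runs.
    """
    if not rankings:
        raise ValueError("no rankings to merge")
    features = rankings[0].features
    for r in rankings:
        if r.features != features:
            raise ValueError(
                f"inconsistent feature sets: {r.features} vs {features}"
            )
    mat = np.vstack([r.ranks for r in rankings])
    avg = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=0)
    order = np.argsort(avg, kind="mergesort")  # stable: mean ties keep input order
    return FeatureRanking(
        features=tuple(features[i] for i in order),
        average_score=avg[order],
        sd=sd[order],
        n_runs=len(rankings),
        per_run=list(rankings),
    )


def _three_way_split(n: int, rng: np.random.Generator):
    perm = rng.permutation(n)
    a = n // 3
    b = 2 * n // 3
    return perm[:a], perm[a:b], perm[b:]


def _train_test_split(n: int, rng: np.random.Generator, train_frac=0.7):
    perm = rng.permutation(n)
    cut = int(np.floor(train_frac * n))
    return perm[:cut], perm[cut:]


def run_ranking(
    table: SurvivalTable,
    rsf_params: dict | None = None,
    n_runs: int = 100,
    split: str = "three_way",
    master_seed: int = 0,
    max_failure_fraction: float = 0.05,
) -> FeatureRanking:
    """The full repeated-split permutation/Borda ranking protocol.

    Per run r the child seed sequence ``SeedSequence([master_seed, r])``
    drives the shuffle, the forest and the permutations, so the whole
    procedure is bit-reproducible from ``master_seed``. ``split`` is
    ``"three_way"`` (default: equal training / ranking / evaluation parts;
    the forest is fit on the first and scored on the second) or
    ``"train_test"`` (70/30; the test part doubles as the ranking part).
    Runs whose concordance is undefined are logged and dropped; more than
    ``max_failure_fraction`` failed runs aborts.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be at least 1")
    if split not in ("three_way", "train_test"):
        raise ValueError("split must be 'three_way' or 'train_test'")
    params = {**DEFAULT_RSF_PARAMS, **(rsf_params or {})}

    rankings: list[RunRanking] = []
    failures = 0
    for r in range(n_runs):
        ss = np.random.SeedSequence([master_seed, r])
        rng_split, rng_fit, rng_perm = (
            np.random.default_rng(s) for s in ss.spawn(3)
        )
        if split == "three_way":
            train_idx, rank_idx, _ = _three_way_split(table.n, rng_split)
        else:
            train_idx, rank_idx = _train_test_split(table.n, rng_split)
        try:
            model = fit_rsf(
                table.subset(train_idx),
                seed=int(rng_fit.integers(2**31 - 1)),
                **params,
            )
            delta = permutation_importance(model, table.subset(rank_idx),
                                           seed=rng_perm)
            rankings.append(
                rank_within_run(delta, table.feature_names, run_id=r)
            )
        except ValueError as exc:
            failures += 1
            logger.warning("ranking run %d failed: %s", r, exc)
            if failures > max_failure_fraction * n_runs:
                raise RuntimeError(
                    f"{failures} of {n_runs} ranking runs failed; aborting"
                ) from exc
    return borda_merge(rankings)


def univariate_screen(table: SurvivalTable) -> list[UnivariateResult]:
    """Per-feature association with the event status.

    Coded (binary/rank) features: chi-square test of the feature x event
    contingency table, no continuity correction. Numeric features: two-sided
    Mann–Whitney U between the event and censored groups (exact null
    distribution when both groups are small and tie-free, tie-corrected
    normal approximation otherwise). Degenerate layouts (single-level
    feature, single event class) are reported with p = nan and a warning.
    """
    results = []
    event = table.event
    for spec in table.features:
        col = table.X[spec.name].to_numpy()
        if spec.kind == "numeric":
            g1, g0 = col[event == 1], col[event == 0]
            if g1.size == 0 or g0.size == 0:
                warnings.warn(f"{spec.name}: one event group is empty; skipped")
                results.append(UnivariateResult(spec.name, "mann_whitney_u",
                                                float("nan")))
                continue
            if np.all(col == col[0]):
                # no separation whatsoever
                results.append(UnivariateResult(spec.name, "mann_whitney_u", 1.0))
                continue
            exact = (
                max(g1.size, g0.size) <= 20
                and np.unique(col).size == col.size
            )
            res = stats.mannwhitneyu(
                g1, g0, alternative="two-sided",
                method="exact" if exact else "asymptotic",
            )
            results.append(
                UnivariateResult(spec.name, "mann_whitney_u", float(res.pvalue))
            )
        else:
            contingency = pd.crosstab(col, event)
            if contingency.shape[0] < 2 or contingency.shape[1] < 2:
                warnings.warn(
                    f"{spec.name}: contingency table has an empty margin; "
                    "chi-square skipped"
                )
                results.append(UnivariateResult(spec.name, "chi_square",
                                                float("nan")))
                continue
            chi2 = stats.chi2_contingency(contingency.to_numpy(),
                                          correction=False)
            results.append(
                UnivariateResult(spec.name, "chi_square", float(chi2.pvalue))
            )
    return results


def univariate_frame(results: list[UnivariateResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature": [r.feature for r in results],
            "test": [r.test for r in results],
            "p_value": [r.p_value for r in results],
            "significant": [r.significant for r in results],
        }
    )
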