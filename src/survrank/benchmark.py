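"""Repeated random-split benchmarking of the three survival learners.

Protocol: ``n_runs`` times (default 100), shuffle the cohort with a seeded
permutation, split it (70/30 train/test by default, or into three equal
training / ranking / evaluation parts), fit every requested model on the
training part with the *same* split shared across models within a run, and
score the held-out part with the concordance index and the IPCW integrated
Brier score. Results are reported as mean +/- sd (population sd over runs).

Per-run child randomness derives from ``SeedSequence([master_seed, run])``,
so a manifest (config + master seed) replays to identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clinical_io import SurvivalTable
from .metrics import concordance_index, integrated_brier_score
from .models import MODEL_KINDS, fit_model, predict_risk, predict_survival
from .ranking import FeatureRanking, UnivariateResult, univariate_frame

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentConfig",
    "BenchmarkResult",
    "repeated_split_benchmark",
    "render_report",
]

SPLIT_SCHEMES = ("train_test", "three_way")


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to replay a benchmark exactly."""

    models: tuple[str, ...] = ("cox", "rsf", "deepsurv")
    model_params: dict = field(default_factory=dict)  # kind -> params dict
    n_runs: int = 100
    split: str = "train_test"          # 70/30; "three_way" = 1/3 each
    train_fraction: float = 0.7
    master_seed: int = 0

    def __post_init__(self):
        if self.n_runs < 1:
            raise ValueError("n_runs must be at least 1")
        if self.split not in SPLIT_SCHEMES:
            raise ValueError(f"split must be one of {SPLIT_SCHEMES}")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        unknown = set(self.models) - set(MODEL_KINDS)
        if unknown:
            raise ValueError(f"unknown models {sorted(unknown)}")

    def to_dict(self) -> dict:
        return {
            "models": list(self.models),
            "model_params": self.model_params,
            "n_runs": self.n_runs,
            "split": self.split,
            "train_fraction": self.train_fraction,
            "master_seed": self.master_seed,
        }


@dataclass
class BenchmarkResult:
    config: ExperimentConfig
    split_sizes: tuple[int, ...]
    per_run: dict                       # model -> list of (run, c, ibs)
    failures: dict                      # model -> count

    def _stats(self, model: str, col: int):
        vals = np.array([row[col] for row in self.per_run[model]])
        return float(vals.mean()), float(vals.std(ddof=0))

    def summary(self) -> pd.DataFrame:
        rows = []
        for model in self.config.models:
            c_mean, c_sd = self._stats(model, 1)
            i_mean, i_sd = self._stats(model, 2)
            rows.append(
                {
                    "model": model,
                    "c_index_mean": c_mean,
                    "c_index_sd": c_sd,
                    "ibs_mean": i_mean,
                    "ibs_sd": i_sd,
                    "n_runs_completed": len(self.per_run[model]),
                    "n_failures": self.failures[model],
                }
            )
        return pd.DataFrame(rows)

    def per_run_frame(self) -> pd.DataFrame:
        rows = []
        for model, runs in self.per_run.items():
            for run, c, ibs in runs:
                rows.append({"model": model, "run": run, "c_index": c,
                             "ibs": ibs})
        return pd.DataFrame(rows)

    def manifest(self, package_version: str = "") -> dict:
        return {
            "config": self.config.to_dict(),
            "split_sizes": list(self.split_sizes),
            "failures": self.failures,
            "package_version": package_version,
        }


def _split_indices(n: int, config: ExperimentConfig, rng: np.random.Generator):
    """Disjoint partition; floor sizes for the leading parts, remainder last."""
    perm = rng.permutation(n)
    if config.split == "train_test":
        cut = int(np.floor(config.train_fraction * n))
        return perm[:cut], perm[cut:]
    a, b = n // 3, 2 * n // 3
    # three-way: fit on the first third, evaluate on the last
    return perm[:a], perm[b:]


def repeated_split_benchmark(table: SurvivalTable,
                             config: ExperimentConfig) -> BenchmarkResult:
    """Run the repeated-split benchmark; see the module docstring.

    A model failure within a run (e.g. undefined concordance on a degenerate
    split) drops that run for that model only and is counted in the summary.
    """
    per_run = {m: [] for m in config.models}
    failures = {m: 0 for m in config.models}
    split_sizes: tuple[int, ...] = ()
    for run in range(config.n_runs):
        ss = np.random.SeedSequence([config.master_seed, run])
        rng_split, rng_models = (np.random.default_rng(s) for s in ss.spawn(2))
        train_idx, test_idx = _split_indices(table.n, config, rng_split)
        if not split_sizes:
            if config.split == "three_way":
                split_sizes = (train_idx.size,
                               table.n - train_idx.size - test_idx.size,
                               test_idx.size)
            else:
                split_sizes = (train_idx.size, test_idx.size)
        train, test = table.subset(train_idx), table.subset(test_idx)
        model_seeds = rng_models.integers(2**31 - 1, size=len(config.models))
        for model_name, mseed in zip(config.models, model_seeds):
            try:
                model = fit_model(train, model_name,
                                  config.model_params.get(model_name),
                                  seed=int(mseed))
                risk = predict_risk(model, test.X)
                c = concordance_index(test.time, test.event, risk).value
                curves = predict_survival(model, test.X)
                ibs = integrated_brier_score(curves, test.time,
                                             test.event).value
                per_run[model_name].append((run, c, ibs))
            except (ValueError, RuntimeError) as exc:
                failures[model_name] += 1
                logger.warning("run %d failed for %s: %s", run, model_name, exc)
    for model_name in config.models:
        if not per_run[model_name]:
            raise RuntimeError(f"every run failed for model {model_name!r}")
    return BenchmarkResult(config=config, split_sizes=split_sizes,
                           per_run=per_run, failures=failures)


# --------------------------------------------------------------------------
# Reporting
# --------------------------------------------------------------------------

def render_report(
    outdir,
    results: BenchmarkResult | None = None,
    ranking: FeatureRanking | None = None,
    univariate: list[UnivariateResult] | None = None,
) -> dict:
    """Write CSV tables, a bar chart with error bars (plus a JSON data
    sidecar), and a markdown summary marking the best model per metric with
    an asterisk. Returns the mapping of artefact names to paths."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}
    md = ["# Survival benchmark report", ""]

    if results is not None:
        summary = results.summary()
        path = outdir / "benchmark.csv"
        summary.to_csv(path, index=False)
        written["benchmark"] = str(path)
        per_run_path = outdir / "benchmark_per_run.csv"
        results.per_run_frame().to_csv(per_run_path, index=False)
        written["benchmark_per_run"] = str(per_run_path)
        written["figure"] = _figure(outdir, summary)
        written["figure_data"] = str(outdir / "figure_data.json")

        best_c = summary.loc[summary["c_index_mean"].idxmax(), "model"]
        best_i = summary.loc[summary["ibs_mean"].idxmin(), "model"]
        md += ["## Model benchmark", "",
               "| model | C-index | IBS |", "|---|---|---|"]
        for _, row in summary.iterrows():
            star_c = "*" if row["model"] == best_c else ""
            star_i = "*" if row["model"] == best_i else ""
            md.append(
                f"| {row['model']} "
                f"| {row['c_index_mean']:.3f} ± {row['c_index_sd']:.3f}{star_c} "
                f"| {row['ibs_mean']:.3f} ± {row['ibs_sd']:.3f}{star_i} |"
            )
        md.append("")
        md.append("(*) best model per metric.")
        md.append("")

    if ranking is not None:
        path = outdir / "ranking.csv"
        ranking.to_frame().to_csv(path, index=False)
        written["ranking"] = str(path)
        md += ["## Feature ranking (average Borda score, lower = more important)",
               "", "| rank | feature | average Borda score | sd |",
               "|---|---|---|---|"]
        for _, row in ranking.to_frame().iterrows():
            md.append(
                f"| {row['rank']} | {row['feature']} "
                f"| {row['average_borda_score']:.2f} | {row['sd']:.2f} |"
            )
        md.append("")
    else:
        md += ["## Feature ranking", "", "No ranking results supplied.", ""]

    if univariate is not None:
        path = outdir / "univariate.csv"
        univariate_frame(univariate).to_csv(path, index=False)
        written["univariate"] = str(path)

    md_path = outdir / "summary.md"
    md_path.write_text("\n".join(md))
    written["summary"] = str(md_path)
    return written


def _figure(outdir, summary: pd.DataFrame) -> str:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    x = np.arange(len(summary))
    ax.bar(x, summary["c_index_mean"], yerr=summary["c_index_sd"],
           capsize=4, color="steelblue")
    ax.set_xticks(x)
    ax.set_xticklabels(summary["model"])
    ax.set_ylabel("C-index (mean ± sd over runs)")
    ax.set_ylim(0, 1)
    ax.axhline(0.5, color="grey", linestyle="--", linewidth=0.8)
    fig.tight_layout()
    fig_path = outdir / "benchmark_figure.png"
    fig.savefig(fig_path, dpi=120)
    plt.close(fig)

    sidecar = {
        "models": summary["model"].tolist(),
        "c_index_mean": summary["c_index_mean"].tolist(),
        "c_index_sd": summary["c_index_sd"].tolist(),
        "ibs_mean": summary["ibs_mean"].tolist(),
        "ibs_sd": summary["ibs_sd"].tolist(),
    }
    (outdir / "figure_data.json").write_text(json.dumps(sidecar, indent=2))
    return str(fig_path)
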