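"""End-to-end pipeline: corpus -> cohort -> graphs -> measures -> trends.

One :func:`run_pipeline` call takes a :class:`PipelineConfig` and writes a
self-contained set of artifacts into the output directory:

* ``corpus.tsv`` — the frequency lexicon used (written when generated);
* ``measures.tsv`` — per-participant, per-grade network measures;
* ``aggregate.tsv`` — per-grade means and SDs over participants;
* ``trends.tsv`` — ANOVA, consecutive-grade Tukey p, polynomial trend and
  R-squared per measure;
* ``degree_fits.tsv`` — log-log power-law fit per participant and grade;
* ``trajectory.tsv`` — mean corpus frequency of newly acquired words per
  grade;
* ``manifest.json`` — config, seeds, package version, stage wall times.

Reruns with the same config and seed are bit-identical except for the
manifest's timings.  Any stage failure aborts with a stage-labeled error
and removes partial outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .corpus_io import (
    FrequencyLexicon,
    read_frequency_lexicon,
    write_frequency_lexicon,
    write_measures_table,
)
from .graph_metrics import (
    DEFAULT_N_SOURCES,
    NetworkMeasures,
    compute_all_measures,
)
from .growth_simulator import (
    GrowthSchedule,
    VirtualLexicon,
    new_word_frequency_trajectory,
    simulate_cohort,
)
from .ortho_neighbors import build_neighbor_graph
from .synthetic_corpus import CorpusGenConfig, generate_corpus
from .trend_stats import analyze_measure, loglog_degree_fit

logger = logging.getLogger(__name__)

#: Measures aggregated and trend-analyzed per grade.
TREND_MEASURES = ("n", "mean_degree", "L", "D", "C", "hermits", "hermit_proportion")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class PipelineConfig:
    """Full description of one reproducible pipeline run."""

    corpus_source: str | CorpusGenConfig
    schedule: GrowthSchedule
    n_participants: int
    base_seed: int
    output_dir: str
    path_mode: Literal["exact", "sampled", "auto"] = "auto"
    n_sources: int = DEFAULT_N_SOURCES
    clustering_policy: Literal["exclude-degree-1", "count-as-zero"] = "exclude-degree-1"
    max_poly_order: int = 4

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.clustering_policy not in ("exclude-degree-1", "count-as-zero"):
            raise ValueError(f"unknown clustering policy {self.clustering_policy!r}")

    @classmethod
    def demo(cls, output_dir: str, base_seed: int = 0) -> "PipelineConfig":
        """Default demo: 5,000-type synthetic corpus, 10 participants, 4 stages."""
        return cls(
            corpus_source=CorpusGenConfig(n_types=5_000, seed=base_seed),
            schedule=GrowthSchedule.demo(),
            n_participants=10,
            base_seed=base_seed,
            output_dir=output_dir,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open("r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        corpus = raw["corpus"]
        if isinstance(corpus, dict):
            corpus_source: str | CorpusGenConfig = CorpusGenConfig(**corpus)
        else:
            corpus_source = str(corpus)
        schedule = GrowthSchedule(
            tuple((str(c["grade"]), int(c["size"])) for c in raw["schedule"])
        )
        return cls(
            corpus_source=corpus_source,
            schedule=schedule,
            n_participants=int(raw["n_participants"]),
            base_seed=int(raw["base_seed"]),
            output_dir=str(raw.get("output_dir", ".")),
            path_mode=raw.get("path_mode", "auto"),
            n_sources=int(raw.get("n_sources", DEFAULT_N_SOURCES)),
            clustering_policy=raw.get("clustering_policy", "exclude-degree-1"),
            max_poly_order=int(raw.get("max_poly_order", 4)),
        )


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d["schedule"] = [
        {"grade": g, "size": s} for g, s in config.schedule.checkpoints
    ]
    return d


def _grade_numeric(label: str, position: int) -> float:
    try:
        return float(label)
    except ValueError:
        return float(position + 1)


def aggregate_measures(measures: pd.DataFrame, grade_order: list[str]) -> pd.DataFrame:
    """Per-grade mean and SD over participants for every measure column."""
    rows = []
    for grade in grade_order:
        sub = measures[measures["grade"] == grade]
        row: dict[str, float | str] = {
            "grade": grade,
            "lexicon_size": int(sub["lexicon_size"].iloc[0]),
            "n_participants": len(sub),
        }
        for col in TREND_MEASURES:
            row[f"{col}_mean"] = float(sub[col].mean())
            row[f"{col}_sd"] = float(sub[col].std(ddof=1)) if len(sub) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run the whole analysis; returns a name -> path map of artifacts."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    timings: dict[str, float] = {}
    stage = "setup"
    try:
        # --- corpus -----------------------------------------------------
        stage = "corpus"
        t0 = time.perf_counter()
        if isinstance(config.corpus_source, CorpusGenConfig):
            corpus = generate_corpus(config.corpus_source)
            corpus_path = out / "corpus.tsv"
            write_frequency_lexicon(corpus, corpus_path)
            artifacts["corpus"] = corpus_path
        else:
            corpus = read_frequency_lexicon(config.corpus_source)
        timings[stage] = time.perf_counter() - t0
        logger.info("corpus ready: %d types (%.2fs)", len(corpus), timings[stage])

        # --- cohort simulation -------------------------------------------
        stage = "simulate"
        t0 = time.perf_counter()
        cohort = simulate_cohort(
            corpus, config.schedule, config.n_participants, config.base_seed
        )
        timings[stage] = time.perf_counter() - t0
        logger.info("cohort simulated: %d lexicons (%.2fs)", len(cohort), timings[stage])

        # --- graphs and measures -----------------------------------------
        stage = "measures"
        t0 = time.perf_counter()
        records: dict[tuple[int, str], NetworkMeasures] = {}
        count_zero = config.clustering_policy == "count-as-zero"
        for (pid, grade), lexicon in sorted(cohort.items()):
            graph = build_neighbor_graph(lexicon.types)
            stage_index = config.schedule.labels.index(grade)
            rng = np.random.default_rng(
                np.random.SeedSequence(
                    [config.base_seed, 10_000 + pid, stage_index]
                )
            )
            records[(pid, grade)] = compute_all_measures(
                lexicon,
                graph,
                path_mode=config.path_mode,
                n_sources=min(config.n_sources, max(len(graph.nodes), 1)),
                rng=rng,
                count_undefined_as_zero=count_zero,
            )
        measures_path = out / "measures.tsv"
        write_measures_table(records, measures_path)
        artifacts["measures"] = measures_path
        timings[stage] = time.perf_counter() - t0
        logger.info("measures computed for %d lexicons (%.2fs)", len(records), timings[stage])

        # --- aggregates ---------------------------------------------------
        stage = "aggregate"
        t0 = time.perf_counter()
        grade_order = list(config.schedule.labels)
        rows = []
        for (pid, grade), m in sorted(records.items()):
            rows.append(
                {
                    "participant": pid,
                    "grade": grade,
                    "lexicon_size": m.lexicon_size,
                    "n": m.n,
                    "mean_degree": m.mean_degree,
                    "L": m.avg_path_length,
                    "D": np.nan if m.diameter is None else m.diameter,
                    "C": m.clustering,
                    "hermits": m.hermit_count,
                    "hermit_proportion": m.hermit_proportion,
                }
            )
        measures_df = pd.DataFrame(rows)
        aggregate = aggregate_measures(measures_df, grade_order)
        aggregate_path = out / "aggregate.tsv"
        aggregate.to_csv(aggregate_path, sep="\t", index=False, float_format="%.6g")
        artifacts["aggregate"] = aggregate_path
        timings[stage] = time.perf_counter() - t0

        # --- trend statistics --------------------------------------------
        stage = "trends"
        t0 = time.perf_counter()
        grade_numeric = [
            _grade_numeric(g, i) for i, g in enumerate(grade_order)
        ]
        trend_rows = []
        for measure in TREND_MEASURES:
            values = {
                g: measures_df.loc[measures_df["grade"] == g, measure].to_numpy()
                for g in grade_order
            }
            if any(np.isnan(v).any() for v in values.values()):
                continue
            try:
                result = analyze_measure(
                    measure, grade_numeric, values, config.max_poly_order
                )
            except ValueError:
                continue
            row: dict[str, object] = {
                "measure": measure,
                "F": result.anova.F,
                "df1": result.anova.df1,
                "df2": result.anova.df2,
                "p_value": result.anova.p_value,
                "r_squared": result.trend.r_squared if result.trend else np.nan,
            }
            for a, b, p in result.pairwise:
                row[f"tukey_{a}_vs_{b}"] = p
            if result.trend:
                for order, coef, t in result.trend.coefficients:
                    row[f"poly{order}_coef"] = coef
                    row[f"poly{order}_t"] = t
                row["intercept_coef"], row["intercept_t"] = result.trend.intercept
            trend_rows.append(row)
        trends_path = out / "trends.tsv"
        pd.DataFrame(trend_rows).to_csv(
            trends_path, sep="\t", index=False, float_format="%.6g"
        )
        artifacts["trends"] = trends_path
        timings[stage] = time.perf_counter() - t0

        # --- degree-distribution fits ------------------------------------
        stage = "degree_fits"
        t0 = time.perf_counter()
        fit_rows = []
        for (pid, grade), m in sorted(records.items()):
            try:
                fit = loglog_degree_fit(m.degree_distribution)
            except ValueError:
                continue
            fit_rows.append(
                {
                    "participant": pid,
                    "grade": grade,
                    "slope": fit.slope,
                    "intercept": fit.intercept,
                    "r_squared": fit.r_squared,
                    "n_points": fit.n_points,
                }
            )
        fits_path = out / "degree_fits.tsv"
        pd.DataFrame(fit_rows).to_csv(
            fits_path, sep="\t", index=False, float_format="%.6g"
        )
        artifacts["degree_fits"] = fits_path
        timings[stage] = time.perf_counter() - t0

        # --- acquisition-frequency trajectory ----------------------------
        stage = "trajectory"
        t0 = time.perf_counter()
        trajectory = new_word_frequency_trajectory(cohort, corpus)
        trajectory_path = out / "trajectory.tsv"
        trajectory.to_csv(trajectory_path, sep="\t", index=False, float_format="%.6g")
        artifacts["trajectory"] = trajectory_path
        timings[stage] = time.perf_counter() - t0

        # --- manifest -----------------------------------------------------
        stage = "manifest"
        manifest = {
            "version": __version__,
            "config": _config_dict(config),
            "base_seed": config.base_seed,
            "n_lexicons": len(cohort),
            "stage_seconds": {k: round(v, 3) for k, v in timings.items()},
            "completed_utc": time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime()),
        }
        manifest_path = out / "manifest.json"
        manifest_path.write_text(
            json.dumps(manifest, indent=2, default=str) + "\n", encoding="utf-8"
        )
        artifacts["manifest"] = manifest_path
        return artifacts
    except Exception as exc:
        for path in artifacts.values():
            path.unlink(missing_ok=True)
        raise PipelineError(f"pipeline stage {stage!r} failed: {exc}") from exc
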