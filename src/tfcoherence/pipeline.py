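"""End-to-end pipeline: read data, fit both conditions, compare, summarise.

A single :class:`RunConfig` (constructible from a YAML file) drives one
reproducible run.  The pipeline fits the activity model independently per
condition, computes the coherence table between them, classifies fold
changes with the category and genome-fraction summaries, and writes all
outputs as TSV plus a JSON run report capturing seeds, ELBO traces,
convergence flags and every TF exclusion.  Identical configs produce
byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .coherence import coherence_table, plot_coherence, write_coherence_table
from .foldchange import (
    category_percentages,
    classify_fold_changes,
    genome_fraction_altered,
    heat_values,
)
from .inference import (
    ModelHyperparams,
    fit_tf_activities,
    write_posterior,
    write_strengths,
)
from .io import FLOAT_FMT, read_categories, read_connectivity, read_expression

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration for one full pipeline run."""

    expression_a: str
    expression_b: str
    connectivity: str
    out_dir: str
    categories: Optional[str] = None
    hyperparams: ModelHyperparams = field(default_factory=ModelHyperparams)
    n_draws: int = 1000
    coherence_seed: int = 0
    genome_size: int = 4598
    x_split: float = 0.5
    y_split: Optional[float] = None
    make_plot: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        hyper = raw.pop("hyperparams", {})
        if isinstance(hyper, dict):
            hyper = ModelHyperparams(**hyper)
        return cls(hyperparams=hyper, **raw)

    def validate(self) -> None:
        for name in ("expression_a", "expression_b", "connectivity"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} path does not exist: {p}")
        if self.categories is not None and not Path(self.categories).exists():
            raise FileNotFoundError(f"categories path does not exist: {self.categories}")


def run_pipeline(config: RunConfig) -> dict:
    """Run simulate-independent inference, coherence and summaries.

    Returns the run report (also written to ``report.json``).  On a stage
    failure, partial outputs are kept and the report carries a FAILED marker
    with the stage name before the exception propagates.
    """
    config.validate()  # before any output is created
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "package_version": __version__,
        "seeds": {"model": config.hyperparams.seed,
                  "coherence": config.coherence_seed},
        "hyperparams": asdict(config.hyperparams),
        "n_draws": config.n_draws,
        "genome_size": config.genome_size,
        "conditions": {},
        "warnings": [],
        "excluded_tfs": [],
        "outputs": [],
        "status": "RUNNING",
    }
    stage = "read"
    try:
        expr_a = read_expression(config.expression_a, condition_label="A")
        expr_b = read_expression(config.expression_b, condition_label="B")
        connectivity = read_connectivity(config.connectivity)
        categories = read_categories(config.categories) if config.categories else None

        stage = "infer"
        posteriors = {}
        for label, expr in (("A", expr_a), ("B", expr_b)):
            post = fit_tf_activities(expr, connectivity, config.hyperparams)
            posteriors[label] = post
            write_posterior(post, out / f"posterior_{label}.tsv")
            write_strengths(post, out / f"strengths_{label}.tsv")
            report["conditions"][label] = {
                "converged": post.converged,
                "n_iters": post.n_iters,
                "noise_sd_hat": post.noise_sd_hat,
                "elbo_final": post.elbo_trace[-1],
                "elbo_trace": post.elbo_trace,
                "dropped_tfs": post.dropped_tfs,
            }
            for tf in post.dropped_tfs:
                report["warnings"].append(
                    f"condition {label}: TF {tf} dropped (no measured targets)")
            report["outputs"] += [f"posterior_{label}.tsv", f"strengths_{label}.tsv"]

        stage = "coherence"
        result = coherence_table(
            posteriors["A"], posteriors["B"], n_draws=config.n_draws,
            seed=config.coherence_seed, x_split=config.x_split,
            y_split=config.y_split)
        write_coherence_table(result, out / "coherence.tsv")
        report["outputs"].append("coherence.tsv")
        for tf, reason in result.excluded:
            report["excluded_tfs"].append({"tf": tf, "reason": reason})
            report["warnings"].append(f"coherence: TF {tf} excluded ({reason})")
        report["coherence_splits"] = {"x": result.x_split, "y": result.y_split}
        if config.make_plot:
            plot_coherence(result, out / "coherence.svg")
            report["outputs"].append("coherence.svg")

        stage = "summarize"
        for label, expr in (("A", expr_a), ("B", expr_b)):
            table = classify_fold_changes(expr, categories)
            genome = genome_fraction_altered(table, config.genome_size)
            genome.to_csv(out / f"genome_fraction_{label}.tsv", sep="\t",
                          index=False, float_format=FLOAT_FMT, lineterminator="\n")
            report["outputs"].append(f"genome_fraction_{label}.tsv")
            heat = heat_values(table)
            heat.to_csv(out / f"heat_{label}.tsv", sep="\t",
                        float_format=FLOAT_FMT, lineterminator="\n")
            report["outputs"].append(f"heat_{label}.tsv")
            if categories is not None:
                cats = category_percentages(table)
                cats.to_csv(out / f"category_summary_{label}.tsv", sep="\t",
                            index=False, float_format=FLOAT_FMT, lineterminator="\n")
                report["outputs"].append(f"category_summary_{label}.tsv")

        report["status"] = "OK"
    except Exception as exc:
        report["status"] = "FAILED"
        report["failed_stage"] = stage
        report["error"] = f"{type(exc).__name__}: {exc}"
        _write_report(report, out)
        raise
    _write_report(report, out)
    return report


def _write_report(report: dict, out: Path) -> None:
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
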