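"""Synthetic paired-condition expression data with known ground truth.

The generator emulates the design of an anaerobic *E. coli* time-course
experiment comparing a CO-releasing compound against its CO-depleted control:
two conditions sampled at 10, 20, 40, 60 and 120 min, ~4,598 genes, and a
sparse regulon connectivity over a 16-TF panel.  Latent TF activities follow
Gaussian random walks over the minute grid; a configurable subset of TFs is
*coherent* (identical true activity in both conditions) and the rest are
*divergent* (independent draws per condition), so that downstream
coherence-plot statistics have a planted contrast to recover.

Expression follows the same bilinear observation model the inference module
fits::

    y[n, t] = mu[n] + sum_m X[n, m] * b[n, m] * c[m, t] + eps[n, t]

with ``eps ~ N(0, noise_sd**2)`` independent per entry.  Both conditions
share the connectivity ``X``, strengths ``b`` and baselines ``mu``; only the
activities ``c`` (and the noise) differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    ConnectivityMatrix,
    ExpressionMatrix,
    FLOAT_FMT,
    write_connectivity,
    write_expression,
)

#: The 16-TF comparison panel used as the default simulation panel.
DEFAULT_TF_PANEL = (
    "BaeR", "CpxR", "CRP", "CysB", "Fis", "FNR", "Fur", "GadX",
    "H-NS", "IHF", "IscR", "NarL", "NarP", "NsrR", "OxyR", "SoxS",
)

DEFAULT_TIME_POINTS_MIN = (10.0, 20.0, 40.0, 60.0, 120.0)


@dataclass
class SimulationConfig:
    """Study-design parameters for one paired-condition simulation.

    Defaults mirror the emulated experiment: 4,598 genes, the 16-TF panel,
    five sampling times, and an even 8/8 split of the panel into coherent
    and divergent TFs.
    """

    n_genes: int = 4598
    tf_names: tuple[str, ...] = DEFAULT_TF_PANEL
    time_points_min: tuple[float, ...] = DEFAULT_TIME_POINTS_MIN
    connectivity_density: float = 0.05
    noise_sd: float = 0.1
    coherent_tfs: tuple[str, ...] = DEFAULT_TF_PANEL[:8]
    divergent_tfs: tuple[str, ...] = DEFAULT_TF_PANEL[8:]
    strength_sd: float = 1.0
    baseline_sd: float = 0.5
    replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        self.tf_names = tuple(self.tf_names)
        self.time_points_min = tuple(float(t) for t in self.time_points_min)
        self.coherent_tfs = tuple(self.coherent_tfs)
        self.divergent_tfs = tuple(self.divergent_tfs)
        if self.n_genes < 1:
            raise ValueError(f"n_genes must be positive, got {self.n_genes}")
        if not self.tf_names:
            raise ValueError("tf_names must be non-empty")
        if len(set(self.tf_names)) != len(self.tf_names):
            raise ValueError("tf_names must be unique")
        t = np.asarray(self.time_points_min)
        if len(t) < 2 or np.any(np.diff(t) <= 0) or np.any(t <= 0):
            raise ValueError("time_points_min must be strictly increasing positive reals")
        if not (0.0 < self.connectivity_density <= 1.0):
            raise ValueError(
                f"connectivity_density must be in (0, 1], got {self.connectivity_density}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be non-negative, got {self.noise_sd}")
        if self.strength_sd < 0:
            raise ValueError(f"strength_sd must be non-negative, got {self.strength_sd}")
        if self.baseline_sd < 0:
            raise ValueError(f"baseline_sd must be non-negative, got {self.baseline_sd}")
        if self.replicates < 1:
            raise ValueError(f"replicates must be >= 1, got {self.replicates}")
        if self.seed < 0:
            raise ValueError(f"seed must be non-negative, got {self.seed}")
        coh, div = set(self.coherent_tfs), set(self.divergent_tfs)
        if coh & div:
            raise ValueError(f"coherent_tfs and divergent_tfs overlap: {sorted(coh & div)}")
        if coh | div != set(self.tf_names):
            raise ValueError("coherent_tfs and divergent_tfs must partition tf_names")

    @property
    def n_tfs(self) -> int:
        return len(self.tf_names)

    @property
    def n_times(self) -> int:
        return len(self.time_points_min)

    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes - 1))
        return [f"g{i:0{width}d}" for i in range(self.n_genes)]


@dataclass
class GroundTruth:
    """Latent quantities behind one simulated dataset (the generative X, b, c, mu, sigma)."""

    tf_names: tuple[str, ...]
    time_points_min: tuple[float, ...]
    activities_a: np.ndarray  # (n_tfs, n_times), condition A (active compound)
    activities_b: np.ndarray  # (n_tfs, n_times), condition B (inactivated control)
    strengths: np.ndarray  # (n_genes, n_tfs), zero off-connectivity
    baselines: np.ndarray  # (n_genes,)
    noise_sd: float
    coherent_tfs: tuple[str, ...]
    divergent_tfs: tuple[str, ...]

    def label_of(self, tf: str) -> str:
        return "coherent" if tf in self.coherent_tfs else "divergent"


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # distinct, seed-reproducible streams per generation stage
    return np.random.default_rng([stream, config.seed])


def generate_connectivity(config: SimulationConfig) -> ConnectivityMatrix:
    """Sample the binary gene x TF regulon matrix.

    Entries are i.i.d. Bernoulli(``connectivity_density``); any TF column
    with fewer than two targets is resampled so every regulon has at least
    two measured genes (resampling is deterministic under the seed).
    """
    rng = _rng(config, 0)
    entries = (rng.random((config.n_genes, config.n_tfs))
               < config.connectivity_density).astype(np.int8)
    for j in range(config.n_tfs):
        tries = 0
        while entries[:, j].sum() < 2:
            tries += 1
            if tries > 1000:
                # sparse limit: force two distinct targets
                picks = rng.choice(config.n_genes, size=2, replace=False)
                entries[picks, j] = 1
                break
            entries[:, j] = (rng.random(config.n_genes)
                             < config.connectivity_density).astype(np.int8)
    return ConnectivityMatrix(
        gene_ids=config.gene_ids(),
        tf_names=list(config.tf_names),
        entries=entries,
    )


def _random_walks(rng: np.random.Generator, n: int,
                  times: Sequence[float]) -> np.ndarray:
    """Gaussian random walks over the minute grid.

    Start value ~ N(0, 1); increments ~ N(0, dt) with unit diffusion per
    minute, so later gaps contribute proportionally larger steps.
    """
    times = np.asarray(times, dtype=float)
    steps = np.empty((n, len(times)))
    steps[:, 0] = rng.standard_normal(n)
    dts = np.diff(times)
    steps[:, 1:] = rng.standard_normal((n, len(dts))) * np.sqrt(dts)
    return np.cumsum(steps, axis=1)


def generate_truth(config: SimulationConfig,
                   connectivity: ConnectivityMatrix) -> GroundTruth:
    """Draw latent activities, strengths and baselines.

    Coherent TFs get one activity walk copied to both conditions; divergent
    TFs get independent walks per condition.  Strengths are
    N(0, strength_sd^2) on nonzero connectivity entries and exactly zero
    elsewhere.
    """
    if connectivity.entries.shape != (config.n_genes, config.n_tfs):
        raise ValueError(
            f"connectivity shape {connectivity.entries.shape} does not match config "
            f"({config.n_genes} genes x {config.n_tfs} TFs)")
    rng = _rng(config, 1)
    m, t = config.n_tfs, config.n_times
    walks_a = _random_walks(rng, m, config.time_points_min)
    walks_b = _random_walks(rng, m, config.time_points_min)
    coherent = np.array([tf in config.coherent_tfs for tf in config.tf_names])
    activities_a = walks_a
    activities_b = np.where(coherent[:, None], walks_a, walks_b)
    strengths = np.zeros((config.n_genes, m))
    mask = connectivity.entries.astype(bool)
    strengths[mask] = rng.normal(0.0, config.strength_sd, size=int(mask.sum()))
    baselines = rng.normal(0.0, config.baseline_sd, size=config.n_genes) \
        if config.baseline_sd > 0 else np.zeros(config.n_genes)
    return GroundTruth(
        tf_names=config.tf_names,
        time_points_min=config.time_points_min,
        activities_a=activities_a,
        activities_b=activities_b,
        strengths=strengths,
        baselines=baselines,
        noise_sd=config.noise_sd,
        coherent_tfs=config.coherent_tfs,
        divergent_tfs=config.divergent_tfs,
    )


def generate_expression(
    truth: GroundTruth,
    connectivity: ConnectivityMatrix,
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Generate the two condition expression matrices from the truth.

    With ``replicates > 1`` each sampling time appears that many times as a
    column, sharing the signal and differing only in the noise draw.
    """
    if truth.strengths.shape != (config.n_genes, config.n_tfs):
        raise ValueError("truth dimensions do not match config")
    rng = _rng(config, 2)
    signal_a = truth.baselines[:, None] + truth.strengths @ truth.activities_a
    signal_b = truth.baselines[:, None] + truth.strengths @ truth.activities_b
    rep = config.replicates
    times = [t for t in config.time_points_min for _ in range(rep)]
    out = []
    for signal, label in ((signal_a, "condition_A"), (signal_b, "condition_B")):
        values = np.repeat(signal, rep, axis=1)
        if config.noise_sd > 0:
            values = values + rng.normal(0.0, config.noise_sd, size=values.shape)
        out.append(ExpressionMatrix(
            gene_ids=config.gene_ids(),
            time_points_min=times,
            values=values,
            condition_label=label,
        ))
    return out[0], out[1]


@dataclass
class SyntheticDataset:
    """A complete simulated study: config, truth, connectivity, both conditions."""

    config: SimulationConfig
    truth: GroundTruth
    connectivity: ConnectivityMatrix
    expression_a: ExpressionMatrix
    expression_b: ExpressionMatrix


def simulate_dataset(config: SimulationConfig | None = None, **overrides) -> SyntheticDataset:
    """Run the full generator: connectivity, truth, both expression matrices.

    Keyword overrides are applied to a default :class:`SimulationConfig`.
    """
    if config is None:
        config = SimulationConfig(**overrides)
    elif overrides:
        raise TypeError("pass either a config or keyword overrides, not both")
    connectivity = generate_connectivity(config)
    truth = generate_truth(config, connectivity)
    expr_a, expr_b = generate_expression(truth, connectivity, config)
    return SyntheticDataset(config, truth, connectivity, expr_a, expr_b)


def write_dataset(dataset: SyntheticDataset, directory: str | Path) -> dict[str, Path]:
    """Write a simulated dataset as TSV files.

    Emits ``expression_A.tsv``, ``expression_B.tsv``, ``connectivity.tsv``
    and ``ground_truth.tsv`` (columns tf, condition, time_min, activity,
    label).  Round-trips through the package readers exactly in double
    precision.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression_a": directory / "expression_A.tsv",
        "expression_b": directory / "expression_B.tsv",
        "connectivity": directory / "connectivity.tsv",
        "ground_truth": directory / "ground_truth.tsv",
    }
    write_expression(dataset.expression_a, paths["expression_a"])
    write_expression(dataset.expression_b, paths["expression_b"])
    write_connectivity(dataset.connectivity, paths["connectivity"])
    truth = dataset.truth
    rows = []
    for cond, acts in (("A", truth.activities_a), ("B", truth.activities_b)):
        for i, tf in enumerate(truth.tf_names):
            for t, value in zip(truth.time_points_min, acts[i]):
                rows.append((tf, cond, t, value, truth.label_of(tf)))
    pd.DataFrame(rows, columns=["tf", "condition", "time_min", "activity", "label"]
                 ).to_csv(paths["ground_truth"], sep="\t", index=False,
                          float_format=FLOAT_FMT, lineterminator="\n")
    return paths


def read_ground_truth(path: str | Path) -> pd.DataFrame:
    """Read a ``ground_truth.tsv`` back as a tidy frame."""
    return pd.read_csv(path, sep="\t")
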