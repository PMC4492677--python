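"""Coherence-plot statistics comparing TF activities between two conditions.

For each TF fitted under two conditions, the coherence plot places a point at

* x — *profile difference*: 1 minus the absolute Pearson correlation between
  the two posterior-mean activity profiles (0 = identical kinetics, up to
  sign and affine scale);
* y — *magnitude difference*: the absolute difference of the Euclidean norms
  of the two profiles (0 = equal response amplitude).

TFs responding the same way in both conditions therefore cluster near the
origin, while TFs that differ in both kinetics and amplitude land in the
far corner.  Uncertainty in the inferred activities is propagated by Monte
Carlo: paired draws from each condition's marginal posterior give the mean
and SD of the absolute correlation (the x error bar) and the SD of the
draw-wise magnitude difference (the y error bar).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .inference import TFActivityPosterior, sample_activities
from .io import FLOAT_FMT

logger = logging.getLogger(__name__)

DEFAULT_N_DRAWS = 1000
DEFAULT_X_SPLIT = 0.5


class ZeroVarianceProfileError(ValueError):
    """A flat activity profile makes the Pearson correlation undefined."""


@dataclass
class CoherencePoint:
    """One TF's coordinates and uncertainty on the coherence plot."""

    tf_name: str
    profile_difference: float  # x: 1 - |Pearson| of posterior-mean profiles
    magnitude_difference: float  # y: | ||c_A|| - ||c_B|| |
    mean_abs_corr: float  # Monte-Carlo mean of |rho| over posterior draws
    sd_abs_corr: float
    x_err: float  # = sd_abs_corr, since x = 1 - |rho|
    y_err: float  # Monte-Carlo SD of the draw-wise magnitude difference
    quadrant: Optional[str] = None


@dataclass
class CoherenceResult:
    """Coherence table plus the side report of excluded TFs."""

    table: pd.DataFrame
    excluded: list[tuple[str, str]]  # (tf, reason)
    x_split: float
    y_split: float


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    da, db = a - a.mean(), b - b.mean()
    na, nb = np.linalg.norm(da), np.linalg.norm(db)
    if na == 0 or nb == 0:
        raise ZeroVarianceProfileError("zero-variance profile: correlation undefined")
    return float(da @ db / (na * nb))


def profile_difference(a: np.ndarray, b: np.ndarray) -> float:
    """1 minus the absolute Pearson correlation of two activity profiles.

    Invariant under sign flips and affine rescaling of either profile.
    Raises :class:`ZeroVarianceProfileError` on a flat profile, for which no
    defensible value exists.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"profiles differ in length: {a.shape} vs {b.shape}")
    if a.size < 3:
        raise ValueError("profiles must have at least 3 time points")
    return 1.0 - abs(_pearson(a, b))


def magnitude_difference(a: np.ndarray, b: np.ndarray) -> float:
    """Absolute difference of the Euclidean norms of two profiles."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"profiles differ in length: {a.shape} vs {b.shape}")
    return float(abs(np.linalg.norm(a) - np.linalg.norm(b)))


def quadrant_assign(x: float, y: float, x_split: float, y_split: float) -> str:
    """2x2 partition of the coherence plane.

    C = near the origin (similar kinetics and amplitude); B = far corner
    (different in both); A = similar kinetics but different amplitude;
    D = different kinetics but similar amplitude.
    """
    if x_split < 0 or y_split < 0:
        raise ValueError("splits must be non-negative")
    if x < x_split:
        return "C" if y < y_split else "A"
    return "D" if y < y_split else "B"


def _rowwise_abs_corr(da: np.ndarray, db: np.ndarray) -> np.ndarray:
    """|Pearson| per paired draw; rows are draws, columns time points."""
    ca = da - da.mean(axis=1, keepdims=True)
    cb = db - db.mean(axis=1, keepdims=True)
    num = np.einsum("ij,ij->i", ca, cb)
    den = np.linalg.norm(ca, axis=1) * np.linalg.norm(cb, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = num / den
    return np.abs(rho)


def coherence_point(
    post_a: TFActivityPosterior,
    post_b: TFActivityPosterior,
    tf: str,
    n_draws: int = DEFAULT_N_DRAWS,
    seed: int = 0,
    x_split: Optional[float] = None,
    y_split: Optional[float] = None,
) -> CoherencePoint:
    """Coherence coordinates and Monte-Carlo error bars for one TF.

    Point coordinates come from the posterior-mean profiles; the draws feed
    only the mean/SD of |rho| and the error-bar half-widths.  The quadrant
    is assigned only when both splits are given (the y split is normally a
    table-level quantity).
    """
    for post in (post_a, post_b):
        if tf not in post.tf_names:
            raise ValueError(f"TF {tf!r} absent from posterior "
                             f"{post.condition_label or '<unlabelled>'}")
    if list(post_a.time_points_min) != list(post_b.time_points_min):
        raise ValueError("posteriors have mismatched time grids")
    prof_a, prof_b = post_a.profile(tf), post_b.profile(tf)
    x = profile_difference(prof_a, prof_b)  # raises on flat profile
    y = magnitude_difference(prof_a, prof_b)

    child_a, child_b = np.random.SeedSequence(seed).generate_state(2)
    draws_a = sample_activities(post_a, n_draws, int(child_a)).for_tf(tf)
    draws_b = sample_activities(post_b, n_draws, int(child_b)).for_tf(tf)
    abs_rho = _rowwise_abs_corr(draws_a, draws_b)
    ok = np.isfinite(abs_rho)
    if not ok.all():
        logger.warning("%s: %d degenerate draw(s) skipped", tf, int((~ok).sum()))
    abs_rho = abs_rho[ok]
    mag = np.abs(np.linalg.norm(draws_a, axis=1)
                 - np.linalg.norm(draws_b, axis=1))[ok]
    mean_abs = float(abs_rho.mean())
    sd_abs = float(abs_rho.std(ddof=1))
    quadrant = None
    if x_split is not None and y_split is not None:
        quadrant = quadrant_assign(x, y, x_split, y_split)
    return CoherencePoint(
        tf_name=tf,
        profile_difference=x,
        magnitude_difference=y,
        mean_abs_corr=mean_abs,
        sd_abs_corr=sd_abs,
        x_err=sd_abs,
        y_err=float(mag.std(ddof=1)),
        quadrant=quadrant,
    )


def coherence_table(
    post_a: TFActivityPosterior,
    post_b: TFActivityPosterior,
    n_draws: int = DEFAULT_N_DRAWS,
    seed: int = 0,
    x_split: float = DEFAULT_X_SPLIT,
    y_split: Optional[float] = None,
) -> CoherenceResult:
    """Coherence statistics for every TF shared by the two posteriors.

    Rows are sorted by TF name.  TFs with a flat posterior-mean profile are
    excluded and listed in the side report rather than assigned an arbitrary
    value.  The default y split is the median magnitude difference over the
    plotted TFs (the x split defaults to 0.5).
    """
    shared = sorted(set(post_a.tf_names) & set(post_b.tf_names))
    if not shared:
        raise ValueError("posteriors share no TFs")
    points: list[CoherencePoint] = []
    excluded: list[tuple[str, str]] = []
    for tf in shared:
        try:
            points.append(coherence_point(post_a, post_b, tf,
                                          n_draws=n_draws, seed=seed))
        except ZeroVarianceProfileError:
            logger.warning("excluding %s: flat activity profile", tf)
            excluded.append((tf, "zero-variance profile"))
    if y_split is None:
        y_split = float(np.median([p.magnitude_difference for p in points])) \
            if points else 0.0
    for p in points:
        p.quadrant = quadrant_assign(p.profile_difference, p.magnitude_difference,
                                     x_split, y_split)
    table = pd.DataFrame(
        [(p.tf_name, p.mean_abs_corr, p.sd_abs_corr, p.profile_difference,
          p.magnitude_difference, p.x_err, p.y_err, p.quadrant)
         for p in points],
        columns=["tf", "mean_abs_pearson", "sd_abs_pearson", "profile_difference",
                 "magnitude_difference", "x_err", "y_err", "quadrant"],
    )
    return CoherenceResult(table=table, excluded=excluded,
                           x_split=x_split, y_split=y_split)


def write_coherence_table(result: CoherenceResult, path: str | Path) -> None:
    result.table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT,
                        lineterminator="\n")


def plot_coherence(result: CoherenceResult, path: str | Path,
                   title: str = "Coherence plot") -> None:
    """Scatter of (profile difference, magnitude difference) with error bars."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = result.table
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.errorbar(df["profile_difference"], df["magnitude_difference"],
                xerr=df["x_err"], yerr=df["y_err"], fmt="o", ms=5,
                capsize=2, lw=1, color="tab:blue", ecolor="0.6")
    for _, row in df.iterrows():
        ax.annotate(row["tf"], (row["profile_difference"],
                                row["magnitude_difference"]),
                    textcoords="offset points", xytext=(4, 4), fontsize=8)
    ax.axvline(result.x_split, color="0.8", ls="--", lw=1)
    ax.axhline(result.y_split, color="0.8", ls="--", lw=1)
    ax.set_xlabel("profile difference (1 − |Pearson r|)")
    ax.set_ylabel("magnitude difference (| ‖c_A‖ − ‖c_B‖ |)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
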