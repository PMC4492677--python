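"""Bayesian inference of latent TF activity profiles.

The model is a regulon-masked bilinear linear-Gaussian factor model.  For
gene ``n`` and time point ``t``::

    y[n, t] = mu[n] + sum_m X[n, m] * b[n, m] * c[m, t] + eps[n, t]

where ``X`` is the fixed binary connectivity (regulon membership), ``b`` are
gene-specific regulatory strengths, ``c`` are latent TF activity profiles,
``mu`` gene baselines and ``eps ~ N(0, sigma**2)`` i.i.d. noise.  Priors:

* ``b[n, m] ~ N(0, strength_prior_sd**2)`` on connected entries,
* ``mu[n] ~ N(0, baseline_prior_sd**2)``,
* random walk on activities: ``c[m, t0] ~ N(0, 1)`` and
  ``c[m, t] ~ N(c[m, t-1], rw_scale**2 * dt)`` over the (minute) time grid.

The posterior is approximated by mean-field variational Bayes factorising as
``q(b, mu) * q(c)``, with ``q(theta_n)`` a joint Gaussian per gene over the
baseline and that gene's strengths, ``q(c_m)`` a joint Gaussian per TF over
the time grid (so random-walk correlations across time are retained), and a
closed-form point update for the shared noise scale.  Each sweep performs
exact coordinate updates, so the evidence lower bound (ELBO) is
non-decreasing; the trace is recorded on the returned posterior.

The bilinear form is unidentifiable per TF up to a sign/scale exchange
between ``b`` and ``c``.  After convergence a deterministic gauge is fixed:
each TF's strength vector is rescaled to unit Euclidean norm (the activities
absorb the scale) and the sign is chosen so the largest-magnitude strength
entry is positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .io import ConnectivityMatrix, ExpressionMatrix, FLOAT_FMT

logger = logging.getLogger(__name__)

_VAR_FLOOR = 1e-12  # lower bound on the noise variance point estimate


@dataclass
class ModelHyperparams:
    """Hyperparameters of the activity-inference model.

    rw_scale is the prior random-walk SD of an activity per unit sqrt
    minute; with the default 0.1 the marginal prior SD after 110 min is
    about 1, matching the unit-scale prior on the first time point.
    """

    strength_prior_sd: float = 1.0
    baseline_prior_sd: float = 1.0
    rw_scale: float = 0.1
    noise_sd_init: float = 0.5
    max_iters: int = 500
    elbo_rel_tol: float = 1e-6
    seed: int = 0
    per_gene_noise: bool = False

    def __post_init__(self) -> None:
        for name in ("strength_prior_sd", "baseline_prior_sd", "rw_scale",
                     "noise_sd_init", "elbo_rel_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")


@dataclass
class TFActivityPosterior:
    """Variational posterior over TF activities for one fitted condition."""

    tf_names: list[str]
    time_points_min: list[float]
    mean: np.ndarray  # (n_tfs, n_times) posterior mean activities
    variance: np.ndarray  # (n_tfs, n_times) marginal posterior variances
    strengths_mean: Optional[np.ndarray] = None  # (n_genes, n_tfs)
    baseline_mean: Optional[np.ndarray] = None  # (n_genes,)
    gene_ids: Optional[list[str]] = None
    noise_sd_hat: float = float("nan")
    noise_sd_gene: Optional[np.ndarray] = None  # set when per-gene noise is on
    elbo_trace: list[float] = field(default_factory=list)
    converged: bool = True
    n_iters: int = 0
    dropped_tfs: list[str] = field(default_factory=list)
    condition_label: str = ""

    @property
    def n_tfs(self) -> int:
        return len(self.tf_names)

    @property
    def n_times(self) -> int:
        return len(self.time_points_min)

    def profile(self, tf: str) -> np.ndarray:
        """Posterior-mean activity profile of one TF."""
        return self.mean[self.tf_names.index(tf)]


@dataclass
class ActivitySampleSet:
    """Monte-Carlo draws from the marginal activity posterior."""

    tf_names: list[str]
    time_points_min: list[float]
    draws: np.ndarray  # (n_draws, n_tfs, n_times)
    seed: int

    def for_tf(self, tf: str) -> np.ndarray:
        """(n_draws, n_times) draws for one TF."""
        return self.draws[:, self.tf_names.index(tf), :]


def _average_replicates(expression: ExpressionMatrix
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Collapse replicate columns (repeated time values) by averaging."""
    times = np.asarray(expression.time_points_min, dtype=float)
    uniq = np.unique(times)
    if len(uniq) == len(times):
        return expression.values, times
    y = np.column_stack([
        expression.values[:, times == t].mean(axis=1) for t in uniq])
    logger.info("averaged replicate columns: %d -> %d time points",
                len(times), len(uniq))
    return y, uniq


def _rw_precision(times: np.ndarray, rw_scale: float) -> np.ndarray:
    """Precision matrix of the Gaussian random-walk prior on one activity row."""
    t = len(times)
    k = np.zeros((t, t))
    k[0, 0] = 1.0  # c[t0] ~ N(0, 1)
    dts = np.diff(times)
    for i, dt in enumerate(dts):
        w = 1.0 / (rw_scale ** 2 * dt)
        k[i, i] += w
        k[i + 1, i + 1] += w
        k[i, i + 1] -= w
        k[i + 1, i] -= w
    return k


def fit_tf_activities(
    expression: ExpressionMatrix,
    connectivity: ConnectivityMatrix,
    hyper: Optional[ModelHyperparams] = None,
) -> TFActivityPosterior:
    """Fit the bilinear model by coordinate-ascent variational Bayes.

    Genes present in the expression matrix but absent from the connectivity
    get an all-zero regulon row (baseline only); connectivity rows for
    unmeasured genes are ignored.  TFs with no measured target are dropped
    with a warning.  Replicate columns (repeated time values) are averaged
    before fitting.  The fit is deterministic given ``hyper.seed``.
    """
    hyper = hyper or ModelHyperparams()
    y, times = _average_replicates(expression)
    n, t = y.shape
    if t < 2:
        raise ValueError("need at least 2 time points to fit activity profiles")

    # --- align gene sets -------------------------------------------------
    conn_index = {g: i for i, g in enumerate(connectivity.gene_ids)}
    if not set(expression.gene_ids) & set(conn_index):
        raise ValueError("no overlap between expression genes and connectivity genes")
    x = np.zeros((n, connectivity.n_tfs), dtype=np.int8)
    for i, g in enumerate(expression.gene_ids):
        if g in conn_index:
            x[i] = connectivity.entries[conn_index[g]]
    kept = x.sum(axis=0) >= 1
    dropped = [tf for tf, k in zip(connectivity.tf_names, kept) if not k]
    if dropped:
        logger.warning("dropping TF(s) with no measured targets: %s",
                       ", ".join(dropped))
    tf_names = [tf for tf, k in zip(connectivity.tf_names, kept) if k]
    x = x[:, kept]
    m = x.shape[1]
    if m == 0:
        raise ValueError("no TF has any measured target gene")

    # --- initialisation ---------------------------------------------------
    # Genes are bucketed by regulator count k so that the per-gene Gaussian
    # updates run as batched linear algebra: within a bucket every gene's
    # theta_n = (mu_n, b_n1..b_nk) has the same dimension k + 1.
    rng = np.random.default_rng(hyper.seed)
    idx = [np.flatnonzero(x[i]).astype(int) for i in range(n)]
    by_k: dict[int, list[int]] = {}
    for i in range(n):
        by_k.setdefault(len(idx[i]), []).append(i)
    buckets = []  # (gi, bidx, tmean, tcov, prior_prec)
    locate = np.empty((n, 2), dtype=int)  # gene -> (bucket, row)
    for b, (k, genes) in enumerate(sorted(by_k.items())):
        gi = np.asarray(genes)
        bidx = np.array([idx[i] for i in genes], dtype=int).reshape(len(genes), k)
        tmean = np.zeros((len(genes), k + 1))
        tmean[:, 0] = y[gi].mean(axis=1)
        tcov = np.zeros((len(genes), k + 1, k + 1))
        prior_prec = np.concatenate(
            ([1.0 / hyper.baseline_prior_sd ** 2],
             np.full(k, 1.0 / hyper.strength_prior_sd ** 2)))
        buckets.append([gi, bidx, tmean, tcov, prior_prec])
        locate[gi, 0] = b
        locate[gi, 1] = np.arange(len(genes))
    # strength-position groups per TF: (bucket, pos, rows, gene_ids) with
    # pos the strength's index within theta_n (0 is the baseline)
    tf_groups: list[list[tuple[int, int, np.ndarray, np.ndarray]]] = [
        [] for _ in range(m)]
    for b, (gi, bidx, *_rest) in enumerate(buckets):
        for pos in range(bidx.shape[1]):
            for j in np.unique(bidx[:, pos]):
                rows = np.flatnonzero(bidx[:, pos] == j)
                tf_groups[j].append((b, pos + 1, rows, gi[rows]))
    # deterministic small random strength init (order: gene-major)
    for i in range(n):
        b, r = locate[i]
        buckets[b][2][r, 1:] = 0.01 * rng.standard_normal(len(idx[i]))

    c_mean = np.zeros((m, t))
    c_cov = np.zeros((m, t, t))
    var_c = np.zeros((m, t))
    sigma2 = np.full(n if hyper.per_gene_noise else 1, hyper.noise_sd_init ** 2)

    k_prior = _rw_precision(times, hyper.rw_scale)
    _, logdet_k = np.linalg.slogdet(k_prior)

    def sigma2_of(genes: np.ndarray) -> np.ndarray:
        return sigma2[genes] if hyper.per_gene_noise else \
            np.full(len(genes), sigma2[0])

    elbo_trace: list[float] = []
    converged = False

    for sweep in range(1, hyper.max_iters + 1):
        # -- update q(c_m), sequentially over TFs --------------------------
        for j in range(m):
            alpha = np.zeros(t)
            beta = np.zeros(t)
            for b, pos, rows, genes in tf_groups[j]:
                _, bidx, tmean, tcov, _ = buckets[b]
                mn = tmean[rows]  # (r, k+1)
                cv = tcov[rows]
                s2 = sigma2_of(genes)
                e_b2 = mn[:, pos] ** 2 + cv[:, pos, pos]
                # w[:, l] = E[b_j * theta_l]: couples this TF's strength to
                # the gene's baseline and its other regulators
                w = mn[:, pos, None] * mn + cv[:, pos, :]
                cross = np.einsum("rk,rkt->rt", w[:, 1:], c_mean[bidx[rows]])
                contrib = mn[:, pos, None] * y[genes] - w[:, 0, None] \
                    - cross + w[:, pos, None] * c_mean[j]
                alpha += (e_b2 / s2).sum()  # E[b^2] is time-constant
                beta += (contrib / s2[:, None]).sum(axis=0)
            prec = k_prior + np.diag(alpha)
            cov_j = np.linalg.inv(prec)
            cov_j = 0.5 * (cov_j + cov_j.T)
            c_cov[j] = cov_j
            c_mean[j] = cov_j @ beta
            var_c[j] = np.diag(cov_j)

        # -- update q(theta_n) = q(mu_n, b_n), batched per bucket ----------
        sum_c = c_mean.sum(axis=1)  # (m,)
        scc_mean = c_mean @ c_mean.T  # (m, m)
        scc = scc_mean + np.diag(var_c.sum(axis=1))
        sum_y = y.sum(axis=1)
        cy = y @ c_mean.T  # (n, m)
        for bucket in buckets:
            gi, bidx, tmean, tcov, prior_prec = bucket
            g, k1 = tmean.shape
            a = np.empty((g, k1, k1))
            a[:, 0, 0] = t
            a[:, 0, 1:] = sum_c[bidx]
            a[:, 1:, 0] = sum_c[bidx]
            a[:, 1:, 1:] = scc[bidx[:, :, None], bidx[:, None, :]]
            rhs = np.empty((g, k1))
            rhs[:, 0] = sum_y[gi]
            rhs[:, 1:] = np.take_along_axis(cy[gi], bidx, axis=1)
            s2 = sigma2_of(gi)
            prec = a / s2[:, None, None]
            diag = np.arange(k1)
            prec[:, diag, diag] += prior_prec
            cov = np.linalg.inv(prec)
            cov = 0.5 * (cov + np.swapaxes(cov, 1, 2))
            bucket[3] = cov
            bucket[2] = np.einsum("gij,gj->gi", cov, rhs / s2[:, None])

        # -- exact scale-rebalancing step per TF ---------------------------
        # The likelihood is invariant under (b_j, c_j) -> (a*b_j, c_j/a); the
        # ELBO as a function of a has a closed-form maximiser (from the b/c
        # prior terms and the q entropies).  Ascending this direction
        # explicitly removes the slow gauge creep of plain coordinate ascent
        # while keeping every recorded ELBO value monotone.
        for j in range(m):
            p = 0.0
            n_targets = 0
            for b, pos, rows, _genes in tf_groups[j]:
                tmean, tcov = buckets[b][2], buckets[b][3]
                p += float(np.sum(tmean[rows, pos] ** 2 + tcov[rows, pos, pos]))
                n_targets += len(rows)
            p /= hyper.strength_prior_sd ** 2
            q = float(c_mean[j] @ k_prior @ c_mean[j] + np.sum(k_prior * c_cov[j]))
            u = ((n_targets - t)
                 + np.sqrt((n_targets - t) ** 2 + 4 * p * q)) / (2 * p)
            a = float(np.sqrt(u))
            if not np.isfinite(a) or a <= 0:
                continue
            for b, pos, rows, _genes in tf_groups[j]:
                tmean, tcov = buckets[b][2], buckets[b][3]
                tmean[rows, pos] *= a
                tcov[rows, pos, :] *= a
                tcov[rows, :, pos] *= a
            c_mean[j] /= a
            c_cov[j] /= u
            var_c[j] = np.diag(c_cov[j])
        scc_mean = c_mean @ c_mean.T
        sum_c = c_mean.sum(axis=1)

        # -- expected squared residuals (feed sigma and the ELBO) ----------
        sum_var_c = var_c.sum(axis=1)  # (m,)
        exp_sse = np.empty(n)
        kl_theta = 0.0
        for gi, bidx, tmean, tcov, prior_prec in buckets:
            g, k1 = tmean.shape
            resid = y[gi] - tmean[:, :1] \
                - np.einsum("gk,gkt->gt", tmean[:, 1:], c_mean[bidx])
            a_geom = np.empty((g, k1, k1))
            a_geom[:, 0, 0] = t
            a_geom[:, 0, 1:] = sum_c[bidx]
            a_geom[:, 1:, 0] = sum_c[bidx]
            a_geom[:, 1:, 1:] = scc_mean[bidx[:, :, None], bidx[:, None, :]]
            var_theta_part = np.einsum("gij,gij->g", tcov, a_geom)
            cov_diag = np.einsum("gii->gi", tcov)
            e_b2 = tmean[:, 1:] ** 2 + cov_diag[:, 1:]
            var_c_part = np.einsum("gk,gk->g", e_b2, sum_var_c[bidx])
            exp_sse[gi] = np.einsum("gt,gt->g", resid, resid) \
                + var_theta_part + var_c_part
            # prior-plus-entropy contribution of q(theta) for this bucket
            _, logdets = np.linalg.slogdet(tcov)
            e_logp = -0.5 * g * float(np.sum(np.log(2 * np.pi / prior_prec))) \
                - 0.5 * float(np.sum((tmean ** 2 + cov_diag) * prior_prec))
            entropy = 0.5 * (g * k1 * np.log(2 * np.pi * np.e)
                             + float(logdets.sum()))
            kl_theta += e_logp + entropy

        # -- point update of the noise scale -------------------------------
        if hyper.per_gene_noise:
            sigma2 = np.maximum(exp_sse / t, _VAR_FLOOR)
        else:
            sigma2 = np.array([max(exp_sse.sum() / (n * t), _VAR_FLOOR)])

        # -- ELBO ----------------------------------------------------------
        if hyper.per_gene_noise:
            loglik = -0.5 * t * float(np.sum(np.log(2 * np.pi * sigma2))) \
                - 0.5 * float(np.sum(exp_sse / sigma2))
        else:
            loglik = -0.5 * n * t * np.log(2 * np.pi * sigma2[0]) \
                - 0.5 * exp_sse.sum() / sigma2[0]
        kl_c = 0.0
        for j in range(m):
            _, logdet_cov = np.linalg.slogdet(c_cov[j])
            e_logp = 0.5 * (logdet_k - t * np.log(2 * np.pi)) \
                - 0.5 * float(c_mean[j] @ k_prior @ c_mean[j]
                              + np.sum(k_prior * c_cov[j]))
            entropy = 0.5 * (t * np.log(2 * np.pi * np.e) + logdet_cov)
            kl_c += e_logp + entropy
        elbo = loglik + kl_theta + kl_c
        elbo_trace.append(float(elbo))
        logger.debug("sweep %d: ELBO %.6f", sweep, elbo)

        if sweep > 2:
            prev = elbo_trace[-2]
            rel = abs(elbo - prev) / (abs(prev) + 1e-12)
            if rel < hyper.elbo_rel_tol:
                converged = True
                break

    if not converged:
        logger.warning("variational fit did not converge in %d sweeps",
                       hyper.max_iters)

    # --- assemble dense strengths/baselines -------------------------------
    strengths = np.zeros((n, m))
    baselines = np.empty(n)
    for gi, bidx, tmean, _tcov, _pp in buckets:
        baselines[gi] = tmean[:, 0]
        strengths[gi[:, None], bidx] = tmean[:, 1:]

    # --- gauge fixing ------------------------------------------------------
    var_c = np.einsum("mtt->mt", c_cov).copy()
    for j in range(m):
        scale = float(np.linalg.norm(strengths[:, j]))
        if scale > 0:
            strengths[:, j] /= scale
            c_mean[j] *= scale
            var_c[j] *= scale ** 2
        pivot = int(np.argmax(np.abs(strengths[:, j])))
        if strengths[pivot, j] < 0:
            strengths[:, j] *= -1
            c_mean[j] *= -1

    noise_sd_gene = np.sqrt(sigma2) if hyper.per_gene_noise else None
    noise_sd_hat = float(np.sqrt(sigma2.mean()))
    return TFActivityPosterior(
        tf_names=tf_names,
        time_points_min=[float(v) for v in times],
        mean=c_mean,
        variance=np.maximum(var_c, np.finfo(float).tiny),
        strengths_mean=strengths,
        baseline_mean=baselines,
        gene_ids=list(expression.gene_ids),
        noise_sd_hat=noise_sd_hat,
        noise_sd_gene=noise_sd_gene,
        elbo_trace=elbo_trace,
        converged=converged,
        n_iters=len(elbo_trace),
        dropped_tfs=dropped,
        condition_label=expression.condition_label,
    )


def sample_activities(posterior: TFActivityPosterior, n_draws: int,
                      seed: int = 0) -> ActivitySampleSet:
    """Draw independent Gaussians from the marginal posterior per (TF, time)."""
    if n_draws < 2:
        raise ValueError("n_draws must be >= 2")
    rng = np.random.default_rng(seed)
    sd = np.sqrt(posterior.variance)
    draws = posterior.mean[None, :, :] + sd[None, :, :] * \
        rng.standard_normal((n_draws, posterior.n_tfs, posterior.n_times))
    return ActivitySampleSet(
        tf_names=list(posterior.tf_names),
        time_points_min=list(posterior.time_points_min),
        draws=draws,
        seed=seed,
    )


def write_posterior(posterior: TFActivityPosterior, path: str | Path) -> None:
    """Write the per-(TF, time) posterior mean/variance TSV."""
    rows = []
    for i, tf in enumerate(posterior.tf_names):
        for k, t in enumerate(posterior.time_points_min):
            rows.append((tf, t, posterior.mean[i, k], posterior.variance[i, k]))
    pd.DataFrame(rows, columns=["tf", "time_min", "mean", "variance"]).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FMT, lineterminator="\n")


def read_posterior(path: str | Path, condition_label: str = "") -> TFActivityPosterior:
    """Read a posterior TSV back (activities only; strengths are not stored)."""
    df = pd.read_csv(path, sep="\t")
    tfs = list(dict.fromkeys(df["tf"]))
    times = sorted(df["time_min"].unique())
    mean = np.empty((len(tfs), len(times)))
    variance = np.empty_like(mean)
    ti = {t: k for k, t in enumerate(times)}
    fi = {tf: i for i, tf in enumerate(tfs)}
    for _, row in df.iterrows():
        i, k = fi[row["tf"]], ti[row["time_min"]]
        mean[i, k] = row["mean"]
        variance[i, k] = row["variance"]
    return TFActivityPosterior(
        tf_names=tfs, time_points_min=[float(t) for t in times],
        mean=mean, variance=variance,
        condition_label=condition_label or Path(path).stem)


def write_strengths(posterior: TFActivityPosterior, path: str | Path) -> None:
    """Write nonzero posterior-mean strengths as a gene, tf, mean TSV."""
    if posterior.strengths_mean is None or posterior.gene_ids is None:
        raise ValueError("posterior carries no strengths")
    rows = []
    for j, tf in enumerate(posterior.tf_names):
        for i in np.flatnonzero(posterior.strengths_mean[:, j]):
            rows.append((posterior.gene_ids[i], tf, posterior.strengths_mean[i, j]))
    pd.DataFrame(rows, columns=["gene", "tf", "mean"]).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FMT, lineterminator="\n")
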