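"""Dirichlet-process Gaussian-process clustering of expression time courses.

Each cluster is a latent trajectory drawn from a zero-mean Gaussian
process with a squared-exponential kernel on the sampling times; member
genes are conditionally independent noisy observations of that latent
function.  A Chinese-restaurant-process prior with concentration alpha
makes the number of clusters open-ended.  Inference is collapsed Gibbs
sampling over gene assignments: the GP latent function is integrated
out analytically, so each sweep only needs the Gaussian posterior
predictive of a gene's trajectory given its prospective cluster's
members.

Post-burn-in partitions are accumulated into a posterior similarity
matrix (co-clustering frequency per gene pair); the reported partition
is the sampled one closest to that matrix in squared distance (a
least-squares consensus), with a MAP option.

Kernel hyperparameters are fixed by default (signal variance 1 on
standardized data, length-scale half the time span, noise variance
0.1), which keeps runs deterministic given the seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve

logger = logging.getLogger(__name__)

DEFAULT_TIMES = (3.0, 7.0, 13.0, 27.0)

_LOG2PI = math.log(2.0 * math.pi)


@dataclass
class ExpressionSeries:
    """Processed gene x time matrix ready for clustering.

    ``matrix`` rows are replicate-averaged and z-standardized (mean 0,
    SD 1).  ``times`` may contain repeated values when replicates are
    kept as separate noisy observations instead of being averaged.
    """

    gene_ids: list[str]
    times: np.ndarray
    matrix: np.ndarray  # genes x len(times), standardized
    averaged: pd.DataFrame | None = None  # genes x unique times, pre-standardization

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.gene_ids), len(self.times)):
            raise ValueError("matrix shape does not match gene_ids x times")


@dataclass
class ClusterConfig:
    """Sampler and kernel settings.

    alpha : Dirichlet-process concentration; larger favours more clusters.
    sigma_f2 : squared-exponential signal variance (standardized units).
    length_scale : kernel length-scale in minutes; None = half the span.
    sigma_n2 : iid observation noise variance.
    n_iterations / burn_in : Gibbs sweeps and how many to discard.
    map_partition : report the max-posterior sampled partition instead of
        the least-squares consensus.
    """

    alpha: float = 1.0
    sigma_f2: float = 1.0
    length_scale: float | None = None
    sigma_n2: float = 0.1
    n_iterations: int = 500
    burn_in: int = 250
    seed: int = 0
    map_partition: bool = False

    def __post_init__(self) -> None:
        if self.sigma_f2 < 0 or self.sigma_n2 <= 0:
            raise ValueError("variances must be positive (sigma_f2 may be 0 in limits)")
        if not (0 <= self.burn_in < self.n_iterations):
            raise ValueError("need 0 <= burn_in < n_iterations")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")


@dataclass
class ClusterResult:
    gene_ids: list[str]
    assignment: dict[str, int]          # gene -> label, contiguous from 1
    similarity: np.ndarray              # gene x gene co-clustering frequency
    n_clusters: int
    n_samples: int                      # post-burn-in partitions accumulated


def prepare_series(raw: pd.DataFrame, times=None, average: bool = True) -> ExpressionSeries:
    """Average replicates per time point and z-standardize each gene.

    ``raw`` is long-form with columns ``gene_id``, ``time``, ``value``
    (extra columns such as replicate or phase are simply part of the
    replicate pool).  Genes missing any requested time point are dropped
    (they cannot be placed on the common grid), as are genes whose
    trajectory is constant after averaging (standardization undefined).

    With ``average=False`` each replicate stays a separate observation
    at a repeated time point, for feeding replicates straight to the GP
    likelihood.
    """
    for col in ("gene_id", "time", "value"):
        if col not in raw.columns:
            raise ValueError(f"raw series table missing column {col!r}")
    if times is None:
        times = np.array(sorted(raw["time"].unique()), dtype=float)
    else:
        times = np.asarray(times, dtype=float)
    if len(times) < 2:
        raise ValueError("need at least 2 time points")

    mean_tbl = (
        raw.groupby(["gene_id", "time"])["value"].mean().unstack("time")
    )
    missing_cols = [t for t in times if t not in mean_tbl.columns]
    if missing_cols:
        raise ValueError(f"no data at time points {missing_cols}")
    mean_tbl = mean_tbl[list(times)]

    complete = mean_tbl.dropna()
    dropped = sorted(set(mean_tbl.index) - set(complete.index))
    if dropped:
        logger.info("prepare_series: dropped %d gene(s) missing a time point: %s",
                    len(dropped), dropped[:5])

    if average:
        values = complete.to_numpy()
        obs_times = times
        gene_ids = [str(g) for g in complete.index]
    else:
        gene_ids = [str(g) for g in complete.index]
        rows, obs_times = [], None
        for g in gene_ids:
            sub = raw[raw["gene_id"] == g].sort_values("time", kind="stable")
            sub = sub[sub["time"].isin(times)]
            if obs_times is None:
                obs_times = sub["time"].to_numpy(dtype=float)
            rows.append(sub["value"].to_numpy(dtype=float))
        values = np.vstack(rows)

    sd = values.std(axis=1, ddof=0)
    constant = sd < 1e-12
    if constant.any():
        culled = [g for g, c in zip(gene_ids, constant) if c]
        logger.warning("prepare_series: dropped %d constant gene(s): %s",
                       len(culled), culled[:5])
    values = values[~constant]
    gene_ids = [g for g, c in zip(gene_ids, constant) if not c]
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=0, keepdims=True)
    standardized = (values - mu) / sd
    return ExpressionSeries(gene_ids=gene_ids, times=np.asarray(obs_times, dtype=float),
                            matrix=standardized, averaged=complete.loc[gene_ids])


def se_kernel(times: np.ndarray, sigma_f2: float, length_scale: float) -> np.ndarray:
    """Squared-exponential Gram matrix on the sampling times."""
    t = np.asarray(times, dtype=float)
    d2 = (t[:, None] - t[None, :]) ** 2
    return sigma_f2 * np.exp(-0.5 * d2 / length_scale**2)


def _kernel_from_config(times: np.ndarray, cfg: ClusterConfig) -> np.ndarray:
    ell = cfg.length_scale
    if ell is None:
        ell = (times.max() - times.min()) / 2.0
    return se_kernel(times, cfg.sigma_f2, ell)


def gp_marginal_loglik(members: np.ndarray, times: np.ndarray,
                       cfg: ClusterConfig | None = None) -> float:
    """Log marginal likelihood of cluster members around a shared latent GP.

    ``members`` is an (n, T) matrix of trajectories.  Stacking them as
    one vector, the marginal covariance is ``J_n (x) K + sigma_n2 * I``
    where J_n is the all-ones matrix (shared latent function) and K the
    SE Gram matrix on ``times``.  Invariant to member ordering.
    """
    cfg = cfg or ClusterConfig()
    Y = np.atleast_2d(np.asarray(members, dtype=float))
    n, T = Y.shape
    if n < 1:
        raise ValueError("need at least one member")
    K = _kernel_from_config(np.asarray(times, float), cfg)
    cov = np.kron(np.ones((n, n)), K) + cfg.sigma_n2 * np.eye(n * T)
    y = Y.reshape(-1)
    try:
        c, low = cho_factor(cov + 1e-10 * np.eye(n * T))
    except np.linalg.LinAlgError as exc:
        raise FloatingPointError(
            f"covariance not positive definite after jitter (n={n}, T={T}): {exc}"
        ) from exc
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    quad = float(y @ cho_solve((c, low), y))
    return -0.5 * (n * T * _LOG2PI + logdet + quad)


class _Predictive:
    """Posterior-predictive machinery for one shared design.

    For a cluster with n members whose trajectories sum to s, the latent
    function posterior is N(A_n s / sigma_n2, A_n) with
    A_n = (K^-1 + n/sigma_n2 I)^-1; a prospective member's predictive is
    N(A_n s / sigma_n2, A_n + sigma_n2 I).  Everything is cached by n
    because all genes share the time design.
    """

    def __init__(self, K: np.ndarray, sigma_n2: float):
        self.T = K.shape[0]
        self.sigma_n2 = sigma_n2
        jitter = 1e-10 * np.eye(self.T)
        self.Kinv = solve(K + jitter, np.eye(self.T), assume_a="pos")
        self._cache: dict[int, tuple[np.ndarray, tuple, float]] = {}

    def _for_n(self, n: int):
        """Returns (M_n, cho(C_n), logdet C_n) with mean = M_n @ s."""
        hit = self._cache.get(n)
        if hit is not None:
            return hit
        if n == 0:
            A = solve(self.Kinv, np.eye(self.T), assume_a="pos")  # = K
            M = np.zeros((self.T, self.T))
        else:
            A = solve(self.Kinv + (n / self.sigma_n2) * np.eye(self.T),
                      np.eye(self.T), assume_a="pos")
            M = A / self.sigma_n2
        C = A + self.sigma_n2 * np.eye(self.T)
        c = cho_factor(C + 1e-12 * np.eye(self.T))
        logdet = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
        out = (M, c, logdet)
        self._cache[n] = out
        return out

    def log_predictive(self, y: np.ndarray, n: int, s: np.ndarray) -> float:
        M, c, logdet = self._for_n(n)
        r = y - M @ s
        quad = float(r @ cho_solve(c, r))
        return -0.5 * (self.T * _LOG2PI + logdet + quad)


def gibbs_cluster(series: ExpressionSeries, cfg: ClusterConfig | None = None) -> ClusterResult:
    """Collapsed Gibbs sampling over gene-to-cluster assignments.

    Sweeps visit genes in lexicographic id order (so the run is
    invariant to input row order up to relabeling); the CRP prior gives
    an occupied cluster weight n_c and a new cluster weight alpha, each
    multiplied by the GP posterior predictive of the gene's trajectory.
    Deterministic given ``cfg.seed``.
    """
    cfg = cfg or ClusterConfig()
    Y = series.matrix
    n_genes, T = Y.shape
    if n_genes < 2:
        raise ValueError("need at least 2 genes to cluster")
    if T < 2:
        raise ValueError("need at least 2 time points")

    K = _kernel_from_config(series.times, cfg)
    pred = _Predictive(K, cfg.sigma_n2)

    rng = np.random.default_rng(cfg.seed)
    sweep_order = sorted(range(n_genes), key=lambda i: series.gene_ids[i])

    labels = np.zeros(n_genes, dtype=np.int64)  # start with one shared cluster
    members: dict[int, set[int]] = {0: set(range(n_genes))}
    sums: dict[int, np.ndarray] = {0: Y.sum(axis=0)}
    next_label = 1

    psm = np.zeros((n_genes, n_genes))
    sampled: list[np.ndarray] = []
    sampled_logpost: list[float] = []

    log_alpha = math.log(cfg.alpha)

    for sweep in range(cfg.n_iterations):
        for i in sweep_order:
            lab = labels[i]
            members[lab].discard(i)
            sums[lab] -= Y[i]
            if not members[lab]:
                del members[lab], sums[lab]

            cand = sorted(members)
            logw = np.empty(len(cand) + 1)
            for j, c in enumerate(cand):
                n_c = len(members[c])
                logw[j] = math.log(n_c) + pred.log_predictive(Y[i], n_c, sums[c])
            logw[-1] = log_alpha + pred.log_predictive(Y[i], 0, np.zeros(T))

            p = np.exp(logw - logw.max())
            p /= p.sum()
            pick = rng.choice(len(p), p=p)
            if pick == len(cand):
                lab = next_label
                next_label += 1
                members[lab] = set()
                sums[lab] = np.zeros(T)
            else:
                lab = cand[pick]
            labels[i] = lab
            members[lab].add(i)
            sums[lab] += Y[i]

        if sweep >= cfg.burn_in:
            same = labels[:, None] == labels[None, :]
            psm += same
            sampled.append(labels.copy())
            if cfg.map_partition:
                sampled_logpost.append(_log_posterior(Y, labels, pred, cfg))

    n_samples = len(sampled)
    psm /= n_samples

    if cfg.map_partition:
        best = sampled[int(np.argmax(sampled_logpost))]
    else:
        # least-squares consensus: the sampled partition closest to the PSM
        dists = [np.sum(((s[:, None] == s[None, :]).astype(float) - psm) ** 2)
                 for s in sampled]
        best = sampled[int(np.argmin(dists))]

    relabel: dict[int, int] = {}
    assignment: dict[str, int] = {}
    for i, g in enumerate(series.gene_ids):
        raw = int(best[i])
        if raw not in relabel:
            relabel[raw] = len(relabel) + 1
        assignment[g] = relabel[raw]

    return ClusterResult(
        gene_ids=list(series.gene_ids),
        assignment=assignment,
        similarity=psm,
        n_clusters=len(relabel),
        n_samples=n_samples,
    )


def _log_posterior(Y: np.ndarray, labels: np.ndarray, pred: _Predictive,
                   cfg: ClusterConfig) -> float:
    """Unnormalized log posterior of a partition (CRP prior x GP likelihood)."""
    logp = 0.0
    for lab in np.unique(labels):
        idx = np.where(labels == lab)[0]
        n_c = len(idx)
        logp += math.log(cfg.alpha) + math.lgamma(n_c)
        s = np.zeros(Y.shape[1])
        for k, i in enumerate(idx):
            logp += pred.log_predictive(Y[i], k, s)
            s = s + Y[i]
    return logp


def summarize_clusters(result: ClusterResult, series: ExpressionSeries) -> pd.DataFrame:
    """Per-cluster mean trajectory and 2xSD band at each time point.

    Returns a tidy frame with columns cluster, time, mean, sd, lower,
    upper, n_genes — the numbers behind a cluster-summary panel (mean
    line with a +/- 2 SD envelope over member trajectories).
    """
    idx = {g: i for i, g in enumerate(series.gene_ids)}
    rows = []
    for cluster in sorted(set(result.assignment.values())):
        genes = [g for g, c in result.assignment.items() if c == cluster]
        block = series.matrix[[idx[g] for g in genes]]
        mean = block.mean(axis=0)
        sd = block.std(axis=0, ddof=0)
        for t, m, s in zip(series.times, mean, sd):
            rows.append({"cluster": cluster, "time": t, "mean": m, "sd": s,
                         "lower": m - 2 * s, "upper": m + 2 * s, "n_genes": len(genes)})
    return pd.DataFrame(rows)


def member_trajectories(result: ClusterResult, series: ExpressionSeries) -> pd.DataFrame:
    """Tidy per-gene standardized trajectories with cluster labels."""
    idx = {g: i for i, g in enumerate(series.gene_ids)}
    rows = []
    for g, cluster in result.assignment.items():
        for t, v in zip(series.times, series.matrix[idx[g]]):
            rows.append({"gene_id": g, "cluster": cluster, "time": t, "value": v})
    return pd.DataFrame(rows)
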