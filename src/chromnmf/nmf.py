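"""Consensus non-negative matrix factorization with KL multiplicative updates.

The signal matrix V (bins x marks) is approximated by W H with W (bins x r)
and H (r x marks) non-negative. Updates are the Lee-Seung multiplicative rules
for the generalized Kullback-Leibler divergence

    D(V || WH) = sum_jk [ V log(V / (WH)) - V + WH ],

which is non-increasing under each update. Runs are restarted from random
uniform initializations; cluster stability across restarts is summarized by
the consensus of mark connectivity matrices (two marks are connected in a run
when they load maximally on the same profile) and its cophenetic correlation.
The factorization rank is chosen by comparing the real cophenetic curve with
the curve obtained on column-permuted copies of the matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .coverage import CoverageMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "NMFFactorization",
    "ConsensusStats",
    "RankSelection",
    "nmf_run",
    "multirun",
    "connectivity",
    "consensus_cophenetic",
    "permute_columns",
    "select_rank",
    "hoyer_sparseness",
]

_EPS = 1e-12


@dataclass
class NMFFactorization:
    """One NMF solution: V ~ W H at rank r."""

    W: np.ndarray
    H: np.ndarray
    r: int
    loss: float  # final KL divergence D(V || WH)
    rss: float  # squared Frobenius residual ||V - WH||^2
    seed: int
    n_iter: int
    converged: bool
    loss_trace: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class ConsensusStats:
    """Cluster-stability summary of one multi-run NMF at a fixed rank."""

    r: int
    connectivity_list: list[np.ndarray]
    consensus: np.ndarray
    cophenetic: float
    rss: float  # best run's RSS
    source: str = "real"
    repeat_id: int = 0
    degenerate: bool = False  # constant consensus distances
    sparseness_w: float = float("nan")
    sparseness_h: float = float("nan")


@dataclass
class RankSelection:
    """Rank-scan diagnostics and the selected rank (None when no rank passes)."""

    r_star: int | None
    ranks: list[int]
    real_cophenetic: dict[int, float]
    random_mean: dict[int, float]
    random_sd: dict[int, float]
    real_rss: dict[int, float]
    random_rss_mean: dict[int, float]
    sd_factor: float
    real_stats: dict[int, ConsensusStats] = field(default_factory=dict)
    random_stats: dict[int, list[ConsensusStats]] = field(default_factory=dict)
    r_star_rss: int | None = None  # RSS-decrease diagnostic rule

    @property
    def passed(self) -> bool:
        return self.r_star is not None


def _as_array(V) -> np.ndarray:
    if isinstance(V, CoverageMatrix):
        return V.values
    return np.asarray(V, dtype=float)


def _kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    mask = V > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(mask, V * np.log(np.where(mask, V, 1.0) / (WH + _EPS)), 0.0)
    return float(term.sum() - V.sum() + WH.sum())


def hoyer_sparseness(X: np.ndarray) -> float:
    """Hoyer sparseness in [0, 1]: 0 for a flat matrix, 1 for one-hot."""
    x = np.asarray(X, dtype=float).ravel()
    n = len(x)
    l1 = np.abs(x).sum()
    l2 = np.sqrt((x ** 2).sum())
    if l2 == 0 or n <= 1:
        return float("nan")
    return float((np.sqrt(n) - l1 / l2) / (np.sqrt(n) - 1))


def nmf_run(
    V,
    r: int,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-5,
    conn_stop: int = 0,
    check_every: int = 10,
    record_loss_every: int | None = None,
    dtype=np.float64,
) -> NMFFactorization:
    """One NMF run from a random uniform initialization.

    W and H start i.i.d. uniform on [0, max(V)]. Iteration stops when the
    relative KL-loss change over a check interval drops below ``tol``, or at
    ``max_iter``; setting ``conn_stop`` additionally stops a run once the
    mark connectivity matrix has been stationary for that many consecutive
    iterations (the classic consensus-NMF rule, used by the rank scan where
    only the clustering matters). ``record_loss_every=1`` stores the loss at every iteration
    for monotonicity diagnostics. ``dtype=np.float32`` halves memory traffic
    for large scans at no cost to the clustering summaries.
    """
    Va = _as_array(V)
    if Va.ndim != 2:
        raise ValueError("V must be 2-D")
    if (Va < 0).any():
        raise ValueError("V must be non-negative")
    vmax = Va.max()
    if vmax <= 0:
        raise ValueError("V is all zeros: nothing to factorize")
    J, K = Va.shape
    if not (1 <= r <= min(J, K)):
        raise ValueError(f"rank {r} out of range for a {J}x{K} matrix")

    rng = np.random.default_rng(seed)
    W = rng.uniform(0, vmax, size=(J, r)).astype(dtype)
    H = rng.uniform(0, vmax, size=(r, K)).astype(dtype)
    Va = Va.astype(dtype, copy=False)
    eps = dtype(_EPS)

    rec_every = record_loss_every or check_every
    trace: list[float] = []
    prev_loss = None
    prev_conn = None
    conn_stable_iters = 0
    converged = False
    n_done = max_iter

    WH = np.empty((J, K), dtype=dtype)
    ratio = np.empty((J, K), dtype=dtype)
    numH = np.empty((r, K), dtype=dtype)
    numW = np.empty((J, r), dtype=dtype)

    for it in range(1, max_iter + 1):
        # H update
        np.matmul(W, H, out=WH)
        WH += eps
        np.divide(Va, WH, out=ratio)
        np.matmul(W.T, ratio, out=numH)
        numH /= W.sum(axis=0)[:, None] + eps
        H *= numH
        # W update
        np.matmul(W, H, out=WH)
        WH += eps
        np.divide(Va, WH, out=ratio)
        np.matmul(ratio, H.T, out=numW)
        numW /= H.sum(axis=1)[None, :] + eps
        W *= numW

        if it % rec_every == 0 or it == max_iter:
            loss = _kl_divergence(Va, W @ H)
            trace.append(loss)
        if it % check_every == 0:
            loss = trace[-1] if it % rec_every == 0 else _kl_divergence(Va, W @ H)
            if prev_loss is not None:
                denom = abs(prev_loss) + _EPS
                if abs(prev_loss - loss) / denom < tol:
                    converged = True
                    n_done = it
                    break
            prev_loss = loss
            if conn_stop:
                conn = connectivity(H, warn=False)
                if prev_conn is not None and np.array_equal(conn, prev_conn):
                    conn_stable_iters += check_every
                    if conn_stable_iters >= conn_stop:
                        converged = True
                        n_done = it
                        break
                else:
                    conn_stable_iters = 0
                prev_conn = conn

    WH = W @ H
    if not np.all(np.isfinite(W)) or not np.all(np.isfinite(H)):
        raise FloatingPointError("NMF update produced non-finite values")
    return NMFFactorization(
        W=W,
        H=H,
        r=r,
        loss=_kl_divergence(Va, WH),
        rss=float(((Va - WH) ** 2).sum()),
        seed=seed,
        n_iter=n_done,
        converged=converged,
        loss_trace=np.asarray(trace),
    )


def connectivity(H: np.ndarray, warn: bool = True) -> np.ndarray:
    """K x K binary matrix: 1 when two marks share the same dominant profile.

    The dominant profile of mark k is argmax_c H(c, k); numpy's argmax breaks
    ties toward the lowest profile index. An all-zero column lands on profile
    0 by the same rule.
    """
    H = np.asarray(H)
    if H.ndim != 2:
        raise ValueError("H must be 2-D")
    if warn and (H.sum(axis=0) == 0).any():
        logger.warning("connectivity: all-zero mark column assigned to profile 0")
    labels = H.argmax(axis=0)
    return (labels[:, None] == labels[None, :]).astype(np.int8)


def consensus_cophenetic(
    connectivity_list: list[np.ndarray],
) -> tuple[np.ndarray, float, bool]:
    """Average connectivity matrices and score their cluster stability.

    The consensus is the element-wise mean; 1 - consensus is treated as a
    distance, clustered by average linkage, and the cophenetic correlation
    between the original and the tree-induced distances is returned. When all
    pairwise distances are identical the correlation is undefined; the
    clustering is then perfectly represented by the tree and 1.0 is returned
    with the ``degenerate`` flag set.
    """
    if len(connectivity_list) < 2:
        raise ValueError("need at least two connectivity matrices")
    consensus = np.mean([np.asarray(c, dtype=float) for c in connectivity_list], axis=0)
    if not np.allclose(consensus, consensus.T):
        raise ValueError("connectivity matrices must be symmetric")
    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    if len(condensed) == 0 or np.allclose(condensed, condensed[0]):
        logger.info("consensus distances constant; cophenetic reported as 1.0")
        return consensus, 1.0, True
    Z = hierarchy.linkage(condensed, method="average")
    coph, _ = hierarchy.cophenet(Z, condensed)
    return consensus, float(coph), False


def multirun(
    V,
    r: int,
    n_runs: int = 30,
    seed: int = 0,
    seeds: list[int] | None = None,
    source: str = "real",
    repeat_id: int = 0,
    **run_kwargs,
) -> tuple[NMFFactorization, ConsensusStats]:
    """Restart NMF ``n_runs`` times; keep the lowest-RSS solution.

    Per-run seeds are spawned deterministically from ``seed`` unless given
    explicitly. The ConsensusStats aggregates all runs' connectivity matrices.
    """
    if seeds is None:
        ss = np.random.SeedSequence(seed)
        seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n_runs)]
    if len(seeds) < 2:
        raise ValueError("multirun needs at least 2 runs")

    best: NMFFactorization | None = None
    conn_list: list[np.ndarray] = []
    errors: list[Exception] = []
    sp_w: list[float] = []
    sp_h: list[float] = []
    for s in seeds:
        try:
            fac = nmf_run(V, r, seed=s, **run_kwargs)
        except (ValueError, FloatingPointError) as exc:
            errors.append(exc)
            continue
        conn_list.append(connectivity(fac.H, warn=False))
        sp_w.append(hoyer_sparseness(fac.W))
        sp_h.append(hoyer_sparseness(fac.H))
        if best is None or fac.rss < best.rss:
            best = fac
    if best is None:
        raise RuntimeError(f"all {len(seeds)} NMF runs failed: {errors[:1]!r}")
    consensus, coph, degen = consensus_cophenetic(conn_list)
    stats = ConsensusStats(
        r=r,
        connectivity_list=conn_list,
        consensus=consensus,
        cophenetic=coph,
        rss=best.rss,
        source=source,
        repeat_id=repeat_id,
        degenerate=degen,
        sparseness_w=float(np.mean(sp_w)),
        sparseness_h=float(np.mean(sp_h)),
    )
    return best, stats


def permute_columns(V, seed: int = 0):
    """Independently permute each column over rows (the randomized null).

    Per-column value multisets are preserved exactly, so marginal
    distributions survive while cross-mark correlation is destroyed.
    """
    rng = np.random.default_rng(seed)
    if isinstance(V, CoverageMatrix):
        vals = V.values.copy()
        for k in range(vals.shape[1]):
            vals[:, k] = vals[rng.permutation(vals.shape[0]), k]
        return CoverageMatrix(
            values=vals,
            marks=list(V.marks),
            bin_chroms=V.bin_chroms,
            bin_starts=V.bin_starts,
            bin_ends=V.bin_ends,
            stage="random",
        )
    vals = np.array(V, dtype=float, copy=True)
    for k in range(vals.shape[1]):
        vals[:, k] = vals[rng.permutation(vals.shape[0]), k]
    return vals


def select_rank(
    V,
    r_range=range(3, 14),
    n_runs: int = 30,
    random_repeats: int = 20,
    sd_factor: float = 4.0,
    seed: int = 0,
    **run_kwargs,
) -> RankSelection:
    """Scan factorization ranks and pick the smallest stably superior one.

    For each rank the real matrix is factorized ``n_runs`` times and its
    cophenetic coefficient recorded; ``random_repeats`` independent
    column-permuted copies are factorized the same way to give a null mean and
    SD of the coefficient. A rank passes when the real coefficient exceeds the
    null mean by ``sd_factor`` standard deviations, and r* is the smallest
    rank where the condition also holds at the next rank (so one-rank spikes
    are ignored). When no rank qualifies, r_star is None and the curves are
    still returned. The RSS-decrease rule (smallest rank whose RSS drop on
    real data beats the drop on random data) is reported as a diagnostic.
    """
    ranks = sorted(r_range)
    if random_repeats < 2:
        raise ValueError("random_repeats must be >= 2")
    # scan-stage defaults: float32 halves memory traffic, and the Brunet
    # connectivity-stationarity stop ends runs once the mark clustering has
    # settled -- the scan only consumes the clustering, not W and H
    run_kwargs.setdefault("dtype", np.float32)
    run_kwargs.setdefault("conn_stop", 40)
    master = np.random.SeedSequence(seed)
    Va = _as_array(V)
    K = Va.shape[1]
    if ranks[-1] >= Va.shape[1] + 1 or ranks[0] < 2:
        logger.warning("rank range %s vs %d marks: usual practice keeps r < K", ranks, K)

    real_c: dict[int, float] = {}
    rnd_mean: dict[int, float] = {}
    rnd_sd: dict[int, float] = {}
    real_rss: dict[int, float] = {}
    rnd_rss: dict[int, float] = {}
    real_stats: dict[int, ConsensusStats] = {}
    rnd_stats: dict[int, list[ConsensusStats]] = {}

    # one permuted matrix per repeat, shared across ranks (one null dataset,
    # scanned like the real one)
    perm_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in master.spawn(random_repeats)]
    permuted = [permute_columns(Va, seed=s) for s in perm_seeds]

    for r in ranks:
        sub = np.random.SeedSequence((seed, r))
        run_seed = int(sub.generate_state(1)[0] % (2 ** 31))
        _, stats = multirun(V, r, n_runs=n_runs, seed=run_seed, **run_kwargs)
        real_c[r] = stats.cophenetic
        real_rss[r] = stats.rss
        real_stats[r] = stats
        cophs = []
        rss = []
        rnd_stats[r] = []
        for rep, Vr in enumerate(permuted):
            sub_r = np.random.SeedSequence((seed, r, rep + 1))
            _, st = multirun(
                Vr,
                r,
                n_runs=n_runs,
                seed=int(sub_r.generate_state(1)[0] % (2 ** 31)),
                source="random",
                repeat_id=rep,
                **run_kwargs,
            )
            cophs.append(st.cophenetic)
            rss.append(st.rss)
            rnd_stats[r].append(st)
        rnd_mean[r] = float(np.mean(cophs))
        rnd_sd[r] = float(np.std(cophs, ddof=1))
        rnd_rss[r] = float(np.mean(rss))

    def passes(r: int) -> bool:
        return real_c[r] > rnd_mean[r] + sd_factor * rnd_sd[r]

    r_star = None
    for i, r in enumerate(ranks[:-1]):
        if passes(r) and passes(ranks[i + 1]):
            r_star = r
            break

    # RSS-decrease diagnostic: smallest rank where the real RSS drop from the
    # previous rank exceeds the random drop
    r_star_rss = None
    for i in range(1, len(ranks)):
        d_real = real_rss[ranks[i - 1]] - real_rss[ranks[i]]
        d_rand = rnd_rss[ranks[i - 1]] - rnd_rss[ranks[i]]
        if d_real > d_rand:
            r_star_rss = ranks[i]
            break

    return RankSelection(
        r_star=r_star,
        ranks=ranks,
        real_cophenetic=real_c,
        random_mean=rnd_mean,
        random_sd=rnd_sd,
        real_rss=real_rss,
        random_rss_mean=rnd_rss,
        sd_factor=sd_factor,
        real_stats=real_stats,
        random_stats=rnd_stats,
        r_star_rss=r_star_rss,
    )
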