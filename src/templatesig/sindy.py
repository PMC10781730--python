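"""Hybrid-SINDy core: phase clustering and sparsity-swept STLSQ.

Pipeline steps 1–2.  Kinematically similar samples are grouped by nearest
neighbors in the continuous phase variable (circular distance on the 0–100%
stride circle); each cluster is fit with sequential-thresholded least squares
(STLSQ) over a logarithmic grid of sparsity thresholds, and the distinct
supports that recur across clusters become candidate template-signature
structures.  Everything here is deterministic given the phase variable.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .config import ClusterConfig, SweepConfig
from .library import LibraryMatrix, N_COLUMNS
from .states import TemplateStates, circular_phase_distance

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# train/test split
# ---------------------------------------------------------------------------


def split_train_test(states: TemplateStates,
                     config: ClusterConfig | None = None,
                     pool_max: int = 10_800) -> tuple[np.ndarray, np.ndarray]:
    """Reserve the last ``n_test`` samples for model evaluation; the first
    (at most ``pool_max``) of the remainder form the clustering pool."""
    config = config or ClusterConfig()
    m = states.n_samples
    required = config.n_test + max(config.k, config.n_train_centroids)
    if m < required:
        raise ValueError(
            f"trial too short: {m} samples; need at least {required} "
            f"(n_test={config.n_test}, k={config.k}, "
            f"n_train_centroids={config.n_train_centroids})"
        )
    test_idx = np.arange(m - config.n_test, m)
    pool_idx = np.arange(min(m - config.n_test, pool_max))
    return pool_idx, test_idx


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


@dataclass
class Cluster:
    seed: int  # pool sample index that seeded the cluster
    members: np.ndarray  # k pool sample indices, nearest-first
    centroid_phase: float  # circular mean of member phases (% stride)
    centroid_gait_phase: str  # majority gait-phase label among members


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    k: int
    pool_idx: np.ndarray

    def __len__(self) -> int:
        return len(self.clusters)


def cluster_by_phase(psi: np.ndarray, gait_phase: np.ndarray,
                     pool_idx: np.ndarray,
                     n_train_centroids: int, k: int,
                     chunk: int = 512) -> ClusterSet:
    """k-nearest-neighbor clusters in circular phase.

    Seeds are the first ``n_train_centroids`` pool samples; members are the
    ``k`` pool samples with smallest circular distance |psi_i - psi_seed|
    mod 100, ties broken by sample index (deterministic).
    """
    pool_idx = np.asarray(pool_idx)
    if k > pool_idx.size:
        raise ValueError(f"k={k} exceeds pool size {pool_idx.size}")
    if n_train_centroids > pool_idx.size:
        raise ValueError("more cluster seeds than pool samples")
    psi_pool = psi[pool_idx]
    seeds = pool_idx[:n_train_centroids]
    clusters: list[Cluster] = []
    for lo in range(0, seeds.size, chunk):
        seed_chunk = seeds[lo:lo + chunk]
        d = circular_phase_distance(psi[seed_chunk][:, None],
                                    psi_pool[None, :])
        # stable tie-break on sample index: lexsort by (index, distance)
        order = np.lexsort((np.broadcast_to(pool_idx, d.shape), d), axis=1)
        members = pool_idx[order[:, :k]]
        for s, mem in zip(seed_chunk, members):
            ang = psi[mem] / 100.0 * 2 * np.pi
            centroid = np.mod(np.angle(np.mean(np.exp(1j * ang))),
                              2 * np.pi) / (2 * np.pi) * 100.0
            label = Counter(gait_phase[mem]).most_common(1)[0][0]
            clusters.append(Cluster(seed=int(s), members=mem,
                                    centroid_phase=float(centroid),
                                    centroid_gait_phase=str(label)))
    return ClusterSet(clusters=clusters, k=k, pool_idx=pool_idx)


# ---------------------------------------------------------------------------
# sequential-thresholded least squares
# ---------------------------------------------------------------------------


def stlsq(theta: np.ndarray, target: np.ndarray, lam: float,
          max_iter: int = 25) -> np.ndarray:
    """Sequential least squares with hard thresholding at |coef| < lam.

    Iterates {fit on the active set; zero all coefficients below lam} until
    the active set is stable.  Rank-deficient active sets get the
    smallest-norm solution (with a debug log).  Returns the full-length
    coefficient vector with zeros off-support.
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    p = theta.shape[1]

    def fit(active: np.ndarray) -> np.ndarray:
        sol, _, rank, _ = np.linalg.lstsq(theta[:, active], target, rcond=None)
        if rank < active.sum():
            logger.debug("rank-deficient active set (%d < %d): "
                         "smallest-norm solution used", rank, active.sum())
        coef = np.zeros(p)
        coef[active] = sol
        return coef

    active = np.ones(p, dtype=bool)
    coef = fit(active)
    if lam == 0:
        return coef
    for _ in range(max_iter):
        new_active = np.abs(coef) >= lam
        if np.array_equal(new_active, active):
            return coef
        active = new_active
        if not active.any():
            return np.zeros(p)
        coef = fit(active)
    return coef * (np.abs(coef) >= lam)


# ---------------------------------------------------------------------------
# sparsity sweep and candidate pool
# ---------------------------------------------------------------------------


@dataclass
class CandidateSignature:
    """A recurring support structure over the 14 library columns."""

    support: np.ndarray  # bool (14,)
    source: list[int] = field(default_factory=list)  # cluster ids
    frequency: float = 0.0
    gait_phases: Counter = field(default_factory=Counter)
    lambdas: list[float] = field(default_factory=list)
    coefficients: np.ndarray | None = None  # refit later, per gait phase

    @property
    def k(self) -> int:
        return int(self.support.sum())

    @property
    def key(self) -> frozenset:
        return frozenset(np.flatnonzero(self.support).tolist())


def lambda_grid(c_max: float, config: SweepConfig) -> np.ndarray:
    return c_max * np.logspace(np.log10(config.lam_min_frac),
                               np.log10(config.lam_max_frac),
                               config.n_lambdas)


def sweep_sparsity(theta_c: np.ndarray, target_c: np.ndarray,
                   config: SweepConfig | None = None
                   ) -> dict[frozenset, list[float]]:
    """Distinct STLSQ supports over the lambda grid for one cluster.

    The grid runs logarithmically from ``lam_min_frac`` to ``lam_max_frac``
    of the largest-magnitude coefficient of the cluster's unthresholded fit.
    Returns {support: [lambdas that produced it]}.
    """
    config = config or SweepConfig()
    xi_full, *_ = np.linalg.lstsq(theta_c, target_c, rcond=None)
    c_max = float(np.max(np.abs(xi_full)))
    supports: dict[frozenset, list[float]] = {}
    if c_max == 0.0:
        supports[frozenset()] = [0.0]
        return supports
    for lam in lambda_grid(c_max, config):
        xi = stlsq(theta_c, target_c, lam)
        key = frozenset(np.flatnonzero(xi).tolist())
        supports.setdefault(key, []).append(float(lam))
    n = len(supports)
    if not 5 <= n <= 15:
        logger.debug("cluster produced %d unique supports (typical band 5-15)", n)
    return supports


def fit_clusters(library: LibraryMatrix, clusters: ClusterSet,
                 config: SweepConfig | None = None
                 ) -> list[dict[frozenset, list[float]]]:
    """Sparsity sweep for every cluster; returns per-cluster support maps."""
    config = config or SweepConfig()
    out = []
    for c in clusters.clusters:
        rows = library.rows_for_samples(c.members)
        out.append(sweep_sparsity(library.theta[rows], library.target[rows],
                                  config))
    return out


def collect_candidates(per_cluster: list[dict[frozenset, list[float]]],
                       clusters: ClusterSet,
                       frequency_threshold: float = 0.01
                       ) -> list[CandidateSignature]:
    """Pool supports across clusters and discard infrequent ones.

    The frequency of a support is the fraction of clusters in which it
    appeared; supports seen in strictly less than ``frequency_threshold`` of
    clusters are dropped (a support at exactly the threshold is retained).
    """
    n_clusters = len(clusters)
    pool: dict[frozenset, CandidateSignature] = {}
    for cid, (sup_map, cluster) in enumerate(zip(per_cluster,
                                                 clusters.clusters)):
        for key, lams in sup_map.items():
            if key not in pool:
                support = np.zeros(N_COLUMNS, dtype=bool)
                support[list(key)] = True
                pool[key] = CandidateSignature(support=support)
            cand = pool[key]
            cand.source.append(cid)
            cand.gait_phases[cluster.centroid_gait_phase] += 1
            cand.lambdas.extend(lams)
    kept = []
    for cand in pool.values():
        cand.frequency = len(cand.source) / n_clusters
        if cand.frequency >= frequency_threshold and cand.k > 0:
            kept.append(cand)
    if not kept:
        raise ValueError("no frequent signatures: every support fell below "
                         f"the {frequency_threshold:.0%} frequency threshold")
    kept.sort(key=lambda c: (-c.frequency, sorted(c.key)))
    return kept
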