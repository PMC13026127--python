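"""Three-phase RMSD clustering of sidechain conformations into rotamers.

Observed conformations (reconstructed from measured chi in the canonical
backbone frame) are grouped by a residue-specific hard RMSD threshold t:

1. sequential initialization — each conformation joins the first cluster
   whose centroid lies within t, recomputing that centroid, else seeds a new
   cluster;
2. Lloyd-style refinement — conformations migrate to the nearest centroid
   when strictly closer and within t, with immediate centroid updates, until
   a full pass makes no move;
3. hierarchical merging — the closest centroid pair below 0.7 t is merged
   repeatedly until no pair qualifies.

A cluster centroid is the conformation reconstructed from the per-dimension
circular mean of its members' chi vectors, so centroids are always valid
sidechain geometries.  Cluster counts are not fixed in advance; the threshold
alone controls granularity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geometry import (ChiSet, Conformation3D, circular_mean,
                       conformation_rmsd, reconstruct_sidechain)

__all__ = [
    "DEFAULT_THRESHOLDS",
    "ClusterConfig",
    "RotamerCluster",
    "RotamerSet",
    "default_threshold",
    "initialize_clusters",
    "refine_clusters",
    "merge_clusters",
    "cluster_rotamers",
    "order_stability",
]

log = logging.getLogger(__name__)


class ClusteringError(ValueError):
    pass


#: Residue-specific RMSD thresholds t (Angstroms), chosen by conformational
#: flexibility: tight for short/branched/aromatic sidechains, loose for long
#: flexible ones.
DEFAULT_THRESHOLDS: dict[str, float] = {
    "ARG": 0.80, "ASN": 0.70, "ASP": 0.30, "CYS": 0.40, "GLN": 0.70,
    "GLU": 0.90, "HIS": 0.50, "ILE": 0.60, "LEU": 0.40, "LYS": 0.70,
    "MET": 0.80, "PHE": 0.35, "PRO": 0.40, "SER": 0.35, "THR": 0.40,
    "TRP": 0.80, "TYR": 0.30, "VAL": 0.40,
}


def default_threshold(aa_type: str) -> float:
    """Default clustering threshold t for one amino acid."""
    try:
        return DEFAULT_THRESHOLDS[aa_type]
    except KeyError:
        raise ClusteringError(f"{aa_type} has no rotamers to cluster") from None


@dataclass
class ClusterConfig:
    threshold_t: float
    merge_factor: float = 0.7
    max_refine_iters: int = 100
    order_seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.merge_factor < 1.0):
            raise ClusteringError("merge_factor must be in (0, 1)")
        if self.threshold_t <= 0:
            raise ClusteringError("threshold must be positive")


@dataclass
class RotamerCluster:
    rotamer_id: int
    canonical_chi: ChiSet
    centroid_conformation: Conformation3D
    member_count: int
    mean_internal_rmsd: float


@dataclass
class RotamerSet:
    aa_type: str
    clusters: list[RotamerCluster]
    threshold: float

    @property
    def canonical_chi_matrix(self) -> np.ndarray:
        return np.array([c.canonical_chi.chi for c in self.clusters])

    @property
    def centroid_coords(self) -> np.ndarray:
        """(n_clusters, n_atoms, 3) stack for vectorized nearest-rotamer search."""
        return np.stack([c.centroid_conformation.coords for c in self.clusters])

    def __len__(self) -> int:
        return len(self.clusters)


class _Cluster:
    """Mutable working cluster: member indices plus a chi-space centroid."""

    __slots__ = ("members", "centroid_chi", "centroid_conf", "aa_type")

    def __init__(self, aa_type: str, members: list[int], chis: np.ndarray):
        self.aa_type = aa_type
        self.members = members
        self.recompute(chis)

    def recompute(self, chis: np.ndarray) -> None:
        sub = chis[self.members]
        self.centroid_chi = np.array(
            [circular_mean(sub[:, k]) for k in range(sub.shape[1])])
        self.centroid_conf = reconstruct_sidechain(self.aa_type,
                                                   self.centroid_chi)


class ClusterState:
    """Shared state across the three phases."""

    def __init__(self, aa_type: str, confs: Sequence[Conformation3D],
                 chis: np.ndarray):
        self.aa_type = aa_type
        self.confs = list(confs)
        self.chis = np.asarray(chis, dtype=float)
        self.clusters: list[_Cluster] = []
        self.assignment = np.full(len(self.confs), -1, dtype=int)

    def n_assigned(self) -> int:
        return int(np.sum(self.assignment >= 0))


def _dist(conf: Conformation3D, cluster: _Cluster) -> float:
    return conformation_rmsd(conf, cluster.centroid_conf)


def initialize_clusters(confs: Sequence[Conformation3D],
                        chis: np.ndarray,
                        aa_type: str,
                        config: ClusterConfig) -> ClusterState:
    """Phase one: sequential seeding in a seeded random processing order."""
    if len(confs) == 0:
        raise ClusteringError("cannot cluster an empty conformation list")
    state = ClusterState(aa_type, confs, chis)
    order = np.random.default_rng(config.order_seed).permutation(len(confs))
    t = config.threshold_t
    for idx in order:
        placed = False
        for ci, cl in enumerate(state.clusters):
            if _dist(state.confs[idx], cl) <= t:
                cl.members.append(int(idx))
                cl.recompute(state.chis)
                state.assignment[idx] = ci
                placed = True
                break
        if not placed:
            state.clusters.append(_Cluster(aa_type, [int(idx)], state.chis))
            state.assignment[idx] = len(state.clusters) - 1
    return state


def refine_clusters(state: ClusterState, config: ClusterConfig) -> ClusterState:
    """Phase two: iterative reassignment to the nearest centroid within t."""
    t = config.threshold_t
    for it in range(config.max_refine_iters):
        moved = False
        for idx in range(len(state.confs)):
            cur = state.assignment[idx]
            cur_d = _dist(state.confs[idx], state.clusters[cur])
            best_ci, best_d = cur, cur_d
            for ci, cl in enumerate(state.clusters):
                if ci == cur or not cl.members:
                    continue
                d = _dist(state.confs[idx], cl)
                # strictly closer, within threshold; ties keep lowest index
                if d < best_d - 1e-12 and d <= t:
                    best_ci, best_d = ci, d
            if best_ci != cur:
                state.clusters[cur].members.remove(idx)
                state.clusters[best_ci].members.append(idx)
                if state.clusters[cur].members:
                    state.clusters[cur].recompute(state.chis)
                state.clusters[best_ci].recompute(state.chis)
                state.assignment[idx] = best_ci
                moved = True
        # drop emptied clusters, remap assignment
        if any(not cl.members for cl in state.clusters):
            keep = [cl for cl in state.clusters if cl.members]
            remap = {id(cl): i for i, cl in enumerate(keep)}
            for i, cl in enumerate(state.clusters):
                if cl.members:
                    for m in cl.members:
                        state.assignment[m] = remap[id(cl)]
            state.clusters = keep
        if not moved:
            break
    else:
        log.warning("refinement hit max_refine_iters=%d without convergence",
                    config.max_refine_iters)
    return state


def merge_clusters(state: ClusterState, config: ClusterConfig) -> RotamerSet:
    """Phase three: merge the closest centroid pair below merge_factor * t."""
    cutoff = config.merge_factor * config.threshold_t
    clusters = state.clusters
    while len(clusters) > 1:
        best = None
        best_d = cutoff
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = conformation_rmsd(clusters[i].centroid_conf,
                                      clusters[j].centroid_conf)
                if d < best_d:
                    best, best_d = (i, j), d
        if best is None:
            break
        i, j = best
        clusters[i].members.extend(clusters[j].members)
        clusters[i].recompute(state.chis)
        del clusters[j]
    for ci, cl in enumerate(clusters):
        for m in cl.members:
            state.assignment[m] = ci
    return _emit(state)


def _emit(state: ClusterState) -> RotamerSet:
    records = []
    for cl in state.clusters:
        rmsds = [conformation_rmsd(state.confs[m], cl.centroid_conf)
                 for m in cl.members]
        records.append((len(cl.members), tuple(cl.centroid_chi), cl,
                        float(np.mean(rmsds))))
    # descending member count, ties by ascending canonical chi1
    records.sort(key=lambda r: (-r[0], r[1][0]))
    out = []
    for rid, (count, chi, cl, mean_rmsd) in enumerate(records):
        out.append(RotamerCluster(
            rotamer_id=rid,
            canonical_chi=ChiSet(state.aa_type, chi),
            centroid_conformation=cl.centroid_conf,
            member_count=count,
            mean_internal_rmsd=mean_rmsd,
        ))
    return RotamerSet(state.aa_type, out, threshold=np.nan)


def cluster_rotamers(residues: Sequence, aa_type: str,
                     config: ClusterConfig | None = None) -> RotamerSet:
    """Run all three phases on the residues' measured chi vectors."""
    if config is None:
        config = ClusterConfig(threshold_t=default_threshold(aa_type))
    chis = []
    for r in residues:
        if r.aa_type != aa_type:
            raise ClusteringError(
                f"residue of type {r.aa_type} in {aa_type} clustering")
        chis.append(r.chi)
    if not chis:
        raise ClusteringError(f"no residues of type {aa_type}")
    chis = np.asarray(chis, dtype=float)
    confs = [reconstruct_sidechain(aa_type, c) for c in chis]
    state = initialize_clusters(confs, chis, aa_type, config)
    state = refine_clusters(state, config)
    rs = merge_clusters(state, config)
    rs.threshold = config.threshold_t
    log.info("%s: %d conformations -> %d rotamers (t=%.2f A)",
             aa_type, len(confs), len(rs), config.threshold_t)
    return rs


def _match_centroids(a: RotamerSet, b: RotamerSet) -> float:
    """Greedy nearest-centroid matching; returns the max matched RMSD."""
    pairs = []
    for i, ca in enumerate(a.clusters):
        for j, cb in enumerate(b.clusters):
            pairs.append((conformation_rmsd(ca.centroid_conformation,
                                            cb.centroid_conformation), i, j))
    pairs.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    worst = 0.0
    for d, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        worst = max(worst, d)
        if len(used_a) == min(len(a), len(b)):
            break
    return worst


def order_stability(residues: Sequence, aa_type: str,
                    config: ClusterConfig, n_orders: int) -> dict:
    """Re-cluster under several random processing orders and compare.

    Reports the spread in cluster count and the worst matched-centroid RMSD
    across all pairs of runs.
    """
    if n_orders < 1:
        raise ClusteringError("n_orders must be >= 1")
    runs = []
    for k in range(n_orders):
        cfg = ClusterConfig(config.threshold_t, config.merge_factor,
                            config.max_refine_iters,
                            order_seed=config.order_seed + k)
        runs.append(cluster_rotamers(residues, aa_type, cfg))
    counts = [len(r) for r in runs]
    worst = 0.0
    for i in range(len(runs)):
        for j in range(i + 1, len(runs)):
            worst = max(worst, _match_centroids(runs[i], runs[j]))
    return {
        "n_orders": n_orders,
        "cluster_counts": counts,
        "count_range": max(counts) - min(counts),
        "max_matched_centroid_rmsd": worst,
    }
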