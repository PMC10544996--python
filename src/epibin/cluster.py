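"""Clustering of within-group RMSD matrices into structural bins.

Four algorithms are provided, all deterministic and implemented from first
principles on precomputed distance matrices:

* ``greedy`` — center-based sphere clustering in input order; members join
  a center when their RMSD to it is strictly below the threshold.
* ``agglomerative`` — hierarchical merging (complete, average or single
  linkage) while the minimum linkage distance is at or below the threshold;
  complete linkage therefore bounds the maximum intra-cluster pairwise RMSD
  by the threshold.
* ``dbscan`` — density clustering; with ``min_samples=2`` the result equals
  the connected components of the graph with edges at distance <= eps,
  noise points reported as singletons.
* ``butina`` — sphere exclusion: repeatedly take the unassigned member with
  the most unassigned neighbours within the threshold as a centroid.

Threshold boundary conventions differ deliberately: greedy admits strictly
below the threshold, the other three include distances exactly at it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import DistanceMatrix, build_length_groups, pairwise_rmsd_matrix
from .io import CDR_NAMES, FvModel, RegionScheme

__all__ = [
    "ClusteringParams",
    "ClusterAssignment",
    "HEAVY_CDRS",
    "greedy_cluster",
    "agglomerative_cluster",
    "dbscan_cluster",
    "butina_cluster",
    "cluster_matrix",
    "run_pipeline",
]

#: CDR subset used by heavy-chain-only clustering.
HEAVY_CDRS = ("CDRH1", "CDRH2", "CDRH3")

_ALGORITHMS = ("greedy", "agglomerative", "dbscan", "butina")
_LINKAGES = ("complete", "average", "single")


@dataclass(frozen=True)
class ClusteringParams:
    """Algorithm choice and its parameters.

    Defaults are the optimized production setting: complete-linkage
    agglomerative clustering at a 1.25 A RMSD threshold.
    """

    algorithm: str = "agglomerative"
    rmsd_threshold: float = 1.25
    linkage: str = "complete"
    min_samples: int = 2
    reorder: bool = False

    def __post_init__(self) -> None:
        if self.algorithm not in _ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}; expected one of {_ALGORITHMS}")
        if not self.rmsd_threshold > 0:
            raise ValueError("rmsd_threshold must be > 0")
        if self.linkage not in _LINKAGES:
            raise ValueError(f"unknown linkage {self.linkage!r}; expected one of {_LINKAGES}")
        if self.min_samples < 2:
            raise ValueError("min_samples must be >= 2")


@dataclass
class ClusterAssignment:
    """Total mapping antibody id -> cluster id, with provenance."""

    assignments: dict[str, str]
    params: ClusteringParams
    scheme_name: str = ""
    cdr_subset: str = "all"
    group_keys: dict[str, str] = field(default_factory=dict)  # id -> group key

    def clusters(self) -> dict[str, list[str]]:
        """Cluster id -> member ids, members in input order."""
        out: dict[str, list[str]] = {}
        for ab, cid in self.assignments.items():
            out.setdefault(cid, []).append(ab)
        return out

    def __len__(self) -> int:
        return len(self.assignments)

    def to_frame(self) -> pd.DataFrame:
        sizes = {cid: len(m) for cid, m in self.clusters().items()}
        rows = [
            {
                "id": ab,
                "cluster_id": cid,
                "cluster_size": sizes[cid],
                "group_key": self.group_keys.get(ab, ""),
                "algorithm": self.params.algorithm,
                "threshold": self.params.rmsd_threshold,
            }
            for ab, cid in self.assignments.items()
        ]
        cols = ["id", "cluster_id", "cluster_size", "group_key", "algorithm", "threshold"]
        return pd.DataFrame(rows, columns=cols)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "ClusterAssignment":
        df = pd.read_csv(path, dtype={"id": str, "cluster_id": str, "group_key": str})
        params = ClusteringParams(
            algorithm=str(df["algorithm"].iloc[0]) if len(df) else "agglomerative",
            rmsd_threshold=float(df["threshold"].iloc[0]) if len(df) else 1.25,
        )
        return cls(
            assignments=dict(zip(df["id"], df["cluster_id"])),
            params=params,
            group_keys=dict(zip(df["id"], df["group_key"])),
        )


def _check_threshold(threshold: float) -> None:
    if not threshold > 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")


def greedy_cluster(d: DistanceMatrix, threshold: float) -> list[list[int]]:
    """Center-based greedy clustering in input order.

    The first unclustered member becomes a center and absorbs every
    yet-unclustered member whose RMSD to it is strictly smaller than the
    threshold; repeat until all members are assigned.  Deterministic given
    input order, and order-dependent by construction.
    """
    _check_threshold(threshold)
    n = len(d.group)
    unassigned = list(range(n))
    clusters: list[list[int]] = []
    while unassigned:
        center = unassigned.pop(0)
        members = [center]
        remaining = []
        for k in unassigned:
            if d.rmsd[center, k] < threshold:
                members.append(k)
            else:
                remaining.append(k)
        unassigned = remaining
        clusters.append(members)
    return clusters


def _linkage_distance(d: np.ndarray, a: list[int], b: list[int], linkage: str) -> float:
    block = d[np.ix_(a, b)]
    if linkage == "complete":
        return float(block.max())
    if linkage == "average":
        return float(block.mean())
    if linkage == "single":
        return float(block.min())
    raise ValueError(f"unknown linkage {linkage!r}")


def agglomerative_cluster(
    d: DistanceMatrix, threshold: float, linkage: str = "complete"
) -> list[list[int]]:
    """Hierarchical agglomerative clustering cut at a distance threshold.

    Starting from singletons, repeatedly merge the pair of clusters with the
    smallest linkage distance while that distance is <= threshold (distances
    exactly at the threshold merge).  Ties are broken by the lowest (i, j)
    index pair over current cluster positions.  With complete linkage the
    maximum intra-cluster pairwise RMSD never exceeds the threshold.
    """
    _check_threshold(threshold)
    if linkage not in _LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}")
    n = len(d.group)
    active: list[list[int]] = [[i] for i in range(n)]
    while len(active) > 1:
        best = None
        best_pair = None
        for i in range(len(active)):
            for j in range(i + 1, len(active)):
                dist = _linkage_distance(d.rmsd, active[i], active[j], linkage)
                if best is None or dist < best - 1e-15:
                    best = dist
                    best_pair = (i, j)
        if best is None or best > threshold:
            break
        i, j = best_pair
        active[i] = active[i] + active[j]
        del active[j]
    return active


def dbscan_cluster(
    d: DistanceMatrix, eps: float, min_samples: int = 2
) -> list[list[int]]:
    """Density-based clustering on the precomputed matrix.

    A member is a core point when its eps-neighbourhood (itself included)
    holds at least ``min_samples`` members.  Clusters grow from core points
    through core-to-core reachability; non-core members attach to the first
    core cluster that reaches them; unreached members are noise and are
    reported as singleton clusters.
    """
    _check_threshold(eps)
    if min_samples < 2:
        raise ValueError("min_samples must be >= 2")
    n = len(d.group)
    neighbours = [np.where(d.rmsd[i] <= eps)[0] for i in range(n)]
    core = [len(nb) >= min_samples for nb in neighbours]  # neighbourhood includes self
    labels = [-1] * n
    cid = 0
    for start in range(n):
        if labels[start] != -1 or not core[start]:
            continue
        labels[start] = cid
        frontier = [start]
        while frontier:
            p = frontier.pop(0)
            for q in neighbours[p]:
                q = int(q)
                if labels[q] == -1:
                    labels[q] = cid
                    if core[q]:
                        frontier.append(q)
        cid += 1
    clusters: list[list[int]] = [[] for _ in range(cid)]
    for idx, lab in enumerate(labels):
        if lab >= 0:
            clusters[lab].append(idx)
    for idx, lab in enumerate(labels):  # noise -> singletons
        if lab == -1:
            clusters.append([idx])
    return clusters


def butina_cluster(
    d: DistanceMatrix, threshold: float, reorder: bool = False
) -> list[list[int]]:
    """Sphere-exclusion clustering.

    Each member's neighbours are those within the threshold (inclusive).
    Repeatedly the unassigned member with the most unassigned neighbours
    (ties to the lowest input index) becomes a centroid and claims itself
    plus its unassigned neighbours; with ``reorder`` the counts are
    recomputed after every exclusion round.
    """
    _check_threshold(threshold)
    n = len(d.group)
    nb_sets = [set(np.where(d.rmsd[i] <= threshold)[0].tolist()) - {i} for i in range(n)]
    unassigned = set(range(n))
    initial_counts = {i: len(nb_sets[i]) for i in range(n)}
    clusters: list[list[int]] = []
    while unassigned:
        if reorder:
            counts = {i: len(nb_sets[i] & unassigned) for i in unassigned}
        else:
            counts = {i: initial_counts[i] for i in unassigned}
        centroid = max(sorted(unassigned), key=lambda i: (counts[i], -i))
        members = [centroid] + sorted((nb_sets[centroid] & unassigned) - {centroid})
        clusters.append(members)
        unassigned -= set(members)
    return clusters


def cluster_matrix(d: DistanceMatrix, params: ClusteringParams) -> list[list[int]]:
    """Dispatch one distance matrix to the configured algorithm."""
    if params.algorithm == "greedy":
        return greedy_cluster(d, params.rmsd_threshold)
    if params.algorithm == "agglomerative":
        return agglomerative_cluster(d, params.rmsd_threshold, params.linkage)
    if params.algorithm == "dbscan":
        return dbscan_cluster(d, params.rmsd_threshold, params.min_samples)
    if params.algorithm == "butina":
        return butina_cluster(d, params.rmsd_threshold, params.reorder)
    raise ValueError(f"unknown algorithm {params.algorithm!r}")


def _order_clusters_by_first_member(clusters: list[list[int]]) -> list[list[int]]:
    return sorted(clusters, key=lambda c: min(c))


def run_pipeline(
    models: Sequence[FvModel],
    scheme: RegionScheme,
    params: ClusteringParams | None = None,
    cdr_subset: str = "all",
    paratope_flags: Mapping[str, tuple[str, ...]] | None = None,
    alignment: str = "pairwise",
) -> ClusterAssignment:
    """Full structural binning pipeline.

    Models are split into groups of identical CDR lengths, each group's
    pairwise CDR RMSD matrix is computed after framework superposition, and
    the configured algorithm clusters each matrix.  Cluster ids are
    namespaced by group key (``"{group_key}:{ordinal}"``) so they are unique
    across groups.

    ``cdr_subset`` selects the comparison regions:

    * ``"all"`` — all six CDRs, aligned on both-chain framework;
    * ``"heavy"`` — CDRs H1-H3 only, aligned on heavy-chain framework;
    * ``"paratope"`` — per-antibody paratope CDR sets (``paratope_flags``
      required); antibodies are first grouped by identical paratope-CDR
      sets, then by the lengths of those CDRs, aligned on heavy-chain
      framework.
    """
    params = params or ClusteringParams()
    if cdr_subset == "all":
        jobs = [(tuple(CDR_NAMES), ("H", "L"), list(models))]
    elif cdr_subset == "heavy":
        jobs = [(HEAVY_CDRS, ("H",), list(models))]
    elif cdr_subset == "paratope":
        if paratope_flags is None:
            raise ValueError("cdr_subset='paratope' requires paratope_flags")
        by_set: dict[tuple[str, ...], list[FvModel]] = {}
        for m in models:
            if m.antibody_id not in paratope_flags:
                raise ValueError(f"no paratope flags for antibody {m.antibody_id}")
            by_set.setdefault(paratope_flags[m.antibody_id], []).append(m)
        jobs = [(cdrs, ("H",), ms) for cdrs, ms in by_set.items()]
    else:
        raise ValueError(f"unknown cdr_subset {cdr_subset!r}")

    assignments: dict[str, str] = {}
    group_keys: dict[str, str] = {}
    for cdrs, fw_chains, job_models in jobs:
        model_map = {m.antibody_id: m for m in job_models}
        for group in build_length_groups(job_models, scheme, cdrs):
            dm = pairwise_rmsd_matrix(group, model_map, scheme, cdrs,
                                      mode=alignment, framework_chains=fw_chains)
            clusters = _order_clusters_by_first_member(cluster_matrix(dm, params))
            key = group.key_str()
            for ordinal, members in enumerate(clusters):
                cid = f"{key}:{ordinal}"
                for idx in members:
                    ab = group.members[idx]
                    assignments[ab] = cid
                    group_keys[ab] = key
    # report in input model order
    ordered = {m.antibody_id: assignments[m.antibody_id] for m in models}
    return ClusterAssignment(
        assignments=ordered,
        params=params,
        scheme_name=scheme.name,
        cdr_subset=cdr_subset,
        group_keys=group_keys,
    )
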