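"""Functional evaluation of structural clusters against epitope labels.

A multiple-occupancy cluster (>= 2 members) is *consistent* when its
members' epitope annotations agree; singletons are excluded from every
accuracy metric.  Two label resolutions are supported:

* epitope level — members must share one epitope-group identifier;
* domain level — members must share the antigen and their domain labels
  must agree under four rules: identical domains; one labeled domain plus
  antigen-only labels; no domain labels at all; or domains forming a chain
  under a configured subdomain hierarchy (e.g. NTD a subdomain of non-RBD).

Seven dataset-level metrics summarise a clustering: two accuracy fractions,
two coverage counts, the accuracy/coverage trade-off count, and two
within-cluster diversity measures (clonotype mixing and mean CDRH3
identity).  A size-matched random-permutation baseline calibrates them.

Clusters containing any label-unknown member at the required resolution are
excluded from accuracy numerators and denominators and counted separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cluster import ClusterAssignment
from .io import UNKNOWN, AntibodyRecord, EpitopeLabel

__all__ = [
    "DomainHierarchy",
    "ConsistencyReport",
    "BaselineReport",
    "classify_epitope_consistency",
    "classify_domain_consistency",
    "compute_metrics",
    "relaxed_consistency",
    "random_baseline",
    "interspecies_cluster_count",
    "mean_pairwise_cdr3_identity",
    "adjusted_rand_index",
]

_METRIC_NAMES = (
    "fraction_consistent_clusters",
    "fraction_clustered_in_consistent",
    "n_multi_clusters",
    "n_in_multi_clusters",
    "n_in_consistent_multi_clusters",
    "fraction_clusters_multi_clonotype",
    "mean_cdrh3_identity_consistent",
)


@dataclass
class DomainHierarchy:
    """Partial order of subdomain relations per antigen (child strictly inside parent)."""

    parents: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # acyclicity: walking parents from any node must terminate
        for antigen, child in self.parents:
            seen = {child}
            cur = child
            while (antigen, cur) in self.parents:
                cur = self.parents[(antigen, cur)]
                if cur in seen:
                    raise ValueError(f"cycle in domain hierarchy for antigen {antigen!r}")
                seen.add(cur)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DomainHierarchy":
        parents = {}
        for _, row in df.iterrows():
            parents[(str(row["antigen"]), str(row["child_domain"]))] = str(row["parent_domain"])
        return cls(parents)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DomainHierarchy":
        return cls.from_frame(pd.read_csv(path, dtype=str))

    def known_domain(self, antigen: str, domain: str) -> bool:
        return (
            (antigen, domain) in self.parents
            or any(a == antigen and p == domain for (a, _), p in self.parents.items())
        )

    def is_subdomain(self, antigen: str, child: str, parent: str) -> bool:
        """Reflexive-transitive subdomain test within one antigen."""
        if child == parent:
            return True
        cur = child
        while (antigen, cur) in self.parents:
            cur = self.parents[(antigen, cur)]
            if cur == parent:
                return True
        return False


def adjusted_rand_index(a: Mapping[str, str], b: Mapping[str, str]) -> float:
    """Chance-corrected agreement of two partitions over the same ids.

    1.0 means identical partitions (up to label names); 0 is the expected
    agreement of random partitions with the same cluster sizes.
    """
    if set(a) != set(b):
        raise ValueError("partitions cover different id sets")
    ids = list(a)
    n = len(ids)
    if n == 0:
        raise ValueError("empty partitions")
    labels_a = sorted({a[i] for i in ids})
    labels_b = sorted({b[i] for i in ids})
    ia = {lab: k for k, lab in enumerate(labels_a)}
    ib = {lab: k for k, lab in enumerate(labels_b)}
    table = np.zeros((len(labels_a), len(labels_b)), dtype=np.int64)
    for i in ids:
        table[ia[a[i]], ib[b[i]]] += 1

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(table).sum()
    sum_a = comb2(table.sum(axis=1)).sum()
    sum_b = comb2(table.sum(axis=0)).sum()
    expected = sum_a * sum_b / comb2(n)
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:  # both partitions trivial
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def classify_epitope_consistency(group_ids: Sequence[str]) -> str:
    """Verdict for one cluster given its members' epitope-group ids."""
    if len(group_ids) == 0:
        raise ValueError("empty cluster")
    if len(group_ids) == 1:
        return "singleton"
    if any(g == UNKNOWN for g in group_ids):
        return "unevaluable"
    return "consistent" if len(set(group_ids)) == 1 else "inconsistent"


def classify_domain_consistency(
    labels: Sequence[EpitopeLabel], hierarchy: DomainHierarchy | None = None
) -> str:
    """Verdict for one cluster given its members' antigen/domain labels.

    Consistent when all members share the antigen and either (1) all share
    one domain, (2) one labeled domain appears alongside domain-unknown
    labels, (3) no member has a domain label, or (4) the labeled domains
    form a chain under the configured subdomain hierarchy.
    """
    if len(labels) == 0:
        raise ValueError("empty cluster")
    if len(labels) == 1:
        return "singleton"
    if any(l.antigen == UNKNOWN for l in labels):
        return "unevaluable"
    antigens = {l.antigen for l in labels}
    if len(antigens) > 1:
        return "inconsistent"
    antigen = next(iter(antigens))
    domains = sorted({l.domain for l in labels if l.domain != UNKNOWN})
    if len(domains) <= 1:
        return "consistent"  # rules 1-3
    if hierarchy is None:
        return "inconsistent"
    for d in domains:
        if not hierarchy.known_domain(antigen, d):
            warnings.warn(f"domain {d!r} of antigen {antigen!r} absent from hierarchy")
            return "inconsistent"
    for i, a in enumerate(domains):  # rule 4: chain under the subdomain order
        for b in domains[i + 1:]:
            if not (hierarchy.is_subdomain(antigen, a, b)
                    or hierarchy.is_subdomain(antigen, b, a)):
                return "inconsistent"
    return "consistent"


@dataclass
class ConsistencyReport:
    """Per-cluster verdicts plus the seven dataset-level metrics.

    Fractions are ``None`` when their denominator is empty (e.g. a
    clustering with no multiple-occupancy clusters).
    """

    per_cluster: dict[str, str]
    modal_fraction: dict[str, float]
    fraction_consistent_clusters: float | None
    fraction_clustered_in_consistent: float | None
    n_multi_clusters: int
    n_in_multi_clusters: int
    n_in_consistent_multi_clusters: int
    fraction_clusters_multi_clonotype: float | None
    mean_cdrh3_identity_consistent: float | None
    n_unevaluable_multi_clusters: int = 0

    def metrics(self) -> dict[str, float | int | None]:
        return {name: getattr(self, name) for name in _METRIC_NAMES}

    def to_frame(self) -> pd.DataFrame:
        rows = [{"metric": k, "value": "" if v is None else v}
                for k, v in self.metrics().items()]
        rows.append({"metric": "n_unevaluable_multi_clusters",
                     "value": self.n_unevaluable_multi_clusters})
        return pd.DataFrame(rows, columns=["metric", "value"])


def mean_pairwise_cdr3_identity(seqs: Sequence[str]) -> float:
    """Mean positional identity over unordered pairs.

    Pairs with unequal lengths (possible in structural clusters compared
    over CDR subsets) or missing sequences score 0 rather than erroring.
    """
    n = len(seqs)
    if n < 2:
        raise ValueError("need at least two sequences")
    total = 0.0
    n_pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            a, b = seqs[i], seqs[j]
            if a and b and len(a) == len(b):
                total += sum(x == y for x, y in zip(a, b)) / len(a)
            n_pairs += 1
    return total / n_pairs


def _labels_for(
    members: Sequence[str],
    records: Mapping[str, AntibodyRecord],
    level: str,
) -> Sequence:
    missing = [m for m in members if m not in records]
    if missing:
        raise ValueError(f"no metadata for clustered antibodies {missing}")
    if level == "epitope":
        # at epitope resolution the antigen column carries the epitope-group id
        return [records[m].epitope_label.antigen for m in members]
    if level == "domain":
        return [records[m].epitope_label for m in members]
    raise ValueError(f"unknown level {level!r}")


def _verdict(labels, level: str, hierarchy: DomainHierarchy | None) -> str:
    if level == "epitope":
        return classify_epitope_consistency(labels)
    return classify_domain_consistency(labels, hierarchy)


def compute_metrics(
    assignment: ClusterAssignment | Mapping[str, str],
    records: Mapping[str, AntibodyRecord],
    clonotypes: Mapping[str, str] | None = None,
    level: str = "epitope",
    hierarchy: DomainHierarchy | None = None,
) -> ConsistencyReport:
    """Classify every cluster and compute the seven dataset-level metrics.

    ``clonotypes`` (id -> clonotype id, typically VH-clonotypes) feeds the
    clonotype-mixing metric; without it that metric is ``None``.  At epitope
    level the modal-epitope fraction per cluster is also recorded for the
    relaxed-consistency analysis.
    """
    mapping = assignment.assignments if isinstance(assignment, ClusterAssignment) else dict(assignment)
    clusters: dict[str, list[str]] = {}
    for ab, cid in mapping.items():
        clusters.setdefault(cid, []).append(ab)

    per_cluster: dict[str, str] = {}
    modal: dict[str, float] = {}
    n_multi = n_in_multi = 0
    n_cons = n_incons = n_unevaluable = 0
    n_in_evaluable = n_in_cons = 0
    cons_cluster_members: list[list[str]] = []
    for cid, members in clusters.items():
        labels = _labels_for(members, records, level)
        verdict = _verdict(labels, level, hierarchy)
        per_cluster[cid] = verdict
        if level == "epitope" and len(members) >= 2:
            known = [g for g in labels if g != UNKNOWN]
            if known:
                modal[cid] = max(known.count(g) for g in set(known)) / len(members)
        if len(members) < 2:
            continue
        n_multi += 1
        n_in_multi += len(members)
        if verdict == "unevaluable":
            n_unevaluable += 1
            continue
        n_in_evaluable += len(members)
        if verdict == "consistent":
            n_cons += 1
            n_in_cons += len(members)
            cons_cluster_members.append(members)
        else:
            n_incons += 1

    n_evaluable = n_cons + n_incons
    frac_cons = n_cons / n_evaluable if n_evaluable else None
    frac_in_cons = n_in_cons / n_in_evaluable if n_in_evaluable else None

    frac_multi_ct: float | None = None
    if clonotypes is not None and cons_cluster_members:
        mixed = sum(
            len({clonotypes[m] for m in members}) > 1
            for members in cons_cluster_members
        )
        frac_multi_ct = mixed / len(cons_cluster_members)

    mean_id: float | None = None
    if cons_cluster_members:
        per_cluster_ids = [
            mean_pairwise_cdr3_identity([records[m].cdrh3_seq for m in members])
            for members in cons_cluster_members
        ]
        mean_id = float(np.mean(per_cluster_ids))

    return ConsistencyReport(
        per_cluster=per_cluster,
        modal_fraction=modal,
        fraction_consistent_clusters=frac_cons,
        fraction_clustered_in_consistent=frac_in_cons,
        n_multi_clusters=n_multi,
        n_in_multi_clusters=n_in_multi,
        n_in_consistent_multi_clusters=n_in_cons,
        fraction_clusters_multi_clonotype=frac_multi_ct,
        mean_cdrh3_identity_consistent=mean_id,
        n_unevaluable_multi_clusters=n_unevaluable,
    )


def relaxed_consistency(
    assignment: ClusterAssignment | Mapping[str, str],
    records: Mapping[str, AntibodyRecord],
    fraction: float = 0.7,
) -> tuple[float, float]:
    """Credit for nearly-consistent clusters at epitope resolution.

    Among evaluable multiple-occupancy clusters that are not fully
    consistent, those whose modal epitope group covers at least ``fraction``
    of members are tallied.  Returns the additional fraction of clusters and
    the additional fraction of antibodies in multiple-occupancy clusters.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    mapping = assignment.assignments if isinstance(assignment, ClusterAssignment) else dict(assignment)
    clusters: dict[str, list[str]] = {}
    for ab, cid in mapping.items():
        clusters.setdefault(cid, []).append(ab)
    n_evaluable = n_in_evaluable = 0
    extra_clusters = extra_abs = 0
    for members in clusters.values():
        if len(members) < 2:
            continue
        labels = _labels_for(members, records, "epitope")
        verdict = classify_epitope_consistency(labels)
        if verdict == "unevaluable":
            continue
        n_evaluable += 1
        n_in_evaluable += len(members)
        if verdict == "consistent":
            continue
        share = max(labels.count(g) for g in set(labels)) / len(members)
        if share >= fraction:
            extra_clusters += 1
            extra_abs += len(members)
    if n_evaluable == 0:
        return 0.0, 0.0
    return extra_clusters / n_evaluable, extra_abs / n_in_evaluable


@dataclass
class BaselineReport:
    """Metrics of a size-matched random clustering, averaged over repetitions."""

    mean: dict[str, float | None]
    sd: dict[str, float | None]
    n_reps: int


def random_baseline(
    assignment: ClusterAssignment | Mapping[str, str],
    records: Mapping[str, AntibodyRecord],
    clonotypes: Mapping[str, str] | None = None,
    n_reps: int = 100,
    seed: int = 0,
    level: str = "epitope",
    hierarchy: DomainHierarchy | None = None,
) -> BaselineReport:
    """Random clustering baseline with the observed cluster-size distribution.

    Per repetition the clustered antibodies are uniformly permuted and cut
    into clusters of exactly the observed sizes; the seven metrics are
    computed and averaged over repetitions.  The coverage counts equal the
    real run's by construction.
    """
    mapping = assignment.assignments if isinstance(assignment, ClusterAssignment) else dict(assignment)
    clusters: dict[str, list[str]] = {}
    for ab, cid in mapping.items():
        clusters.setdefault(cid, []).append(ab)
    sizes = [len(m) for m in clusters.values()]
    ids = list(mapping.keys())
    rng = np.random.default_rng(seed)
    samples: dict[str, list[float]] = {name: [] for name in _METRIC_NAMES}
    for _ in range(n_reps):
        perm = [ids[k] for k in rng.permutation(len(ids))]
        shuffled: dict[str, str] = {}
        pos = 0
        for c, size in enumerate(sizes):
            for ab in perm[pos:pos + size]:
                shuffled[ab] = f"rand:{c}"
            pos += size
        rep = compute_metrics(shuffled, records, clonotypes, level, hierarchy)
        for name, value in rep.metrics().items():
            if value is not None:
                samples[name].append(float(value))
    mean = {k: (float(np.mean(v)) if v else None) for k, v in samples.items()}
    sd = {k: (float(np.std(v, ddof=1)) if len(v) > 1 else None) for k, v in samples.items()}
    return BaselineReport(mean=mean, sd=sd, n_reps=n_reps)


def interspecies_cluster_count(
    assignment: ClusterAssignment | Mapping[str, str],
    records: Mapping[str, AntibodyRecord],
    level: str = "epitope",
    hierarchy: DomainHierarchy | None = None,
) -> int:
    """Count consistent multiple-occupancy clusters mixing more than one species.

    Species ``unknown`` is ignored for the more-than-one test; only
    functionally consistent clusters qualify.
    """
    mapping = assignment.assignments if isinstance(assignment, ClusterAssignment) else dict(assignment)
    clusters: dict[str, list[str]] = {}
    for ab, cid in mapping.items():
        clusters.setdefault(cid, []).append(ab)
    count = 0
    for members in clusters.values():
        if len(members) < 2:
            continue
        labels = _labels_for(members, records, level)
        if _verdict(labels, level, hierarchy) != "consistent":
            continue
        species = {records[m].species for m in members} - {UNKNOWN}
        if len(species) > 1:
            count += 1
    return count
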