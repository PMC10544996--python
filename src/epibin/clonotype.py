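"""Sequence-based clonotype assignment — the baseline to structural binning.

A VH-clonotype groups antibodies with matching IGHV genes, length-matched
CDRH3 and CDRH3 sequence identity strictly above a threshold (80% by the
lenient community convention).  An Fv-clonotype additionally requires
matching light-chain V genes, length-matched CDRL3 and CDRL3 identity above
the same threshold.  The pairwise rule is closed transitively
(single-linkage connected components), the standard convention and the only
order-independent one.

Gene names are compared after stripping allele suffixes
(``IGHV3-53*01`` -> ``IGHV3-53``); allele-level matching is a switch.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings
from typing import Iterable, Sequence

import pandas as pd

from .io import UNKNOWN, AntibodyRecord

__all__ = [
    "ClonotypeParams",
    "cdr3_identity",
    "strip_allele",
    "vh_clonotype",
    "fv_clonotype",
    "clonotype_frame",
]


@dataclass(frozen=True)
class ClonotypeParams:
    """Thresholds and matching level for clonotype assignment."""

    identity_threshold: float = 0.8
    require_j_match: bool = False
    level: str = "VH"
    allele_level: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.identity_threshold <= 1:
            raise ValueError("identity_threshold must be in (0, 1]")
        if self.level not in ("VH", "Fv"):
            raise ValueError(f"level must be 'VH' or 'Fv', got {self.level!r}")


def cdr3_identity(a: str, b: str) -> float:
    """Positional (Hamming) identity of two length-matched CDR3 sequences."""
    if not a or not b:
        raise ValueError("empty CDR3 sequence")
    if len(a) != len(b):
        raise ValueError(f"CDR3 length mismatch: {len(a)} vs {len(b)}")
    return sum(x == y for x, y in zip(a, b)) / len(a)


def strip_allele(gene: str) -> str:
    return gene.split("*", 1)[0]


class _UnionFind:
    def __init__(self, items: Iterable[str]):
        self.parent = {i: i for i in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _gene_key(gene: str, allele_level: bool) -> str:
    return gene if allele_level else strip_allele(gene)


def _components(
    records: Sequence[AntibodyRecord],
    block_key,
    connect,
    incomplete,
) -> dict[str, str]:
    """Single-linkage components of the pairwise predicate within blocks.

    Records failing ``incomplete`` become warned singletons.  Cluster ids
    are assigned by first-member input order, making the partition itself
    independent of record order.
    """
    valid: list[AntibodyRecord] = []
    singles: list[AntibodyRecord] = []
    for r in records:
        (singles if incomplete(r) else valid).append(r)
    if singles:
        warnings.warn(
            f"{len(singles)} record(s) missing clonotyping fields kept as singletons"
        )
    uf = _UnionFind([r.antibody_id for r in records])
    blocks: dict[tuple, list[AntibodyRecord]] = {}
    for r in valid:
        blocks.setdefault(block_key(r), []).append(r)
    for members in blocks.values():
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if connect(members[i], members[j]):
                    uf.union(members[i].antibody_id, members[j].antibody_id)
    order = {r.antibody_id: k for k, r in enumerate(records)}
    roots: dict[str, str] = {}
    out: dict[str, str] = {}
    for r in sorted(records, key=lambda r: order[r.antibody_id]):
        root = uf.find(r.antibody_id)
        if root not in roots:
            roots[root] = f"ct{len(roots)}"
        out[r.antibody_id] = roots[root]
    return {r.antibody_id: out[r.antibody_id] for r in records}


def vh_clonotype(
    records: Sequence[AntibodyRecord], params: ClonotypeParams | None = None
) -> dict[str, str]:
    """Heavy-chain clonotypes: id -> clonotype id.

    Pairs connect when IGHV genes match, CDRH3 lengths match and CDRH3
    identity is strictly greater than the threshold; clonotypes are the
    connected components of that relation.  J-gene matching joins the block
    key when ``require_j_match``.
    """
    params = params or ClonotypeParams()

    def block_key(r: AntibodyRecord):
        key = [_gene_key(r.heavy_v_gene, params.allele_level), len(r.cdrh3_seq)]
        if params.require_j_match:
            key.append(_gene_key(r.heavy_j_gene, params.allele_level))
        return tuple(key)

    def connect(a: AntibodyRecord, b: AntibodyRecord) -> bool:
        return cdr3_identity(a.cdrh3_seq, b.cdrh3_seq) > params.identity_threshold

    def incomplete(r: AntibodyRecord) -> bool:
        return r.heavy_v_gene == UNKNOWN or not r.cdrh3_seq

    return _components(records, block_key, connect, incomplete)


def fv_clonotype(
    records: Sequence[AntibodyRecord], params: ClonotypeParams | None = None
) -> dict[str, str]:
    """Paired-chain clonotypes: the VH predicate AND light V gene match,
    CDRL3 length match and CDRL3 identity strictly above the threshold."""
    params = params or ClonotypeParams(level="Fv")

    def block_key(r: AntibodyRecord):
        key = [
            _gene_key(r.heavy_v_gene, params.allele_level), len(r.cdrh3_seq),
            _gene_key(r.light_v_gene, params.allele_level), len(r.cdrl3_seq),
        ]
        if params.require_j_match:
            key.append(_gene_key(r.heavy_j_gene, params.allele_level))
        return tuple(key)

    def connect(a: AntibodyRecord, b: AntibodyRecord) -> bool:
        return (
            cdr3_identity(a.cdrh3_seq, b.cdrh3_seq) > params.identity_threshold
            and cdr3_identity(a.cdrl3_seq, b.cdrl3_seq) > params.identity_threshold
        )

    def incomplete(r: AntibodyRecord) -> bool:
        return (
            r.heavy_v_gene == UNKNOWN or not r.cdrh3_seq
            or r.light_v_gene == UNKNOWN or not r.cdrl3_seq
        )

    return _components(records, block_key, connect, incomplete)


def clonotype_frame(partition: dict[str, str]) -> pd.DataFrame:
    return pd.DataFrame(
        {"id": list(partition.keys()), "clonotype_id": list(partition.values())}
    )
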