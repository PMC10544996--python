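"""Rigid-body framework superposition and CDR Calpha RMSD.

Antibodies are compared only within groups sharing identical CDR lengths:
models are superposed on the Calpha atoms of framework residues common to
both, and the pooled RMSD over the concatenated CDR Calpha atoms is the
distance.  Distances are never computed across length groups, which keeps
the pairwise matrix computation tractable on large repertoires.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CDR_NAMES, FvModel, RegionExtract, RegionScheme, extract_regions

__all__ = [
    "RigidTransform",
    "LengthGroup",
    "DistanceMatrix",
    "MIN_SHARED_FRAMEWORK",
    "kabsch_superpose",
    "cdr_rmsd",
    "build_length_groups",
    "pairwise_rmsd_matrix",
    "write_distance_matrix",
]

#: Minimum number of framework positions two models must share for a
#: meaningful superposition.
MIN_SHARED_FRAMEWORK = 20


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t (rotation in SO(3), t in Angstrom)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation determinant is not +1 (improper rotation)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ np.asarray(self.rotation).T + np.asarray(self.translation)


@dataclass(frozen=True)
class LengthGroup:
    """Antibodies sharing identical lengths over a fixed set of CDRs.

    ``cdrs`` names the CDRs defining the group (all six in the standard
    pipeline; a subset in heavy-chain or paratope modes) and ``lengths``
    their common lengths, in the canonical H1,H2,H3,L1,L2,L3 order.
    Member order equals input order.
    """

    cdrs: tuple[str, ...]
    lengths: tuple[int, ...]
    members: tuple[str, ...]

    def key_str(self) -> str:
        s = "-".join(str(n) for n in self.lengths)
        if self.cdrs != CDR_NAMES:
            tag = "+".join(c.replace("CDR", "") for c in self.cdrs)
            return f"{tag}_{s}"
        return s

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class DistanceMatrix:
    """Symmetric within-group matrix of pooled CDR Calpha RMSDs (Angstrom)."""

    group: LengthGroup
    rmsd: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.group)
        m = np.asarray(self.rmsd, dtype=float)
        if m.shape != (n, n):
            raise ValueError(f"matrix shape {m.shape} does not match group size {n}")
        if not np.allclose(m, m.T, atol=1e-9):
            raise ValueError("distance matrix is not symmetric")
        if (m < 0).any():
            raise ValueError("negative distances")
        if not np.allclose(np.diag(m), 0.0, atol=1e-9):
            raise ValueError("nonzero diagonal")


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[RigidTransform, float]:
    """Least-squares proper superposition of ``mobile`` onto ``reference``.

    Returns the rigid transform minimizing the RMSD of the index-paired
    point sets, with reflections excluded by the usual determinant sign
    correction of the SVD solution, and the minimized RMSD.

    Raises on fewer than 3 points or exactly collinear point sets (the
    rotation about the common axis would be undetermined).
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("mobile and reference must be matching (n, 3) arrays")
    n = P.shape[0]
    if n < 3:
        raise ValueError(f"superposition needs >= 3 points, got {n}")
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    # Collinear sets leave a free rotation; coplanar sets are fine for SVD.
    if np.linalg.matrix_rank(Qc, tol=1e-10) < 2 or np.linalg.matrix_rank(Pc, tol=1e-10) < 2:
        raise ValueError("degenerate (collinear) point set")
    H = Pc.T @ Qc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = Q.mean(axis=0) - R @ P.mean(axis=0)
    transform = RigidTransform(rotation=R, translation=t)
    moved = transform.apply(P)
    fit_rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return transform, fit_rmsd


def _pooled_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def _shared_framework(
    ea: RegionExtract, eb: RegionExtract
) -> tuple[np.ndarray, np.ndarray]:
    keys_b = {k: i for i, k in enumerate(eb.framework_keys)}
    ia, ib = [], []
    for i, k in enumerate(ea.framework_keys):
        j = keys_b.get(k)
        if j is not None:
            ia.append(i)
            ib.append(j)
    return ea.framework_points[ia], eb.framework_points[ib]


def _stack_cdrs(extract: RegionExtract, cdr_subset: Sequence[str]) -> np.ndarray:
    return np.vstack([extract.cdr_points[c] for c in cdr_subset])


def cdr_rmsd(
    a: FvModel,
    b: FvModel,
    scheme: RegionScheme,
    cdr_subset: Sequence[str] = CDR_NAMES,
    framework_chains: Iterable[str] = ("H", "L"),
) -> float:
    """Pooled CDR Calpha RMSD of ``b`` against ``a`` after framework superposition.

    The framework alignment set is the intersection of framework residue
    keys present in both models (at least MIN_SHARED_FRAMEWORK positions).
    CDR atoms are paired by sequential order within each CDR, which is valid
    because lengths match within a group, and pooled over all CDRs in
    ``cdr_subset`` — not averaged per CDR.
    """
    cdr_subset = tuple(cdr_subset)
    ea = extract_regions(a, scheme, cdr_subset, framework_chains)
    eb = extract_regions(b, scheme, cdr_subset, framework_chains)
    for cdr, la, lb in zip(cdr_subset, ea.cdr_lengths, eb.cdr_lengths):
        if la != lb:
            raise ValueError(
                f"{cdr} length mismatch between {a.antibody_id} ({la}) and "
                f"{b.antibody_id} ({lb}); group by CDR lengths first"
            )
    fw_a, fw_b = _shared_framework(ea, eb)
    if fw_a.shape[0] < MIN_SHARED_FRAMEWORK:
        raise ValueError(
            f"only {fw_a.shape[0]} shared framework positions between "
            f"{a.antibody_id} and {b.antibody_id} (need >= {MIN_SHARED_FRAMEWORK})"
        )
    transform, _ = kabsch_superpose(fw_b, fw_a)
    cdr_a = _stack_cdrs(ea, cdr_subset)
    cdr_b = transform.apply(_stack_cdrs(eb, cdr_subset))
    return _pooled_rmsd(cdr_a, cdr_b)


def build_length_groups(
    models: Sequence[FvModel],
    scheme: RegionScheme,
    cdr_subset: Sequence[str] = CDR_NAMES,
) -> list[LengthGroup]:
    """Partition models by their tuple of CDR lengths over ``cdr_subset``.

    Singleton groups are allowed; group order follows first appearance and
    member order follows input order.
    """
    cdr_subset = tuple(cdr_subset)
    groups: dict[tuple[int, ...], list[str]] = {}
    for model in models:
        extract = extract_regions(model, scheme, cdr_subset)
        groups.setdefault(extract.cdr_lengths, []).append(model.antibody_id)
    return [
        LengthGroup(cdrs=cdr_subset, lengths=lengths, members=tuple(ids))
        for lengths, ids in groups.items()
    ]


def pairwise_rmsd_matrix(
    group: LengthGroup,
    models: Mapping[str, FvModel],
    scheme: RegionScheme,
    cdr_subset: Sequence[str] | None = None,
    mode: str = "pairwise",
    framework_chains: Iterable[str] = ("H", "L"),
) -> DistanceMatrix:
    """Within-group matrix of pooled CDR RMSDs.

    ``mode='pairwise'`` (default) performs an independent framework
    superposition per pair.  ``mode='reference'`` superposes every model
    once onto the group's first member and computes all RMSDs in that
    common frame without re-fitting — an O(n) approximation whose
    discrepancy against pairwise mode is documented, never silent.
    """
    cdr_subset = tuple(cdr_subset) if cdr_subset is not None else group.cdrs
    n = len(group)
    mats = np.zeros((n, n))
    member_models = [models[mid] for mid in group.members]
    if mode == "pairwise":
        for i in range(n):
            for j in range(i + 1, n):
                try:
                    d = cdr_rmsd(member_models[i], member_models[j], scheme,
                                 cdr_subset, framework_chains)
                except ValueError as exc:
                    raise ValueError(
                        f"pair ({group.members[i]}, {group.members[j]}): {exc}"
                    ) from exc
                mats[i, j] = mats[j, i] = d
    elif mode == "reference":
        extracts = [extract_regions(m, scheme, cdr_subset, framework_chains)
                    for m in member_models]
        ref = extracts[0]
        cdrs: list[np.ndarray] = [_stack_cdrs(ref, cdr_subset)]
        for k in range(1, n):
            fw_m, fw_r = _shared_framework(extracts[k], ref)
            if fw_m.shape[0] < MIN_SHARED_FRAMEWORK:
                raise ValueError(
                    f"pair ({group.members[k]}, {group.members[0]}): only "
                    f"{fw_m.shape[0]} shared framework positions"
                )
            transform, _ = kabsch_superpose(fw_m, fw_r)
            cdrs.append(transform.apply(_stack_cdrs(extracts[k], cdr_subset)))
        for i in range(n):
            for j in range(i + 1, n):
                mats[i, j] = mats[j, i] = _pooled_rmsd(cdrs[i], cdrs[j])
    else:
        raise ValueError(f"unknown mode {mode!r} (expected 'pairwise' or 'reference')")
    return DistanceMatrix(group=group, rmsd=mats)


def write_distance_matrix(dm: DistanceMatrix, directory: str | Path) -> Path:
    """Export one group's matrix as CSV, group key encoded in the filename."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{dm.group.key_str()}.csv"
    df = pd.DataFrame(dm.rmsd, index=dm.group.members, columns=dm.group.members)
    df.to_csv(path)
    return path
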