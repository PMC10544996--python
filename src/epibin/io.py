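"""Reading and writing IMGT-numbered Fv models and antibody metadata.

Structural models are expected one Fv per PDB file with chains ``H`` and
``L``, residue sequence numbers equal to IMGT positions (insertion codes
allowed) and a Calpha atom per residue.  Only Calpha coordinates are ever
loaded; all downstream geometry operates on them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "ResidueKey",
    "FvModel",
    "RegionScheme",
    "RegionExtract",
    "EpitopeLabel",
    "AntibodyRecord",
    "CDR_NAMES",
    "UNKNOWN",
    "read_fv_model",
    "write_fv_model",
    "read_models_dir",
    "extract_regions",
    "read_metadata",
    "write_metadata",
    "read_paratope_flags",
]

#: Canonical CDR order used for length keys: (H1, H2, H3, L1, L2, L3).
CDR_NAMES = ("CDRH1", "CDRH2", "CDRH3", "CDRL1", "CDRL2", "CDRL3")

#: Sentinel for absent metadata values (empty gene calls, epitope labels ...).
UNKNOWN = "unknown"

_METADATA_COLUMNS = [
    "id", "heavy_v_gene", "heavy_j_gene", "light_v_gene", "light_j_gene",
    "cdrh3", "cdrl3", "species", "antigen", "domain",
]


@dataclass(frozen=True, order=True)
class ResidueKey:
    """Identity of one Fv residue: chain, IMGT position, insertion code."""

    chain: str
    imgt_position: int
    insertion_code: str = ""

    def __post_init__(self) -> None:
        if self.chain not in ("H", "L"):
            raise ValueError(f"chain must be 'H' or 'L', got {self.chain!r}")
        if self.imgt_position < 1:
            raise ValueError(f"IMGT position must be >= 1, got {self.imgt_position}")
        if len(self.insertion_code) > 1:
            raise ValueError(f"insertion code must be one character or blank: {self.insertion_code!r}")


@dataclass
class FvModel:
    """One antibody's Calpha trace keyed by IMGT residue identity.

    ``residues`` preserves file order; every residue carries exactly one
    Calpha coordinate in Angstrom.
    """

    antibody_id: str
    residues: list[tuple[ResidueKey, np.ndarray]]
    source_path: str = ""

    def __post_init__(self) -> None:
        seen: set[ResidueKey] = set()
        for key, xyz in self.residues:
            if key in seen:
                raise ValueError(f"{self.antibody_id}: duplicate residue {key}")
            seen.add(key)
            if np.asarray(xyz).shape != (3,):
                raise ValueError(f"{self.antibody_id}: coordinate for {key} is not a 3-vector")

    @property
    def chains(self) -> set[str]:
        return {k.chain for k, _ in self.residues}

    def __len__(self) -> int:
        return len(self.residues)

    def coord_map(self) -> dict[ResidueKey, np.ndarray]:
        return {k: xyz for k, xyz in self.residues}

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "FvModel":
        """Return a copy with every coordinate mapped to ``R x + t``."""
        new = [(k, rotation @ np.asarray(xyz) + translation) for k, xyz in self.residues]
        return FvModel(self.antibody_id, new, self.source_path)


@dataclass(frozen=True)
class RegionScheme:
    """CDR position intervals (inclusive IMGT bounds) per chain.

    Framework is defined as the complement of the CDR intervals within the
    occupied Fv positions up to ``max_position``.  Defaults follow the
    North CDR boundaries expressed in IMGT numbering; they are configuration,
    not hard-coded truth.
    """

    name: str = "north_imgt"
    h_cdr1: tuple[int, int] = (24, 40)
    h_cdr2: tuple[int, int] = (55, 66)
    h_cdr3: tuple[int, int] = (105, 117)
    l_cdr1: tuple[int, int] = (24, 40)
    l_cdr2: tuple[int, int] = (55, 66)
    l_cdr3: tuple[int, int] = (105, 117)
    max_position: int = 128

    def __post_init__(self) -> None:
        for chain in "HL":
            ivals = sorted(self.cdr_intervals(chain).values())
            for (a1, b1), (a2, b2) in zip(ivals, ivals[1:]):
                if a2 <= b1:
                    raise ValueError(f"overlapping CDR intervals on chain {chain}")

    def cdr_intervals(self, chain: str) -> dict[str, tuple[int, int]]:
        if chain == "H":
            return {"CDRH1": self.h_cdr1, "CDRH2": self.h_cdr2, "CDRH3": self.h_cdr3}
        if chain == "L":
            return {"CDRL1": self.l_cdr1, "CDRL2": self.l_cdr2, "CDRL3": self.l_cdr3}
        raise ValueError(f"unknown chain {chain!r}")

    def region_of(self, key: ResidueKey) -> str:
        """Region name for a residue: one of CDR_NAMES or ``'framework'``."""
        for cdr, (lo, hi) in self.cdr_intervals(key.chain).items():
            if lo <= key.imgt_position <= hi:
                return cdr
        return "framework"

    @classmethod
    def from_dict(cls, cfg: Mapping) -> "RegionScheme":
        """Build a scheme from a keyed config naming the six intervals."""
        kw = {}
        for fld in ("h_cdr1", "h_cdr2", "h_cdr3", "l_cdr1", "l_cdr2", "l_cdr3"):
            if fld in cfg:
                lo, hi = cfg[fld]
                kw[fld] = (int(lo), int(hi))
        if "name" in cfg:
            kw["name"] = str(cfg["name"])
        if "max_position" in cfg:
            kw["max_position"] = int(cfg["max_position"])
        return cls(**kw)


@dataclass
class RegionExtract:
    """CDR/framework split of one model under one scheme."""

    framework_keys: list[ResidueKey]
    framework_points: np.ndarray          # (n_fw, 3), file order
    cdr_points: dict[str, np.ndarray]     # CDR name -> (len, 3), file order
    cdr_lengths: tuple[int, ...]          # lengths in CDR_NAMES order of the requested subset


def _normalise_icode(icode: str) -> str:
    return "" if icode in ("", " ", "\x00") else icode


def read_fv_model(path: str | Path, heavy_only: bool = False) -> FvModel:
    """Read a Calpha-only Fv model from a PDB file.

    Residue keys are taken from (chain id, residue sequence number,
    insertion code).  Chains other than H/L are rejected.  Residues without
    a Calpha atom are skipped with a warning; a missing H chain is an error.
    With ``heavy_only`` the L chain is not required.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError(f"{path}: no models in file")
    residues: list[tuple[ResidueKey, np.ndarray]] = []
    seen: set[ResidueKey] = set()
    n_skipped = 0
    for chain in st[0]:
        cname = chain.name.strip()
        if cname not in ("H", "L"):
            raise ValueError(f"{path}: unexpected chain {cname!r}; only H and L are accepted")
        for res in chain:
            cas = [atom for atom in res if atom.name == "CA"]
            if not cas:
                n_skipped += 1
                continue
            ca = cas[0]
            if len(cas) > 1:
                # genuine altlocs carry indicator characters; repeated plain
                # CA records are a duplicated residue, not an altloc
                if all(_normalise_icode(a.altloc) == "" for a in cas):
                    raise ValueError(
                        f"{path}: duplicate residue "
                        f"{ResidueKey(cname, res.seqid.num, _normalise_icode(res.seqid.icode))}"
                    )
                warnings.warn(
                    f"{path}: alternate Calpha locations at {cname}{res.seqid.num}; keeping the first"
                )
            key = ResidueKey(cname, res.seqid.num, _normalise_icode(res.seqid.icode))
            if key in seen:
                raise ValueError(f"{path}: duplicate residue {key}")
            seen.add(key)
            residues.append((key, np.array([ca.pos.x, ca.pos.y, ca.pos.z])))
    if n_skipped:
        warnings.warn(f"{path}: {n_skipped} residue(s) without a Calpha atom skipped")
    if not residues:
        raise ValueError(f"{path}: no Calpha atoms found")
    chains = {k.chain for k, _ in residues}
    if "H" not in chains:
        raise ValueError(f"{path}: no H chain present")
    if not heavy_only and "L" not in chains:
        raise ValueError(f"{path}: no L chain present (use heavy_only for single-chain models)")
    return FvModel(path.stem, residues, str(path))


def write_fv_model(model: FvModel, path: str | Path) -> None:
    """Write a Calpha-only model as standard PDB ATOM records.

    Coordinates are emitted at PDB precision (3 decimals); residue names
    are a uniform GLY placeholder since sequence truth lives in metadata.
    """
    st = gemmi.Structure()
    st.name = model.antibody_id
    gm = gemmi.Model("1")
    by_chain: dict[str, list[tuple[ResidueKey, np.ndarray]]] = {}
    for key, xyz in model.residues:
        by_chain.setdefault(key.chain, []).append((key, xyz))
    for cname in ("H", "L"):
        if cname not in by_chain:
            continue
        chain = gemmi.Chain(cname)
        for key, xyz in by_chain[cname]:
            res = gemmi.Residue()
            res.name = "GLY"
            res.seqid = gemmi.SeqId(key.imgt_position, key.insertion_code or " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.pos = gemmi.Position(float(xyz[0]), float(xyz[1]), float(xyz[2]))
            atom.element = gemmi.Element("C")
            atom.occ = 1.0
            atom.b_iso = 0.0
            res.add_atom(atom)
            chain.add_residue(res)
        gm.add_chain(chain)
    st.add_model(gm)
    st.write_pdb(str(path))


def read_models_dir(directory: str | Path, heavy_only: bool = False) -> list[FvModel]:
    """Read every ``*.pdb`` file in a directory, sorted by filename."""
    directory = Path(directory)
    paths = sorted(directory.glob("*.pdb"))
    if not paths:
        raise FileNotFoundError(f"no .pdb files in {directory}")
    return [read_fv_model(p, heavy_only=heavy_only) for p in paths]


def extract_regions(
    model: FvModel,
    scheme: RegionScheme,
    cdr_subset: Sequence[str] = CDR_NAMES,
    framework_chains: Iterable[str] = ("H", "L"),
) -> RegionExtract:
    """Split a model into framework and CDR point sets.

    Every residue is assigned to exactly one region by interval membership;
    ordering within a region follows file order.  ``cdr_subset`` selects
    which CDRs are extracted and length-reported (all six by default);
    ``framework_chains`` restricts the framework set (heavy-chain-only
    alignment passes ``("H",)``).

    Raises if any requested CDR is empty — that indicates a malformed model.
    """
    if len(model) == 0:
        raise ValueError("empty model")
    framework_chains = set(framework_chains)
    fw_keys: list[ResidueKey] = []
    fw_pts: list[np.ndarray] = []
    cdr_pts: dict[str, list[np.ndarray]] = {c: [] for c in cdr_subset}
    for key, xyz in model.residues:
        region = scheme.region_of(key)
        if region == "framework":
            if key.chain in framework_chains and key.imgt_position <= scheme.max_position:
                fw_keys.append(key)
                fw_pts.append(xyz)
        elif region in cdr_pts:
            cdr_pts[region].append(xyz)
    for cdr in cdr_subset:
        if not cdr_pts[cdr]:
            raise ValueError(f"{model.antibody_id}: no residues in {cdr}")
    return RegionExtract(
        framework_keys=fw_keys,
        framework_points=np.array(fw_pts) if fw_pts else np.zeros((0, 3)),
        cdr_points={c: np.array(v) for c, v in cdr_pts.items()},
        cdr_lengths=tuple(len(cdr_pts[c]) for c in cdr_subset),
    )


@dataclass(frozen=True)
class EpitopeLabel:
    """Epitope annotation at whatever resolution the source data offers."""

    antigen: str = UNKNOWN
    domain: str = UNKNOWN

    @property
    def resolution(self) -> str:
        if self.antigen == UNKNOWN:
            return UNKNOWN
        return "domain-level" if self.domain != UNKNOWN else "antigen-level"


@dataclass
class AntibodyRecord:
    """One antibody's sequence-level metadata row."""

    antibody_id: str
    heavy_v_gene: str = UNKNOWN
    heavy_j_gene: str = UNKNOWN
    light_v_gene: str = UNKNOWN
    light_j_gene: str = UNKNOWN
    cdrh3_seq: str = ""
    cdrl3_seq: str = ""
    species: str = UNKNOWN
    epitope_label: EpitopeLabel = field(default_factory=EpitopeLabel)


def _cell(value) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return UNKNOWN
    s = str(value).strip()
    return s if s else UNKNOWN


def read_metadata(path: str | Path) -> list[AntibodyRecord]:
    """Read the antibody metadata table (CSV with documented columns).

    Empty gene/epitope cells are preserved as ``"unknown"``.  Duplicate ids
    and missing required columns are errors.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if df["id"].duplicated().any():
        dupes = sorted(df.loc[df["id"].duplicated(), "id"])
        raise ValueError(f"{path}: duplicate antibody id(s) {dupes}")
    records = []
    for _, row in df.iterrows():
        cdrh3 = _cell(row["cdrh3"])
        cdrl3 = _cell(row["cdrl3"])
        records.append(
            AntibodyRecord(
                antibody_id=str(row["id"]).strip(),
                heavy_v_gene=_cell(row["heavy_v_gene"]),
                heavy_j_gene=_cell(row["heavy_j_gene"]),
                light_v_gene=_cell(row["light_v_gene"]),
                light_j_gene=_cell(row["light_j_gene"]),
                cdrh3_seq="" if cdrh3 == UNKNOWN else cdrh3,
                cdrl3_seq="" if cdrl3 == UNKNOWN else cdrl3,
                species=_cell(row["species"]),
                epitope_label=EpitopeLabel(_cell(row["antigen"]), _cell(row["domain"])),
            )
        )
    return records


def write_metadata(records: Sequence[AntibodyRecord], path: str | Path) -> None:
    rows = [
        {
            "id": r.antibody_id,
            "heavy_v_gene": r.heavy_v_gene,
            "heavy_j_gene": r.heavy_j_gene,
            "light_v_gene": r.light_v_gene,
            "light_j_gene": r.light_j_gene,
            "cdrh3": r.cdrh3_seq,
            "cdrl3": r.cdrl3_seq,
            "species": r.species,
            "antigen": r.epitope_label.antigen,
            "domain": r.epitope_label.domain,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_METADATA_COLUMNS).to_csv(path, index=False)


_SHORT_CDR = {"H1": "CDRH1", "H2": "CDRH2", "H3": "CDRH3",
              "L1": "CDRL1", "L2": "CDRL2", "L3": "CDRL3"}


def read_paratope_flags(path: str | Path) -> dict[str, tuple[str, ...]]:
    """Read per-antibody paratope-CDR flags.

    CSV with columns ``id,paratope_cdrs`` where the flags cell is a
    semicolon-separated list of CDR names (``H1;H3;L3`` or full names).
    Returns id -> ordered tuple of canonical CDR names.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("id", "paratope_cdrs"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    out: dict[str, tuple[str, ...]] = {}
    for _, row in df.iterrows():
        names = []
        for tok in str(row["paratope_cdrs"]).replace(",", ";").split(";"):
            tok = tok.strip()
            if not tok:
                continue
            full = _SHORT_CDR.get(tok.upper(), tok.upper())
            if full not in CDR_NAMES:
                raise ValueError(f"{path}: unknown CDR name {tok!r}")
            names.append(full)
        ordered = tuple(c for c in CDR_NAMES if c in names)
        if not ordered:
            raise ValueError(f"{path}: antibody {row['id']} has no paratope CDRs")
        out[str(row["id"]).strip()] = ordered
    return out
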