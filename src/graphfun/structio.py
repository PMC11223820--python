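"""Reading and writing the standard formats the pipeline touches.

FASTA sequences, PDB/mmCIF structures, per-residue score tables, and
score-annotated structures.  Structures are reduced to a single chain of
residues with complete N/CA/C backbones; everything downstream (graphs,
frames, features) operates on :class:`ProteinRecord`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
import biotite.structure as bst
from biotite.structure.io import pdb as bpdb
from biotite.structure.io import pdbx as bpdbx

logger = logging.getLogger(__name__)

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Documented output order for the ten ligand-binding tasks.
LIGAND_ORDER = ("DNA", "RNA", "peptide", "protein", "ATP", "HEM", "ZN", "CA", "MG", "MN")

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLU": "E", "GLN": "Q", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # selenomethionine is treated as methionine
    "MSE": "M",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items() if k != "MSE"}
_ONE_TO_THREE["X"] = "UNK"

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class AtomRecord:
    """A single heavy atom: name, element symbol and coordinates in Angstrom."""

    name: str
    element: str
    coords: np.ndarray

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("atom name must be non-empty")
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")


@dataclass
class ResidueStructure:
    """One residue: complete N/CA/C backbone, optional O, heavy sidechain atoms."""

    index: int
    aa: str
    backbone: dict
    sidechain: list = field(default_factory=list)
    plddt: float | None = None

    def __post_init__(self) -> None:
        for name in ("N", "CA", "C"):
            if name not in self.backbone:
                raise ValueError(f"residue {self.index}: backbone atom {name} missing")
        if self.plddt is not None and not (0.0 <= self.plddt <= 100.0):
            raise ValueError(f"residue {self.index}: pLDDT {self.plddt} outside [0, 100]")

    @property
    def ca(self) -> np.ndarray:
        return self.backbone["CA"].coords


@dataclass
class ProteinRecord:
    """A parsed single-chain protein structure plus its sequence."""

    id: str
    sequence: str
    residues: list
    source: str = "native"

    def __post_init__(self) -> None:
        if self.source not in ("native", "predicted"):
            raise ValueError(f"source must be 'native' or 'predicted', got {self.source!r}")
        if len(self.sequence) != len(self.residues):
            raise ValueError(
                f"{self.id}: sequence length {len(self.sequence)} != "
                f"residue count {len(self.residues)}"
            )
        for aa, res in zip(self.sequence, self.residues):
            if aa != res.aa:
                raise ValueError(f"{self.id}: sequence/residue mismatch at index {res.index}")

    def __len__(self) -> int:
        return len(self.residues)

    def ca_coords(self) -> np.ndarray:
        """(L, 3) array of C-alpha coordinates."""
        return np.array([r.ca for r in self.residues])


@dataclass
class PredictionResult:
    """Scores in [0, 1]: per-residue per ligand task and/or per-protein labels."""

    protein_id: str
    residue_scores: dict = field(default_factory=dict)  # task -> (L,) array
    protein_scores: dict = field(default_factory=dict)  # label -> float


def read_fasta(path) -> list:
    """Read a FASTA file into an ordered list of ``(id, sequence)`` tuples.

    Sequences are uppercased and non-standard residue letters mapped to ``X``.
    Raises on an empty file and on duplicate record ids.
    """
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id: {rec.id}")
        seen.add(rec.id)
        seq = "".join(c if c in STANDARD_AA else "X" for c in str(rec.seq).upper())
        records.append((rec.id, seq))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records, path) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")


def _load_atom_array(path):
    path = Path(path)
    if path.suffix.lower() in (".cif", ".mmcif"):
        cif = bpdbx.CIFFile.read(str(path))
        return bpdbx.get_structure(
            cif, model=1, altloc="occupancy", extra_fields=["b_factor"]
        )
    pdbf = bpdb.PDBFile.read(str(path))
    return bpdb.get_structure(
        pdbf, model=1, altloc="occupancy", extra_fields=["b_factor"]
    )


def read_structure(path, chain: str | None = None, source: str = "native") -> ProteinRecord:
    """Parse a PDB or mmCIF file into a :class:`ProteinRecord`.

    Only the first model is read; altloc conflicts are resolved by highest
    occupancy.  Residues missing any of N/CA/C are dropped with a warning.
    When ``source="predicted"`` the CA B-factor is stored as per-residue pLDDT.

    Parameters
    ----------
    chain:
        Chain id to extract; defaults to the first chain in file order.
    """
    arr = _load_atom_array(path)
    arr = arr[bst.filter_amino_acids(arr)]
    arr = arr[~np.isin(arr.element, ("H", "D"))]
    if arr.array_length() == 0:
        raise ValueError(f"{path}: no amino-acid atoms found")

    chains = list(dict.fromkeys(arr.chain_id))
    if chain is None:
        chain = chains[0]
    elif chain not in chains:
        raise ValueError(f"{path}: chain {chain!r} not found (available: {chains})")
    arr = arr[arr.chain_id == chain]

    residues = []
    sequence = []
    n_dropped = 0
    for res in bst.residue_iter(arr):
        names = list(res.atom_name)
        if any(a not in names for a in ("N", "CA", "C")):
            n_dropped += 1
            continue
        backbone = {}
        sidechain = []
        plddt = None
        for i in range(res.array_length()):
            atom = AtomRecord(res.atom_name[i], res.element[i], res.coord[i])
            if atom.name in BACKBONE_ATOMS and atom.name not in backbone:
                backbone[atom.name] = atom
            elif atom.name not in BACKBONE_ATOMS:
                sidechain.append(atom)
            if atom.name == "CA" and source == "predicted":
                plddt = float(np.clip(res.b_factor[i], 0.0, 100.0))
        aa = _THREE_TO_ONE.get(res.res_name[0], "X")
        residues.append(
            ResidueStructure(
                index=len(residues), aa=aa, backbone=backbone,
                sidechain=sidechain, plddt=plddt,
            )
        )
        sequence.append(aa)
    if n_dropped:
        logger.warning("%s: dropped %d residue(s) with incomplete backbone", path, n_dropped)
    if not residues:
        raise ValueError(f"{path}: no residues with complete N/CA/C backbone")
    return ProteinRecord(
        id=Path(path).stem, sequence="".join(sequence), residues=residues, source=source
    )


def _record_to_atom_array(record: ProteinRecord, bfactors=None) -> bst.AtomArray:
    atoms = []
    for res in record.residues:
        ordered = [res.backbone[a] for a in BACKBONE_ATOMS if a in res.backbone]
        ordered += list(res.sidechain)
        for atom in ordered:
            atoms.append((res.index, res.aa, atom))
    arr = bst.AtomArray(len(atoms))
    arr.coord = np.array([a.coords for _, _, a in atoms])
    arr.chain_id = np.array(["A"] * len(atoms))
    arr.res_id = np.array([ri + 1 for ri, _, _ in atoms])
    arr.res_name = np.array([_ONE_TO_THREE.get(aa, "UNK") for _, aa, _ in atoms])
    arr.atom_name = np.array([a.name for _, _, a in atoms])
    arr.element = np.array([a.element for _, _, a in atoms])
    arr.hetero = np.zeros(len(atoms), dtype=bool)
    if bfactors is not None:
        arr.set_annotation(
            "b_factor", np.array([bfactors[ri] for ri, _, _ in atoms], dtype=float)
        )
    else:
        arr.set_annotation("b_factor", np.zeros(len(atoms)))
    return arr


def write_pdb(record: ProteinRecord, path, bfactors=None) -> None:
    """Write a ProteinRecord as a single-chain PDB file (internal 0-based indices
    become 1-based residue ids)."""
    arr = _record_to_atom_array(record, bfactors)
    pdbf = bpdb.PDBFile()
    pdbf.set_structure(arr)
    pdbf.write(str(path))


def write_scored_structure(record: ProteinRecord, scores, path) -> None:
    """Write a PDB with per-residue scores (in [0,1]) times 100 in the B-factor
    column of every atom of the residue."""
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (len(record),):
        raise ValueError(
            f"score length {scores.shape} does not match residue count {len(record)}"
        )
    if scores.min() < 0.0 or scores.max() > 1.0:
        raise ValueError("scores must lie in [0, 1]")
    write_pdb(record, path, bfactors=scores * 100.0)


def _ordered_tasks(tasks) -> list:
    known = [t for t in LIGAND_ORDER if t in tasks]
    extra = sorted(t for t in tasks if t not in LIGAND_ORDER)
    return known + extra


def write_residue_scores(pred: PredictionResult, path) -> None:
    """Write per-residue scores as a TSV table (or JSON if the path ends in
    ``.json``), one row per residue, one column per task in the documented
    ligand order."""
    if not pred.residue_scores:
        raise ValueError("prediction contains no residue scores")
    tasks = _ordered_tasks(pred.residue_scores)
    lengths = {len(pred.residue_scores[t]) for t in tasks}
    if len(lengths) != 1:
        raise ValueError("residue score vectors have inconsistent lengths")
    for t in tasks:
        s = np.asarray(pred.residue_scores[t], dtype=float)
        if s.size == 0:
            raise ValueError("empty prediction")
        if s.min() < 0.0 or s.max() > 1.0:
            raise ValueError(f"task {t}: scores outside [0, 1]")
    n = lengths.pop()
    df = pd.DataFrame({"residue": np.arange(1, n + 1)})
    for t in tasks:
        df[t] = np.asarray(pred.residue_scores[t], dtype=float)
    path = Path(path)
    if path.suffix == ".json":
        payload = {
            "protein_id": pred.protein_id,
            "tasks": tasks,
            "scores": {t: list(map(float, pred.residue_scores[t])) for t in tasks},
        }
        path.write_text(json.dumps(payload, indent=1))
    else:
        df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_residue_scores(path) -> dict:
    """Read back a score table written by :func:`write_residue_scores`;
    returns ``{task: (L,) array}``."""
    path = Path(path)
    if path.suffix == ".json":
        payload = json.loads(path.read_text())
        return {t: np.array(v, dtype=float) for t, v in payload["scores"].items()}
    df = pd.read_csv(path, sep="\t")
    return {c: df[c].to_numpy(dtype=float) for c in df.columns if c != "residue"}


def write_protein_scores(preds, path) -> None:
    """Write per-protein label scores for a batch of predictions as TSV."""
    rows = []
    for p in preds:
        row = {"protein_id": p.protein_id}
        row.update({k: float(v) for k, v in p.protein_scores.items()})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6f")
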