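"""Non-geometric node features and graph assembly.

Language-model embeddings enter through a provider interface: any per-residue
matrix keyed by protein id qualifies, and a deterministic stub provider is
bundled so the pipeline runs without a language model.  Embeddings are
min-max normalised per protein and per dimension.  Structural properties
(relative solvent accessibility and an 8-state secondary-structure one-hot)
come from a DSSP output file when one is supplied, otherwise from internal
fallbacks: Shrake-Rupley accessible surface area and a torsion-bin heuristic.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
import biotite.structure as bst

from .graph import ProteinGraph
from .geometry import (
    RBFConfig,
    backbone_angles,
    edge_geometric_features,
    node_geometric_features,
    residue_frames,
)
from .structio import ProteinRecord, _record_to_atom_array

# 8-state secondary-structure vocabulary (DSSP letters, '-' = coil) plus
# a trailing "unknown" state.
SS_STATES = ("H", "B", "E", "G", "I", "T", "S", "-")
SS_DIM = len(SS_STATES) + 1

#: Theoretical maximum accessible surface areas (A^2), Tien et al. 2013.
MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}
GENERIC_MAX_ASA = 200.0


@dataclass
class EmbeddingMatrix:
    """Per-residue embedding components (L x D), tagged with their provider."""

    values: np.ndarray
    provider: str = "unknown"

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))


@dataclass
class StructuralProfile:
    """RSA in [0,1] and an (L, 9) secondary-structure one-hot (8 states +
    unknown)."""

    rsa: np.ndarray
    ss: np.ndarray

    def __post_init__(self) -> None:
        self.rsa = np.asarray(self.rsa, dtype=float)
        self.ss = np.asarray(self.ss, dtype=float)
        if self.rsa.min() < 0 or self.rsa.max() > 1:
            raise ValueError("rsa outside [0, 1]")
        if self.ss.shape[1] != SS_DIM or not np.allclose(self.ss.sum(axis=1), 1.0):
            raise ValueError("ss rows must be one-hot over the 9-state vocabulary")


def minmax_normalize(emb: EmbeddingMatrix) -> EmbeddingMatrix:
    """Per-dimension min-max normalisation over the protein's residues;
    zero-range dimensions map to 0."""
    x = emb.values
    if not np.all(np.isfinite(x)):
        raise ValueError("embedding contains non-finite values")
    lo = x.min(axis=0)
    rng = x.max(axis=0) - lo
    out = np.where(rng > 0, (x - lo) / np.where(rng > 0, rng, 1.0), 0.0)
    return EmbeddingMatrix(values=out, provider=emb.provider)


class StubEmbeddingProvider:
    """Deterministic pseudo-random per-residue embeddings.

    Each row is seeded from a hash of (protein id, residue position), so the
    same id always yields the same matrix and different ids differ.
    """

    def __init__(self, dim: int = 32):
        self.dim = dim

    def embed(self, protein_id: str, length: int) -> EmbeddingMatrix:
        rows = np.empty((length, self.dim))
        for pos in range(length):
            digest = hashlib.sha256(f"{protein_id}|{pos}".encode()).digest()
            seed = int.from_bytes(digest[:4], "little")
            rows[pos] = np.random.default_rng(seed).standard_normal(self.dim)
        return EmbeddingMatrix(values=rows, provider="stub")


def save_embeddings(embeddings: dict, path) -> None:
    """Write {protein_id: EmbeddingMatrix} to a TSV keyed by id and position."""
    frames = []
    for pid, emb in embeddings.items():
        df = pd.DataFrame(emb.values, columns=[f"e{k}" for k in range(emb.values.shape[1])])
        df.insert(0, "pos", np.arange(len(df)))
        df.insert(0, "id", pid)
        frames.append(df)
    pd.concat(frames).to_csv(path, sep="\t", index=False, float_format="%.8g")


def load_embeddings(path, protein_id: str, length: int) -> EmbeddingMatrix:
    """Load one protein's embedding rows from an id-keyed TSV table."""
    df = pd.read_csv(path, sep="\t")
    sub = df[df["id"] == protein_id].sort_values("pos")
    if len(sub) == 0:
        raise ValueError(f"no embedding rows for id {protein_id!r} in {path}")
    if len(sub) != length:
        raise ValueError(
            f"embedding length {len(sub)} != sequence length {length} for id {protein_id!r}"
        )
    cols = [c for c in df.columns if c.startswith("e")]
    return EmbeddingMatrix(values=sub[cols].to_numpy(dtype=float), provider="file")


def compute_rsa(
    record: ProteinRecord,
    probe: float = 1.4,
    n_points: int = 960,
    dssp_path=None,
) -> np.ndarray:
    """Per-residue relative solvent accessibility in [0, 1].

    Shrake-Rupley accessible surface area per residue divided by the
    residue's theoretical maximum (Tien et al. 2013 scale); parses the DSSP
    ACC column instead when a DSSP file is given.
    """
    if dssp_path is not None:
        acc, _ = parse_dssp(dssp_path)
        return _acc_to_rsa(record, acc)
    if len(record) == 0:
        raise ValueError("empty record")
    arr = _record_to_atom_array(record)
    asa = bst.sasa(arr, probe_radius=probe, point_number=n_points, vdw_radii="Single")
    asa = np.nan_to_num(asa)
    per_res = np.zeros(len(record))
    for k in range(len(record)):
        per_res[k] = asa[arr.res_id == k + 1].sum()
    return _acc_to_rsa(record, per_res)


def _acc_to_rsa(record: ProteinRecord, acc: np.ndarray) -> np.ndarray:
    import warnings

    acc = np.asarray(acc, dtype=float)
    if len(acc) != len(record):
        raise ValueError("ACC length does not match residue count")
    maxasa = np.empty(len(record))
    for k, aa in enumerate(record.sequence):
        if aa not in MAX_ASA:
            warnings.warn(f"unknown residue type {aa!r}: using generic max ASA")
            maxasa[k] = GENERIC_MAX_ASA
        else:
            maxasa[k] = MAX_ASA[aa]
    return np.clip(acc / maxasa, 0.0, 1.0)


def parse_dssp(path):
    """Parse a classic DSSP output table; returns (ACC array, ss letter list).

    Only the per-residue block after the '#  RESIDUE' header is read; chain
    breaks ('!') are skipped.
    """
    acc, ss = [], []
    in_table = False
    with open(path) as fh:
        for line in fh:
            if line.lstrip().startswith("#  RESIDUE"):
                in_table = True
                continue
            if not in_table or len(line) < 39:
                continue
            if line[13] == "!":
                continue
            state = line[16]
            ss.append(state if state in SS_STATES else "-")
            try:
                acc.append(float(line[34:38]))
            except ValueError as exc:
                raise ValueError(f"malformed DSSP ACC field: {line!r}") from exc
    if not acc:
        raise ValueError(f"no residue rows parsed from DSSP file {path}")
    return np.array(acc), ss


def _ss_onehot(letters) -> np.ndarray:
    out = np.zeros((len(letters), SS_DIM))
    for k, s in enumerate(letters):
        idx = SS_STATES.index(s) if s in SS_STATES else SS_DIM - 1
        out[k, idx] = 1.0
    return out


def assign_secondary_structure(record: ProteinRecord = None, dssp_path=None) -> np.ndarray:
    """(L, 9) secondary-structure one-hot.

    Parses the DSSP file when given (faithful path); otherwise applies a
    3-state torsion-bin heuristic (helix / strand / coil mapped into the
    8-state vocabulary).  Residues with undefined phi or psi (chain termini)
    get the "unknown" state.
    """
    if dssp_path is not None:
        _, ss = parse_dssp(dssp_path)
        return _ss_onehot(ss)
    if record is None:
        raise ValueError("need a record or a DSSP file")
    angles, flags = backbone_angles(record)
    letters = []
    for k in range(len(record)):
        if flags["phi"][k] == 0 or flags["psi"][k] == 0:
            letters.append("?")  # unknown
            continue
        phi, psi = angles["phi"][k], angles["psi"][k]
        if -100.0 < phi < -30.0 and -80.0 < psi < -5.0:
            letters.append("H")
        elif -180.0 <= phi < -60.0 and (psi > 90.0 or psi < -150.0):
            letters.append("E")
        else:
            letters.append("-")
    return _ss_onehot(letters)


def structural_profile(record: ProteinRecord, dssp_path=None, probe=1.4, n_points=960):
    rsa = compute_rsa(record, probe=probe, n_points=n_points, dssp_path=dssp_path)
    ss = assign_secondary_structure(record, dssp_path=dssp_path)
    return StructuralProfile(rsa=rsa, ss=ss)


def assemble_graph(
    record: ProteinRecord,
    topology: ProteinGraph,
    emb: EmbeddingMatrix,
    profile: StructuralProfile,
    node_geo: np.ndarray,
    edge_geo: np.ndarray,
) -> ProteinGraph:
    """Concatenate all per-residue blocks into node features and attach edge
    features; block boundaries are recorded in ``graph.meta``.

    Node feature order: normalised embedding | RSA | SS one-hot | geometric.
    """
    L = len(record)
    for name, block in (
        ("embedding", emb.values), ("rsa", profile.rsa), ("ss", profile.ss),
        ("node_geo", node_geo),
    ):
        if len(block) != L:
            raise ValueError(f"{name} rows ({len(block)}) != residue count ({L})")
    if len(edge_geo) != topology.n_edges:
        raise ValueError("edge feature rows != edge count")
    norm = minmax_normalize(emb)
    blocks = [norm.values, profile.rsa[:, None], profile.ss, node_geo]
    node_features = np.concatenate(blocks, axis=1)
    dims = [b.shape[1] for b in blocks]
    bounds = np.cumsum([0] + dims)
    meta = {
        "node_dim": int(node_features.shape[1]),
        "edge_dim": int(edge_geo.shape[1]),
        "blocks": {
            name: (int(bounds[k]), int(bounds[k + 1]))
            for k, name in enumerate(("embedding", "rsa", "ss", "node_geo"))
        },
        "protein_id": record.id,
        "source": record.source,
    }
    return ProteinGraph(
        n_nodes=topology.n_nodes,
        edges=topology.edges,
        ca_coords=topology.ca_coords,
        node_features=node_features,
        edge_features=np.asarray(edge_geo, dtype=float),
        meta=meta,
    )


def featurize(
    record: ProteinRecord,
    emb: EmbeddingMatrix | None = None,
    cutoff: float = 15.0,
    rbf: RBFConfig = RBFConfig(),
    dssp_path=None,
    embed_dim: int = 32,
    sasa_points: int = 960,
) -> ProteinGraph:
    """Full featurization pipeline: radius graph + geometric node/edge features
    + embeddings + structural profile, assembled into one ProteinGraph."""
    from .graph import build_radius_graph

    topology = build_radius_graph(record, cutoff=cutoff)
    frames = residue_frames(record)
    node_geo = node_geometric_features(record, frames=frames, rbf=rbf)
    edge_geo = edge_geometric_features(record, topology.edges, frames=frames, rbf=rbf)
    if emb is None:
        emb = StubEmbeddingProvider(dim=embed_dim).embed(record.id, len(record))
    profile = structural_profile(record, dssp_path=dssp_path, n_points=sasa_points)
    return assemble_graph(record, topology, emb, profile, node_geo, edge_geo)
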