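"""Synthetic proteins, binding labels and embeddings for offline testing.

Backbones are grown residue-by-residue (NERF chain extension) from canonical
bond lengths and angles with (phi, psi) sampled from the alpha-helical or
extended basin, so ideal helices (1.5 A rise, ~100 degrees per residue,
consecutive CA-CA spacing 3.8 A) and strands emerge from torsion choice
alone.  A pseudo-sidechain atom sits 1.5 A along the CA outward normal
(glycine gets none, exercising the centroid fallback).

Binding labels follow a known geometric rule: "ghost ligand" points are
placed 3 A outward of anchor residues and every residue whose CA lies within
``ligand_radius`` of a ghost point is positive.  By default anchors are the
most buried residues (highest CA contact count) so the labels are a
deterministic function of the geometry; ``anchor_mode="random"`` draws
anchors uniformly instead (labels then carry an irreducible random
component).

The generator is a client of the real featurization pipeline, not a mock:
:func:`generate_dataset` returns fully featurized examples, with a paired
"predicted-structure" variant per protein (extra coordinate jitter, shared
labels and group id) to exercise the augmentation path.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .features import StubEmbeddingProvider, featurize, save_embeddings
from .geometry import RBFConfig
from .structio import (
    AtomRecord,
    ProteinRecord,
    ResidueStructure,
    STANDARD_AA,
    write_fasta,
    write_pdb,
)
from .training import LabeledExample

# canonical backbone internal coordinates (A, degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.229
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 116.6, 121.7
_BASINS = {"H": (-57.0, -47.0), "E": (-120.0, 130.0)}


@dataclass
class SyntheticConfig:
    n_proteins: int = 200
    length_range: tuple = (40, 80)
    helix_fraction: float = 0.5
    coord_noise_sd: float = 0.1
    ligand_radius: float = 8.0
    positives_per_protein: int = 2
    embed_dim: int = 32
    seed: int = 0
    anchor_mode: str = "pocket"  # "pocket" (most buried) or "random"
    ghost_offset: float = 3.0
    contact_radius: float = 10.0
    torsion_noise_sd: float = 8.0
    predicted_noise_sd: float = 1.0
    cutoff: float = 15.0
    sasa_points: int = 240

    def __post_init__(self):
        if self.length_range[0] < 5:
            raise ValueError("minimum length must be >= 5")
        if self.coord_noise_sd < 0:
            raise ValueError("coordinate noise must be >= 0")
        if self.ligand_radius <= 0:
            raise ValueError("ligand radius must be positive")
        if self.anchor_mode not in ("pocket", "random"):
            raise ValueError(f"unknown anchor mode {self.anchor_mode!r}")


def _place(a, b, c, bond, angle_deg, torsion_deg):
    """Natural-extension-of-reference-frame atom placement: position the next
    atom at distance ``bond`` from c, angle at c, torsion about b-c."""
    ang = np.deg2rad(angle_deg)
    tor = np.deg2rad(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = bond * np.array(
        [-np.cos(ang), np.cos(tor) * np.sin(ang), np.sin(tor) * np.sin(ang)]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def _segment_plan(length, helix_fraction, rng):
    kinds = []
    while len(kinds) < length:
        seg = int(rng.integers(6, 15))
        kinds += ["H" if rng.random() < helix_fraction else "E"] * seg
    return kinds[:length]


def generate_backbone(length: int, config: SyntheticConfig, rng) -> ProteinRecord:
    """One synthetic ProteinRecord with full N/CA/C/O backbone and a CB
    pseudo-sidechain atom (random sequence; glycine gets no sidechain)."""
    if length < 5:
        raise ValueError("length must be >= 5")
    kinds = _segment_plan(length, config.helix_fraction, rng)
    seq = "".join(rng.choice(list(STANDARD_AA), size=length))
    N = [np.zeros(3)]
    CA = [np.array([_B_N_CA, 0.0, 0.0])]
    C = [
        _place(
            np.array([0.0, 1.0, 0.0]), N[0], CA[0], _B_CA_C, _A_N_CA_C,
            float(rng.uniform(-180, 180)),
        )
    ]
    for i in range(1, length):
        psi = _BASINS[kinds[i - 1]][1] + rng.normal(0.0, config.torsion_noise_sd)
        phi = _BASINS[kinds[i]][0] + rng.normal(0.0, config.torsion_noise_sd)
        n = _place(N[-1], CA[-1], C[-1], _B_C_N, _A_CA_C_N, psi)
        ca = _place(CA[-1], C[-1], n, _B_N_CA, _A_C_N_CA, 180.0)
        c = _place(C[-1], n, ca, _B_CA_C, _A_N_CA_C, phi)
        N.append(n)
        CA.append(ca)
        C.append(c)
    N, CA, C = np.array(N), np.array(CA), np.array(C)

    # carbonyl O in the sp2 plane, opposite the bisector of CA and next N
    O = np.empty_like(C)
    for i in range(length):
        u1 = CA[i] - C[i]
        u1 /= np.linalg.norm(u1)
        nxt = N[i + 1] if i + 1 < length else N[i]
        u2 = nxt - C[i]
        u2 /= np.linalg.norm(u2)
        d = -(u1 + u2)
        O[i] = C[i] + _B_C_O * d / np.linalg.norm(d)

    # pseudo-sidechain 1.5 A along the CA outward normal
    SC = np.empty_like(CA)
    for i in range(length):
        d = -(
            (N[i] - CA[i]) / np.linalg.norm(N[i] - CA[i])
            + (C[i] - CA[i]) / np.linalg.norm(C[i] - CA[i])
        )
        SC[i] = CA[i] + 1.5 * d / np.linalg.norm(d)

    if config.coord_noise_sd > 0:
        for arr in (N, CA, C, O, SC):
            arr += rng.normal(0.0, config.coord_noise_sd, arr.shape)

    residues = []
    for i, aa in enumerate(seq):
        backbone = {
            "N": AtomRecord("N", "N", N[i]),
            "CA": AtomRecord("CA", "C", CA[i]),
            "C": AtomRecord("C", "C", C[i]),
            "O": AtomRecord("O", "O", O[i]),
        }
        sidechain = [] if aa == "G" else [AtomRecord("CB", "C", SC[i])]
        residues.append(
            ResidueStructure(index=i, aa=aa, backbone=backbone, sidechain=sidechain)
        )
    return ProteinRecord(id="synth", sequence=seq, residues=residues, source="native")


def generate_ghost_ligand_labels(record: ProteinRecord, config: SyntheticConfig, rng):
    """Per-residue {0,1} labels from the ghost-ligand rule; also returns the
    ghost points for inspection."""
    if len(record) == 0:
        raise ValueError("empty record")
    ca = record.ca_coords()
    k = min(config.positives_per_protein, len(ca))
    if config.anchor_mode == "random":
        anchors = rng.choice(len(ca), size=k, replace=False)
    else:
        contacts = (cdist(ca, ca) < config.contact_radius).sum(axis=1)
        anchors = np.argsort(-contacts, kind="stable")[:k]
    center = ca.mean(axis=0)
    dirs = ca[anchors] - center
    norms = np.linalg.norm(dirs, axis=1, keepdims=True)
    dirs = np.where(norms > 1e-9, dirs / np.where(norms > 1e-9, norms, 1.0), 0.0)
    ghosts = ca[anchors] + config.ghost_offset * dirs
    labels = (cdist(ca, ghosts).min(axis=1) < config.ligand_radius).astype(int)
    return labels, ghosts


def _jitter(record: ProteinRecord, sd: float, rng) -> ProteinRecord:
    residues = []
    for res in record.residues:
        backbone = {
            k: AtomRecord(a.name, a.element, a.coords + rng.normal(0, sd, 3))
            for k, a in res.backbone.items()
        }
        sidechain = [
            AtomRecord(a.name, a.element, a.coords + rng.normal(0, sd, 3))
            for a in res.sidechain
        ]
        residues.append(
            ResidueStructure(res.index, res.aa, backbone, sidechain, res.plddt)
        )
    return ProteinRecord(
        id=record.id, sequence=record.sequence, residues=residues, source="predicted"
    )


TASK = "ghost"


def generate_records(config: SyntheticConfig):
    """(record, labels, predicted-variant record) triples, fully seeded."""
    rng = np.random.default_rng(config.seed)
    out = []
    for k in range(config.n_proteins):
        length = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
        record = generate_backbone(length, config, rng)
        record.id = f"synth{k:04d}"
        labels, _ = generate_ghost_ligand_labels(record, config, rng)
        variant = _jitter(record, config.predicted_noise_sd, rng)
        out.append((record, labels, variant))
    return out


def generate_dataset(config: SyntheticConfig, include_predicted: bool = True,
                     protein_labels: bool = False):
    """Fully featurized LabeledExamples via the real pipeline.

    Each protein contributes a native example and (optionally) a
    predicted-structure variant sharing labels and group id.  When
    ``protein_labels`` is set, a protein-level binary label marks proteins
    whose positive-residue fraction exceeds 20%.
    """
    provider = StubEmbeddingProvider(dim=config.embed_dim)
    rbf = RBFConfig()
    examples = []
    for record, labels, variant in generate_records(config):
        prot_lab = None
        if protein_labels:
            prot_lab = np.array([int(labels.mean() > 0.2)])
        variants = [record, variant] if include_predicted else [record]
        for rec in variants:
            graph = featurize(
                rec,
                emb=provider.embed(rec.id, len(rec)),
                cutoff=config.cutoff,
                rbf=rbf,
                sasa_points=config.sasa_points,
            )
            examples.append(
                LabeledExample(
                    graph=graph,
                    residue_labels={TASK: labels.copy()},
                    protein_labels=None if prot_lab is None else prot_lab.copy(),
                    group_id=record.id,
                    protein_id=rec.id,
                )
            )
    return examples


def write_dataset(config: SyntheticConfig, outdir) -> dict:
    """Write the synthetic dataset as PDB + FASTA + label TSV + embedding TSV
    so the file-based workflow can be exercised end to end."""
    outdir = Path(outdir)
    (outdir / "structures").mkdir(parents=True, exist_ok=True)
    provider = StubEmbeddingProvider(dim=config.embed_dim)
    fasta, labels_rows, embeddings = [], [], {}
    manifest = {"task": TASK, "proteins": [], "config": config.__dict__.copy()}
    manifest["config"]["length_range"] = list(config.length_range)
    for record, labels, variant in generate_records(config):
        write_pdb(record, outdir / "structures" / f"{record.id}_native.pdb")
        write_pdb(variant, outdir / "structures" / f"{record.id}_predicted.pdb")
        fasta.append((record.id, record.sequence))
        for i, y in enumerate(labels):
            labels_rows.append(f"{record.id}\t{i}\t{int(y)}")
        embeddings[record.id] = provider.embed(record.id, len(record))
        manifest["proteins"].append({"id": record.id, "length": len(record)})
    write_fasta(fasta, outdir / "sequences.fasta")
    (outdir / "labels.tsv").write_text(
        "protein_id\tresidue\tlabel\n" + "\n".join(labels_rows) + "\n"
    )
    save_embeddings(embeddings, outdir / "embeddings.tsv")
    import json

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
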