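import numpy as np
import pytest

from graphfun.structio import AtomRecord, ProteinRecord, ResidueStructure
from graphfun.synthetic import SyntheticConfig, generate_backbone


def record_from_ca(ca_coords, aa="A") -> ProteinRecord:
    """Minimal ProteinRecord with residues at given CA positions (N and C at
    fixed non-collinear offsets so frames are well defined)."""
    ca_coords = np.asarray(ca_coords, dtype=float)
    residues = []
    for k, ca in enumerate(ca_coords):
        backbone = {
            "N": AtomRecord("N", "N", ca + np.array([-1.2, 0.6, 0.0])),
            "CA": AtomRecord("CA", "C", ca),
            "C": AtomRecord("C", "C", ca + np.array([1.3, 0.4, 0.3])),
            "O": AtomRecord("O", "O", ca + np.array([1.9, 1.4, 0.1])),
        }
        residues.append(ResidueStructure(index=k, aa=aa, backbone=backbone))
    return ProteinRecord(
        id="fake", sequence=aa * len(residues), residues=residues, source="native"
    )


def random_rotation(rng) -> np.ndarray:
    """Uniform random rotation matrix (QR with sign fix)."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def transform_record(record: ProteinRecord, R: np.ndarray, t: np.ndarray) -> ProteinRecord:
    """Apply a rigid transform x -> R x + t to every atom."""
    residues = []
    for res in record.residues:
        backbone = {
            k: AtomRecord(a.name, a.element, R @ a.coords + t)
            for k, a in res.backbone.items()
        }
        sidechain = [
            AtomRecord(a.name, a.element, R @ a.coords + t) for a in res.sidechain
        ]
        residues.append(
            ResidueStructure(res.index, res.aa, backbone, sidechain, res.plddt)
        )
    return ProteinRecord(record.id, record.sequence, residues, record.source)


def mirror_record(record: ProteinRecord) -> ProteinRecord:
    """Reflect all coordinates through the xy-plane (changes chirality)."""
    M = np.diag([1.0, 1.0, -1.0])
    residues = []
    for res in record.residues:
        backbone = {
            k: AtomRecord(a.name, a.element, M @ a.coords)
            for k, a in res.backbone.items()
        }
        sidechain = [AtomRecord(a.name, a.element, M @ a.coords) for a in res.sidechain]
        residues.append(
            ResidueStructure(res.index, res.aa, backbone, sidechain, res.plddt)
        )
    return ProteinRecord(record.id, record.sequence, residues, record.source)


@pytest.fixture(scope="session")
def small_record() -> ProteinRecord:
    """A 30-residue synthetic protein, fixed seed."""
    rng = np.random.default_rng(42)
    rec = generate_backbone(30, SyntheticConfig(), rng)
    rec.id = "fix30"
    return rec


@pytest.fixture(scope="session")
def tiny_examples():
    """Six small featurized proteins (native only) for fast training tests."""
    from graphfun.synthetic import generate_dataset

    cfg = SyntheticConfig(n_proteins=6, length_range=(18, 26), seed=11, sasa_points=120)
    return generate_dataset(cfg, include_predicted=False)
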