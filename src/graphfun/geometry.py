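"""SE(3)-invariant geometric featurization.

Each residue gets a local orthonormal frame built from its backbone N, CA and
C atoms.  Node features describe the arrangement of the residue's own atoms
(pairwise distances, directions to CA in the local frame, backbone bond and
torsion angles); edge features describe the relation between two residues
(cross-residue atom distances, directions of the neighbour's atoms seen from
the central frame, and the relative rotation between the two frames as a unit
quaternion).  Sidechains enter through their heavy-atom centroid, which is
treated as a regular atom of the fixed vocabulary.

All features are functions of distances, frame-local directions and angles
only, hence invariant under global rotations and translations; torsion signs
flip under mirror reflection (chirality sensitivity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .structio import ProteinRecord, ResidueStructure

#: Fixed atom vocabulary; "SC" is the sidechain heavy-atom centroid.
ATOM_VOCAB = ("N", "CA", "C", "O", "SC")
_N, _CA, _C, _O, _SC = range(5)


@dataclass
class RBFConfig:
    """Gaussian radial basis encoding of a distance.

    ``n_centers`` centres evenly spaced on [r_min, r_max] A; width defaults to
    the centre spacing.
    """

    n_centers: int = 16
    r_min: float = 0.0
    r_max: float = 20.0
    width: float | None = None

    @property
    def centers(self) -> np.ndarray:
        return np.linspace(self.r_min, self.r_max, self.n_centers)

    @property
    def sigma(self) -> float:
        if self.width is not None:
            return self.width
        return (self.r_max - self.r_min) / (self.n_centers - 1)


@dataclass
class LocalFrame:
    """Per-residue coordinate system: origin at CA, rows of ``basis`` are the
    orthonormal right-handed axes."""

    origin: np.ndarray
    basis: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.basis = np.asarray(self.basis, dtype=float)
        if not np.allclose(self.basis @ self.basis.T, np.eye(3), atol=1e-6):
            raise ValueError("frame basis is not orthonormal")
        if not np.isclose(np.linalg.det(self.basis), 1.0, atol=1e-6):
            raise ValueError("frame basis is not right-handed")


def compute_local_frame(n, ca, c, label: str = "?") -> LocalFrame:
    """Gram-Schmidt frame from backbone atoms: e1 along CA->C, e3 = e1 x (N-CA),
    e2 completing the right-handed triad; origin at CA."""
    n = np.asarray(n, float); ca = np.asarray(ca, float); c = np.asarray(c, float)
    u = c - ca
    v = n - ca
    area = 0.5 * np.linalg.norm(np.cross(u, v))
    if area <= 1e-6:
        raise ValueError(f"degenerate frame for residue {label}: N/CA/C nearly collinear")
    e1 = u / np.linalg.norm(u)
    w = np.cross(e1, v)
    e3 = w / np.linalg.norm(w)
    e2 = np.cross(e3, e1)
    return LocalFrame(origin=ca, basis=np.stack([e1, e2, e3]))


def sidechain_centroid(res: ResidueStructure) -> np.ndarray:
    """Mean of heavy sidechain atom coordinates; CA for residues without a
    sidechain (glycine)."""
    if not res.sidechain:
        return res.ca.copy()
    return np.mean([a.coords for a in res.sidechain], axis=0)


def _dihedral(p1, p2, p3, p4):
    """Vectorised dihedral, IUPAC convention (cis = 0, right-handed sign), degrees."""
    b0 = np.asarray(p1, float) - p2
    b1 = np.asarray(p3, float) - p2
    b1 = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    b2 = np.asarray(p4, float) - p3
    v = b0 - np.sum(b0 * b1, axis=-1, keepdims=True) * b1
    w = b2 - np.sum(b2 * b1, axis=-1, keepdims=True) * b1
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1, v) * w, axis=-1)
    return np.degrees(np.arctan2(y, x))


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Torsion angle in (-180, 180] degrees; raises if consecutive points coincide."""
    pts = [np.asarray(p, float) for p in (p1, p2, p3, p4)]
    for a, b in zip(pts, pts[1:]):
        if np.linalg.norm(b - a) < 1e-9:
            raise ValueError("coincident consecutive points define no dihedral")
    ang = float(_dihedral(*pts))
    return 180.0 if np.isclose(ang, -180.0) else ang


def bond_angle(p1, p2, p3) -> float:
    """Angle at vertex p2 in [0, 180] degrees."""
    a = np.asarray(p1, float) - p2
    b = np.asarray(p3, float) - p2
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-9 or nb < 1e-9:
        raise ValueError("zero-length arm in bond angle")
    cosang = np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def rbf_encode(d, config: RBFConfig = RBFConfig()) -> np.ndarray:
    """Encode distance(s) as Gaussian radial basis responses in (0, 1]."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    diff = d[..., None] - config.centers
    return np.exp(-(diff ** 2) / (2.0 * config.sigma ** 2))


def _matrix_to_quaternion(mats: np.ndarray) -> np.ndarray:
    """Scalar-first unit quaternions with scalar part >= 0."""
    q = Rotation.from_matrix(mats).as_quat()  # (x, y, z, w)
    q = np.concatenate([q[..., 3:4], q[..., :3]], axis=-1)
    sign = np.where(q[..., :1] < 0, -1.0, 1.0)
    return q * sign


def relative_rotation_quaternion(frame_i: LocalFrame, frame_j: LocalFrame) -> np.ndarray:
    """Unit quaternion of the rotation carrying frame j onto frame i, expressed
    invariantly (unchanged when both frames are rotated together)."""
    rel = frame_i.basis @ frame_j.basis.T
    return _matrix_to_quaternion(rel)


# ---------------------------------------------------------------------------
# record-level featurization


def residue_frames(record: ProteinRecord) -> list:
    """Local frames for every residue; raises naming the residue on degeneracy."""
    frames = []
    for res in record.residues:
        frames.append(
            compute_local_frame(
                res.backbone["N"].coords, res.ca, res.backbone["C"].coords,
                label=f"{record.id}:{res.index}",
            )
        )
    return frames


def atom_matrix(record: ProteinRecord):
    """(L, 5, 3) coordinates over the atom vocabulary and an (L, 5) presence
    mask (O may be absent; SC falls back to CA for glycine)."""
    L = len(record)
    coords = np.zeros((L, 5, 3))
    present = np.ones((L, 5), dtype=bool)
    for k, res in enumerate(record.residues):
        coords[k, _N] = res.backbone["N"].coords
        coords[k, _CA] = res.ca
        coords[k, _C] = res.backbone["C"].coords
        if "O" in res.backbone:
            coords[k, _O] = res.backbone["O"].coords
        else:
            present[k, _O] = False
        coords[k, _SC] = sidechain_centroid(res)
    return coords, present


def backbone_angles(record: ProteinRecord):
    """Backbone torsions (phi, psi, omega) and bond angles with validity flags.

    Chain-terminal angles that are undefined are flagged invalid and set to 0.
    Returns dict of (L,) arrays: phi/psi/omega (degrees), their flags, and
    bond angles tau1 (C[i-1]-N-CA), tau2 (N-CA-C), tau3 (CA-C-N[i+1]) + flags.
    """
    L = len(record)
    N = np.array([r.backbone["N"].coords for r in record.residues])
    CA = np.array([r.ca for r in record.residues])
    C = np.array([r.backbone["C"].coords for r in record.residues])
    out = {k: np.zeros(L) for k in ("phi", "psi", "omega", "tau1", "tau2", "tau3")}
    flags = {k: np.zeros(L) for k in ("phi", "psi", "omega", "tau1", "tau2", "tau3")}
    if L > 1:
        out["phi"][1:] = _dihedral(C[:-1], N[1:], CA[1:], C[1:])
        flags["phi"][1:] = 1.0
        out["psi"][:-1] = _dihedral(N[:-1], CA[:-1], C[:-1], N[1:])
        flags["psi"][:-1] = 1.0
        out["omega"][1:] = _dihedral(CA[:-1], C[:-1], N[1:], CA[1:])
        flags["omega"][1:] = 1.0
        out["tau1"][1:] = [bond_angle(C[i - 1], N[i], CA[i]) for i in range(1, L)]
        flags["tau1"][1:] = 1.0
        out["tau3"][:-1] = [bond_angle(CA[i], C[i], N[i + 1]) for i in range(L - 1)]
        flags["tau3"][:-1] = 1.0
    out["tau2"][:] = [bond_angle(N[i], CA[i], C[i]) for i in range(L)]
    flags["tau2"][:] = 1.0
    return out, flags


_PAIRS_INTRA = [(a, b) for a in range(5) for b in range(a + 1, 5)]  # 10 pairs


def node_feature_dim(rbf: RBFConfig = RBFConfig()) -> int:
    # distances + directions + 6 angles (sin/cos + flag) + O-presence flag
    return len(_PAIRS_INTRA) * rbf.n_centers + 4 * 3 + 6 * 3 + 1


def edge_feature_dim(rbf: RBFConfig = RBFConfig()) -> int:
    return 25 * rbf.n_centers + 5 * 3 + 4


def node_geometric_features(
    record: ProteinRecord, frames=None, rbf: RBFConfig = RBFConfig()
) -> np.ndarray:
    """(L, D) SE(3)-invariant per-residue geometric features.

    Blocks, in order: RBF-encoded intra-residue atom-pair distances over the
    vocabulary (N, CA, C, O, SC); unit directions of non-CA atoms to CA in the
    local frame; sin/cos of phi/psi/omega and the three backbone bond angles,
    each followed by a validity flag; an O-presence flag.  Entries involving a
    missing O are zero-filled.
    """
    if frames is None:
        frames = residue_frames(record)
    coords, present = atom_matrix(record)
    L = len(record)
    bases = np.stack([f.basis for f in frames])

    # pairwise intra-residue distances
    blocks = []
    for a, b in _PAIRS_INTRA:
        d = np.linalg.norm(coords[:, a] - coords[:, b], axis=1)
        enc = rbf_encode(d, rbf)
        ok = (present[:, a] & present[:, b]).astype(float)
        blocks.append(enc * ok[:, None])
    dist_block = np.concatenate(blocks, axis=1)

    # directions of N, C, O, SC to CA, in the local frame
    dir_cols = []
    for a in (_N, _C, _O, _SC):
        v = coords[:, a] - coords[:, _CA]
        norm = np.linalg.norm(v, axis=1)
        safe = np.where(norm > 1e-9, norm, 1.0)
        u = v / safe[:, None]
        local = np.einsum("lij,lj->li", bases, u)
        ok = (present[:, a] & (norm > 1e-9)).astype(float)
        dir_cols.append(local * ok[:, None])
    dir_block = np.concatenate(dir_cols, axis=1)

    angles, flags = backbone_angles(record)
    ang_cols = []
    for k in ("phi", "psi", "omega", "tau1", "tau2", "tau3"):
        rad = np.radians(angles[k])
        f = flags[k]
        ang_cols += [np.sin(rad) * f, np.cos(rad) * f, f]
    ang_block = np.stack(ang_cols, axis=1)

    o_flag = present[:, _O].astype(float)[:, None]
    return np.concatenate([dist_block, dir_block, ang_block, o_flag], axis=1)


def edge_geometric_features(
    record: ProteinRecord, edges: np.ndarray, frames=None, rbf: RBFConfig = RBFConfig()
) -> np.ndarray:
    """(E, D) SE(3)-invariant features for directed edges (source j, target i).

    Blocks: RBF-encoded distances between all vocabulary atom pairs across the
    two residues (25 pairs, source atom x target atom); unit directions of the
    source residue's atoms to the target CA in the target frame; the relative
    rotation between the two frames as a scalar-first unit quaternion.
    """
    if frames is None:
        frames = residue_frames(record)
    coords, present = atom_matrix(record)
    edges = np.asarray(edges, dtype=int)
    if edges.size == 0:
        return np.zeros((0, edge_feature_dim(rbf)))
    src, dst = edges[:, 0], edges[:, 1]
    bases = np.stack([f.basis for f in frames])

    # cross-residue atom-pair distances: (E, 5 source, 5 target)
    diff = coords[src][:, :, None, :] - coords[dst][:, None, :, :]
    d = np.linalg.norm(diff, axis=-1)
    ok = (present[src][:, :, None] & present[dst][:, None, :]).astype(float)
    enc = rbf_encode(d.reshape(len(edges), 25), rbf)
    enc *= ok.reshape(len(edges), 25)[:, :, None]
    dist_block = enc.reshape(len(edges), 25 * rbf.n_centers)

    # directions of source atoms to target CA, in target frame
    v = coords[src] - coords[dst][:, None, _CA, :]
    norm = np.linalg.norm(v, axis=-1)
    safe = np.where(norm > 1e-9, norm, 1.0)
    u = v / safe[..., None]
    local = np.einsum("eij,eaj->eai", bases[dst], u)
    okd = (present[src] & (norm > 1e-9)).astype(float)
    dir_block = (local * okd[..., None]).reshape(len(edges), 15)

    rel = np.einsum("eij,ekj->eik", bases[dst], bases[src])  # basis_i . basis_j^T
    quat = _matrix_to_quaternion(rel)

    return np.concatenate([dist_block, dir_block, quat], axis=1)
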