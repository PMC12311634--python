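"""Residue-level geometric graph featurization for the GVP-GNN.

Each residue becomes a node; edges connect a node to its k nearest
neighbors by C-alpha distance (default k = 30). Scalar features are
SE(3)-invariant (dihedral sin/cos, amino-acid and chain one-hots, distance
RBFs, sequence-offset positional embeddings); vector features are
SO(3)-equivariant unit vectors (backbone orientation, imputed C-beta
direction, edge direction). Inter-chain edges carry an all-zero positional
embedding because primary-sequence distance is undefined across chains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structures import ChainRole, StructureModel

__all__ = [
    "ComplexGraph",
    "build_graph",
    "impute_cbeta_direction",
    "backbone_dihedrals",
    "rbf_encode",
    "positional_embedding",
    "NODE_SCALAR_DIM",
    "EDGE_SCALAR_DIM",
]

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
ROLE_ORDER = (ChainRole.TCRA, ChainRole.TCRB, ChainRole.PEP, ChainRole.MHC)

N_RBF = 16
RBF_MAX = 20.0  # A; Gaussian centers evenly spaced on [0, RBF_MAX]
N_POS_EMB = 16

NODE_SCALAR_DIM = 6 + 20 + 4   # dihedral sin/cos + aa one-hot + chain one-hot
EDGE_SCALAR_DIM = N_RBF + N_POS_EMB


@dataclass
class ComplexGraph:
    """Graph-form complex ready for the GVP-GNN.

    Arrays (float64 / int64):
      node_scalar  (N, 30 [+512])   node_vector (N, 3, 3)
      edge_index   (2, E) rows = (source j, destination i)
      edge_scalar  (E, 32)          edge_vector (E, 1, 3)
    """
    target_id: str
    candidate_id: str
    node_scalar: np.ndarray
    node_vector: np.ndarray
    edge_index: np.ndarray
    edge_scalar: np.ndarray
    edge_vector: np.ndarray
    target_dockq: float | None = None

    @property
    def n_nodes(self) -> int:
        return self.node_scalar.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edge_index.shape[1]

    def save_npz(self, path):
        meta = dict(target_id=self.target_id, candidate_id=self.candidate_id)
        np.savez_compressed(
            path,
            node_scalar=self.node_scalar, node_vector=self.node_vector,
            edge_index=self.edge_index, edge_scalar=self.edge_scalar,
            edge_vector=self.edge_vector,
            target_dockq=np.array(np.nan if self.target_dockq is None else self.target_dockq),
            meta=np.array([meta["target_id"], meta["candidate_id"]]),
        )

    @classmethod
    def load_npz(cls, path):
        z = np.load(path, allow_pickle=False)
        tq = float(z["target_dockq"])
        return cls(
            target_id=str(z["meta"][0]), candidate_id=str(z["meta"][1]),
            node_scalar=z["node_scalar"], node_vector=z["node_vector"],
            edge_index=z["edge_index"], edge_scalar=z["edge_scalar"],
            edge_vector=z["edge_vector"],
            target_dockq=None if np.isnan(tq) else tq,
        )


def impute_cbeta_direction(n_vec, c_vec) -> np.ndarray:
    """Imputed unit C-beta direction from backbone geometry.

    With n = N - CA and c = C - CA, the direction is
    ``normalize( (1/3) (n x c)/||n x c|| - (2/3) (n + c)/||n + c|| )``,
    defined for every residue including glycine (no observed C-beta needed).
    """
    n = np.asarray(n_vec, float)
    c = np.asarray(c_vec, float)
    cross = np.cross(n, c)
    plus = n + c
    ncross, nplus = np.linalg.norm(cross), np.linalg.norm(plus)
    if ncross < 1e-9 or nplus < 1e-9 or np.linalg.norm(n) < 1e-9 or np.linalg.norm(c) < 1e-9:
        raise ValueError("degenerate backbone geometry (parallel or zero N/C vectors)")
    v = cross / ncross / 3.0 - 2.0 * plus / nplus / 3.0
    return v / np.linalg.norm(v)


def _dihedral(p0, p1, p2, p3) -> float:
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = n1 @ n2
    y = m1 @ n2
    return float(np.arctan2(y, x))


def backbone_dihedrals(model: StructureModel, i: int):
    """(phi, psi, omega) in radians for residue ``i`` with defined-ness flags.

    Dihedrals never cross chain boundaries; an angle undefined at a chain
    terminus is flagged False and reported as 0.0.
    """
    res = model.residues[i]
    same_chain = lambda j: (0 <= j < len(model.residues)
                            and model.residues[j].chain_role == res.chain_role
                            and model.residues[j].chain_id == res.chain_id)
    angles, flags = [0.0, 0.0, 0.0], [False, False, False]
    if same_chain(i - 1):
        prev = model.residues[i - 1]
        angles[0] = _dihedral(prev.coords["C"], res.coords["N"], res.coords["CA"], res.coords["C"])
        flags[0] = True
        angles[2] = _dihedral(prev.coords["CA"], prev.coords["C"], res.coords["N"], res.coords["CA"])
        flags[2] = True
    if same_chain(i + 1):
        nxt = model.residues[i + 1]
        angles[1] = _dihedral(res.coords["N"], res.coords["CA"], res.coords["C"], nxt.coords["N"])
        flags[1] = True
    return tuple(angles), tuple(flags)


def rbf_encode(distances, n_rbf=N_RBF, d_max=RBF_MAX):
    """Gaussian RBF encoding of distances; centers on [0, d_max], sigma = spacing."""
    d = np.atleast_1d(np.asarray(distances, float))
    centers = np.linspace(0.0, d_max, n_rbf)
    sigma = centers[1] - centers[0]
    return np.exp(-(((d[:, None] - centers[None, :]) / sigma) ** 2))


def positional_embedding(offsets, n_dim=N_POS_EMB, period=1000.0):
    """Sinusoidal embedding of signed sequence offsets (j - i).

    Frequencies are geometrically spaced, transformer-style; zeroed by the
    caller for inter-chain edges.
    """
    off = np.atleast_1d(np.asarray(offsets, float))
    k = np.arange(n_dim // 2)
    freq = period ** (-k / (n_dim // 2))
    ang = off[:, None] * freq[None, :]
    return np.concatenate([np.cos(ang), np.sin(ang)], axis=1)


def build_graph(model: StructureModel, k: int = 30, embeddings=None) -> ComplexGraph:
    """Build the residue graph of a complex.

    Parameters
    ----------
    k
        Number of nearest C-alpha neighbors per node (default 30; capped at
        N-1 for small complexes). Ties broken by lower residue index;
        self-edges excluded.
    embeddings
        Optional (512, N_AA) per-residue embedding matrix appended column-wise
        to the node scalar features (canonical residue order).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = model.n_residues
    if n < 2:
        raise ValueError("need at least 2 residues")

    ca = np.array([r.coords["CA"] for r in model.residues])
    chain_codes = np.array([ROLE_ORDER.index(r.chain_role) for r in model.residues])
    seq_idx = np.array([r.seq_index for r in model.residues])

    # --- node scalars: dihedral sin/cos (0 where undefined), aa/chain one-hot
    dihed = np.zeros((n, 6))
    for i in range(n):
        (phi, psi, omega), (fphi, fpsi, fom) = backbone_dihedrals(model, i)
        for j, (ang, ok) in enumerate(((phi, fphi), (psi, fpsi), (omega, fom))):
            if ok:
                dihed[i, 2 * j] = np.sin(ang)
                dihed[i, 2 * j + 1] = np.cos(ang)
    aa_onehot = np.zeros((n, 20))
    for i, r in enumerate(model.residues):
        aa_onehot[i, AA_ORDER.index(r.aa)] = 1.0
    chain_onehot = np.zeros((n, 4))
    chain_onehot[np.arange(n), chain_codes] = 1.0
    node_scalar = np.concatenate([dihed, aa_onehot, chain_onehot], axis=1)
    if embeddings is not None:
        emb = np.asarray(embeddings, float)
        if emb.shape[1] != n:
            raise ValueError(f"embeddings have {emb.shape[1]} columns, expected {n}")
        node_scalar = np.concatenate([node_scalar, emb.T], axis=1)

    # --- node vectors: unit vectors to CA(i-1), CA(i+1) (zero at chain
    #     termini) and the imputed C-beta direction
    node_vector = np.zeros((n, 3, 3))
    for i, r in enumerate(model.residues):
        if i > 0 and chain_codes[i - 1] == chain_codes[i]:
            v = ca[i - 1] - ca[i]
            node_vector[i, 0] = v / np.linalg.norm(v)
        if i + 1 < n and chain_codes[i + 1] == chain_codes[i]:
            v = ca[i + 1] - ca[i]
            node_vector[i, 1] = v / np.linalg.norm(v)
        node_vector[i, 2] = impute_cbeta_direction(
            r.coords["N"] - r.coords["CA"], r.coords["C"] - r.coords["CA"])

    # --- k-nearest-neighbor edges (j -> i)
    kk = min(k, n - 1)
    d = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    # ties resolved toward the lower residue index; distances rounded to
    # 1e-6 A first so the neighbor set is stable under rigid motion of the
    # coordinates (float round-off must not flip near-ties)
    nbrs = np.argsort(np.round(d, 6), axis=1, kind="stable")[:, :kk]
    dst = np.repeat(np.arange(n), kk)
    src = nbrs.reshape(-1)
    edge_index = np.stack([src, dst])

    dist = d[dst, src]
    rbf = rbf_encode(dist)
    offsets = seq_idx[src] - seq_idx[dst]
    pos = positional_embedding(offsets)
    pos[chain_codes[src] != chain_codes[dst]] = 0.0  # undefined across chains
    edge_scalar = np.concatenate([rbf, pos], axis=1)

    evec = ca[src] - ca[dst]
    edge_vector = (evec / np.linalg.norm(evec, axis=1, keepdims=True))[:, None, :]

    return ComplexGraph(
        target_id=model.target_id, candidate_id=model.candidate_id,
        node_scalar=node_scalar, node_vector=node_vector,
        edge_index=edge_index, edge_scalar=edge_scalar, edge_vector=edge_vector,
    )
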