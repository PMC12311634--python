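"""Synthetic TCR-pMHC fixtures: native complexes, graded decoy pools,
correlated confidence scores and specificity tables.

The generator builds idealized backbones (N, CA, C, O, CB) from internal
coordinates and assembles them into a class-I-like layout: an MHC helix
platform, a peptide in extended conformation lying on it, and two small
TCR variable-domain stand-ins whose CDR3 loops contact the peptide from
above. Decoys are produced by rigid-body displacement of the TCR plus
Gaussian jitter on CDR loops, which sweeps the true DockQ over its full
range. Synthetic AF-style confidence and per-residue pLDDT are noisy
monotone functions of the true DockQ with an optional over-confident tail.

No attempt is made at physically realistic energetics or
sequence-structure consistency; every downstream computation in this
package uses backbone atoms plus an imputed C-beta only, for which these
fixtures are sufficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .quality import compute_dockq
from .structures import (
    ChainRole,
    ResidueRecord,
    StructureModel,
    annotate_cdrs_from_ranges,
)

__all__ = [
    "DecoyRecipe",
    "make_native",
    "make_decoys",
    "default_recipes",
    "make_specificity_table",
    "build_chain_coords",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# idealized backbone internal coordinates (Angstrom / degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8

HELIX = (-57.0, -47.0)
STRAND = (-139.0, 135.0)


def _place(a, b, c, r, theta_deg, phi_deg):
    """NeRF atom placement: position D given A-B-C, bond r, angle B-C-D, dihedral A-B-C-D."""
    theta, phi = np.deg2rad(theta_deg), np.deg2rad(phi_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-np.cos(theta), np.sin(theta) * np.cos(phi), -np.sin(theta) * np.sin(phi)])
    return c + r * (d[0] * bc + d[1] * m + d[2] * n)


def build_chain_coords(phis, psis, omegas=None):
    """Build backbone coordinates for one chain from (phi, psi[, omega]) lists.

    ``phis[0]`` is ignored (undefined at the N-terminus); omegas default to
    trans (180 deg) and ``omegas[i]`` is the peptide-bond dihedral preceding
    residue ``i``. Returns a list of atom-name -> coordinate dicts.
    """
    n = len(phis)
    if omegas is None:
        omegas = [180.0] * n
    res = []
    # first residue in a canonical local frame
    N = np.array([0.0, 0.0, 0.0])
    CA = np.array([_B_N_CA, 0.0, 0.0])
    ang = np.deg2rad(_A_N_CA_C)
    C = CA + _B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    res.append({"N": N, "CA": CA, "C": C})
    for i in range(1, n):
        prev = res[-1]
        Np = _place(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, psis[i - 1])
        CAp = _place(prev["CA"], prev["C"], Np, _B_N_CA, _A_C_N_CA, omegas[i])
        Cp = _place(prev["C"], Np, CAp, _B_CA_C, _A_N_CA_C, phis[i])
        res.append({"N": Np, "CA": CAp, "C": Cp})
    # carbonyl O: dihedral N-CA-C-O = psi + 180; last residue uses 0 (arbitrary trans)
    for i in range(n):
        psi = psis[i] if i < n - 1 else 0.0
        res[i]["O"] = _place(res[i]["N"], res[i]["CA"], res[i]["C"], _B_C_O, _A_CA_C_O, psi + 180.0)
    # idealized C-beta from the local backbone frame
    for i in range(n):
        nv = res[i]["N"] - res[i]["CA"]
        cv = res[i]["C"] - res[i]["CA"]
        x = np.cross(nv, cv)
        x /= np.linalg.norm(x)
        y = nv + cv
        y /= np.linalg.norm(y)
        res[i]["CB"] = res[i]["CA"] + 1.53 * (x / 3.0 - 2.0 * y / 3.0) / np.linalg.norm(x / 3.0 - 2.0 * y / 3.0)
    return res


def _rotation_from_to(a, b):
    """Proper rotation taking unit vector a to unit vector b (Rodrigues)."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(a @ b)
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # pick any perpendicular axis for a half turn
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-6:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return _axis_angle(axis, 180.0)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def _axis_angle(axis, deg):
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    th = np.deg2rad(deg)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)


def _random_seq(rng, length):
    return "".join(rng.choice(list(AA20), size=length))


def _tcr_sequence(rng, length):
    """Random variable-domain-like sequence with a Cys...FGxG-framed CDR3."""
    seq = list(_random_seq(rng, length))
    c0 = length // 2 - 3
    c1 = length // 2 + 3
    seq[c0 - 1] = "C"
    cdr3 = list(_random_seq(rng, c1 - c0))
    seq[c0:c1] = cdr3
    seq[c1:c1 + 4] = list("FGQG")
    return "".join(seq), (c0, c1)


def _default_cdr_ranges(c0):
    """Approximate CDR1/2 windows packed before the CDR3 anchor cysteine."""
    mid = 1 + max(1, (c0 - 2) // 2)
    return [("CDR1", 1, mid), ("CDR2", mid, max(mid + 1, c0 - 1))]


DEFAULT_CHAIN_LENGTHS = {"TCRA": 110, "TCRB": 110, "PEP": 9, "MHC": 180}


def make_native(target_id, chain_lengths=None, seed=0):
    """Generate a native-like synthetic TCR-pMHC complex.

    The returned model carries CDR annotation and guarantees at least 5
    reference residue contacts (5 A heavy-atom criterion) for each of the
    TRA-peptide and TRB-peptide interfaces, with no backbone clash closer
    than ~3.5 A.
    """
    lengths = dict(DEFAULT_CHAIN_LENGTHS)
    if chain_lengths:
        lengths.update({(k.value if isinstance(k, ChainRole) else k): v
                        for k, v in chain_lengths.items()})
    for role, ln in lengths.items():
        if ln < 3:
            raise ValueError(f"chain {role} too short ({ln})")
    rng = np.random.default_rng(seed)

    # ---- peptide: extended strand along x, centered at the origin
    lp = lengths["PEP"]
    pep_seq = _random_seq(rng, lp)
    pep = build_chain_coords([STRAND[0]] * lp, [STRAND[1]] * lp)
    pep_ca = np.array([r["CA"] for r in pep])
    axis = pep_ca[-1] - pep_ca[0]
    Rp = _rotation_from_to(axis, np.array([1.0, 0.0, 0.0]))
    center = pep_ca.mean(axis=0)
    pep = [{k: Rp @ (v - center) for k, v in r.items()} for r in pep]

    # ---- MHC: helix platform below the peptide
    lm = lengths["MHC"]
    mhc_seq = _random_seq(rng, lm)
    mhc = build_chain_coords([HELIX[0]] * lm, [HELIX[1]] * lm)
    mhc_ca = np.array([r["CA"] for r in mhc])
    Rm = _rotation_from_to(mhc_ca[-1] - mhc_ca[0], np.array([1.0, 0.0, 0.0]))
    cm = mhc_ca.mean(axis=0)
    mhc = [{k: Rm @ (v - cm) + np.array([0.0, 0.0, -9.0]) for k, v in r.items()} for r in mhc]

    # ---- TCR chains: strand-loop-strand stand-ins, CDR3 loop pointing down
    chains = {"PEP": (pep, pep_seq), "MHC": (mhc, mhc_seq)}
    cdr_ranges = {}
    pep_atoms = np.array([v for r in pep for v in r.values()])
    for role, xside in (("TCRA", -1.0), ("TCRB", 1.0)):
        lt = lengths[role]
        seq, (c0, c1) = _tcr_sequence(rng, lt)
        # helical body segments flanking an extended CDR3 loop; small
        # seed-dependent dihedral jitter individualizes the fold
        phis = np.empty(lt)
        psis = np.empty(lt)
        phis[:c0], psis[:c0] = HELIX
        phis[c1:], psis[c1:] = HELIX
        phis[c0:c1] = STRAND[0] + rng.uniform(-8, 8, size=c1 - c0)
        psis[c0:c1] = STRAND[1] + rng.uniform(-8, 8, size=c1 - c0)
        phis += rng.uniform(-3, 3, size=lt)
        psis += rng.uniform(-3, 3, size=lt)
        tcr = build_chain_coords(list(phis), list(psis))
        ca = np.array([r["CA"] for r in tcr])
        loop_c = ca[c0:c1].mean(axis=0)
        # loop axis along the peptide direction (x) ...
        R1 = _rotation_from_to(ca[c1 - 1] - ca[c0], np.array([1.0, 0.0, 0.0]))
        tcr = [{k: R1 @ (v - loop_c) for k, v in r.items()} for r in tcr]
        # ... then spin about x so the chain body sits above the loop
        ca1 = np.array([r["CA"] for r in tcr])
        body_c = np.concatenate([ca1[:c0], ca1[c1:]]).mean(axis=0)
        up = body_c.copy()
        up[0] = 0.0
        if np.linalg.norm(up) > 1e-6:
            ang = np.rad2deg(np.arctan2(up[1], up[2]))
            tcr = [{k: _axis_angle([1.0, 0.0, 0.0], ang) @ v for k, v in r.items()}
                   for r in tcr]
        # anchor the loop above the peptide quarter-points, then pick the spin
        # about the loop axis and the descent depth that maximize residue
        # contacts (5 A) while keeping every atom pair above a 3.3 A floor
        anchor_idx = max(1, lp // 3) if role == "TCRA" else min(lp - 2, lp - 1 - lp // 3)
        anchor = pep[anchor_idx]["CA"] + np.array([0.0, 0.0, 10.0])
        tcr = [{k: v + anchor for k, v in r.items()} for r in tcr]
        pep_xyz = np.array([v for r in pep for v in r.values()])
        pep_rid = np.array([i for i, r in enumerate(pep) for _ in r.values()])

        best = None  # (contacts, spin, depth)
        for spin in range(-90, 91, 5):
            Rs = _axis_angle([1.0, 0.0, 0.0], float(spin))
            xyz = np.array([Rs @ (v - anchor) + anchor
                            for r in tcr for v in r.values()])
            rid = np.array([i for i, r in enumerate(tcr) for _ in r.values()])
            dxy2 = ((xyz[:, None, :2] - pep_xyz[None, :, :2]) ** 2).sum(-1)
            dzz = xyz[:, None, 2] - pep_xyz[None, :, 2]
            for depth in np.arange(0.0, 14.01, 0.25):
                d = np.sqrt(dxy2 + (dzz - depth) ** 2)
                if d.min() < 3.3:
                    break
                pairs = {(int(a), int(b))
                         for a, b in zip(rid[np.nonzero(d < 5.0)[0]],
                                         pep_rid[np.nonzero(d < 5.0)[1]])}
                cand = (len(pairs), spin, depth)
                if best is None or cand[0] > best[0]:
                    best = cand
            if best is not None and best[0] >= 8:
                break
        n_best, spin, depth = best
        Rs = _axis_angle([1.0, 0.0, 0.0], float(spin))
        shift = np.array([0.0, 0.0, -depth])
        tcr = [{k: Rs @ (v - anchor) + anchor + shift for k, v in r.items()}
               for r in tcr]
        chains[role] = (tcr, seq)
        cdr_ranges[role] = _default_cdr_ranges(c0) + [("CDR3", c0, c1)]

    residues = []
    chain_ids = {"TCRA": "D", "TCRB": "E", "PEP": "C", "MHC": "A"}
    for role in ("TCRA", "TCRB", "PEP", "MHC"):
        coords_list, seq = chains[role]
        for i, (coords, aa) in enumerate(zip(coords_list, seq)):
            if aa == "G":
                coords = {k: v for k, v in coords.items() if k != "CB"}
            residues.append(
                ResidueRecord(ChainRole(role), chain_ids[role], i, aa,
                              {k: v.copy() for k, v in coords.items()})
            )
    model = StructureModel(target_id=target_id, candidate_id=f"{target_id}_native",
                           residues=residues)
    model = annotate_cdrs_from_ranges(model, cdr_ranges)

    # the native must present a genuine two-sided interface
    from .quality import interface_contacts
    for role in (ChainRole.TCRA, ChainRole.TCRB):
        n_contacts = len(interface_contacts(model, [role], cutoff=5.0))
        if n_contacts < 5:
            raise RuntimeError(
                f"generator failed to place {role.value} with >=5 peptide contacts "
                f"(got {n_contacts}); adjust chain lengths"
            )
    return model


@dataclass(frozen=True)
class DecoyRecipe:
    rigid_translation: float = 0.0   # Angstrom
    rigid_rotation: float = 0.0      # degrees
    loop_jitter_sigma: float = 0.0   # Angstrom
    seed: int = 0

    def __post_init__(self):
        if min(self.rigid_translation, self.rigid_rotation, self.loop_jitter_sigma) < 0:
            raise ValueError("recipe magnitudes must be >= 0")


def default_recipes(n, seed=0, max_translation=30.0):
    """A graded recipe ladder whose true-DockQ distribution spans [0, 1]."""
    rng = np.random.default_rng(seed)
    # geometric ladder from near-native to fully undocked
    base_t = np.concatenate([[0.0, 0.1, 0.25], np.geomspace(0.5, max_translation, 17)])
    recipes = []
    for i in range(n):
        t = float(base_t[i % len(base_t)] * rng.uniform(0.8, 1.25))
        rot = float(min(60.0, t * 2.0) * rng.uniform(0.0, 1.0))
        jit = float(rng.uniform(0.0, 0.6) * min(1.0, t))
        recipes.append(DecoyRecipe(t, rot, jit, seed=int(rng.integers(2**31 - 1))))
    return recipes


def _synthetic_confidence(rng, dockq, miscalibrated):
    conf = 0.85 * dockq + 0.10 + rng.normal(0.0, 0.05)
    if miscalibrated and dockq < 0.23 and rng.uniform() < 0.15:
        conf = rng.uniform(0.70, 0.90)  # over-confident tail
    return float(np.clip(conf, 0.01, 0.99))


def _assign_synthetic_plddt(model, rng, dockq):
    base = 0.80 * dockq + 0.15
    for res in model.residues:
        noisy = res.is_cdr or res.chain_role == ChainRole.PEP
        sd = 0.10 if noisy else 0.04
        res.plddt = float(np.clip(100.0 * (base + rng.normal(0.0, sd)), 0.0, 100.0))


def make_decoys(native, recipes, miscalibrated=False, interface=None):
    """Generate decoys from a native via rigid TCR displacement + CDR jitter.

    Returns ``(pool, scores)`` where ``scores[i]`` is the QualityScores of
    ``pool[i]`` against the native (computed with the quality module).
    Synthetic per-model confidence and per-residue pLDDT are attached,
    correlated with true DockQ; with ``miscalibrated`` a fraction of
    incorrect decoys receives confidence in the 0.7-0.9 range.
    """
    recipes = list(recipes)
    if not recipes:
        raise ValueError("need at least one recipe")
    tcr_roles = [ChainRole.TCRA, ChainRole.TCRB]
    pool, scores = [], []
    for k, rc in enumerate(recipes):
        rng = np.random.default_rng(rc.seed)
        decoy = native.copy()
        decoy.candidate_id = f"{native.target_id}_decoy{k:04d}"
        if rc.rigid_rotation > 0 or rc.rigid_translation > 0:
            centroid = decoy.atom_coords(tcr_roles).mean(axis=0)
            axis = rng.normal(size=3)
            R = _axis_angle(axis, rc.rigid_rotation)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            t = centroid - R @ centroid + rc.rigid_translation * direction
            decoy = decoy.transformed(R, t, roles=tcr_roles)
            decoy.candidate_id = f"{native.target_id}_decoy{k:04d}"
        if rc.loop_jitter_sigma > 0:
            for res in decoy.residues:
                if res.chain_role in tcr_roles and res.is_cdr:
                    for name in res.coords:
                        res.coords[name] = res.coords[name] + rng.normal(
                            0.0, rc.loop_jitter_sigma, size=3)
        qs = compute_dockq(decoy, native, interface=interface)
        decoy.af_confidence = _synthetic_confidence(rng, qs.dockq, miscalibrated)
        _assign_synthetic_plddt(decoy, rng, qs.dockq)
        pool.append(decoy)
        scores.append(qs)
    return pool, scores


def make_specificity_table(n_peptides, positives_per_peptide, seed=0,
                           peptide_length=9, mhc_allele="HLA-A*02:01"):
    """Synthetic TCR specificity table of binder records.

    Peptides form families derived from a common ancestor by 1..5 point
    substitutions, so pairwise Levenshtein distances span the small-integer
    range relevant to the swapped-negative donor constraint.
    """
    if n_peptides < 2:
        raise ValueError("need at least 2 peptides")
    rng = np.random.default_rng(seed)
    base = _random_seq(rng, peptide_length)
    peptides = [base]
    while len(peptides) < n_peptides:
        n_mut = int(rng.integers(1, 6))  # 1..5 substitutions from the ancestor
        pep = list(base)
        pos = rng.choice(peptide_length, size=n_mut, replace=False)
        for p in pos:
            choices = [a for a in AA20 if a != pep[p]]
            pep[p] = choices[int(rng.integers(len(choices)))]
        pep = "".join(pep)
        if pep not in peptides:
            peptides.append(pep)
    rows = []
    for pep in peptides:
        for _ in range(positives_per_peptide):
            ta, _ = _tcr_sequence(rng, 24)
            tb, _ = _tcr_sequence(rng, 24)
            rows.append({
                "tcra": ta, "tcrb": tb, "peptide": pep, "mhc": mhc_allele,
                "label": "binder", "source_peptide": pep,
            })
    return pd.DataFrame(rows)
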