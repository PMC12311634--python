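"""Independent reference implementations used only to cross-check tcrqa.

Deliberately written on a different code path from the package: plain
Python loops, scipy's Rotation.align_vectors for superposition (the package
uses its own SVD Kabsch), and textbook formulas computed step by step.
"""

import math

import numpy as np
from scipy.spatial.transform import Rotation

from tcrqa.structures import ChainRole

BACKBONE = ("N", "CA", "C", "O")


def _atom_list(model, roles):
    out = []
    for res in model.residues:
        if res.chain_role in roles:
            for name, xyz in res.coords.items():
                out.append(((res.chain_role.value, res.seq_index), name, tuple(xyz)))
    return out


def _pair_min_dist(res_a, res_b):
    best = math.inf
    for xa in res_a:
        for xb in res_b:
            best = min(best, math.dist(xa, xb))
    return best


def _residue_map(model, roles):
    out = {}
    for res in model.residues:
        if res.chain_role in roles:
            out[(res.chain_role.value, res.seq_index)] = [tuple(v) for v in res.coords.values()]
    return out


def _superpose_rmsd(mobile_pts, target_pts, apply_to=None):
    """RMSD after least-squares superposition, via scipy align_vectors.

    With ``apply_to`` given, returns the transformed ``apply_to`` points
    instead (the superposition is still fit on mobile/target).
    """
    P = np.asarray(mobile_pts, float)
    Q = np.asarray(target_pts, float)
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    rot, _ = Rotation.align_vectors(Q - qc, P - pc)
    if apply_to is None:
        moved = rot.apply(P - pc) + qc
        return float(np.sqrt(((moved - Q) ** 2).sum(axis=1).mean())), None
    moved = rot.apply(np.asarray(apply_to, float) - pc) + qc
    return None, moved


def dockq_oracle(candidate, reference, receptor_frame="pmhc"):
    """Brute-force restricted-interface DockQ (TCR ligand vs peptide partner)."""
    lig_roles = {ChainRole.TCRA, ChainRole.TCRB}
    par_roles = {ChainRole.PEP}

    ref_lig = _residue_map(reference, lig_roles)
    ref_par = _residue_map(reference, par_roles)
    cand_lig = _residue_map(candidate, lig_roles)
    cand_par = _residue_map(candidate, par_roles)

    # fnat: native residue contacts (< 5 A) reproduced by the candidate
    native_contacts = set()
    for ka, ra in ref_lig.items():
        for kb, rb in ref_par.items():
            if _pair_min_dist(ra, rb) < 5.0:
                native_contacts.add((ka, kb))
    kept = 0
    for ka, kb in native_contacts:
        if _pair_min_dist(cand_lig[ka], cand_par[kb]) < 5.0:
            kept += 1
    fnat = kept / len(native_contacts)

    # interface residues (<10 A, either side), backbone RMSD after
    # superposition of the candidate's interface onto the reference's
    iface = set()
    for ka, ra in ref_lig.items():
        for kb, rb in ref_par.items():
            if _pair_min_dist(ra, rb) < 10.0:
                iface.add(ka)
                iface.add(kb)

    def backbone(model, keys):
        pts = []
        for res in model.residues:
            if (res.chain_role.value, res.seq_index) in keys:
                for name in BACKBONE:
                    if name in res.coords:
                        pts.append(list(res.coords[name]))
        return np.array(pts)

    ref_bb = backbone(reference, iface)
    cand_bb = backbone(candidate, iface)
    irms, _ = _superpose_rmsd(cand_bb, ref_bb)

    # LRMS: superpose candidate receptor on reference receptor, measure ligand
    rec_roles = ({ChainRole.PEP, ChainRole.MHC} if receptor_frame == "pmhc"
                 else {ChainRole.PEP})
    rec_c = backbone(candidate, set(_residue_map(candidate, rec_roles)))
    rec_r = backbone(reference, set(_residue_map(reference, rec_roles)))
    lig_c = backbone(candidate, set(_residue_map(candidate, lig_roles)))
    lig_r = backbone(reference, set(_residue_map(reference, lig_roles)))
    _, lig_moved = _superpose_rmsd(rec_c, rec_r, apply_to=lig_c)
    lrms = float(np.sqrt(((lig_moved - lig_r) ** 2).sum(axis=1).mean()))

    dockq = (fnat + 1 / (1 + (irms / 1.5) ** 2) + 1 / (1 + (lrms / 8.5) ** 2)) / 3
    return {"fnat": fnat, "irms": irms, "lrms": lrms, "dockq": dockq}


def spearman_oracle(x, y):
    """Rank correlation from first principles (average ranks for ties)."""
    def ranks(v):
        v = list(v)
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(x), ranks(y)
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


def partial_auc_oracle(labels, scores, max_fpr=0.1, standardize=True):
    """Trapezoidal partial ROC area from an explicit threshold sweep."""
    pairs = sorted(zip(scores, labels), key=lambda p: -p[0])
    pos = sum(labels)
    neg = len(labels) - pos
    pts = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < len(pairs):
        j = i
        while j + 1 < len(pairs) and pairs[j + 1][0] == pairs[i][0]:
            j += 1
        for k in range(i, j + 1):
            if pairs[k][1]:
                tp += 1
            else:
                fp += 1
        pts.append((fp / neg, tp / pos))
        i = j + 1
    # integrate to max_fpr
    area = 0.0
    for (x0, y0), (x1, y1) in zip(pts, pts[1:]):
        if x1 <= max_fpr:
            area += (x1 - x0) * (y0 + y1) / 2
        else:
            if x0 < max_fpr:
                yat = y0 + (y1 - y0) * (max_fpr - x0) / (x1 - x0)
                area += (max_fpr - x0) * (y0 + yat) / 2
            break
    if not standardize:
        return area
    amin, amax = 0.5 * max_fpr**2, max_fpr
    return 0.5 * (1 + (area - amin) / (amax - amin))
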