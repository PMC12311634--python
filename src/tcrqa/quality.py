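"""DockQ docking quality restricted to the TCR-peptide interface.

DockQ combines three classical CAPRI quantities into one score in [0, 1]:

    DockQ = ( fnat + 1/(1 + (iRMS/1.5)^2) + 1/(1 + (LRMS/8.5)^2) ) / 3

where fnat is the fraction of native residue-residue interface contacts
(any heavy-atom pair < 5 A) reproduced by the candidate, iRMS the backbone
RMSD over native interface residues (10 A heavy-atom criterion) after
superposition on that interface, and LRMS the ligand backbone RMSD after
superposition on the receptor.

Here the interface is restricted to TCR-peptide interactions: the two TCR
chains form one merged ligand group, the peptide is the contact partner,
and MHC atoms enter neither fnat nor iRMS. For LRMS the receptor frame is
the full pMHC by default (``receptor_frame="pmhc"``), with a peptide-only
option for sensitivity analysis.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .structures import (
    BACKBONE_ATOMS,
    AlignmentError,
    ChainRole,
    StructureModel,
    kabsch,
    rmsd,
)

__all__ = [
    "CapriClass",
    "QualityScores",
    "compute_dockq",
    "capri_class",
    "dockq_from_components",
    "interface_contacts",
    "FNAT_CUTOFF",
    "INTERFACE_CUTOFF",
]

FNAT_CUTOFF = 5.0       # A, heavy-atom contact distance defining fnat
INTERFACE_CUTOFF = 10.0  # A, heavy-atom distance defining interface residues


class CapriClass(enum.Enum):
    Incorrect = "Incorrect"
    Acceptable = "Acceptable"
    Medium = "Medium"
    High = "High"


def capri_class(dockq: float) -> CapriClass:
    """Map a DockQ value onto the CAPRI quality category."""
    if not (0.0 <= dockq <= 1.0):
        raise ValueError(f"DockQ out of range: {dockq}")
    if dockq < 0.23:
        return CapriClass.Incorrect
    if dockq < 0.49:
        return CapriClass.Acceptable
    if dockq < 0.80:
        return CapriClass.Medium
    return CapriClass.High


def dockq_from_components(fnat: float, irms: float, lrms: float) -> float:
    return (fnat + 1.0 / (1.0 + (irms / 1.5) ** 2) + 1.0 / (1.0 + (lrms / 8.5) ** 2)) / 3.0


@dataclass(frozen=True)
class QualityScores:
    fnat: float
    irms: float
    lrms: float
    dockq: float
    capri: CapriClass

    @classmethod
    def from_components(cls, fnat, irms, lrms):
        dq = dockq_from_components(fnat, irms, lrms)
        return cls(float(fnat), float(irms), float(lrms), float(dq), capri_class(dq))


def _default_interface():
    return frozenset({(ChainRole.TCRA, ChainRole.PEP), (ChainRole.TCRB, ChainRole.PEP)})


def _group_roles(interface):
    ligand = sorted({a for a, _ in interface}, key=lambda r: r.value)
    partner = sorted({b for _, b in interface}, key=lambda r: r.value)
    return ligand, partner


def _residue_atoms(model, roles):
    """(residue key, atom array) per residue of the given roles; heavy atoms only."""
    out = []
    for res in model.residues:
        if res.chain_role in set(roles):
            out.append(((res.chain_role.value, res.seq_index),
                        np.asarray(list(res.coords.values()))))
    return out


def interface_contacts(model, ligand_roles, partner_roles=(ChainRole.PEP,),
                       cutoff=FNAT_CUTOFF):
    """Residue-pair contacts across the ligand/partner interface.

    A contact is any residue pair with at least one heavy-atom pair closer
    than ``cutoff``. Returns a set of ((role, idx), (role, idx)) keys.
    """
    lig = _residue_atoms(model, ligand_roles)
    par = _residue_atoms(model, partner_roles)
    contacts = set()
    for lk, la in lig:
        for pk, pa in par:
            d2 = np.sum((la[:, None, :] - pa[None, :, :]) ** 2, axis=-1)
            if np.min(d2) < cutoff**2:
                contacts.add((lk, pk))
    return contacts


def _interface_residues(model, ligand_roles, partner_roles, cutoff=INTERFACE_CUTOFF):
    """Residue keys (both sides) with any heavy atom within ``cutoff`` of the other side."""
    lig = _residue_atoms(model, ligand_roles)
    par = _residue_atoms(model, partner_roles)
    keys = set()
    for lk, la in lig:
        for pk, pa in par:
            d2 = np.sum((la[:, None, :] - pa[None, :, :]) ** 2, axis=-1)
            if np.min(d2) < cutoff**2:
                keys.add(lk)
                keys.add(pk)
    return keys


def _backbone_of(model, keys):
    out = []
    keys = set(keys)
    for res in model.residues:
        if (res.chain_role.value, res.seq_index) in keys:
            for a in BACKBONE_ATOMS:
                if a in res.coords:
                    out.append(res.coords[a])
    return np.asarray(out).reshape(-1, 3)


def _check_compatible(candidate, reference):
    for role in ChainRole:
        if len(candidate.chain(role)) != len(reference.chain(role)):
            raise AlignmentError(f"{role.value}: residue count mismatch")
        if candidate.sequence(role) != reference.sequence(role):
            raise AlignmentError(f"{role.value}: sequence mismatch")


def compute_dockq(candidate: StructureModel, reference: StructureModel,
                  interface=None, receptor_frame="pmhc") -> QualityScores:
    """DockQ of ``candidate`` against ``reference`` over the TCR-peptide interface.

    Parameters
    ----------
    interface
        Set of (ligand_role, partner_role) pairs; defaults to
        {(TCRA, PEP), (TCRB, PEP)}. All ligand roles are merged into one
        ligand group, all partner roles into one contact partner.
    receptor_frame
        "pmhc" superimposes on PEP+MHC backbone for LRMS (default),
        "pep" on the peptide alone.
    """
    interface = _default_interface() if interface is None else frozenset(interface)
    if not interface:
        raise ValueError("empty interface specification")
    _check_compatible(candidate, reference)
    ligand_roles, partner_roles = _group_roles(interface)

    ref_contacts = interface_contacts(reference, ligand_roles, partner_roles)
    if not ref_contacts:
        raise ValueError(
            f"reference {reference.candidate_id!r} has an empty "
            f"{'+'.join(r.value for r in ligand_roles)}-"
            f"{'+'.join(r.value for r in partner_roles)} interface"
        )
    cand_contacts = interface_contacts(candidate, ligand_roles, partner_roles)
    fnat = len(ref_contacts & cand_contacts) / len(ref_contacts)

    # iRMS: backbone RMSD over native interface residues, after superposing
    # the candidate's copies of those residues onto the reference's
    iface_keys = _interface_residues(reference, ligand_roles, partner_roles)
    ref_bb = _backbone_of(reference, iface_keys)
    cand_bb = _backbone_of(candidate, iface_keys)
    R, t = kabsch(cand_bb, ref_bb)
    irms = rmsd(cand_bb @ R.T + t, ref_bb)

    # LRMS: ligand backbone RMSD after receptor superposition
    if receptor_frame == "pmhc":
        rec_roles = [ChainRole.PEP, ChainRole.MHC]
    elif receptor_frame == "pep":
        rec_roles = [ChainRole.PEP]
    else:
        raise ValueError(f"unknown receptor_frame {receptor_frame!r}")
    R, t = kabsch(candidate.atom_coords(rec_roles), reference.atom_coords(rec_roles))
    lig_cand = candidate.atom_coords(ligand_roles) @ R.T + t
    lrms = rmsd(lig_cand, reference.atom_coords(ligand_roles))

    return QualityScores.from_components(fnat, irms, lrms)
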