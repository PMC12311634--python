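"""Consensus quality scores: GNN ensembles, CDR-peptide pLDDT, GNN-AF.

The two cross-validated GVP-GNN ensembles are averaged arithmetically
within each half and combined by a harmonic mean (GNN-ens). The GNN-AF
consensus takes the harmonic mean of four quantities on a common [0, 1]
scale: the two GNN ensemble means, the AF-M ranking confidence, and the
mean pLDDT over CDR123 alpha/beta plus peptide residues (divided by 100).
The harmonic mean deliberately weights small components heavily: a single
low sub-score drags the consensus down, which suits quality estimation
where over-confident components are the failure mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structures import ChainRole, StructureModel

__all__ = ["ScoreBundle", "harmonic_mean", "cdrpep_plddt", "assemble_bundle",
           "score_candidate", "CLAMP_EPS"]

CLAMP_EPS = 1e-4


def harmonic_mean(values) -> float:
    """n / sum(1/x); inputs are clamped to >= CLAMP_EPS first."""
    vals = np.asarray(list(values), float)
    if vals.size == 0:
        raise ValueError("harmonic mean of empty sequence")
    if np.any(vals <= 0):
        raise ValueError("harmonic mean requires positive values")
    vals = np.clip(vals, CLAMP_EPS, None)
    return float(vals.size / np.sum(1.0 / vals))


def cdrpep_plddt(model: StructureModel) -> float:
    """Mean pLDDT over CDR-labeled TCR residues and all peptide residues, / 100."""
    relevant = [
        r for r in model.residues
        if r.chain_role == ChainRole.PEP
        or (r.chain_role in (ChainRole.TCRA, ChainRole.TCRB) and r.is_cdr)
    ]
    if not any(r.is_cdr for r in relevant):
        raise ValueError("no annotated CDR residues; annotate CDRs first")
    vals = []
    for r in relevant:
        if r.plddt is None:
            raise ValueError(f"missing pLDDT at {r.chain_id}:{r.seq_index}")
        vals.append(r.plddt)
    return float(np.mean(vals) / 100.0)


@dataclass(frozen=True)
class ScoreBundle:
    per_fold_full: tuple
    per_fold_high: tuple
    gnn_full: float
    gnn_high: float
    gnn_ens: float
    af_confidence: float
    cdrpep_plddt: float
    gnn_af: float

    def as_dict(self):
        d = {f"fold_full_{i}": v for i, v in enumerate(self.per_fold_full)}
        d.update({f"fold_high_{i}": v for i, v in enumerate(self.per_fold_high)})
        d.update(gnn_full=self.gnn_full, gnn_high=self.gnn_high, gnn_ens=self.gnn_ens,
                 af_confidence=self.af_confidence, cdrpep_plddt=self.cdrpep_plddt,
                 gnn_af=self.gnn_af)
        return d


def assemble_bundle(per_fold_full, per_fold_high, af_confidence, cdrpep) -> ScoreBundle:
    """Combine fold predictions and AF-derived scores into one ScoreBundle."""
    full = tuple(float(v) for v in per_fold_full)
    high = tuple(float(v) for v in per_fold_high)
    if len(full) != 5 or len(high) != 5:
        raise ValueError("expected 5 fold predictions per ensemble half")
    gnn_full = float(np.mean(np.clip(full, CLAMP_EPS, 1.0)))
    gnn_high = float(np.mean(np.clip(high, CLAMP_EPS, 1.0)))
    af = float(np.clip(af_confidence, CLAMP_EPS, 1.0))
    cp = float(np.clip(cdrpep, CLAMP_EPS, 1.0))
    return ScoreBundle(
        per_fold_full=full, per_fold_high=high,
        gnn_full=gnn_full, gnn_high=gnn_high,
        gnn_ens=harmonic_mean([gnn_full, gnn_high]),
        af_confidence=af, cdrpep_plddt=cp,
        gnn_af=harmonic_mean([gnn_full, gnn_high, af, cp]),
    )


def score_candidate(model, graph, ensemble) -> ScoreBundle:
    """Score one candidate with a trained EnsembleSpec.

    Requires the model to carry af_confidence, per-residue pLDDT and CDR
    annotation; ``graph`` is its featurized form.
    """
    from .gvp_model import predict_many

    if model.af_confidence is None:
        raise ValueError(f"{model.candidate_id}: missing af_confidence")
    full = predict_many(ensemble.fold_models_full, [graph])[:, 0]
    high = predict_many(ensemble.fold_models_high, [graph])[:, 0]
    return assemble_bundle(full, high, model.af_confidence, cdrpep_plddt(model))
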