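"""Dataset construction: redundancy reduction, partitioning, decoy binning,
clash filtering, specificity downsampling and swapped-negative generation.

Specificity tables are pandas DataFrames with columns
``tcra, tcrb, peptide, mhc, label, source_peptide`` (CSV on disk); dataset
manifests carry ``target_id, candidate_id, dockq, fold, split``.
"""

from __future__ import annotations

import edlib
import numpy as np
import pandas as pd
from Bio import Align
from sklearn.cluster import AgglomerativeClustering

__all__ = [
    "read_fasta_sequences",
    "sequence_similarity",
    "hobohm1_reduce",
    "partition_targets",
    "bin_sample_by_dockq",
    "filter_clashed",
    "downsample_positives",
    "generate_swapped_negatives",
    "levenshtein",
    "split_by_release_date",
]


def read_fasta_sequences(path) -> dict:
    """Read a FASTA file into an ordered ``{record_id: sequence}`` mapping."""
    from Bio import SeqIO

    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise ValueError(f"{path}: no FASTA records")
    return out


def _aligner():
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1.0
    a.mismatch_score = 0.0
    a.open_gap_score = -1.0
    a.extend_gap_score = -1.0
    return a


def sequence_similarity(a: str, b: str) -> float:
    """Identities / alignment length from a global pairwise alignment.

    Identity scoring (match 1, mismatch 0) with a simple gap penalty of -1;
    alignment length counts all alignment columns including gaps.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    aln = _aligner().align(a, b)[0]
    s1, s2 = str(aln[0]), str(aln[1])
    ident = sum(x == y for x, y in zip(s1, s2))
    return ident / len(s1)


def levenshtein(a: str, b: str) -> int:
    return edlib.align(a, b)["editDistance"]


def hobohm1_reduce(entries, threshold: float = 0.95):
    """Greedy single-pass redundancy reduction over (target_id, tcra, tcrb).

    An entry is dropped when its TCR-alpha OR TCR-beta sequence is at least
    ``threshold`` similar to the corresponding chain of any already retained
    entry. Entries are processed in the caller's order (priority first);
    re-running on the output is the identity.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    retained = []
    for entry in entries:
        _, tcra, tcrb = entry
        redundant = any(
            sequence_similarity(tcra, ra) >= threshold
            or sequence_similarity(tcrb, rb) >= threshold
            for _, ra, rb in retained
        )
        if not redundant:
            retained.append(entry)
    return retained


def partition_targets(entries, n_clusters: int = 5):
    """Complete-linkage clustering of targets into folds.

    Distance between two targets is ``1 - mean(sim_alpha, sim_beta)`` over
    global pairwise similarities. Returns ``{target_id: fold}`` with exactly
    ``n_clusters`` non-empty folds.
    """
    entries = list(entries)
    if n_clusters > len(entries):
        raise ValueError(f"{n_clusters} clusters requested for {len(entries)} targets")
    ids = [e[0] for e in entries]
    n = len(entries)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sim = 0.5 * (sequence_similarity(entries[i][1], entries[j][1])
                         + sequence_similarity(entries[i][2], entries[j][2]))
            dist[i, j] = dist[j, i] = 1.0 - sim
    clust = AgglomerativeClustering(
        n_clusters=n_clusters, metric="precomputed", linkage="complete")
    labels = clust.fit_predict(dist)
    return {tid: int(lab) for tid, lab in zip(ids, labels)}


def bin_sample_by_dockq(models, n_bins: int = 20, per_bin: int = 20, seed: int = 0):
    """Per-target DockQ-bin subsampling against redundancy.

    ``models`` is a sequence of ``(target_id, candidate_id, dockq)``. DockQ
    values are placed in ``n_bins`` equal-width bins of [0, 1] (left-closed,
    1.0 assigned to the top bin) and up to ``per_bin`` candidates per bin and
    target are kept, sampled uniformly without replacement.
    """
    if n_bins < 1 or per_bin < 1:
        raise ValueError("n_bins and per_bin must be >= 1")
    rng = np.random.default_rng(seed)
    by_key = {}
    for target_id, cand_id, dockq in models:
        b = min(int(dockq * n_bins), n_bins - 1)
        by_key.setdefault((target_id, b), []).append((target_id, cand_id, dockq))
    retained = []
    for key in sorted(by_key):
        pool = by_key[key]
        if len(pool) <= per_bin:
            retained.extend(pool)
        else:
            idx = rng.choice(len(pool), size=per_bin, replace=False)
            retained.extend(pool[i] for i in sorted(idx))
    return retained


def filter_clashed(models, max_clashes: int = 5):
    """Keep models whose TRA-pep AND TRB-pep backbone clash counts are <= max."""
    if max_clashes < 0:
        raise ValueError("max_clashes must be >= 0")
    out = []
    for model, report in models:
        if report.tra_pep_clashes <= max_clashes and report.trb_pep_clashes <= max_clashes:
            out.append((model, report))
    return out


def downsample_positives(records: pd.DataFrame, cap: int = 200, seed: int = 0) -> pd.DataFrame:
    """Retain up to ``cap`` binder records per peptide, uniformly at random."""
    if cap < 1:
        raise ValueError("cap must be >= 1")
    rng = np.random.default_rng(seed)
    parts = []
    for _, group in records.groupby("peptide", sort=True):
        if len(group) <= cap:
            parts.append(group)
        else:
            idx = rng.choice(len(group), size=cap, replace=False)
            parts.append(group.iloc[np.sort(idx)])
    return pd.concat(parts).reset_index(drop=True)


def generate_swapped_negatives(positives: pd.DataFrame, n_per_positive: int = 5,
                               min_peptide_levenshtein: int | None = None,
                               seed: int = 0) -> pd.DataFrame:
    """Swapped negatives: each positive's pMHC re-paired with donor TCRs.

    Donor TCRs are drawn without replacement (per positive) from positives of
    *other* peptides; with ``min_peptide_levenshtein`` set, the donor's source
    peptide must differ from the recipient peptide by at least that many
    edits, guarding against sampling potentially cross-reactive TCRs.
    """
    rng = np.random.default_rng(seed)
    rows = []
    peptides = positives["peptide"].to_numpy()
    for i, pos in positives.reset_index(drop=True).iterrows():
        eligible = np.flatnonzero(peptides != pos["peptide"])
        if min_peptide_levenshtein is not None:
            eligible = np.array([
                j for j in eligible
                if levenshtein(peptides[j], pos["peptide"]) >= min_peptide_levenshtein
            ], dtype=int)
        if len(eligible) < n_per_positive:
            raise ValueError(
                f"peptide {pos['peptide']!r}: only {len(eligible)} eligible donor "
                f"TCRs for {n_per_positive} swaps"
            )
        donors = rng.choice(eligible, size=n_per_positive, replace=False)
        for j in donors:
            donor = positives.iloc[int(j)]
            rows.append({
                "tcra": donor["tcra"], "tcrb": donor["tcrb"],
                "peptide": pos["peptide"], "mhc": pos["mhc"],
                "label": "swapped", "source_peptide": donor["peptide"],
            })
    return pd.DataFrame(rows)


def split_by_release_date(records: pd.DataFrame, cutoff: str = "2021-09-30",
                          date_column: str = "release_date") -> pd.DataFrame:
    """Annotate a metadata table with split = train (<= cutoff) or benchmark (>)."""
    dates = pd.to_datetime(records[date_column])
    out = records.copy()
    out["split"] = np.where(dates <= pd.Timestamp(cutoff), "train", "benchmark")
    return out
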