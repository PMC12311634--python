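"""Evaluation statistics: ranking correlations, top-1 selection, failed-
proportion curves, batch-sampling TPR/accuracy, cumulative TPR curves and
partial ROC AUC.

The batch-sampling experiment groups one binder with k swapped negatives
sharing the same pMHC; a scorer ranks the six complexes and the batch TPR

    TPR = (batch_length - 1 - binder_index) / (batch_length - 1)

is 1 when the binder is ranked first and 0 when last. Batch accuracy is the
fraction of batches with the binder on top.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

__all__ = [
    "EvalBatch",
    "RankingReport",
    "make_batches",
    "compute_tpr",
    "batch_accuracy",
    "cumulative_tpr_curve",
    "ranking_report",
    "failed_proportion_curve",
    "auc01",
    "FAILED_DOCKQ",
]

FAILED_DOCKQ = 0.23  # CAPRI "Incorrect" threshold


def compute_tpr(batch_length: int, binder_index: int) -> float:
    """Batch true-positive rank statistic; 1.0 = binder ranked first."""
    if batch_length < 2:
        raise ValueError("batch_length must be >= 2")
    if not 0 <= binder_index <= batch_length - 1:
        raise ValueError(f"binder_index {binder_index} out of range")
    return (batch_length - 1 - binder_index) / (batch_length - 1)


@dataclass(frozen=True)
class EvalBatch:
    peptide: str
    complexes: tuple  # ordered (record_id, label, score)

    def __post_init__(self):
        labels = [lab for _, lab, _ in self.complexes]
        if labels.count("binder") != 1:
            raise ValueError("a batch needs exactly one binder")
        if len(self.complexes) < 2:
            raise ValueError("a batch needs at least 2 complexes")

    @property
    def batch_length(self) -> int:
        return len(self.complexes)

    @property
    def binder_index(self) -> int:
        """Rank of the binder after sorting by descending score (0 = top).

        Ties are broken against the binder: a non-binder with an equal score
        outranks it, so degenerate constant scorers get no credit.
        """
        binder_score = next(s for _, lab, s in self.complexes if lab == "binder")
        return sum(1 for _, lab, s in self.complexes
                   if lab != "binder" and s >= binder_score)

    @property
    def tpr(self) -> float:
        return compute_tpr(self.batch_length, self.binder_index)

    @property
    def max_score(self) -> float:
        return max(s for _, _, s in self.complexes)


def make_batches(records: pd.DataFrame, score_column: str = "score",
                 negatives_per_batch: int = 5, seed: int = 0):
    """Group scored specificity records into 1-binder + k-negative batches.

    ``records`` needs columns peptide, label, score plus any id column; for
    each binder, negatives are drawn without replacement from the same
    peptide's swapped pool.
    """
    rng = np.random.default_rng(seed)
    batches = []
    for peptide, group in records.groupby("peptide", sort=True):
        binders = group[group["label"] == "binder"]
        negatives = group[group["label"] == "swapped"]
        for _, binder in binders.iterrows():
            if len(negatives) < negatives_per_batch:
                raise ValueError(
                    f"peptide {peptide!r}: {len(negatives)} negatives available, "
                    f"{negatives_per_batch} needed")
            pick = rng.choice(len(negatives), size=negatives_per_batch, replace=False)
            complexes = [(str(binder.name), "binder", float(binder[score_column]))]
            complexes += [
                (str(negatives.iloc[int(i)].name), "swapped",
                 float(negatives.iloc[int(i)][score_column]))
                for i in pick
            ]
            batches.append(EvalBatch(peptide=peptide, complexes=tuple(complexes)))
    return batches


def batch_accuracy(batches) -> float:
    """Fraction of batches whose binder is ranked first."""
    batches = list(batches)
    if not batches:
        raise ValueError("no batches")
    return float(np.mean([b.binder_index == 0 for b in batches]))


def cumulative_tpr_curve(batches, order_key: str = "max_intra_batch_score"):
    """Mean TPR of the top-x batches, x = 1..n, after sorting by ``order_key``.

    ``order_key`` is ``max_intra_batch_score`` (descending maximal score in
    the batch, i.e. a confidence ordering) or ``tpr``. Ties keep the
    stable input order. Returns a list of (x, mean TPR of first x batches).
    """
    batches = list(batches)
    if order_key == "max_intra_batch_score":
        key = [b.max_score for b in batches]
    elif order_key == "tpr":
        key = [b.tpr for b in batches]
    else:
        raise ValueError(f"unknown order_key {order_key!r}")
    order = np.argsort(-np.asarray(key), kind="stable")
    tprs = np.asarray([batches[i].tpr for i in order])
    cum = np.cumsum(tprs) / np.arange(1, len(tprs) + 1)
    return [(i + 1, float(v)) for i, v in enumerate(cum)]


@dataclass(frozen=True)
class RankingReport:
    global_scc: float
    global_scc_high: float     # restricted to DockQ > 0.5
    mean_local_scc: float
    mean_top1_dockq: float
    per_target: pd.DataFrame


def ranking_report(candidates: pd.DataFrame, score_key: str) -> RankingReport:
    """Ranking quality of a predicted score against true DockQ.

    ``candidates`` needs columns target_id, dockq and ``score_key``. Targets
    with fewer than 3 candidates are excluded from the local (per-target)
    Spearman with a warning but still contribute to global statistics and
    top-1 selection.
    """
    import warnings

    df = candidates
    global_scc = float(spearmanr(df[score_key], df["dockq"]).statistic)
    high = df[df["dockq"] > 0.5]
    global_scc_high = (float(spearmanr(high[score_key], high["dockq"]).statistic)
                       if len(high) >= 3 else float("nan"))
    rows = []
    for target, group in df.groupby("target_id", sort=True):
        top1 = group.loc[group[score_key].idxmax(), "dockq"]
        if len(group) < 3:
            warnings.warn(f"target {target}: <3 candidates, excluded from local SCC")
            local = float("nan")
        else:
            local = float(spearmanr(group[score_key], group["dockq"]).statistic)
        rows.append({"target_id": target, "local_scc": local,
                     "top1_dockq": float(top1), "n_candidates": len(group)})
    per_target = pd.DataFrame(rows)
    return RankingReport(
        global_scc=global_scc,
        global_scc_high=global_scc_high,
        mean_local_scc=float(np.nanmean(per_target["local_scc"])),
        mean_top1_dockq=float(per_target["top1_dockq"].mean()),
        per_target=per_target,
    )


def failed_proportion_curve(candidates: pd.DataFrame, score_key: str,
                            n_bins: int = 10):
    """Failed-candidate (DockQ < 0.23) proportions by score bin and by rank.

    Scores are min-max normalized over the pool for binning. Returns
    ``(bin_table, cumulative)``: per-bin failed proportions with counts, and
    the cumulative failed proportion over candidates sorted by descending
    score.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    df = candidates
    failed = (df["dockq"] < FAILED_DOCKQ).to_numpy()
    score = df[score_key].to_numpy(dtype=float)
    lo, hi = score.min(), score.max()
    norm = (score - lo) / (hi - lo) if hi > lo else np.zeros_like(score)
    bins = np.minimum((norm * n_bins).astype(int), n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = bins == b
        rows.append({
            "bin": b,
            "score_lo": b / n_bins, "score_hi": (b + 1) / n_bins,
            "n": int(mask.sum()),
            "failed_proportion": float(failed[mask].mean()) if mask.any() else float("nan"),
        })
    order = np.argsort(-score, kind="stable")
    cum = np.cumsum(failed[order]) / np.arange(1, len(order) + 1)
    return pd.DataFrame(rows), [(i + 1, float(v)) for i, v in enumerate(cum)]


def auc01(labels, scores, max_fpr: float = 0.1, standardize: bool = True) -> float:
    """Partial ROC AUC up to FPR ``max_fpr``.

    Computed by trapezoidal integration of the ROC curve (average-rank tie
    handling via simultaneous threshold sweeps) and, by default, McClish-
    standardized to [0, 1] so that a random scorer gives 0.5.
    """
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, float)
    if y.min() == y.max():
        raise ValueError("both classes required")
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    # threshold sweep: group tied scores
    distinct = np.flatnonzero(np.diff(s_sorted)) if len(s_sorted) > 1 else np.array([], int)
    idx = np.concatenate([distinct, [len(s_sorted) - 1]])
    tps = np.cumsum(y_sorted)[idx]
    fps = np.cumsum(1 - y_sorted)[idx]
    tpr = np.concatenate([[0.0], tps / tps[-1]])
    fpr = np.concatenate([[0.0], fps / fps[-1]])
    # clip the curve at max_fpr, interpolating the last segment
    stop = np.searchsorted(fpr, max_fpr, side="right")
    fpr_c, tpr_c = fpr[:stop], tpr[:stop]
    if fpr_c[-1] < max_fpr and stop < len(fpr):
        f0, f1 = fpr[stop - 1], fpr[stop]
        t0, t1 = tpr[stop - 1], tpr[stop]
        t_at = t0 + (t1 - t0) * (max_fpr - f0) / (f1 - f0)
        fpr_c = np.concatenate([fpr_c, [max_fpr]])
        tpr_c = np.concatenate([tpr_c, [t_at]])
    pauc = float(np.trapezoid(tpr_c, fpr_c))
    if not standardize:
        return pauc
    min_area = 0.5 * max_fpr**2
    max_area = max_fpr
    return float(0.5 * (1.0 + (pauc - min_area) / (max_area - min_area)))
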