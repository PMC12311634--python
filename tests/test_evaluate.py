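import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tcrqa.evaluate import (
    EvalBatch,
    auc01,
    batch_accuracy,
    compute_tpr,
    cumulative_tpr_curve,
    failed_proportion_curve,
    make_batches,
    ranking_report,
)

from oracles import partial_auc_oracle, spearman_oracle


def _batch(scores, binder_pos=0, peptide="PEP"):
    cx = [(f"c{i}", "binder" if i == binder_pos else "swapped", float(s))
          for i, s in enumerate(scores)]
    return EvalBatch(peptide=peptide, complexes=tuple(cx))


class TestTpr:
    @pytest.mark.parametrize("bl,bi,expected", [
        (6, 0, 1.0), (6, 5, 0.0), (6, 2, 0.6), (2, 0, 1.0), (2, 1, 0.0),
    ])
    def test_values(self, bl, bi, expected):
        assert compute_tpr(bl, bi) == pytest.approx(expected)

    @pytest.mark.parametrize("bl,bi", [(6, 6), (6, -1), (1, 0)])
    def test_out_of_range(self, bl, bi):
        with pytest.raises(ValueError):
            compute_tpr(bl, bi)

    @given(st.integers(2, 20))
    def test_uniform_null_mean_is_half(self, bl):
        vals = [compute_tpr(bl, i) for i in range(bl)]
        assert np.mean(vals) == pytest.approx(0.5, abs=1e-12)

    def test_binder_index_from_scores(self):
        assert _batch([0.9, 0.5, 0.4, 0.3, 0.2, 0.1], binder_pos=0).binder_index == 0
        assert _batch([0.35, 0.5, 0.4, 0.3, 0.2, 0.1], binder_pos=0).binder_index == 2
        # score ties count against the binder
        assert _batch([0.5, 0.5, 0.1, 0.1, 0.1, 0.1], binder_pos=0).binder_index == 1


class TestBatchAccuracy:
    def test_perfect_scorer(self):
        batches = [_batch([1.0, 0.2, 0.3, 0.1, 0.4, 0.2]) for _ in range(10)]
        assert batch_accuracy(batches) == 1.0

    def test_worst_scorer(self):
        batches = [_batch([0.0, 0.2, 0.3, 0.1, 0.4, 0.2]) for _ in range(10)]
        assert batch_accuracy(batches) == 0.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            batch_accuracy([])


class TestCumulativeTprCurve:
    def test_flat_at_one_for_perfect_batches(self):
        batches = [_batch(np.linspace(1, 0.1, 6) * s) for s in (1.0, 0.9, 0.8)]
        curve = cumulative_tpr_curve(batches)
        assert all(v == pytest.approx(1.0) for _, v in curve)

    def test_final_point_is_unsorted_mean(self):
        rng = np.random.default_rng(0)
        batches = [_batch(rng.uniform(size=6), binder_pos=int(rng.integers(6)))
                   for _ in range(30)]
        mean_tpr = np.mean([b.tpr for b in batches])
        for key in ("max_intra_batch_score", "tpr"):
            curve = cumulative_tpr_curve(batches, order_key=key)
            assert curve[-1][1] == pytest.approx(mean_tpr)

    def test_prefix_means_match_brute_force(self):
        rng = np.random.default_rng(1)
        batches = [_batch(rng.uniform(size=6), binder_pos=int(rng.integers(6)))
                   for _ in range(50)]
        curve = cumulative_tpr_curve(batches)
        ordered = sorted(batches, key=lambda b: -b.max_score)
        for x, v in curve:
            assert v == pytest.approx(np.mean([b.tpr for b in ordered[:x]]), abs=1e-12)

    def test_random_scores_converge_to_half(self):
        rng = np.random.default_rng(2)
        batches = [_batch(rng.uniform(size=6), binder_pos=int(rng.integers(6)))
                   for _ in range(3000)]
        curve = cumulative_tpr_curve(batches)
        assert curve[-1][1] == pytest.approx(0.5, abs=0.02)


class TestMakeBatches:
    def test_grouping_and_composition(self):
        rng = np.random.default_rng(3)
        rows = []
        for pep in ("AAA", "BBB"):
            for i in range(3):
                rows.append({"peptide": pep, "label": "binder", "score": rng.uniform()})
            for i in range(15):
                rows.append({"peptide": pep, "label": "swapped", "score": rng.uniform()})
        batches = make_batches(pd.DataFrame(rows), seed=0)
        assert len(batches) == 6
        for b in batches:
            assert b.batch_length == 6
            assert sum(lab == "binder" for _, lab, _ in b.complexes) == 1

    def test_insufficient_negatives(self):
        df = pd.DataFrame([
            {"peptide": "AAA", "label": "binder", "score": 0.5},
            {"peptide": "AAA", "label": "swapped", "score": 0.4},
        ])
        with pytest.raises(ValueError, match="negatives"):
            make_batches(df, seed=0)


class TestRankingReport:
    def _pools(self, seed=0, n_targets=4, n_cands=12):
        rng = np.random.default_rng(seed)
        rows = []
        for t in range(n_targets):
            dockq = rng.uniform(size=n_cands)
            for d in dockq:
                rows.append({"target_id": f"t{t}", "dockq": d,
                             "score": d + rng.normal(0, 0.1)})
        return pd.DataFrame(rows)

    def test_perfect_monotone_case(self):
        df = self._pools()
        df["score"] = df["dockq"]
        rep = ranking_report(df, "score")
        assert rep.global_scc == pytest.approx(1.0)
        assert rep.mean_local_scc == pytest.approx(1.0)
        expected_top1 = df.groupby("target_id")["dockq"].max().mean()
        assert rep.mean_top1_dockq == pytest.approx(expected_top1)

    def test_anti_monotone(self):
        df = self._pools()
        df["score"] = -df["dockq"]
        assert ranking_report(df, "score").global_scc == pytest.approx(-1.0)

    def test_matches_rank_correlation_oracle(self):
        df = self._pools(seed=5)
        rep = ranking_report(df, "score")
        assert rep.global_scc == pytest.approx(
            spearman_oracle(list(df["score"]), list(df["dockq"])), abs=1e-9)
        high = df[df["dockq"] > 0.5]
        assert rep.global_scc_high == pytest.approx(
            spearman_oracle(list(high["score"]), list(high["dockq"])), abs=1e-9)

    def test_invariant_under_monotone_transform(self):
        df = self._pools(seed=6)
        r1 = ranking_report(df, "score")
        df["score"] = np.exp(3 * df["score"]) + 7
        r2 = ranking_report(df, "score")
        assert r1.global_scc == pytest.approx(r2.global_scc)
        assert r1.mean_top1_dockq == pytest.approx(r2.mean_top1_dockq)

    def test_small_target_excluded_with_warning(self):
        df = self._pools(seed=7)
        df = pd.concat([df, pd.DataFrame([
            {"target_id": "tiny", "dockq": 0.5, "score": 0.5},
            {"target_id": "tiny", "dockq": 0.6, "score": 0.6}])])
        with pytest.warns(UserWarning, match="tiny"):
            rep = ranking_report(df, "score")
        row = rep.per_target[rep.per_target["target_id"] == "tiny"]
        assert np.isnan(row["local_scc"].iloc[0])


class TestFailedProportionCurve:
    def test_no_failures(self):
        df = pd.DataFrame({"dockq": np.linspace(0.5, 1.0, 30),
                           "score": np.linspace(0, 1, 30)})
        bins, cum = failed_proportion_curve(df, "score")
        filled = bins.dropna(subset=["failed_proportion"])
        assert (filled["failed_proportion"] == 0).all()
        assert all(v == 0 for _, v in cum)

    def test_all_failures(self):
        df = pd.DataFrame({"dockq": np.linspace(0, 0.2, 30),
                           "score": np.linspace(0, 1, 30)})
        bins, cum = failed_proportion_curve(df, "score")
        filled = bins.dropna(subset=["failed_proportion"])
        assert (filled["failed_proportion"] == 1).all()
        assert all(v == 1 for _, v in cum)

    def test_cumulative_matches_brute_force(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame({"dockq": rng.uniform(size=60), "score": rng.uniform(size=60)})
        _, cum = failed_proportion_curve(df, "score")
        order = df.sort_values("score", ascending=False, kind="stable")
        failed = (order["dockq"] < 0.23).to_numpy()
        for x, v in cum:
            assert v == pytest.approx(failed[:x].mean(), abs=1e-12)


class TestAuc01:
    def test_perfect_separation(self):
        assert auc01([0, 0, 0, 1, 1], [0.1, 0.2, 0.3, 0.8, 0.9]) == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc01([1, 1, 1], [0.1, 0.2, 0.3])

    def test_agreement_with_brute_force_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            n = int(rng.integers(10, 40))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = np.round(rng.uniform(size=n), 2)  # induce ties
            assert auc01(labels, scores) == pytest.approx(
                partial_auc_oracle(list(labels), list(scores)), abs=1e-9)

    def test_agreement_with_sklearn_mcclish(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(10)
        labels = rng.integers(0, 2, size=500)
        scores = rng.uniform(size=500)
        assert auc01(labels, scores) == pytest.approx(
            roc_auc_score(labels, scores, max_fpr=0.1), abs=1e-9)
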