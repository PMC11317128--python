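"""Truth construction, pooled ranking and AUROC/AUPRC scoring."""

import itertools

import numpy as np
import pandas as pd
import pytest

from crosspipe import (
    assign_tf_markers,
    auprc,
    auroc,
    build_marker_truth,
    perturbation_truth,
    pooled_rank,
    pseudobulk,
)
from crosspipe.benchmark import score_benchmark
from crosspipe.core import ContrastSpec, GeneSetCollection
from crosspipe.errors import ValidationError


def _auroc_pair_counting(labels, scores):
    """Brute-force oracle: count positive/negative pairs, ties worth 1/2."""
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestPseudobulk:
    @staticmethod
    def _cells(counts_by_cell, meta_rows):
        cells = list(counts_by_cell)
        counts = pd.DataFrame(
            np.array([counts_by_cell[c] for c in cells]), index=cells,
            columns=["gA", "gB"],
        )
        meta = pd.DataFrame(meta_rows, index=cells, columns=["sample", "cell_type"])
        return counts, meta

    def test_counts_are_summed_per_sample_and_type(self):
        counts, meta = self._cells(
            {f"c{i}": [i + 1, 400] for i in range(3)},
            [("s1", "T")] * 3,
        )
        m, sheet = pseudobulk(counts, meta, min_cells=3, min_counts=1)
        assert m.counts.loc["gA", "s1|T"] == 6
        assert sheet.groups.tolist() == ["T"]

    def test_underpopulated_pseudobulk_dropped(self):
        counts, meta = self._cells(
            {f"c{i}": [100, 100] for i in range(19)},
            [("s1", "T")] * 9 + [("s1", "B")] * 10,
        )
        m, _ = pseudobulk(counts, meta)  # min_cells 10
        assert m.sample_ids == ["s1|B"]

    def test_low_count_pseudobulk_dropped(self):
        # T sums to 999 reads (one short of the threshold), B to exactly 1000
        t_cells = {f"c{i}": [50, 50] for i in range(9)}
        t_cells["c9"] = [50, 49]
        b_cells = {f"d{i}": [50, 50] for i in range(10)}
        counts, meta = self._cells(
            {**t_cells, **b_cells},
            [("s1", "T")] * 10 + [("s1", "B")] * 10,
        )
        m, _ = pseudobulk(counts, meta)
        assert m.sample_ids == ["s1|B"]

    def test_unlabeled_cells_discarded(self):
        counts, meta = self._cells(
            {f"c{i}": [200, 200] for i in range(20)},
            [("s1", "T")] * 10 + [(None, None)] * 10,
        )
        m, _ = pseudobulk(counts, meta)
        assert m.sample_ids == ["s1|T"]
        assert m.counts["s1|T"].sum() == 4000

    def test_nothing_survives_is_error(self):
        counts, meta = self._cells({"c0": [1, 1]}, [("s1", "T")])
        with pytest.raises(ValidationError):
            pseudobulk(counts, meta)


class TestMarkerTruth:
    @staticmethod
    def _contrasts(cell_types):
        return [ContrastSpec(ct, "rest", f"{ct}_vs_rest") for ct in cell_types]

    def test_one_positive_among_seven(self):
        types = [f"T{k}" for k in range(7)]
        coll = GeneSetCollection("markers", {t: [("g1", 1.0)] for t in types})
        truth = build_marker_truth(self._contrasts(types), coll)
        sums = truth.groupby("contrast")["label"].agg(["sum", "count"])
        assert (sums["sum"] == 1).all()
        assert (sums["count"] == 7).all()

    def test_minimal_two_type_case(self):
        coll = GeneSetCollection("markers", {"A": [("g1", 1.0)], "B": [("g2", 1.0)]})
        truth = build_marker_truth(self._contrasts(["A", "B"]), coll)
        assert truth.groupby("contrast")["label"].sum().tolist() == [1, 1]

    def test_unmapped_cell_type_is_error(self):
        coll = GeneSetCollection("markers", {"A": [("g1", 1.0)]})
        with pytest.raises(ValidationError, match="B"):
            build_marker_truth(self._contrasts(["A", "B"]), coll)


class TestTFAssignment:
    @staticmethod
    def _coll(tfs):
        return GeneSetCollection("tf", {t: [("g1", 1.0)] for t in tfs})

    def test_shared_tf_goes_to_higher_score(self):
        binding = pd.DataFrame(
            [("endo", "TF1", 5.0), ("peri", "TF1", 3.0), ("peri", "TF2", 2.0)],
            columns=["cell_type", "tf", "score"],
        )
        out = {a.cell_type: a.tf_ids for a in assign_tf_markers(binding, k=2)}
        assert out["endo"] == ("TF1",)
        assert out["peri"] == ("TF2",)

    def test_lists_shorter_than_k_when_tfs_run_out(self):
        binding = pd.DataFrame(
            [("endo", f"TF{i}", 10 - i) for i in range(3)],
            columns=["cell_type", "tf", "score"],
        )
        out = assign_tf_markers(binding, k=10)
        assert out[0].tf_ids == ("TF0", "TF1", "TF2")

    def test_disjoint_candidates_fill_to_k(self):
        rows = [(ct, f"{ct}_TF{i}", float(i)) for ct in ("a", "b") for i in range(6)]
        binding = pd.DataFrame(rows, columns=["cell_type", "tf", "score"])
        out = {a.cell_type: a.tf_ids for a in assign_tf_markers(binding, k=4)}
        assert len(out["a"]) == len(out["b"]) == 4

    def test_tfs_absent_from_collection_discarded(self):
        binding = pd.DataFrame(
            [("endo", "TF1", 5.0), ("endo", "ghost", 9.0)],
            columns=["cell_type", "tf", "score"],
        )
        out = assign_tf_markers(binding, k=5, coll=self._coll(["TF1"]))
        assert out[0].tf_ids == ("TF1",)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(0)
        rows = [
            (f"ct{i % 4}", f"TF{j}", float(rng.integers(0, 50)))
            for j in range(30)
            for i in (j, j + 1)
        ]
        binding = pd.DataFrame(rows, columns=["cell_type", "tf", "score"])
        a = assign_tf_markers(binding, k=5)
        b = assign_tf_markers(binding.sample(frac=1.0, random_state=3), k=5)
        assert a == b

    def test_empty_binding_is_error(self):
        with pytest.raises(ValidationError):
            assign_tf_markers(pd.DataFrame(columns=["cell_type", "tf", "score"]))


class TestPooledRank:
    @staticmethod
    def _inputs(n_contrasts=6, n_candidates=7, seed=0):
        rng = np.random.default_rng(seed)
        truth_rows, act_rows = [], []
        for c in range(n_contrasts):
            pos = rng.integers(n_candidates)
            for k in range(n_candidates):
                truth_rows.append((f"c{c}", f"S{k}", int(k == pos)))
                act_rows.append(("p1", f"c{c}", "r", f"S{k}", rng.normal()))
        truth = pd.DataFrame(truth_rows, columns=["contrast", "candidate", "label"])
        act = pd.DataFrame(act_rows, columns=["pipeline", "contrast", "resource", "set", "score"])
        return act, truth

    def test_pooled_cardinality(self):
        act, truth = self._inputs()
        ranked = pooled_rank(act, truth)
        assert len(ranked) == 42

    def test_single_contrast_pooling_is_identity(self):
        act, truth = self._inputs(n_contrasts=1)
        ranked = pooled_rank(act, truth)
        assert len(ranked) == 7
        assert (ranked["score"].diff().dropna() <= 1e-12).all()

    def test_input_row_order_irrelevant(self):
        act, truth = self._inputs()
        a = pooled_rank(act, truth)
        b = pooled_rank(act.sample(frac=1.0, random_state=2), truth)
        pd.testing.assert_frame_equal(a, b)

    def test_missing_score_is_error(self):
        act, truth = self._inputs()
        with pytest.raises(ValidationError, match="missing"):
            pooled_rank(act.iloc[:-1], truth)

    def test_score_benchmark_reports_counts(self):
        act, truth = self._inputs()
        report = score_benchmark(pooled_rank(act, truth), "bench")
        assert report.loc[0, "n_pos"] == 6
        assert report.loc[0, "n_neg"] == 36


class TestAUROC:
    def test_perfect_separation(self):
        assert auroc([1, 0, 0], [0.9, 0.5, 0.8]) == 1.0

    def test_all_ties_give_half(self):
        assert auroc([1, 0, 1, 0], [3, 3, 3, 3]) == 0.5

    def test_score_reversal_symmetry(self):
        labels = [1, 0, 1, 0, 0]
        scores = [0.1, 0.7, 0.8, 0.2, 0.4]
        assert auroc(labels, scores) == pytest.approx(
            1.0 - auroc(labels, [-s for s in scores])
        )

    def test_matches_pair_counting_on_short_lists(self):
        # exhaustive over label patterns and tie-rich score grids, n <= 8
        rng = np.random.default_rng(7)
        for n in range(2, 9):
            for labels in itertools.product([0, 1], repeat=n):
                if sum(labels) in (0, n):
                    continue
                scores = rng.integers(0, 4, size=n).astype(float)
                assert auroc(labels, scores) == pytest.approx(
                    _auroc_pair_counting(labels, scores), abs=1e-12
                )

    def test_single_class_is_error(self):
        with pytest.raises(ValidationError):
            auroc([1, 1], [0.1, 0.2])


class TestAUPRC:
    def test_perfect_ranking_is_one(self):
        assert auprc([1, 0], [0.9, 0.1]) == 1.0
        assert auprc([1, 1, 0, 0, 0], [5, 4, 3, 2, 1]) == 1.0

    def test_worst_single_positive_hand_value(self):
        # positive ranked second of two: precision 1/2 at full recall
        assert auprc([0, 1], [0.9, 0.1]) == 0.5

    def test_random_scores_approach_prevalence(self):
        rng = np.random.default_rng(11)
        labels = np.zeros(70_000, dtype=int)
        labels[: 10_000] = 1
        values = [auprc(labels, rng.uniform(size=labels.size)) for _ in range(15)]
        assert np.mean(values) == pytest.approx(1 / 7, abs=0.01)


class TestPerturbationTruth:
    @staticmethod
    def _mapping():
        return pd.DataFrame(
            {
                "perturbation": ["il6", "tnf", "_pad", "_pad", "_pad", "_pad"],
                "gene_set": ["H1", "H2", "H3", "H4", "H5", "H6"],
            }
        )

    def test_single_mapping_prevalence_one_sixth(self):
        contrasts = pd.DataFrame({"contrast": ["c1"], "perturbation": ["il6"]})
        truth = perturbation_truth(self._mapping(), contrasts)
        assert truth["label"].sum() == 1
        assert len(truth) == 6

    def test_multi_mapping_counts(self):
        mapping = pd.concat(
            [self._mapping(), pd.DataFrame({"perturbation": ["il6"], "gene_set": ["H5"]})]
        )
        contrasts = pd.DataFrame({"contrast": ["c1"], "perturbation": ["il6"]})
        truth = perturbation_truth(mapping, contrasts)
        assert truth["label"].sum() == 2
        assert (truth["label"] == 0).sum() == 4

    def test_unmapped_contrast_excluded(self):
        contrasts = pd.DataFrame(
            {"contrast": ["c1", "c2"], "perturbation": ["il6", "mystery"]}
        )
        truth = perturbation_truth(self._mapping(), contrasts)
        assert truth.attrs["excluded"] == ["c2"]
        assert set(truth["contrast"]) == {"c1"}

    def test_all_unmapped_is_error(self):
        contrasts = pd.DataFrame({"contrast": ["c1"], "perturbation": ["nope"]})
        with pytest.raises(ValidationError):
            perturbation_truth(self._mapping(), contrasts)
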