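"""Retrieval ranking and evaluation statistics."""

import numpy as np
import pytest

from ddsd.descriptor import ShapeDescriptor
from ddsd.evaluate import (
    BenchmarkManifest,
    RetrievalRun,
    average_precision_recall,
    e_measure,
    f_measure,
    nearest_neighbor_accuracy,
    precision_recall,
    rank_database,
)


def desc(bins):
    bins = np.asarray(bins, dtype=float)
    return ShapeDescriptor(bins=bins / bins.sum(), n_bin=len(bins), range=(0, 1))


@pytest.fixture
def toy_manifest():
    entries = [
        ("a1", "a1.vox", "A"), ("a2", "a2.vox", "A"), ("a3", "a3.vox", "A"),
        ("b1", "b1.vox", "B"), ("b2", "b2.vox", "B"),
    ]
    return BenchmarkManifest(entries)


class TestManifest:
    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            BenchmarkManifest([("x", "p", "G"), ("x", "q", "G")])

    def test_groups_collected(self, toy_manifest):
        assert toy_manifest.groups == {"A": ["a1", "a2", "a3"], "B": ["b1", "b2"]}

    def test_tsv_roundtrip(self, toy_manifest, tmp_path):
        path = tmp_path / "bench.tsv"
        toy_manifest.write_tsv(path)
        back = BenchmarkManifest.read_tsv(path)
        assert back.entries == toy_manifest.entries


class TestRankDatabase:
    def test_exact_duplicate_ranked_first_with_zero_score(self):
        q = desc([1, 2, 3])
        db = {"q": q, "dup": desc([1, 2, 3]), "far": desc([5, 1, 1])}
        run = rank_database("q", q, db)
        assert run.ranked_ids[0] == "dup"
        assert run.scores[0] == 0.0

    def test_database_of_one(self):
        q = desc([1, 1])
        run = rank_database("q", q, {"q": q, "only": desc([2, 1])})
        assert run.ranked_ids == ["only"]

    def test_empty_database_rejected(self):
        q = desc([1, 1])
        with pytest.raises(ValueError, match="empty"):
            rank_database("q", q, {"q": q})

    def test_order_matches_independent_sort(self):
        rng = np.random.default_rng(0)
        q = desc(rng.uniform(0.1, 1, 8))
        db = {f"s{i}": desc(rng.uniform(0.1, 1, 8)) for i in range(20)}
        run = rank_database("q", q, {**db, "q": q})
        scores = {sid: np.abs(q.bins - d.bins).sum() for sid, d in db.items()}
        expected = [sid for _, sid in sorted((s, sid) for sid, s in scores.items())]
        assert run.ranked_ids == expected

    def test_ties_broken_lexicographically(self):
        q = desc([1, 0])
        same = desc([0, 1])
        run = rank_database("q", q, {"q": q, "zz": same, "aa": same})
        assert run.ranked_ids == ["aa", "zz"]


class TestPrecisionRecall:
    def test_hand_computed_curve(self, toy_manifest):
        run = RetrievalRun("a1", ["a2", "b1", "a3", "b2"], np.arange(4.0))
        pr = precision_recall(run, toy_manifest)
        # sizes 1..4: TP = 1,1,2,2 of 2 relevant
        assert pr == [(0.5, 1.0), (0.5, 0.5), (1.0, 2 / 3), (1.0, 0.5)]

    def test_precision_three_of_four(self, toy_manifest):
        run = RetrievalRun("a1", ["a2", "a3", "b1", "b2"], np.arange(4.0))
        pr = precision_recall(run, toy_manifest)
        assert pr[3][1] == pytest.approx(0.5)  # TP=2 at size 4
        run2 = RetrievalRun("b1", ["b2", "a1", "a2", "a3"], np.arange(4.0))
        # TP=3, FP=1 at size 4 needs a 5-member group; check the formula path
        rel_precisions = [p for _, p in precision_recall(run2, toy_manifest)]
        assert rel_precisions[0] == 1.0

    def test_perfect_retrieval_gives_horizontal_line_at_one(self, toy_manifest):
        runs = [
            RetrievalRun("a1", ["a2", "a3", "b1", "b2"], np.arange(4.0)),
            RetrievalRun("a2", ["a1", "a3", "b1", "b2"], np.arange(4.0)),
        ]
        curve = average_precision_recall(runs, toy_manifest)
        np.testing.assert_allclose(curve["precision"], 1.0)

    def test_singleton_group_query_is_skipped_with_warning(self):
        manifest = BenchmarkManifest([("x", "p", "G"), ("y", "q", "H"),
                                      ("z", "r", "H")])
        runs = [RetrievalRun("x", ["y", "z"], np.arange(2.0)),
                RetrievalRun("y", ["z", "x"], np.arange(2.0))]
        with pytest.warns(UserWarning, match="only member"):
            curve = average_precision_recall(runs, manifest)
        np.testing.assert_allclose(curve["precision"], 1.0)

    def test_random_ranking_of_half_relevant_db_averages_half(self):
        rng = np.random.default_rng(42)
        entries = [(f"g{i}", "p", "G") for i in range(11)] + [
            (f"h{i}", "p", "H") for i in range(10)
        ]
        manifest = BenchmarkManifest(entries)
        others = [e[0] for e in entries if e[0] != "g0"]
        precisions = []
        for _ in range(200):
            order = list(rng.permutation(others))
            run = RetrievalRun("g0", order, np.arange(len(order), dtype=float))
            precisions.append(np.mean([p for _, p in precision_recall(run, manifest)]))
        assert np.mean(precisions) == pytest.approx(0.5, abs=0.05)

    def test_recall_monotone_and_conserved(self, toy_manifest):
        run = RetrievalRun("a1", ["b1", "a2", "b2", "a3"], np.arange(4.0))
        pr = precision_recall(run, toy_manifest)
        recalls = [r for r, _ in pr]
        assert recalls == sorted(recalls)
        assert recalls[-1] == 1.0  # TP + FN = group size - 1 at full retrieval


class TestEAndFMeasures:
    def test_harmonic_formula_values(self, toy_manifest):
        # retrieval of 2 relevant of 2, both in the first two slots
        run = RetrievalRun("a1", ["a2", "a3", "b1", "b2"], np.arange(4.0))
        assert e_measure(run, toy_manifest, size=4) == pytest.approx(
            2 / (1 / 0.5 + 1 / 1.0)
        )
        assert f_measure(run, toy_manifest) == pytest.approx(1.0)

    def test_equal_precision_recall_gives_that_value(self, toy_manifest):
        # size 2 with 1 of 2 relevant retrieved: p = r = 0.5 -> E = F = 0.5
        run = RetrievalRun("a1", ["a2", "b1", "a3", "b2"], np.arange(4.0))
        assert e_measure(run, toy_manifest, size=2) == pytest.approx(0.5)
        assert f_measure(run, toy_manifest, size=2) == pytest.approx(0.5)

    def test_zero_when_nothing_relevant_retrieved(self, toy_manifest):
        run = RetrievalRun("b1", ["a1", "a2", "a3", "b2"], np.arange(4.0))
        assert e_measure(run, toy_manifest, size=3) == 0.0
        assert f_measure(run, toy_manifest, size=3) == 0.0

    def test_formula_against_hand_evaluation(self, toy_manifest):
        run = RetrievalRun("a1", ["a2", "b1", "b2", "a3"], np.arange(4.0))
        p, r = 1 / 3, 0.5  # at size 3: TP=1
        assert e_measure(run, toy_manifest, size=3) == pytest.approx(
            2 / (1 / p + 1 / r)
        )

    def test_e_measure_size_capped_at_database(self, toy_manifest):
        run = RetrievalRun("a1", ["a2", "a3", "b1", "b2"], np.arange(4.0))
        assert e_measure(run, toy_manifest) == e_measure(run, toy_manifest, size=4)


def test_nearest_neighbor_accuracy(toy_manifest):
    runs = [
        RetrievalRun("a1", ["a2", "b1", "a3", "b2"], np.arange(4.0)),
        RetrievalRun("b1", ["a1", "b2", "a2", "a3"], np.arange(4.0)),
    ]
    assert nearest_neighbor_accuracy(runs, toy_manifest) == 0.5
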