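"""Splits, identification metrics, permutation test, sweeps, UMAP."""

import itertools

import numpy as np
import pandas as pd
import pytest

from neurofp import ModelConfig
from neurofp.core import IdentificationReport
from neurofp.evaluation import (
    SplitPlan,
    dataset_size_grid,
    identify_from_embeddings,
    macro_metrics,
    make_lro_folds,
    make_lso_folds,
    permutation_t_test,
    split_ratio_fractions,
    sweep_segment_length,
    umap_project,
)
from neurofp.models import EmbeddingSet


def _unit(v):
    return v / np.linalg.norm(v)


def _embedding_set(rng, n_subjects, n_runs, dim, spread=0.0):
    vectors = {}
    for i in range(n_subjects):
        proto = rng.standard_normal(dim)
        for j in range(n_runs):
            v = spread * proto + rng.standard_normal(dim)
            vectors[(f"sub-{i:03d}", f"run-{j + 1}")] = _unit(v)
    return EmbeddingSet(vectors=vectors)


def brute_force_identify(emb):
    """Naive double loop over the embedding dictionary."""
    keys = sorted(emb.vectors)
    rows = []
    for key in keys:
        d_pos, d_neg = np.inf, np.inf
        nearest, nearest_d = None, np.inf
        for other in keys:
            if other == key:
                continue
            d = float(((emb.vectors[key] - emb.vectors[other]) ** 2).sum())
            if other[0] == key[0]:
                d_pos = min(d_pos, d)
            else:
                d_neg = min(d_neg, d)
            if d < nearest_d:
                nearest, nearest_d = other, d
        rows.append((key, nearest[0], int(d_pos < d_neg)))
    return rows


class TestLroFolds:
    def test_sixty_plans_for_four_runs(self):
        plans = make_lro_folds(["run-1", "run-2", "run-3", "run-4"], n_reps=10)
        assert len(plans) == 60
        assert len({p.seed for p in plans}) == 60

    def test_partition_properties(self):
        runs = ["run-1", "run-2", "run-3", "run-4"]
        for plan in make_lro_folds(runs, n_reps=2):
            assert set(plan.train) | set(plan.test) == set(runs)
            assert not set(plan.train) & set(plan.test)

    def test_combinations_enumerated_once_per_repetition(self):
        runs = ["run-1", "run-2", "run-3", "run-4"]
        plans = make_lro_folds(runs, n_reps=3)
        expected = set(itertools.combinations(sorted(runs), 2))
        for rep in range(3):
            got = {p.train for p in plans if p.repetition_id == rep}
            assert got == expected


class TestLsoFolds:
    def test_138_subjects_six_folds(self):
        subjects = [f"sub-{i:03d}" for i in range(138)]
        plans = make_lso_folds(subjects, n_folds=6, n_reps=1)
        assert len(plans) == 6
        for plan in plans:
            assert len(plan.test) == 23
            assert len(plan.train) == 115

    def test_folds_disjoint_and_covering(self):
        subjects = [f"sub-{i:03d}" for i in range(20)]
        plans = make_lso_folds(subjects, n_folds=4, n_reps=2)
        for rep in range(2):
            tests = [set(p.test) for p in plans if p.repetition_id == rep]
            assert set().union(*tests) == set(subjects)
            for a, b in itertools.combinations(tests, 2):
                assert not a & b

    def test_repetitions_reshuffle(self):
        subjects = [f"sub-{i:03d}" for i in range(24)]
        plans = make_lso_folds(subjects, n_folds=3, n_reps=2, base_seed=0)
        first = [p.test for p in plans if p.repetition_id == 0]
        second = [p.test for p in plans if p.repetition_id == 1]
        assert first != second

    def test_plan_validation(self):
        with pytest.raises(ValueError):
            SplitPlan("LSO", ("a",), ("a",), 0, 0, 0)


class TestIdentifyFromEmbeddings:
    def test_perfect_clusters(self, rng):
        emb = _embedding_set(rng, 5, 3, dim=16, spread=50.0)
        rep = identify_from_embeddings(emb)
        assert rep.accuracy == 1.0
        assert rep.f1 == 1.0

    def test_chance_level_for_random_embeddings(self):
        """i.i.d. unit vectors, 10 subjects x 2 runs: the single positive is
        the nearest of 18 candidates with probability 1/18."""
        accs = []
        for seed in range(500):
            rng = np.random.default_rng(seed)
            emb = _embedding_set(rng, 10, 2, dim=8, spread=0.0)
            accs.append(identify_from_embeddings(emb).accuracy)
        accs = np.asarray(accs)
        se = accs.std(ddof=1) / np.sqrt(len(accs))
        assert abs(accs.mean() - 1 / 18) <= 3 * se

    def test_agrees_with_brute_force(self, rng):
        emb = _embedding_set(rng, 8, 3, dim=6, spread=0.7)
        rep = identify_from_embeddings(emb)
        expected = brute_force_identify(emb)
        got = list(
            zip(
                zip(rep.records["query_subject_id"],
                    rep.records["query_run_id"]),
                rep.records["predicted_subject_id"],
                rep.records["score"],
            )
        )
        for (key, pred, score), (ekey, epred, escore) in zip(got, expected):
            assert key == (ekey[0], ekey[1])
            assert pred == epred
            assert score == escore

    def test_single_run_subject_rejected(self, rng):
        emb = _embedding_set(rng, 3, 2, dim=5)
        emb.vectors[("sub-lone", "run-1")] = _unit(rng.standard_normal(5))
        with pytest.raises(ValueError, match="sub-lone"):
            identify_from_embeddings(emb)


class TestMacroMetrics:
    @staticmethod
    def _report(y_true, y_pred):
        return IdentificationReport(
            records=pd.DataFrame(
                {
                    "query_subject_id": y_true,
                    "query_run_id": ["r"] * len(y_true),
                    "predicted_subject_id": y_pred,
                    "score": [int(a == b) for a, b in zip(y_true, y_pred)],
                }
            )
        )

    def test_perfect_predictions(self):
        rep = self._report(list("aabbcc"), list("aabbcc"))
        assert macro_metrics(rep) == (1.0, 1.0, 1.0)

    def test_hand_computed_confusion(self):
        # confusion: a->a,a ; b->b,c ; c->a,c
        y_true = list("aabbcc")
        y_pred = list("aabcac")
        p, r, f1 = macro_metrics(self._report(y_true, y_pred))
        # per-class precision: a: 2/3, b: 1/1, c: 1/2 ; recall: 1, .5, .5
        assert p == pytest.approx((2 / 3 + 1.0 + 0.5) / 3)
        assert r == pytest.approx((1.0 + 0.5 + 0.5) / 3)
        f_a = 2 * (2 / 3) / (2 / 3 + 1)
        f_b = 2 * 0.5 / 1.5
        f_c = 0.5
        assert f1 == pytest.approx((f_a + f_b + f_c) / 3)

    def test_accuracy_equals_micro_recall(self):
        rep = self._report(list("aabbcc"), list("abbcac"))
        total_correct = sum(
            a == b for a, b in zip(list("aabbcc"), list("abbcac"))
        )
        assert rep.accuracy == pytest.approx(total_correct / 6)


class TestPermutationTTest:
    def test_identical_samples(self):
        t, p = permutation_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], n_perm=1000)
        assert p == 1.0

    def test_exact_enumeration_small_case(self):
        # only the original split and its mirror reach |t|; p = 2/20
        t, p = permutation_t_test([1.0, 2.0, 3.0], [4.0, 5.0, 6.0], n_perm=1000)
        assert p == pytest.approx(2 / 20)
        assert t < 0

    def test_matches_scipy_exact(self, rng):
        from scipy import stats

        x = rng.standard_normal(5)
        y = rng.standard_normal(4) + 0.8

        def abs_t(a, b):
            na, nb = len(a), len(b)
            va = np.var(a, ddof=0) * na
            vb = np.var(b, ddof=0) * nb
            sp2 = (va + vb) / (na + nb - 2)
            return abs(
                (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / na + 1 / nb))
            )

        # |t| exceedance under exhaustive reassignment
        ref = stats.permutation_test(
            (x, y), abs_t, permutation_type="independent", n_resamples=np.inf,
            alternative="greater",
        )
        _, p = permutation_t_test(x, y, n_perm=10_000)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_paired_mode_detects_shift(self, rng):
        x = rng.standard_normal(10)
        y = x + 1.0 + 0.01 * rng.standard_normal(10)
        _, p = permutation_t_test(x, y, n_perm=2000, paired=True, rng=rng)
        assert p < 0.01

    def test_degenerate_sizes_rejected(self):
        with pytest.raises(ValueError):
            permutation_t_test([1.0], [2.0, 3.0])


class TestSweepStructure:
    def test_segment_length_grid_shape(self, tiny_cohort):
        cfg = ModelConfig(
            input_dim=45, hidden_1=16, hidden_2=8, epochs=2, crops_per_epoch=1,
            batch_size=64,
        )
        res = sweep_segment_length(
            tiny_cohort.runs,
            lengths_s=[90.0, "full"],
            methods=("baseline", "lro_ce", "lro_tl", "lso_tl"),
            n_reps=2,
            cfg=cfg,
            lso_n_folds=2,
        )
        counts = res.grid.groupby(["segment_length_s", "method"]).size()
        assert (counts == 2).all()
        assert len(counts) == 2 * 4
        base = res.grid[res.grid["method"] == "baseline"]["accuracy"]
        assert base.nunique() == 1  # full-run baseline independent of length
        assert res.tests is not None
        assert set(res.tests["comparison"]) == {
            "lro_tl vs lro_ce", "lso_tl vs lro_ce"
        }

    def test_split_ratio_has_19_cells(self):
        fractions = split_ratio_fractions()
        assert len(fractions) == 19
        assert fractions[0] == pytest.approx(0.05)
        assert fractions[-1] == pytest.approx(0.95)
        np.testing.assert_allclose(np.diff(fractions), 0.05)

    def test_dataset_size_grid_endpoints(self):
        grid = dataset_size_grid()
        assert grid[0] == (92, 46)
        assert grid[-1] == (8, 4)
        trains = [t for t, _ in grid]
        assert all(a > b for a, b in zip(trains, trains[1:]))
        # each step shrinks the training side by about 10%
        for a, b in zip(trains, trains[1:]):
            assert b >= int(round(a * 0.9)) - 1

    def test_replicate_values_recompute_summary(self, tiny_cohort):
        cfg = ModelConfig(
            input_dim=45, hidden_1=16, hidden_2=8, epochs=2, crops_per_epoch=1,
            batch_size=64,
        )
        res = sweep_segment_length(
            tiny_cohort.runs, lengths_s=[90.0], methods=("lro_tl",),
            n_reps=3, cfg=cfg,
        )
        cell = res.grid[res.grid["method"] == "lro_tl"]["accuracy"]
        row = res.summary[res.summary["method"] == "lro_tl"].iloc[0]
        assert row["mean"] == pytest.approx(cell.mean())
        assert row["std"] == pytest.approx(cell.std(ddof=1))
        assert row["n_replicates"] == 3


class TestUmap:
    def test_projection_shape_and_determinism(self, rng):
        emb = _embedding_set(rng, 8, 4, dim=16, spread=8.0)
        a = umap_project(emb, seed=5)
        b = umap_project(emb, seed=5)
        assert list(a.columns) == ["subject_id", "run_id", "umap_1", "umap_2"]
        assert len(a) == 32
        np.testing.assert_allclose(
            a[["umap_1", "umap_2"]].to_numpy(), b[["umap_1", "umap_2"]].to_numpy()
        )

    def test_separated_subjects_stay_separated(self, rng):
        emb = _embedding_set(rng, 6, 6, dim=16, spread=20.0)
        coords = umap_project(emb, seed=0, n_neighbors=5)
        xy = coords[["umap_1", "umap_2"]].to_numpy()
        subs = coords["subject_id"].to_numpy()
        within, between = [], []
        for i in range(len(subs)):
            for j in range(i + 1, len(subs)):
                d = np.linalg.norm(xy[i] - xy[j])
                (within if subs[i] == subs[j] else between).append(d)
        assert np.mean(within) < np.mean(between)

    def test_too_few_points_rejected(self, rng):
        emb = _embedding_set(rng, 2, 2, dim=8)
        with pytest.raises(ValueError, match="n_neighbors"):
            umap_project(emb, seed=0, n_neighbors=15)
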