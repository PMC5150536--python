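"""F-score ranking, scan mechanics and the greedy combination step."""

import numpy as np
import pytest

import enhancerkit as ek
from enhancerkit.encoders import FeatureMatrix
from enhancerkit.evaluation import EvalMetrics
from enhancerkit.feature_selection import (
    SelectionConfig,
    coarse_threshold_scan,
    fine_dimension_scan,
    fscore,
    greedy_add,
    run_full_selection,
)

from conftest import naive_fscore


def matrix_from(values, names=None):
    values = np.asarray(values, dtype=float)
    names = names or [f"f{i}" for i in range(values.shape[1])]
    ids = [f"s{i}" for i in range(values.shape[0])]
    return FeatureMatrix(values, names, ids)


class TestFScore:
    def test_hand_arithmetic_example(self):
        # pos={2,4}, neg={0,2}: means 3/1/2 -> numerator 2, denominator 4
        m = matrix_from([[2], [4], [0], [2]])
        r = fscore(m, [1, 1, -1, -1])
        assert r.scores[0] == pytest.approx(0.5)

    def test_perfect_separator_scores_inf_and_ranks_first(self):
        m = matrix_from([[1, 0.3], [1, 0.1], [0, 0.2], [0, 0.9]])
        r = fscore(m, [1, 1, -1, -1])
        assert np.isinf(r.scores[0])
        assert r.order[0] == 0

    def test_constant_feature_scores_zero(self):
        m = matrix_from([[5, 1], [5, 2], [5, 3], [5, 4]])
        r = fscore(m, [1, 1, -1, -1])
        assert r.scores[0] == 0.0

    def test_brute_force_oracle_agreement(self, rng):
        for _ in range(10):
            n_samples = int(rng.integers(4, 21))
            X = rng.random((n_samples, 10))
            y = np.array([1] * (n_samples // 2) + [-1] * (n_samples - n_samples // 2))
            r = fscore(matrix_from(X), y)
            np.testing.assert_allclose(r.scores, naive_fscore(X, y), rtol=1e-10)

    def test_rank_stability_under_feature_shift(self, rng):
        X = rng.random((12, 6))
        y = np.array([1] * 6 + [-1] * 6)
        base = fscore(matrix_from(X), y)
        shifted = X.copy()
        shifted[:, 2] += 7.5
        after = fscore(matrix_from(shifted), y)
        keep = [i for i in range(6) if i != 2]
        np.testing.assert_allclose(after.scores[keep], base.scores[keep], rtol=1e-12)
        # a constant shift of one feature also leaves its own score unchanged
        assert after.scores[2] == pytest.approx(base.scores[2], rel=1e-9)

    def test_small_class_rejected(self):
        m = matrix_from([[1], [2], [3]])
        with pytest.raises(ValueError, match="2 samples"):
            fscore(m, [1, -1, -1])

    def test_tie_break_by_original_index(self):
        # two identical features: equal scores, ascending index order
        m = matrix_from([[1, 1], [2, 2], [0, 0], [1, 1]])
        r = fscore(m, [1, 1, -1, -1])
        assert list(r.order) == [0, 1]


def counting_evaluator(best_n):
    """Deterministic fake jackknife: accuracy peaks at exactly best_n features."""

    def ev(X, y):
        d = X.shape[1]
        correct = len(y) - abs(d - best_n)
        correct = max(0, correct)
        tp = min(correct, int(np.sum(np.asarray(y) > 0)))
        tn = correct - tp
        fn = int(np.sum(np.asarray(y) > 0)) - tp
        fp = int(np.sum(np.asarray(y) < 0)) - tn
        return EvalMetrics(tp=tp, tn=tn, fp=fp, fn=fn)

    return ev


class TestScanMechanics:
    def setup_method(self):
        rng = np.random.default_rng(5)
        self.X = rng.random((10, 6))
        self.y = np.array([1] * 5 + [-1] * 5)
        self.m = matrix_from(self.X)
        self.r = fscore(self.m, self.y)

    def test_threshold_zero_retains_all(self):
        res = coarse_threshold_scan(
            self.r, self.m, self.y, counting_evaluator(6), w_start=0.0,
            w_end=0.0, step=0.1,
        )
        assert len(res.selected) == 6

    def test_threshold_above_max_skipped(self):
        top = self.r.max_finite_score
        res = coarse_threshold_scan(
            self.r, self.m, self.y, counting_evaluator(3),
            w_start=0.0, w_end=top * 2, step=top * 0.9,
        )
        invalid = [p for p in res.trajectory if p.metrics is None]
        assert invalid and invalid[-1].n_features == 0

    def test_tie_goes_to_larger_threshold(self):
        # evaluator constant -> every threshold ties -> fewest features win
        res = coarse_threshold_scan(
            self.r, self.m, self.y, counting_evaluator(0),
            w_start=0.0, w_end=self.r.max_finite_score, step=0.01,
        )
        valid = [p for p in res.trajectory if p.metrics is not None]
        assert len(res.selected) == min(p.n_features for p in valid)

    def test_fine_scan_full_range_is_no_selection(self):
        res = fine_dimension_scan(
            self.r, self.m, self.y, counting_evaluator(6), d_min=6, d_max=6
        )
        assert len(res.selected) == 6

    def test_fine_scan_single_top_feature(self):
        res = fine_dimension_scan(
            self.r, self.m, self.y, counting_evaluator(1), d_min=1, d_max=1
        )
        assert res.selected == [self.r.feature_names[self.r.order[0]]]

    def test_fine_scan_tie_goes_to_smaller_d(self):
        res = fine_dimension_scan(
            self.r, self.m, self.y, counting_evaluator(0), d_min=1, d_max=6, step=1
        )
        assert len(res.selected) == 1

    def test_fine_scan_d_max_bounds_checked(self):
        with pytest.raises(ValueError, match="exceeds"):
            fine_dimension_scan(
                self.r, self.m, self.y, counting_evaluator(3), d_min=1, d_max=7
            )

    def test_best_acc_matches_trajectory_max(self):
        res = fine_dimension_scan(
            self.r, self.m, self.y, counting_evaluator(4), d_min=1, d_max=6, step=1
        )
        assert res.best_acc == max(p.metrics.acc for p in res.trajectory)


class TestGreedyAdd:
    def setup_method(self):
        rng = np.random.default_rng(11)
        base_col = np.concatenate([rng.normal(1, 0.2, 10), rng.normal(-1, 0.2, 10)])
        dup = base_col.copy()
        noise = rng.random(20)
        self.y = np.array([1] * 10 + [-1] * 10)
        self.m = matrix_from(
            np.column_stack([base_col, dup, noise]), ["base", "dup", "noise"]
        )
        self.ev = ek.make_matrix_evaluator(ek.SvmConfig(C=2.0, gamma=0.5))

    def base_result(self):
        metrics = self.ev(self.m.subset(["base"]).values, self.y)
        return ek.SelectionResult(["base"], [], metrics.acc, stage="base")

    def test_k_max_zero_returns_base(self):
        cand = fscore(self.m.subset(["dup", "noise"]), self.y)
        res = greedy_add(self.base_result(), cand, self.m, self.y, self.ev, k_max=0)
        assert res.selected == ["base"]

    def test_duplicate_column_rejected(self):
        cand = fscore(self.m.subset(["dup"]), self.y)
        res = greedy_add(self.base_result(), cand, self.m, self.y, self.ev, k_max=2)
        assert "dup" not in res.selected  # no accuracy change -> strict reject

    def test_accuracy_never_decreases(self):
        base = self.base_result()
        cand = fscore(self.m.subset(["dup", "noise"]), self.y)
        res = greedy_add(base, cand, self.m, self.y, self.ev, k_max=2)
        assert res.best_acc >= base.best_acc


@pytest.fixture(scope="module")
def small_dataset():
    spec = ek.two_class_spec(n_per_class=50, n=60, effect_size=1.0, seed=3)
    return ek.generate(spec)


@pytest.fixture(scope="module")
def config():
    return SelectionConfig(
        svm=ek.SvmConfig(C=2.0, gamma=0.5),
        bpb_coarse_step=0.02,
        psenc_coarse_step=0.05,
        fine_window=6,
    )


class TestFullSelection:
    def test_planted_nc_composition_shift_recovered(self):
        # C-composition shift only: NC_C must top the NC ranking
        spec = ek.two_class_spec(
            n_per_class=200, n=100, n_positional=0, boost=0.0,
            c_shift=0.08, trimer_mult=1.0, seed=2,
        )
        ds = ek.generate(spec)
        recs, y = ds.layer1()
        m = ek.encode_dataset(recs, families=["NC"])
        r = fscore(m, y)
        assert r.feature_names[r.order[0]] == "NC_C"

    def test_scans_disabled_returns_everything(self, small_dataset, config):
        from dataclasses import replace

        cfg = replace(
            config, run_bpb_scan=False, run_nc_greedy=False, run_psenc_scan=False
        )
        res = run_full_selection(small_dataset, "I", cfg)
        assert len(res.selected) == 2 * 60 + 4 + 64
        assert res.stage == "no_selection"

    def test_monotone_accept_and_structure(self, small_dataset, config):
        res = run_full_selection(small_dataset, "I", config)
        first = res.stages["bpb_coarse"]
        assert res.best_acc >= first.best_acc - 1e-12
        assert res.selected  # non-empty
        # selected names are unique and all exist in the known families
        assert len(set(res.selected)) == len(res.selected)

    def test_selection_deterministic(self, small_dataset, config):
        r1 = run_full_selection(small_dataset, "I", config)
        r2 = run_full_selection(small_dataset, "I", config)
        assert r1.selected == r2.selected
        assert r1.best_acc == r2.best_acc

    def test_trajectory_serialisation(self, small_dataset, config):
        res = run_full_selection(small_dataset, "I", config)
        d = res.stages["bpb_coarse"].to_dict()
        assert d["selected"]
        tsv = res.stages["bpb_coarse"].trajectory_tsv()
        assert tsv.startswith("param\tn_features")
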