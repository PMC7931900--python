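"""Cross-validation planning: fold arithmetic, coverage and leakage guards."""

import numpy as np
import pytest

from vegmem.crossval import (RunConfig, aggregate_repetitions, make_plan,
                             make_spatial_folds, make_temporal_folds)


class TestSpatialFolds:
    def test_blocks_share_fold(self, rng):
        retained = np.ones(100, bool)
        fold = make_spatial_folds((10, 10), retained, block=5, k=4,
                                  anchor=(0, 0), rng=rng).reshape(10, 10)
        for r0 in (0, 5):
            for c0 in (0, 5):
                blockvals = fold[r0:r0 + 5, c0:c0 + 5]
                assert np.unique(blockvals).size == 1

    def test_forced_assignment_counts(self, rng):
        # with 4 blocks on a 10x10 grid each fold must hold 25 pixels when
        # the draw assigns all 4 folds (retry loop guarantees it)
        fold = make_spatial_folds((10, 10), np.ones(100, bool), block=5, k=4,
                                  anchor=(0, 0), rng=np.random.default_rng(0))
        counts = np.bincount(fold)[1:]
        assert sorted(counts.tolist()) == [25, 25, 25, 25]

    def test_anchor_shifts_boundaries(self, rng):
        fold = make_spatial_folds((10, 10), np.ones(100, bool), block=5, k=4,
                                  anchor=(2, 3), rng=rng).reshape(10, 10)
        # edge fragments form their own blocks: rows split at 2,7; cols at 3,8
        for rr in ((0, 2), (2, 7), (7, 10)):
            for cc in ((0, 3), (3, 8), (8, 10)):
                block = fold[rr[0]:rr[1], cc[0]:cc[1]]
                assert np.unique(block).size == 1

    def test_k_too_small(self, rng):
        with pytest.raises(ValueError):
            make_spatial_folds((10, 10), np.ones(100, bool), k=2, rng=rng)


class TestTemporalFolds:
    def test_study_layout(self):
        folds = make_temporal_folds(33, 9, 1, 4, start_year=1983)
        assert [f.start_year for f in folds] == [1983, 1991, 1999, 2007]
        assert all(f.n_years == 9 for f in folds)
        # consecutive spans share exactly the warmup year
        for a, b in zip(folds, folds[1:]):
            assert a.end_year - 1 == b.start_year

    def test_evaluable_period_excludes_warmups(self):
        folds = make_temporal_folds(33, 9, 1, 4, start_year=1983)
        evaluable = set()
        for f in folds:
            evaluable |= set(range(f.start_year + f.warmup_years, f.end_year))
        assert min(evaluable) == 1984 and max(evaluable) == 2015
        assert len(evaluable) == 32

    def test_no_overlap_variant(self):
        folds = make_temporal_folds(32, 8, 0, 4, start_year=2000)
        assert [f.start_year for f in folds] == [2000, 2008, 2016, 2024]

    def test_arithmetic_violation(self):
        with pytest.raises(ValueError, match="33"):
            make_temporal_folds(33, 9, 0, 4)


class TestPlan:
    def test_default_run_count(self, rng):
        plan = make_plan(4, 4, 10, rng)
        assert len(plan) == 160

    def test_single_repetition_coverage(self, rng):
        """16 runs; per repetition the test sets partition the evaluable
        pixel-time domain exactly once."""
        plan = make_plan(4, 4, 1, rng)
        assert len(plan) == 16
        retained = np.ones(100, bool)
        folds = make_temporal_folds(33, 9, 1, 4, start_year=1983)
        count = np.zeros((100, 33), int)  # per pixel-year
        spatial_cache = {}
        for run in plan:
            key = (run.anchor, run.spatial_seed)
            if key not in spatial_cache:
                spatial_cache[key] = make_spatial_folds(
                    (10, 10), retained, block=5, k=4, anchor=run.anchor,
                    rng=np.random.default_rng(run.spatial_seed))
            spat = spatial_cache[key]
            tf = folds[run.test_temporal - 1]
            pix = np.flatnonzero(spat == run.test_spatial)
            years = np.arange(tf.start_year + tf.warmup_years, tf.end_year)
            count[np.ix_(pix, years - 1983)] += 1
        assert (count[:, 1:] == 1).all()   # every evaluable year exactly once
        assert (count[:, 0] == 0).all()    # the first warmup year never tested

    def test_leakage_guards(self, rng):
        plan = make_plan(4, 4, 1, rng)
        folds = make_temporal_folds(33, 9, 1, 4, start_year=1983)
        for run in plan:
            spat = make_spatial_folds(
                (10, 10), np.ones(100, bool), block=5, k=4, anchor=run.anchor,
                rng=np.random.default_rng(run.spatial_seed)).reshape(10, 10)
            # no training pixel shares a 5x5 block with a test pixel
            test_rows = np.isin(spat, [run.test_spatial])
            train_rows = np.isin(spat, list(run.train_spatial))
            assert not np.any(test_rows & train_rows)
            # training-loss years never intersect evaluated test years:
            # only the declared warmup years may be shared between spans
            test_f = folds[run.test_temporal - 1]
            train_loss_years = set()
            for f in folds:
                if f.index != test_f.index:
                    train_loss_years |= set(
                        range(f.start_year + f.warmup_years, f.end_year))
            test_eval = set(range(test_f.start_year + test_f.warmup_years,
                                  test_f.end_year))
            assert not (train_loss_years & test_eval)

    def test_plan_determinism(self):
        a = make_plan(4, 4, 3, np.random.default_rng(9))
        b = make_plan(4, 4, 3, np.random.default_rng(9))
        assert a == b

    def test_insufficient_rotations_error(self, rng):
        with pytest.raises(ValueError, match="coverage"):
            make_plan(4, 4, 1, rng, rotations=2)

    def test_role_disjointness_enforced(self):
        with pytest.raises(ValueError):
            RunConfig(1, (1, 2), 2, 3, 1, (0, 0), 0)


class TestAggregateRepetitions:
    def test_identical_reps(self, rng):
        p = np.tile(rng.normal(size=(1, 4, 6)), (5, 1, 1))
        np.testing.assert_array_equal(aggregate_repetitions(p), p[0])

    def test_median_of_ten(self):
        p = np.arange(1, 11, dtype=float).reshape(10, 1, 1)
        assert aggregate_repetitions(p)[0, 0] == pytest.approx(5.5)

    def test_single_rep_passthrough(self, rng):
        p = rng.normal(size=(1, 3, 4))
        np.testing.assert_array_equal(aggregate_repetitions(p), p[0])

    def test_missing_anywhere_invalidates(self):
        p = np.ones((3, 2, 2))
        p[1, 0, 1] = np.nan
        out = aggregate_repetitions(p)
        assert np.isnan(out[0, 1]) and np.isfinite(out[1, 1])

    def test_zero_reps_error(self):
        with pytest.raises(ValueError):
            aggregate_repetitions(np.empty((0, 2, 2)))
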