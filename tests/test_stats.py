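"""Windowed group statistics, Bonferroni control, seed analyses."""

import numpy as np
import pytest
from scipy import stats as sps

from hddot.preprocess import BLOCK_GRID
from hddot.reconstruct import CorticalImageSeries
from hddot.stats import (
    SeedRegion,
    WindowSpec,
    define_seed,
    one_sample_tmap,
    paired_tmap,
    seed_timecourse,
    window_values,
)


def make_images(arrays, coverage=None):
    out = []
    for a in arrays:
        a = np.asarray(a, float)
        out.append(
            CorticalImageSeries(
                hbo=a, hbr=-0.3 * a, grid=BLOCK_GRID.copy(), coverage=coverage
            )
        )
    return out


class TestWindowValues:
    def test_window_spec_validation(self):
        with pytest.raises(ValueError):
            WindowSpec(15.0, 11.0)
        with pytest.raises(ValueError):
            WindowSpec(-1.0, 5.0)

    def test_11_to_15s_window_has_17_grid_samples(self):
        w = WindowSpec(11.0, 15.0)
        assert w.grid_mask(BLOCK_GRID).sum() == 17

    def test_16_participants_concatenate_to_272(self):
        rng = np.random.default_rng(0)
        images = make_images(rng.standard_normal((16, 5, 89)))
        vecs = window_values(images, WindowSpec(11.0, 15.0))
        assert vecs.shape == (5, 16 * 17)

    def test_single_instant_window(self):
        images = make_images(np.zeros((4, 3, 89)))
        vecs = window_values(images, WindowSpec(11.9, 12.1))
        assert vecs.shape == (3, 4)

    def test_all_zero_images_give_zero_vector(self):
        images = make_images(np.zeros((2, 3, 89)))
        assert not window_values(images, WindowSpec(11, 15)).any()

    def test_uncovered_participant_contributes_nan(self):
        cov0 = np.array([True, False, True])
        images = make_images(np.ones((2, 3, 89)))
        images[0].coverage = cov0
        vecs = window_values(images, WindowSpec(11, 15))
        assert np.isnan(vecs[1, :17]).all()
        assert np.isfinite(vecs[1, 17:]).all()


class TestOneSampleTmap:
    def test_all_zero_values(self):
        vecs = np.zeros((4, 30))
        sm = one_sample_tmap(vecs, np.ones(4, bool))
        # zero variance -> excluded from significance, t undefined
        assert not sm.significant.any()

    def test_matches_hand_coded_t(self):
        rng = np.random.default_rng(1)
        vecs = 0.5 + rng.standard_normal((6, 40))
        sm = one_sample_tmap(vecs, np.ones(6, bool))
        for i in range(6):
            v = vecs[i]
            t_hand = v.mean() / (v.std(ddof=1) / np.sqrt(len(v)))
            assert sm.t[i] == pytest.approx(t_hand, abs=1e-10)
            ref = sps.ttest_1samp(v, 0.0)
            assert sm.p[i] == pytest.approx(ref.pvalue, rel=1e-10)

    def test_untested_nodes_nan(self):
        vecs = np.ones((3, 10))
        tested = np.array([True, False, True])
        sm = one_sample_tmap(vecs, tested)
        assert np.isnan(sm.t[1]) and not sm.significant[1]
        assert sm.n_tested == 2

    def test_bonferroni_familywise_error_controlled(self):
        """Null simulation: FWER across 1000 nodes stays near alpha."""
        rng = np.random.default_rng(42)
        n_nodes, n_vals, reps = 1000, 20, 500
        fw_errors = 0
        crit = sps.t.ppf(1 - (0.05 / n_nodes) / 2, df=n_vals - 1)
        for _ in range(reps):
            vals = rng.standard_normal((n_nodes, n_vals))
            tt = vals.mean(axis=1) / (vals.std(axis=1, ddof=1) / np.sqrt(n_vals))
            fw_errors += np.any(np.abs(tt) > crit)
        fwer = fw_errors / reps
        # binomial 3-sigma band around the nominal 0.05
        assert fwer <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_tmap_agrees_with_vectorised_null(self):
        """Spot-check the StatMap path against the fast null used above."""
        rng = np.random.default_rng(7)
        vals = rng.standard_normal((50, 20))
        sm = one_sample_tmap(vals, np.ones(50, bool))
        tt = vals.mean(axis=1) / (vals.std(axis=1, ddof=1) / np.sqrt(20))
        np.testing.assert_allclose(sm.t, tt, atol=1e-10)

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        vals = rng.standard_normal((5, 25)) + 0.3
        a = one_sample_tmap(vals, np.ones(5, bool))
        b = one_sample_tmap(1e6 * vals, np.ones(5, bool))
        np.testing.assert_allclose(a.t, b.t, rtol=1e-9)


class TestPairedTmap:
    def test_equal_conditions_give_zero_t(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal((4, 30))
        sm = paired_tmap(a, a.copy(), np.ones(4, bool))
        # zero-variance differences: t undefined, nothing significant
        assert not sm.significant.any()

    def test_constant_offset_positive_and_matches_closed_form(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal((3, 40))
        b = a - 0.5
        sm = paired_tmap(a, b, np.ones(3, bool))
        assert np.all(sm.t > 0)
        for i in range(3):
            ref = sps.ttest_rel(a[i], b[i])
            assert sm.t[i] == pytest.approx(ref.statistic, rel=1e-9)
            assert sm.p[i] == pytest.approx(ref.pvalue, rel=1e-9)

    def test_pair_order_permutation_invariance(self):
        rng = np.random.default_rng(2)
        a, b = rng.standard_normal((2, 4, 30))
        perm = rng.permutation(30)
        sm1 = paired_tmap(a, b, np.ones(4, bool))
        sm2 = paired_tmap(a[:, perm], b[:, perm], np.ones(4, bool))
        np.testing.assert_allclose(sm1.t, sm2.t, atol=1e-10)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_tmap(np.zeros((3, 5)), np.zeros((3, 6)), np.ones(3, bool))


class TestSeeds:
    @pytest.fixture(scope="class")
    def vertices(self):
        rng = np.random.default_rng(0)
        return 50.0 * rng.standard_normal((200, 3))

    def test_global_max_is_centre(self, vertices):
        vals = np.linspace(0, 1, 200)
        seed = define_seed(vals, np.ones(200, bool), vertices)
        assert seed.centre == 199

    def test_peak_negative_on_negated_map(self, vertices):
        rng = np.random.default_rng(1)
        vals = rng.standard_normal(200)
        pos = define_seed(vals, np.ones(200, bool), vertices, polarity="peak-positive")
        neg = define_seed(-vals, np.ones(200, bool), vertices, polarity="peak-negative")
        assert pos.centre == neg.centre

    def test_zero_radius_members_is_centre(self, vertices):
        vals = np.arange(200.0)
        seed = define_seed(vals, np.ones(200, bool), vertices, radius=0.0)
        assert list(seed.members) == [seed.centre]

    def test_members_within_radius(self, vertices):
        vals = np.arange(200.0)
        seed = define_seed(vals, np.ones(200, bool), vertices, radius=25.0)
        d = np.linalg.norm(vertices[seed.members] - vertices[seed.centre], axis=1)
        assert d.max() <= 25.0 + 1e-9
        assert seed.centre in seed.members

    def test_identical_images_give_zero_sem(self, vertices):
        img = np.outer(np.arange(10.0), np.ones(89))
        images = make_images([img] * 5)
        seed = SeedRegion(centre=3, members=np.array([3, 4]), polarity="peak-positive")
        tc = seed_timecourse(images, seed)
        np.testing.assert_allclose(tc["sem"], 0.0, atol=1e-12)
        np.testing.assert_allclose(tc["mean"], img[[3, 4]].mean(axis=0), atol=1e-12)

    def test_single_participant_sem_zero_by_convention(self):
        images = make_images(np.ones((1, 5, 89)))
        seed = SeedRegion(centre=0, members=np.array([0, 1]), polarity="peak-positive")
        tc = seed_timecourse(images, seed)
        assert int(tc["n"]) == 1
        np.testing.assert_allclose(tc["sem"], 0.0)

    def test_uncovered_participant_excluded(self):
        images = make_images(np.ones((3, 5, 89)))
        images[1].coverage = np.zeros(5, bool)
        seed = SeedRegion(centre=0, members=np.array([0]), polarity="peak-positive")
        tc = seed_timecourse(images, seed)
        assert int(tc["n"]) == 2
        assert list(tc["excluded"]) == [1]
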