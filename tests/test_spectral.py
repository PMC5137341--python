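import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import Point, Polygon

from canopycarbon.io_formats import HyperCube
from canopycarbon.spectral import (ClassifierSpec, ConfusionMatrix,
                                   classify_itcs, confusion_metrics,
                                   extract_sunlit_pixels, jm_distance,
                                   load_packaged_confusion, normalize_pixels,
                                   PixelSample, sffs_select, train_classifier)


def cube_from(values, res=1.0):
    values = np.asarray(values, dtype=float)
    return HyperCube(0.0, values.shape[1] * res, res, values,
                     np.linspace(400, 990, values.shape[0]))


class TestNormalize:
    def test_arithmetic(self):
        cube = cube_from(np.array([1.0, 2.0, 3.0, 4.0]).reshape(4, 1, 1))
        out = normalize_pixels(cube)
        np.testing.assert_allclose(out.band_values[:, 0, 0], [0.1, 0.2, 0.3, 0.4])

    def test_idempotent(self):
        cube = cube_from(np.array([0.1, 0.2, 0.3, 0.4]).reshape(4, 1, 1))
        out = normalize_pixels(normalize_pixels(cube))
        np.testing.assert_allclose(out.band_values[:, 0, 0], [0.1, 0.2, 0.3, 0.4])

    def test_every_pixel_sums_to_one(self, rng):
        cube = cube_from(rng.random((7, 9, 11)) + 0.01)
        out = normalize_pixels(cube)
        np.testing.assert_allclose(out.band_values.sum(axis=0), 1.0, atol=1e-9)

    def test_zero_sum_pixel_flagged_nodata(self):
        v = np.ones((3, 2, 2))
        v[:, 0, 0] = 0.0
        out = normalize_pixels(cube_from(v))
        assert (out.band_values[:, 0, 0] == out.nodata).all()


class FakeITC:
    def __init__(self, id, polygon, height=20.0):
        self.id = id
        self.polygon = polygon
        self.height = height


class TestSunlitExtraction:
    def test_median_rule_on_four_pixels(self):
        # 4 pixels in a row, brightnesses 1,2,3,4 -> median 2.5 -> keep 3 and 4
        v = np.stack([np.array([[1.0, 2.0, 3.0, 4.0]])] * 2)
        cube = cube_from(v)
        itc = FakeITC(1, Polygon([(-1, -1), (5, -1), (5, 2), (-1, 2)]))
        samples = extract_sunlit_pixels(cube, [itc])
        kept = sorted(s.feature_vector[0] for s in samples)
        assert kept == [3.0, 4.0]

    def test_single_pixel_itc_keeps_its_pixel(self):
        cube = cube_from(np.ones((3, 3, 3)))
        itc = FakeITC(2, Point(1.5, 1.5).buffer(0.6))
        samples = extract_sunlit_pixels(cube, [itc])
        assert len(samples) == 1 and samples[0].itc_id == 2

    def test_selected_brighter_than_rejected(self, rng):
        # radial brightness gradient: shaded crown edges are rejected
        n = 11
        v = np.empty((4, n, n))
        yy, xx = np.mgrid[0:n, 0:n]
        bright = 2.0 - np.hypot(xx - n // 2, yy - n // 2) / n
        v[:] = bright
        cube = cube_from(v)
        itc = FakeITC(3, Point(n / 2, n / 2).buffer(n / 2 - 0.5))
        samples = extract_sunlit_pixels(cube, [itc])
        sel_mean = np.mean([s.feature_vector.mean() for s in samples])
        assert sel_mean > bright.mean()


class TestJMDistance:
    def test_identical_distributions_give_zero(self, rng):
        x = rng.normal(0, 1, (200, 3))
        assert jm_distance(x, x) == pytest.approx(0.0, abs=1e-9)

    def test_1d_closed_form(self):
        # equal unit variances, means 0 and 2: B = 0.5, JM = 2(1-e^-0.5)
        a = np.array([[-1.0], [0.0], [1.0]])       # mean 0, var 1
        b = a + 2.0
        # tolerance reflects the 1e-6 diagonal covariance loading
        assert jm_distance(a, b) == pytest.approx(2 * (1 - np.exp(-0.5)), abs=1e-5)

    def test_monotone_in_mean_separation(self, rng):
        a = rng.normal(0, 1, (500, 2))
        prev = -1.0
        for shift in (0.5, 1.0, 2.0, 4.0, 8.0):
            jm = jm_distance(a, a + shift)
            assert jm > prev
            prev = jm
        assert prev < 2.0

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 10_000), st.floats(0.1, 5.0))
    def test_bounds_and_symmetry(self, seed, shift):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, (50, 2))
        b = rng.normal(shift, 1.3, (60, 2))
        jm = jm_distance(a, b)
        assert 0.0 <= jm <= 2.0
        assert jm == pytest.approx(jm_distance(b, a), rel=1e-9)


class TestSFFS:
    def test_finds_informative_features(self, rng):
        # 2 informative features out of 5; exhaustive search agrees
        n = 120
        y = np.repeat([0, 1, 2], n // 3)
        X = rng.normal(0, 1, (n, 5))
        X[:, 1] += y * 2.5
        X[:, 3] += (y == 2) * 3.0
        got = sffs_select(X, y, 2)
        from itertools import combinations
        from canopycarbon.spectral import _criterion
        best = max(combinations(range(5), 2),
                   key=lambda f: _criterion(X, y, list(f)))
        assert got == sorted(best) == [1, 3]

    def test_target_all_is_identity(self, rng):
        X = rng.normal(0, 1, (60, 4))
        y = np.repeat([0, 1], 30)
        assert sffs_select(X, y, 4) == [0, 1, 2, 3]

    def test_fewer_than_two_classes_is_error(self, rng):
        with pytest.raises(ValueError):
            sffs_select(rng.normal(0, 1, (30, 4)), np.zeros(30), 2)

    def test_floating_search_at_least_as_good_as_pure_forward(self, rng):
        from canopycarbon.spectral import _criterion

        def pure_forward(X, y, k):
            sel = []
            for _ in range(k):
                cand = [f for f in range(X.shape[1]) if f not in sel]
                sel.append(max(cand, key=lambda f: _criterion(X, y, sel + [f])))
            return sorted(sel)

        for trial in range(20):
            r = np.random.default_rng(trial)
            n = 90
            y = np.repeat([0, 1, 2], n // 3)
            X = r.normal(0, 1, (n, 6))
            for j in range(3):
                X[:, j] += (y == j) * r.uniform(0.5, 2.0)
            sffs = _criterion(X, y, sffs_select(X, y, 3))
            fwd = _criterion(X, y, pure_forward(X, y, 3))
            assert sffs >= fwd - 1e-9


class TestClassifier:
    def test_separable_classes_reach_perfect_training_accuracy(self, rng):
        X0 = rng.normal(0, 0.3, (40, 3))
        X1 = rng.normal(5, 0.3, (40, 3))
        samples = [PixelSample(x, itc_id=i, class_label="a")
                   for i, x in enumerate(X0)] + \
                  [PixelSample(x, itc_id=100 + i, class_label="b")
                   for i, x in enumerate(X1)]
        spec = train_classifier(samples, ClassifierSpec(seed=0))
        X = np.vstack([s.feature_vector for s in samples])
        y = np.array([s.class_label for s in samples])
        assert (spec.model.predict(X) == y).all()

    def test_shuffled_labels_score_near_chance(self, rng):
        from sklearn.model_selection import cross_val_score
        X = rng.normal(0, 1, (200, 4))
        y = rng.integers(0, 2, 200).astype(str)
        samples = [PixelSample(x, itc_id=i, class_label=lab)
                   for i, (x, lab) in enumerate(zip(X, y))]
        spec = train_classifier(samples, ClassifierSpec(
            c_grid=(1.0,), gamma_grid=(0.1,), seed=0))
        scores = cross_val_score(spec.model, X, y, cv=5)
        assert abs(scores.mean() - 0.5) < 0.15  # binomial error at n=200

    def test_small_class_excluded(self, rng):
        samples = [PixelSample(rng.normal(0, 1, 3), i, "a") for i in range(20)] \
            + [PixelSample(rng.normal(4, 1, 3), 100 + i, "b") for i in range(20)] \
            + [PixelSample(rng.normal(8, 1, 3), 200 + i, "c") for i in range(3)]
        spec = train_classifier(samples, ClassifierSpec(seed=0))
        assert set(spec.classes_) == {"a", "b"}


class TestMajorityRule:
    def _fit(self, rng):
        X0 = rng.normal(0, 0.5, (30, 2))
        X1 = rng.normal(4, 0.5, (30, 2))
        samples = [PixelSample(x, 0, "A") for x in X0] + \
                  [PixelSample(x, 1, "B") for x in X1]
        return train_classifier(samples, ClassifierSpec(
            c_grid=(10.0,), gamma_grid=(0.1,), seed=0))

    def test_majority_vote(self, rng):
        spec = self._fit(rng)
        px = [PixelSample(rng.normal(0, 0.5, 2), 7) for _ in range(3)] + \
             [PixelSample(rng.normal(4, 0.5, 2), 7)]
        assert classify_itcs(spec, px)[7] == "A"

    def test_single_pixel_itc(self, rng):
        spec = self._fit(rng)
        px = [PixelSample(np.array([4.1, 3.9]), 42)]
        assert classify_itcs(spec, px)[42] == "B"

    def test_vote_equals_brute_force_count_and_order_invariance(self, rng):
        spec = self._fit(rng)
        px = [PixelSample(rng.normal(rng.choice([0, 4]), 0.5, 2),
                          int(rng.integers(0, 6))) for _ in range(60)]
        got = classify_itcs(spec, px)
        X = np.vstack([s.feature_vector for s in px])
        pred = spec.model.predict(X)
        for itc_id in set(s.itc_id for s in px):
            votes = {}
            for s, p in zip(px, pred):
                if s.itc_id == itc_id:
                    votes[p] = votes.get(p, 0) + 1
            top = max(votes.values())
            winners = [k for k, v in votes.items() if v == top]
            if len(winners) == 1:
                assert got[itc_id] == winners[0]
            else:
                assert got[itc_id] in winners
        shuffled = [px[i] for i in rng.permutation(len(px))]
        assert classify_itcs(spec, shuffled) == got


class TestConfusionMetrics:
    def test_perfect_diagonal(self):
        cm = ConfusionMatrix(np.diag([5, 8, 12]), ["a", "b", "c"])
        s = confusion_metrics(cm)
        assert s.overall_acc_pct == 100.0
        assert s.kappa == pytest.approx(1.0)

    def test_kappa_below_overall_and_bounded(self, rng):
        for _ in range(20):
            counts = rng.integers(0, 30, (4, 4))
            if counts.sum() == 0:
                continue
            s = confusion_metrics(ConfusionMatrix(counts, list("abcd")))
            assert -1.0 <= s.kappa <= 1.0
            assert s.kappa <= s.overall_acc_pct / 100.0 + 1e-12

    def test_packaged_testset_matrix_reproduces_printed_row(self):
        s = confusion_metrics(load_packaged_confusion())
        expected = {"Abies alba": 76.2, "Angiosperm": 91.3, "Picea abies": 79.6,
                    "Larix decidua": 88.1, "Pinus cembra": 73.2,
                    "Pinus nigra": 87.5, "Pinus sylvestris": 100.0}
        for lab, val in expected.items():
            assert s.producers_acc_pct[lab] == pytest.approx(val, abs=0.05)
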