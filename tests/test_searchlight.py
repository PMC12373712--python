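"""Searchlight geometry, partitions, LDA and accuracy maps."""

import numpy as np
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from slmvpa.searchlight import (
    build_searchlights,
    cross_phase_decode,
    lda_classify,
    make_partitions,
    searchlight_accuracy_map,
)
from slmvpa.simulate import VolumeGrid

from conftest import make_patterns, two_class_noise_patterns


def brute_force_sphere_offsets(radius_mm=4.4, voxel_mm=2.2):
    """Exhaustive lattice enumeration of offsets within the radius."""
    r = radius_mm / voxel_mm
    hits = []
    m = int(np.ceil(r))
    for i in range(-m, m + 1):
        for j in range(-m, m + 1):
            for k in range(-m, m + 1):
                if i * i + j * j + k * k <= r * r + 1e-12:
                    hits.append((i, j, k))
    return hits


class TestGeometry:
    def test_interior_center_has_33_members(self):
        """4.4 mm radius at 2.2 mm voxels: 33 voxels (offset norm^2 <= 4)."""
        offsets = brute_force_sphere_offsets()
        assert len(offsets) == 33
        grid = VolumeGrid((9, 9, 9))
        voxels = np.arange(grid.n_voxels)  # solid mask
        spheres = build_searchlights(voxels, grid)
        center = grid.ijk_to_flat(np.array([4, 4, 4]))
        sph = next(s for s in spheres if s.center_voxel == center)
        assert len(sph.member_cols) == 33
        got = {tuple(r) for r in grid.flat_to_ijk(voxels[sph.member_cols]) - 4}
        assert got == set(offsets)

    def test_radius_below_voxel_size_gives_singleton(self):
        grid = VolumeGrid((5, 5, 5))
        spheres = build_searchlights(np.arange(125), grid, radius_mm=2.0)
        assert all(len(s.member_cols) == 1 for s in spheres)
        assert all(s.member_cols[0] == s.center_col for s in spheres)

    def test_boundary_center_members_subset_of_mask(self):
        grid = VolumeGrid((9, 9, 9))
        voxels = np.arange(200)  # partial mask
        spheres = build_searchlights(voxels, grid)
        for s in spheres:
            assert np.isin(voxels[s.member_cols], voxels).all()
            assert len(s.member_cols) <= 33
            assert s.center_col in s.member_cols

    def test_empty_voxel_set_raises(self):
        with pytest.raises(ValueError, match="empty"):
            build_searchlights(np.array([]), VolumeGrid((5, 5, 5)))


class TestPartitions:
    def test_folds_partition_trials_and_balance_training(self):
        labels = np.array(["fast"] * 24 + ["slow"] * 16)
        chunks = np.tile(np.arange(2), 20)
        scheme = make_partitions(labels, chunks, seed=3)
        assert len(scheme.splits) == 16
        y = scheme.y
        for r in range(4):
            tests = [scheme.splits[4 * r + f][1] for f in range(4)]
            assert sorted(np.concatenate(tests)) == list(range(40))
            for train, test in (scheme.splits[4 * r + f] for f in range(4)):
                assert len(np.intersect1d(train, test)) == 0
                counts = np.bincount(y[train], minlength=2)
                assert counts[0] == counts[1]  # balanced training split

    def test_test_folds_hold_a_quarter_of_trials(self):
        labels = np.array(["a", "b"] * 20)
        scheme = make_partitions(labels, np.zeros(40, int), seed=1)
        for _, test in scheme.splits:
            assert len(test) == 10

    def test_deterministic_given_seed(self):
        labels = np.array(["a", "b"] * 16)
        s1 = make_partitions(labels, np.zeros(32, int), seed=9)
        s2 = make_partitions(labels, np.zeros(32, int), seed=9)
        for (tr1, te1), (tr2, te2) in zip(s1.splits, s2.splits):
            assert np.array_equal(tr1, tr2) and np.array_equal(te1, te2)

    def test_small_class_raises(self):
        labels = np.array(["a"] * 10 + ["b"] * 3)
        with pytest.raises(ValueError, match="class"):
            make_partitions(labels, np.zeros(13, int), seed=0)


class TestLdaClassifier:
    def test_separable_point_masses(self):
        train = np.array([[-1.0], [-1.0], [-1.1], [1.0], [1.0], [1.1]])
        y = np.array(["neg", "neg", "neg", "pos", "pos", "pos"])
        pred = lda_classify(train, y, np.array([[1.0], [-1.0]]))
        assert list(pred) == ["pos", "neg"]

    def test_shuffled_labels_give_chance_accuracy(self):
        """Monte-Carlo over 200 label shuffles: accuracy -> 0.5."""
        rng = np.random.default_rng(12)
        train = rng.standard_normal((40, 6))
        test = rng.standard_normal((400, 6))
        truth = np.array(["a", "b"] * 200)
        accs = []
        for _ in range(200):
            y = rng.permutation(np.array(["a", "b"] * 20))
            accs.append((lda_classify(train, y, test) == truth).mean())
        mean = np.mean(accs)
        se = np.std(accs) / np.sqrt(len(accs))
        assert abs(mean - 0.5) < max(3 * se, 0.01)

    def test_duplicated_features_match_single_feature(self):
        """Perfect collinearity is handled by shrinkage: same predictions."""
        rng = np.random.default_rng(5)
        x = np.vstack([rng.normal(-1, 1, (20, 1)), rng.normal(1, 1, (20, 1))])
        y = np.array(["a"] * 20 + ["b"] * 20)
        test = rng.standard_normal((50, 1))
        single = lda_classify(x, y, test)
        dup = lda_classify(np.hstack([x, x]), y, np.hstack([test, test]))
        assert np.array_equal(single, dup)

    def test_agrees_with_sklearn_lda(self):
        """Independent route: scikit-learn's shrinkage LDA on the same data."""
        rng = np.random.default_rng(7)
        n = 120
        x = np.vstack(
            [rng.multivariate_normal([1, 0, 0.5, 0], np.eye(4), n // 2),
             rng.multivariate_normal([-1, 0.3, -0.5, 0], np.eye(4), n // 2)]
        )
        y = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
        test = rng.standard_normal((300, 4)) * 2
        ours = lda_classify(x, y, test)
        sk = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto").fit(x, y)
        agree = (ours == sk.predict(test)).mean()
        assert agree > 0.95


class TestAccuracyMaps:
    def _signal_patterns(self, rng, cnr=1.5, n_per_class=20, n_vox=40,
                         sig=slice(15, 25)):
        n = 2 * n_per_class
        labels = np.array(["up", "down"] * n_per_class)
        signs = np.where(labels == "up", 1.0, -1.0)
        matrix = rng.standard_normal((n, n_vox))
        pattern = np.zeros(n_vox)
        pattern[sig] = 1.0
        matrix += cnr * np.outer(signs, pattern)
        chunks = np.repeat([0, 1], n // 2)
        return make_patterns(matrix, {"direction": labels}, chunks), sig

    def test_planted_signal_region_carries_top_accuracies(self):
        rng = np.random.default_rng(21)
        pats, sig = self._signal_patterns(rng)
        spheres = build_searchlights(pats.voxels, pats.grid)
        scheme = make_partitions(
            pats.labels["direction"].to_numpy(), pats.chunks, seed=2
        )
        amap = searchlight_accuracy_map(pats, spheres, scheme, "dir")
        top5 = np.argsort(amap.accuracies)[-5:]
        assert all(sig.start - 2 <= c < sig.stop + 2 for c in amap.centers[top5])

    def test_random_labels_map_mean_near_chance(self):
        rng = np.random.default_rng(31)
        pats = two_class_noise_patterns(rng)
        spheres = build_searchlights(pats.voxels, pats.grid)
        means = []
        for i in range(30):
            labels = rng.permutation(pats.labels["velocity"].to_numpy())
            scheme = make_partitions(labels, pats.chunks, seed=100 + i)
            pats.labels["velocity"] = labels
            amap = searchlight_accuracy_map(pats, spheres, scheme, "perm")
            means.append(amap.mean_accuracy)
        se = np.std(means) / np.sqrt(len(means))
        assert abs(np.mean(means) - 0.5) < 2 * max(se, 0.005)

    def test_constant_features_decode_at_chance(self):
        pats = make_patterns(
            np.ones((40, 20)), {"velocity": np.array(["f", "s"] * 20)},
            np.repeat([0, 1], 20),
        )
        spheres = build_searchlights(pats.voxels, pats.grid)
        scheme = make_partitions(pats.labels["velocity"].to_numpy(), pats.chunks, 7)
        amap = searchlight_accuracy_map(pats, spheres, scheme, "const")
        assert np.all(np.abs(amap.accuracies - 0.5) < 0.06)

    def test_map_invariant_to_run_relabeling(self):
        """Runs do not enter within-phase folds: renaming them changes nothing."""
        rng = np.random.default_rng(41)
        pats, _ = self._signal_patterns(rng)
        spheres = build_searchlights(pats.voxels, pats.grid)
        labels = pats.labels["direction"].to_numpy()
        scheme = make_partitions(labels, pats.chunks, seed=5)
        a = searchlight_accuracy_map(pats, spheres, scheme, "a")
        pats.chunks = (pats.chunks + 1) % 2
        b = searchlight_accuracy_map(pats, spheres, scheme, "b")
        assert np.array_equal(a.accuracies, b.accuracies)

    def test_accuracy_monotone_in_planted_cnr(self):
        """Median signal-sphere accuracy never drops as CNR rises."""
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            noise = rng.standard_normal((40, 40))
            medians = []
            for cnr in (0.2, 0.8, 2.0):
                labels = np.array(["up", "down"] * 20)
                signs = np.where(labels == "up", 1.0, -1.0)
                pattern = np.zeros(40)
                pattern[15:25] = 1.0
                pats = make_patterns(
                    noise + cnr * np.outer(signs, pattern),
                    {"direction": labels}, np.repeat([0, 1], 20),
                )
                spheres = build_searchlights(pats.voxels, pats.grid)
                scheme = make_partitions(labels, pats.chunks, seed=seed)
                amap = searchlight_accuracy_map(pats, spheres, scheme, "cnr")
                in_sig = (amap.centers >= 15) & (amap.centers < 25)
                medians.append(np.median(amap.accuracies[in_sig]))
            assert medians[0] <= medians[1] + 1e-9 <= medians[2] + 2e-9


class TestCrossPhase:
    def _phase_pair(self, rho, cnr=2.0, n_per_class=16, n_vox=30, seed=11):
        rng = np.random.default_rng(seed)
        base = rng.standard_normal(n_vox)
        indep = rng.standard_normal(n_vox)
        occ = rho * base + np.sqrt(1 - rho**2) * indep
        labels = np.array(["fast", "slow"] * n_per_class)
        signs = np.where(labels == "fast", 1.0, -1.0)
        chunks = np.repeat([0, 1], n_per_class)
        vis_m = rng.standard_normal((2 * n_per_class, n_vox)) + cnr * np.outer(
            signs, base
        )
        occ_m = rng.standard_normal((2 * n_per_class, n_vox)) + cnr * np.outer(
            signs, occ
        )
        vis = make_patterns(vis_m, {"velocity": labels}, chunks, phase="visible")
        occt = make_patterns(occ_m, {"velocity": labels}, chunks, phase="occluded")
        return vis, occt

    def test_shared_pattern_transfers(self):
        vis, occ = self._phase_pair(rho=1.0)
        spheres = build_searchlights(vis.voxels, vis.grid)
        amap = cross_phase_decode(vis, occ, spheres, 3, "velocity")
        assert amap.mean_accuracy > 0.75

    def test_independent_patterns_do_not_transfer(self):
        vis, occ = self._phase_pair(rho=0.0)
        spheres = build_searchlights(vis.voxels, vis.grid)
        amap = cross_phase_decode(vis, occ, spheres, 3, "velocity")
        assert abs(amap.mean_accuracy - 0.5) < 0.08

    def test_noiseless_symmetric_design_same_ranking(self):
        """With rho = 1 and class-pure noiseless patterns, swapping the
        train/test roles leaves every sphere's accuracy unchanged."""
        n_vox = 30
        rng = np.random.default_rng(17)
        base = rng.standard_normal(n_vox)
        labels = np.array(["fast", "slow"] * 10)
        signs = np.where(labels == "fast", 1.0, -1.0)
        matrix = np.outer(signs, base)  # identical rows per class, no noise
        chunks = np.repeat([0, 1], 10)
        vis = make_patterns(matrix, {"velocity": labels}, chunks, phase="visible")
        occ = make_patterns(matrix.copy(), {"velocity": labels}, chunks,
                            phase="occluded")
        spheres = build_searchlights(vis.voxels, vis.grid)
        fwd = cross_phase_decode(vis, occ, spheres, 3, "velocity")
        rev = cross_phase_decode(occ, vis, spheres, 3, "velocity")
        assert np.array_equal(fwd.accuracies, rev.accuracies)

    def test_voxel_mismatch_raises(self):
        vis, occ = self._phase_pair(rho=1.0)
        occ.voxels = occ.voxels + 1
        spheres = build_searchlights(vis.voxels, vis.grid)
        with pytest.raises(ValueError, match="voxel"):
            cross_phase_decode(vis, occ, spheres, 3, "velocity")
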