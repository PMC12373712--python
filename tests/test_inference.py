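"""Top-5% selection, permutation nulls, group p-values, sphere overlap."""

import numpy as np
import pytest
from scipy.stats import hypergeom

from slmvpa._rng import substream
from slmvpa.inference import (
    NullDistribution,
    group_level_p,
    paired_accuracy_ttest,
    permute_within_runs,
    select_informative_spheres,
    selection_statistic,
    sphere_center_overlap,
    subject_permutation_null,
)
from slmvpa.searchlight import (
    AccuracyMap,
    build_searchlights,
    make_partitions,
    searchlight_accuracy_map,
)

from conftest import make_patterns, two_class_noise_patterns


def _map(accs, centers=None, analysis_id="a"):
    accs = np.asarray(accs, dtype=float)
    if centers is None:
        centers = np.arange(len(accs))
    return AccuracyMap(analysis_id=analysis_id, centers=np.asarray(centers),
                       accuracies=accs)


class TestSelection:
    def test_top5_of_100_survivors(self):
        rng = np.random.default_rng(0)
        accs = rng.uniform(0.51, 0.9, 100)
        sel = select_informative_spheres(_map(accs))
        assert sel.n_selected == 5
        assert sel.selected_accuracies.min() >= np.percentile(accs, 95) - 1e-12

    def test_rounding_rule_40_survivors(self):
        accs = np.concatenate([np.linspace(0.51, 0.9, 40), np.full(10, 0.4)])
        sel = select_informative_spheres(_map(accs))
        assert sel.n_surviving == 40
        assert sel.n_selected == 2  # round(0.05 * 40)

    def test_minimum_one_sphere(self):
        sel = select_informative_spheres(_map([0.3, 0.7, 0.45]))
        assert sel.n_selected == 1
        assert sel.selected_centers[0] == 1

    def test_all_at_or_below_chance_flagged_empty(self):
        sel = select_informative_spheres(_map([0.5, 0.4, 0.5]))
        assert sel.is_empty
        assert np.isnan(sel.mean_accuracy)
        assert sel.n_surviving == 0

    def test_boundary_ties_break_by_ascending_center(self):
        accs = np.full(40, 0.6)  # all tied; 2 to select
        sel = select_informative_spheres(_map(accs, centers=np.arange(40)[::-1]))
        assert list(sel.selected_centers) == [0, 1]


class TestPValueMechanics:
    def test_p_zero_when_no_permutation_reaches_true(self):
        d = NullDistribution(true_value=0.8, permuted_values=np.full(1000, 0.5))
        assert d.p_value == 0.0
        assert d.p_value_conservative == pytest.approx(1 / 1001)

    def test_p_max_when_all_reach_true(self):
        d = NullDistribution(true_value=0.5, permuted_values=np.full(1000, 0.6))
        assert d.p_value == pytest.approx(1000 / 1001)

    def test_ties_count_as_extreme(self):
        d = NullDistribution(true_value=0.6, permuted_values=np.array([0.6, 0.5]))
        assert d.p_value == pytest.approx(1 / 3)

    def test_p_monotone_nonincreasing_in_true_value(self):
        rng = np.random.default_rng(3)
        null = rng.uniform(0.4, 0.6, 500)
        ps = [
            NullDistribution(t, null).p_value for t in np.linspace(0.3, 0.7, 41)
        ]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_group_null_averages_subjects_per_iteration(self):
        true = np.array([0.6, 0.8])
        nulls = np.array([[0.5, 0.9], [0.5, 0.3]])
        d = group_level_p(true, nulls)
        assert d.true_value == pytest.approx(0.7)
        assert np.allclose(d.permuted_values, [0.5, 0.6])
        assert d.p_value == pytest.approx(0 / 3)

    def test_empty_subjects_raise(self):
        with pytest.raises(ValueError, match="subject"):
            group_level_p(np.array([]), np.empty((0, 5)))


class TestSubjectNull:
    def _subject(self, seed=0):
        rng = np.random.default_rng(seed)
        pats = two_class_noise_patterns(rng, n_per_class=16, n_vox=30)
        spheres = build_searchlights(pats.voxels, pats.grid)
        labels = pats.labels["velocity"].to_numpy()
        scheme = make_partitions(labels, pats.chunks, seed=seed)
        amap = searchlight_accuracy_map(pats, spheres, scheme, "vel")
        sel = select_informative_spheres(amap)
        return pats, spheres, labels, scheme, amap, sel

    def test_within_run_shuffle_preserves_per_run_counts(self):
        labels = np.array(["a", "a", "b", "b", "a", "b", "b", "b"])
        chunks = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        rng = substream(5, "t")
        for _ in range(20):
            perm = permute_within_runs(labels, chunks, rng)
            for run in (0, 1):
                orig = sorted(labels[chunks == run])
                assert sorted(perm[chunks == run]) == orig

    def test_identity_relabeling_reproduces_selected_mean(self):
        """Recomputing the map restricted to the selected centers with the
        original labels and scheme returns exactly the selected mean."""
        pats, spheres, labels, scheme, amap, sel = self._subject(seed=4)
        by_center = {s.center_voxel: s for s in spheres}
        sub = [by_center[int(c)] for c in sel.selected_centers]
        again = searchlight_accuracy_map(pats, sub, scheme, "again")
        assert again.mean_accuracy == pytest.approx(sel.mean_accuracy, abs=1e-12)

    def test_fixed_center_null_centers_on_chance_for_noise_data(self):
        """Without reselection, permuted accuracies at the original centers
        are ordinary chance-level accuracies."""
        pats, spheres, labels, scheme, amap, sel = self._subject(seed=8)
        null = subject_permutation_null(
            pats, spheres, labels, sel, n_iter=200, seed=9, reselect=False
        )
        se = null.std() / np.sqrt(len(null))
        assert abs(null.mean() - 0.5) < max(3 * se, 0.01)

    def test_reselection_null_carries_selection_inflation(self):
        """With reselection, the null mirrors the top-5% inflation: its mean
        sits above chance, in the neighbourhood of the true selected mean."""
        pats, spheres, labels, scheme, amap, sel = self._subject(seed=8)
        null = subject_permutation_null(
            pats, spheres, labels, sel, n_iter=200, seed=9
        )
        assert null.mean() > 0.55
        assert abs(null.mean() - sel.mean_accuracy) < 0.1

    def test_selection_statistic_matches_selector_on_true_map(self):
        pats, spheres, labels, scheme, amap, sel = self._subject(seed=4)
        stat = selection_statistic(amap.accuracies)[0]
        assert stat == pytest.approx(sel.mean_accuracy, abs=1e-12)

    def test_selection_bias_inflates_true_mean_but_p_stays_calibrated(self):
        """On signal-free data the selected-sphere mean exceeds 0.5 (the
        selection looks at the data), yet the permutation p is NOT small,
        because the null is sampled at the same fixed centers without
        reselection."""
        pats, spheres, labels, scheme, amap, sel = self._subject(seed=15)
        assert sel.mean_accuracy > 0.5
        null = subject_permutation_null(
            pats, spheres, labels, sel, n_iter=99, seed=16
        )
        p = NullDistribution(sel.mean_accuracy, null).p_value
        assert p >= 0.05

    def test_invalid_arguments(self):
        pats, spheres, labels, scheme, amap, sel = self._subject(seed=2)
        with pytest.raises(ValueError, match="n_iter"):
            subject_permutation_null(pats, spheres, labels, sel, n_iter=0, seed=1)

    def test_type_one_error_rate_calibrated(self):
        """8 signal-free subjects, 99 permutations: across 100 repetitions
        the group p rejects at 5% about 5% of the time (binomial 3-sigma)."""
        n_rej = 0
        for rep in range(100):
            true_means, nulls = [], []
            for s in range(8):
                rng = np.random.default_rng(10_000 + 97 * rep + s)
                pats = two_class_noise_patterns(rng, n_per_class=12, n_vox=20)
                spheres = build_searchlights(pats.voxels, pats.grid)
                labels = pats.labels["velocity"].to_numpy()
                scheme = make_partitions(labels, pats.chunks, seed=3 * rep + s)
                amap = searchlight_accuracy_map(pats, spheres, scheme, "vel")
                sel = select_informative_spheres(amap)
                null = subject_permutation_null(
                    pats, spheres, labels, sel, n_iter=99, seed=7 * rep + s
                )
                true_means.append(float(selection_statistic(amap.accuracies)[0]))
                nulls.append(null)
            p = group_level_p(np.array(true_means), np.vstack(nulls)).p_value
            n_rej += p < 0.05
        assert n_rej <= 12  # 5 + 3 * sqrt(100 * .05 * .95) ~ 11.5


class TestOverlap:
    def _set(self, centers, analysis_id="a"):
        centers = np.asarray(centers)
        return select_informative_spheres(
            _map(np.linspace(0.9, 0.6, len(centers)), centers, analysis_id),
            top_fraction=1.0,
        )

    def test_identical_sets_overlap_fully(self):
        a = self._set([3, 5, 9], "a")
        b = self._set([3, 5, 9], "b")
        ov = sphere_center_overlap([a, b])
        assert ov["pairwise"][("a", "b")] == 3
        assert ov["all_way"] == 3

    def test_disjoint_sets_overlap_zero(self):
        ov = sphere_center_overlap([self._set([1, 2], "a"), self._set([3, 4], "b")])
        assert ov["pairwise"][("a", "b")] == 0
        assert ov["mean_pairwise"] == 0.0

    def test_shared_signal_beats_hypergeometric_null(self):
        """Two analyses driven by one planted region share far more sphere
        centers than random top-5% draws would (closed-form hypergeometric)."""
        rng = np.random.default_rng(23)
        n, n_vox = 48, 60
        lab_a = np.array(["up", "down"] * (n // 2))
        lab_b = rng.permutation(np.array(["fast", "slow"] * (n // 2)))
        # two near-orthogonal patterns over the SAME voxel region
        pat_a = np.zeros(n_vox)
        pat_a[20:32] = rng.standard_normal(12)
        pat_b = np.zeros(n_vox)
        pat_b[20:32] = rng.standard_normal(12)
        m = (
            rng.standard_normal((n, n_vox))
            + 2.5 * np.outer(np.where(lab_a == "up", 1, -1), pat_a)
            + 2.5 * np.outer(np.where(lab_b == "fast", 1, -1), pat_b)
        )
        chunks = np.repeat([0, 1], n // 2)
        pats = make_patterns(m, {"direction": lab_a, "velocity": lab_b}, chunks)
        spheres = build_searchlights(pats.voxels, pats.grid)
        sels = []
        for col, aid in (("direction", "dir"), ("velocity", "vel")):
            labels = pats.labels[col].to_numpy()
            scheme = make_partitions(labels, pats.chunks, seed=5)
            amap = searchlight_accuracy_map(pats, spheres, scheme, aid)
            sels.append(
                select_informative_spheres(amap, top_fraction=0.15)
            )
        ov = sphere_center_overlap(sels)["pairwise"][("dir", "vel")]
        k1, k2 = sels[0].n_selected, sels[1].n_selected
        crit = hypergeom.ppf(0.95, n_vox, k1, k2)
        assert ov > crit

    def test_mismatched_grids_raise(self):
        a = self._set([1], "a")
        b = self._set([1], "b")
        a.grid_dims, b.grid_dims = (5, 5, 5), (6, 6, 6)
        with pytest.raises(ValueError, match="grid"):
            sphere_center_overlap([a, b])


def test_paired_ttest_matches_scipy_direction():
    a = np.array([0.6, 0.62, 0.58, 0.61])
    b = np.array([0.55, 0.54, 0.56, 0.53])
    t, p = paired_accuracy_ttest(a, b)
    assert t > 0 and p < 0.05
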