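"""Selection-plus-permutation inference for searchlight accuracies.

Per subject and analysis: discard spheres at or below chance (0.5), keep the
top 5% of the surviving accuracy distribution (round-half-up, floor 1), and
summarize them by their mean accuracy. The subject-level null shuffles class
labels within run and recomputes the searchlight accuracies at the SAME
selected centers; the group-level null averages subject nulls per iteration
and appends the true group mean, giving N + 1 group values. The permutation
p-value is the paper-of-record convention in this literature::

    p = #(permuted group means >= true group mean) / (N + 1)

which can return 0; the conservative (b + 1)/(N + 1) variant is reported
alongside, clearly labeled, without replacing it.

Selection on the true labels inflates the selected-sphere mean above 0.5
even on pure noise. The permutation p remains calibrated because the null
recomputes the identical statistic — cutoff, top-5% selection, mean — on
every permuted map, so the selection inflation is present in the null to
exactly the same degree and cancels. (A fixed-center null without
reselection centers on chance instead and is strongly anticonservative; it
is available as ``reselect=False`` for comparison.)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._rng import substream
from .glm import PatternSet
from .lda import balanced_lda_accuracy, pad_features, pad_members
from .searchlight import AccuracyMap, Searchlight, _encode_labels

__all__ = [
    "TopSphereSet",
    "NullDistribution",
    "select_informative_spheres",
    "selection_statistic",
    "subject_permutation_null",
    "cross_phase_permutation_null",
    "group_level_p",
    "sphere_center_overlap",
    "paired_accuracy_ttest",
    "permute_within_runs",
]

CUTOFF = 0.5
TOP_FRACTION = 0.05


@dataclass
class TopSphereSet:
    """The top-5% most informative spheres of one subject-level analysis."""

    analysis_id: str
    subject_id: str
    selected_centers: np.ndarray  # flat voxel indices, selection order
    selected_accuracies: np.ndarray
    n_surviving: int
    grid_dims: tuple | None = None

    @property
    def n_selected(self) -> int:
        return len(self.selected_centers)

    @property
    def is_empty(self) -> bool:
        return self.n_selected == 0

    @property
    def mean_accuracy(self) -> float:
        """Mean over selected spheres; NaN when no sphere survived the cutoff."""
        if self.is_empty:
            return float("nan")
        return float(self.selected_accuracies.mean())


@dataclass
class NullDistribution:
    """Group permutation null: N permuted group means plus the true value."""

    true_value: float
    permuted_values: np.ndarray

    @property
    def n_iter(self) -> int:
        return len(self.permuted_values)

    @property
    def p_value(self) -> float:
        """#(permuted >= true) / (N + 1); can be exactly 0."""
        b = int((self.permuted_values >= self.true_value).sum())
        return b / (self.n_iter + 1)

    @property
    def p_value_conservative(self) -> float:
        """(b + 1) / (N + 1) — never zero; reported alongside, not instead."""
        b = int((self.permuted_values >= self.true_value).sum())
        return (b + 1) / (self.n_iter + 1)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def select_informative_spheres(
    acc_map: AccuracyMap,
    subject_id: str = "",
    cutoff: float = CUTOFF,
    top_fraction: float = TOP_FRACTION,
) -> TopSphereSet:
    """Cutoff at chance, then keep the top fraction of the survivors.

    Ties at the selection boundary break by ascending center index. An
    analysis where no sphere exceeds the cutoff returns an explicitly empty
    set (mean NaN) rather than a silent zero.
    """
    if acc_map.n_spheres == 0:
        raise ValueError("empty accuracy map")
    surviving = acc_map.accuracies > cutoff
    n_surv = int(surviving.sum())
    grid_dims = acc_map.grid.dims if acc_map.grid is not None else None
    if n_surv == 0:
        return TopSphereSet(
            analysis_id=acc_map.analysis_id,
            subject_id=subject_id,
            selected_centers=np.array([], dtype=int),
            selected_accuracies=np.array([]),
            n_surviving=0,
            grid_dims=grid_dims,
        )
    n_sel = max(1, _round_half_up(top_fraction * n_surv))
    centers = acc_map.centers[surviving]
    accs = acc_map.accuracies[surviving]
    order = np.lexsort((centers, -accs))[:n_sel]
    return TopSphereSet(
        analysis_id=acc_map.analysis_id,
        subject_id=subject_id,
        selected_centers=centers[order],
        selected_accuracies=accs[order],
        n_surviving=n_surv,
        grid_dims=grid_dims,
    )


def permute_within_runs(
    labels: np.ndarray, chunks: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Shuffle labels within each run, preserving per-run class counts."""
    labels = np.asarray(labels)
    out = labels.copy()
    for run in np.unique(chunks):
        idx = np.flatnonzero(chunks == run)
        out[idx] = labels[idx[rng.permutation(len(idx))]]
    return out


def _restrict_spheres(
    spheres: list[Searchlight], selected: TopSphereSet
) -> list[Searchlight]:
    by_center = {s.center_voxel: s for s in spheres}
    return [by_center[int(c)] for c in selected.selected_centers]


def selection_statistic(
    acc: np.ndarray, cutoff: float = CUTOFF, top_fraction: float = TOP_FRACTION
) -> np.ndarray:
    """Mean of the top-fraction spheres of each accuracy map (row-wise).

    Applies the full selection rule — cutoff, round-half-up top fraction of
    the survivors, floor 1 — to each row of ``acc`` (n_maps, n_spheres).
    A map with no sphere above the cutoff falls back to its single best
    sphere, keeping the statistic defined (and conservative) under extreme
    permutations.
    """
    acc = np.atleast_2d(np.asarray(acc, dtype=float))
    srt = -np.sort(-acc, axis=1)  # descending
    surviving = (acc > cutoff).sum(axis=1)
    n_sel = np.maximum(1, np.floor(top_fraction * surviving + 0.5).astype(int))
    n_sel = np.minimum(n_sel, np.maximum(surviving, 1))
    csum = np.cumsum(srt, axis=1)
    return csum[np.arange(len(acc)), n_sel - 1] / n_sel


def subject_permutation_null(
    patterns: PatternSet,
    spheres: list[Searchlight],
    labels: np.ndarray,
    selected: TopSphereSet,
    n_iter: int = 1000,
    seed: int = 0,
    cutoff: float = CUTOFF,
    top_fraction: float = TOP_FRACTION,
    reselect: bool = True,
) -> np.ndarray:
    """Within-run label-permutation null of the selected-sphere mean accuracy.

    Each iteration shuffles the class labels within each run, regenerates the
    balanced partition scheme from the derived permutation stream, and
    recomputes the searchlight analysis on the same data.

    With ``reselect=True`` (default) the full statistic — cutoff, top-5%
    selection, mean — is recomputed on every permuted accuracy map, so the
    null carries the same selection inflation as the true value and the
    permutation p is calibrated. ``reselect=False`` instead averages the
    permuted accuracies at the originally selected centers only; that null
    centers on chance and is strongly anticonservative on selected means —
    it is provided for comparison and sensitivity analyses, not inference.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if not reselect and selected.is_empty:
        raise ValueError(
            "fixed-center null requires a non-empty sphere selection"
        )
    use = spheres if reselect else _restrict_spheres(spheres, selected)
    x = pad_features(np.asarray(patterns.matrix, dtype=float))
    cols, n_members = pad_members([s.member_cols for s in use], patterns.n_voxels)
    chunks = np.asarray(patterns.chunks)
    y, _ = _encode_labels(np.asarray(labels))
    rng = substream(seed, "perm-within")
    acc = _null_sphere_accuracies(x, cols, n_members, y, chunks, n_iter, rng)
    if reselect:
        return selection_statistic(acc, cutoff, top_fraction)
    return acc.mean(axis=1)


def _null_sphere_accuracies(
    x: np.ndarray,
    cols: np.ndarray,
    n_members: np.ndarray,
    y: np.ndarray,
    chunks: np.ndarray,
    n_iter: int,
    rng: np.random.Generator,
    n_folds: int = 4,
    n_repeats: int = 4,
) -> np.ndarray:
    """(n_iter, n_spheres) split-mean accuracies under within-run label
    permutation, with partitions regenerated per iteration."""
    perm_y = _batched_within_run_permutations(y, chunks, n_iter, rng)
    n0 = int((y == 0).sum())
    # stable argsort: per iteration, first n0 columns are class-0 trials
    order = np.argsort(perm_y, axis=1, kind="stable")
    idx_cls = (order[:, :n0], order[:, n0:])

    # per class: (n_iter, n_repeats, n_c) randomly permuted trial indices;
    # static fold labels arange(n_c) % n_folds stratify every repeat
    perm_cls = [
        rng.permuted(np.repeat(idx[:, None, :], n_repeats, axis=1), axis=2)
        for idx in idx_cls
    ]
    fold_of = [np.arange(idx.shape[1]) % n_folds for idx in idx_cls]

    n_spheres = len(n_members)
    sums = np.zeros((n_iter, n_spheres))
    for f in range(n_folds):
        train_parts, test_parts = [], []
        for c in (0, 1):
            in_fold = fold_of[c] == f
            test_parts.append(perm_cls[c][..., in_fold])
            train_parts.append(perm_cls[c][..., ~in_fold])
        m = min(p.shape[-1] for p in train_parts)
        train_rows = np.concatenate(
            [rng.permuted(p, axis=2)[..., :m] for p in train_parts], axis=-1
        )  # (n_iter, n_repeats, 2m), class-0 block first
        test_rows = np.concatenate(test_parts, axis=-1)
        test_y = np.take_along_axis(
            perm_y, test_rows.reshape(n_iter, -1), axis=1
        ).reshape(test_rows.shape)

        acc = _chunked_balanced_accuracy(
            x,
            train_rows.reshape(-1, train_rows.shape[-1]),
            test_rows.reshape(-1, test_rows.shape[-1]),
            test_y.reshape(-1, test_y.shape[-1]),
            cols,
            n_members,
        )
        sums += acc.reshape(n_iter, n_repeats, n_spheres).mean(axis=1)
    return sums / n_folds


def cross_phase_permutation_null(
    train_patterns: PatternSet,
    test_patterns: PatternSet,
    spheres: list[Searchlight],
    label_column: str,
    selected: TopSphereSet,
    n_iter: int = 1000,
    seed: int = 0,
    cutoff: float = CUTOFF,
    top_fraction: float = TOP_FRACTION,
    reselect: bool = True,
) -> np.ndarray:
    """Cross-phase analogue: labels shuffled within run in both phases."""
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if not reselect and selected.is_empty:
        raise ValueError(
            "fixed-center null requires a non-empty sphere selection"
        )
    use = spheres if reselect else _restrict_spheres(spheres, selected)
    if not np.array_equal(train_patterns.voxels, test_patterns.voxels):
        raise ValueError("train and test PatternSets must share one voxel set")
    n_train = train_patterns.n_trials
    # train and test rows index one stacked matrix
    x = pad_features(
        np.vstack([train_patterns.matrix, test_patterns.matrix]).astype(float)
    )
    cols, n_members = pad_members(
        [s.member_cols for s in use], train_patterns.n_voxels
    )
    y_tr0, _ = _encode_labels(train_patterns.labels[label_column].to_numpy())
    y_te0, _ = _encode_labels(test_patterns.labels[label_column].to_numpy())
    rng = substream(seed, "xperm-within")
    n_repeats = 4

    perm_tr = _batched_within_run_permutations(
        y_tr0, np.asarray(train_patterns.chunks), n_iter, rng
    )
    perm_te = _batched_within_run_permutations(
        y_te0, np.asarray(test_patterns.chunks), n_iter, rng
    )

    def balanced_rows(perm_y, offset):
        n0 = int((perm_y[0] == 0).sum())
        order = np.argsort(perm_y, axis=1, kind="stable")
        parts = (order[:, :n0], order[:, n0:])
        m = min(p.shape[-1] for p in parts)
        sub = [
            rng.permuted(np.repeat(p[:, None, :], n_repeats, axis=1), axis=2)[..., :m]
            for p in parts
        ]
        return np.concatenate(sub, axis=-1) + offset  # (n_iter, n_repeats, 2m)

    train_rows = balanced_rows(perm_tr, 0)
    test_rows = balanced_rows(perm_te, 0)
    test_y = np.take_along_axis(
        perm_te, test_rows.reshape(n_iter, -1), axis=1
    ).reshape(test_rows.shape)

    n_spheres = len(use)
    acc = _chunked_balanced_accuracy(
        x,
        train_rows.reshape(-1, train_rows.shape[-1]),
        test_rows.reshape(-1, test_rows.shape[-1]) + n_train,
        test_y.reshape(-1, test_y.shape[-1]),
        cols,
        n_members,
    ).reshape(n_iter, n_repeats, n_spheres).mean(axis=1)
    if reselect:
        return selection_statistic(acc, cutoff, top_fraction)
    return acc.mean(axis=1)


def _batched_within_run_permutations(
    y: np.ndarray, chunks: np.ndarray, n_iter: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_iter, n_trials) label codes, independently shuffled within run."""
    perm_y = np.tile(y, (n_iter, 1))
    for run in np.unique(chunks):
        idx = np.flatnonzero(chunks == run)
        block = perm_y[:, idx].copy()
        rng.permuted(block, axis=1, out=block)
        perm_y[:, idx] = block
    return perm_y


def _chunked_balanced_accuracy(
    x: np.ndarray,
    train_rows: np.ndarray,
    test_rows: np.ndarray,
    test_y: np.ndarray,
    cols: np.ndarray,
    n_members: np.ndarray,
    max_batch: int = 8192,
) -> np.ndarray:
    """Expand (problem x sphere) batches and evaluate in memory-bounded chunks.

    Returns accuracies of shape (n_problems * n_spheres,) ordered with the
    sphere axis fastest.
    """
    n_spheres = len(n_members)
    n_prob = train_rows.shape[0]
    out = np.empty(n_prob * n_spheres)
    step = max(1, max_batch // max(n_spheres, 1))
    for lo in range(0, n_prob, step):
        sl = slice(lo, min(lo + step, n_prob))
        g = sl.stop - sl.start
        out[lo * n_spheres : sl.stop * n_spheres] = balanced_lda_accuracy(
            x,
            np.repeat(train_rows[sl], n_spheres, axis=0),
            np.repeat(test_rows[sl], n_spheres, axis=0),
            np.repeat(test_y[sl], n_spheres, axis=0),
            np.tile(cols, (g, 1)),
            np.tile(n_members, g),
        )
    return out


def group_level_p(
    true_means: np.ndarray, null_means: np.ndarray
) -> NullDistribution:
    """Average subject nulls per iteration; p against the true group mean.

    Parameters
    ----------
    true_means : (n_subjects,) selected-sphere mean accuracy per subject.
    null_means : (n_subjects, n_iter) subject-level null values.
    """
    true_means = np.asarray(true_means, dtype=float)
    null_means = np.atleast_2d(np.asarray(null_means, dtype=float))
    if true_means.size == 0:
        raise ValueError("at least one subject required")
    if null_means.shape[0] != true_means.size:
        raise ValueError("null_means must have one row per subject")
    return NullDistribution(
        true_value=float(true_means.mean()),
        permuted_values=null_means.mean(axis=0),
    )


def sphere_center_overlap(sets: list[TopSphereSet]) -> dict:
    """Shared sphere centers across analyses of one subject.

    Returns pairwise counts, the all-way intersection count, and the mean
    pairwise overlap.
    """
    if len(sets) < 2:
        raise ValueError("need at least two sphere sets")
    grids = {s.grid_dims for s in sets if s.grid_dims is not None}
    if len(grids) > 1:
        raise ValueError(f"sphere sets live on different grids: {grids}")
    centers = [set(int(c) for c in s.selected_centers) for s in sets]
    ids = [s.analysis_id for s in sets]
    pairwise = {}
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            pairwise[(ids[i], ids[j])] = len(centers[i] & centers[j])
    all_way = len(set.intersection(*centers)) if centers else 0
    return {
        "pairwise": pairwise,
        "all_way": all_way,
        "mean_pairwise": float(np.mean(list(pairwise.values()))),
    }


def paired_accuracy_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Paired t-test on per-subject accuracies (e.g. HP vs LP contexts).

    Note: inputs are typically selected-sphere means, which carry selection
    bias; the comparison is between two equally biased quantities.
    """
    res = stats.ttest_rel(np.asarray(a, float), np.asarray(b, float))
    return float(res.statistic), float(res.pvalue)
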