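"""ROI-restricted searchlight decoding with balanced leave-25%-trials-out.

Every retained ROI voxel is a searchlight center; a sphere collects the
voxels whose centers lie within 4.4 mm (two voxel widths at 2.2 mm — 33
voxels for an interior center). Decoding is binary shrinkage LDA, evaluated
with a leave-25%-trials-out scheme: trials are dealt into 4 class-stratified
folds, every training split is balanced by subsampling the majority class,
and the whole partitioning is repeated 4 times (16 splits). Cross-phase
decoding (train visible, test occluded) uses all balanced trials of each
phase, with 4 balancing redraws in place of folds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import substream
from .glm import PatternSet
from .lda import batched_lda_predict, pad_features, pad_members
from .simulate import VolumeGrid

__all__ = [
    "Searchlight",
    "PartitionScheme",
    "AccuracyMap",
    "build_searchlights",
    "make_partitions",
    "lda_classify",
    "searchlight_accuracy_map",
    "cross_phase_decode",
    "SEARCHLIGHT_RADIUS_MM",
]

SEARCHLIGHT_RADIUS_MM = 4.4


@dataclass
class Searchlight:
    """One sphere: its center voxel and the member pattern columns."""

    center_voxel: int  # flat grid index
    center_col: int  # column in the PatternSet matrix
    member_cols: np.ndarray


@dataclass
class PartitionScheme:
    """16 balanced train/test splits (4 stratified folds x 4 repeats)."""

    splits: list[tuple[np.ndarray, np.ndarray]]
    y: np.ndarray  # 0/1 class codes per trial
    classes: list
    n_folds: int
    n_repeats: int


@dataclass
class AccuracyMap:
    """Per-sphere mean decoding accuracy for one analysis."""

    analysis_id: str
    centers: np.ndarray  # flat voxel index per sphere
    accuracies: np.ndarray
    grid: VolumeGrid | None = None

    @property
    def n_spheres(self) -> int:
        return len(self.centers)

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"center": self.centers, "accuracy": self.accuracies}
        ).assign(analysis_id=self.analysis_id)


def build_searchlights(
    pattern_voxels: np.ndarray,
    grid: VolumeGrid,
    radius_mm: float = SEARCHLIGHT_RADIUS_MM,
) -> list[Searchlight]:
    """One searchlight per retained voxel; membership by voxel-center distance."""
    voxels = np.asarray(pattern_voxels)
    if voxels.size == 0:
        raise ValueError("pattern voxel set is empty")
    if radius_mm <= 0:
        raise ValueError("radius must be > 0")
    r_vox = radius_mm / grid.voxel_size
    r_int = int(np.floor(r_vox))
    rng_off = np.arange(-r_int, r_int + 1)
    off = np.stack(np.meshgrid(rng_off, rng_off, rng_off, indexing="ij"), -1).reshape(
        -1, 3
    )
    off = off[(off**2).sum(1) <= r_vox**2 + 1e-9]

    col_of = {int(v): i for i, v in enumerate(voxels)}
    ijk = grid.flat_to_ijk(voxels)
    dims = np.array(grid.dims)
    spheres = []
    for col, (v, center) in enumerate(zip(voxels, ijk)):
        neigh = center[None, :] + off
        ok = ((neigh >= 0) & (neigh < dims)).all(axis=1)
        flats = grid.ijk_to_flat(neigh[ok])
        member_cols = np.array(
            [col_of[int(fl)] for fl in flats if int(fl) in col_of], dtype=np.intp
        )
        spheres.append(
            Searchlight(center_voxel=int(v), center_col=col, member_cols=member_cols)
        )
    return spheres


def _encode_labels(labels: np.ndarray) -> tuple[np.ndarray, list]:
    classes = sorted(set(np.asarray(labels).tolist()))
    if len(classes) != 2:
        raise ValueError(f"binary labels required, got classes {classes}")
    lut = {c: i for i, c in enumerate(classes)}
    return np.array([lut[v] for v in np.asarray(labels).tolist()]), classes


def make_partitions(
    labels: np.ndarray,
    chunks: np.ndarray,
    seed: int,
    n_folds: int = 4,
    n_repeats: int = 4,
) -> PartitionScheme:
    """Stratified leave-25%-trials-out folds with balanced training splits.

    Trials are stratified by class into ``n_folds`` folds; within each
    training split the majority class is randomly subsampled to the minority
    count. Runs (``chunks``) are recorded on the trials for permutation use
    but do not constrain the folds: the scheme leaves trials out, not runs.
    """
    y, classes = _encode_labels(labels)
    rng = substream(seed, "partitions")
    counts = np.bincount(y, minlength=2)
    if counts.min() < n_folds:
        raise ValueError(
            f"every class needs >= {n_folds} trials; got counts {counts.tolist()}"
        )
    splits: list[tuple[np.ndarray, np.ndarray]] = []
    for _ in range(n_repeats):
        fold = np.empty(len(y), dtype=int)
        for c in (0, 1):
            idx = rng.permutation(np.flatnonzero(y == c))
            fold[idx] = np.arange(len(idx)) % n_folds
        for f in range(n_folds):
            test_idx = np.flatnonzero(fold == f)
            train_idx = np.flatnonzero(fold != f)
            tr_y = y[train_idx]
            m = min((tr_y == 0).sum(), (tr_y == 1).sum())
            keep = []
            for c in (0, 1):
                pool = train_idx[tr_y == c]
                keep.append(rng.permutation(pool)[:m])
            train_bal = np.sort(np.concatenate(keep))
            splits.append((train_bal, test_idx))
    return PartitionScheme(
        splits=splits, y=y, classes=classes, n_folds=n_folds, n_repeats=n_repeats
    )


def lda_classify(
    train_x: np.ndarray, train_y: np.ndarray, test_x: np.ndarray
) -> np.ndarray:
    """Shrinkage-LDA predictions for one feature set (single 'sphere')."""
    y, classes = _encode_labels(train_y)
    members = np.arange(train_x.shape[1], dtype=np.intp)[None, :]
    pred = batched_lda_predict(
        pad_features(np.asarray(train_x, dtype=float)),
        y,
        pad_features(np.asarray(test_x, dtype=float)),
        members,
        np.array([train_x.shape[1]]),
    )[0]
    return np.array([classes[p] for p in pred])


def _sphere_arrays(spheres: list[Searchlight], n_features: int):
    members, n_members = pad_members([s.member_cols for s in spheres], n_features)
    centers = np.array([s.center_voxel for s in spheres])
    return members, n_members, centers


def searchlight_accuracy_map(
    patterns: PatternSet,
    spheres: list[Searchlight],
    scheme: PartitionScheme,
    analysis_id: str,
) -> AccuracyMap:
    """Mean LDA accuracy per sphere over all splits of the scheme."""
    x = pad_features(np.asarray(patterns.matrix, dtype=float))
    for s in spheres:
        if s.member_cols.max(initial=0) >= patterns.n_voxels:
            raise IndexError(
                f"sphere at voxel {s.center_voxel} references a column outside "
                f"the pattern matrix"
            )
    members, n_members, centers = _sphere_arrays(spheres, patterns.n_voxels)
    acc = np.zeros(len(spheres))
    for train_idx, test_idx in scheme.splits:
        pred = batched_lda_predict(
            x[train_idx], scheme.y[train_idx], x[test_idx], members, n_members
        )
        acc += (pred == scheme.y[test_idx][None, :]).mean(axis=1)
    acc /= len(scheme.splits)
    return AccuracyMap(
        analysis_id=analysis_id, centers=centers, accuracies=acc, grid=patterns.grid
    )


def cross_phase_decode(
    train_patterns: PatternSet,
    test_patterns: PatternSet,
    spheres: list[Searchlight],
    seed: int,
    label_column: str,
    analysis_id: str = "crossphase",
    n_repeats: int = 4,
) -> AccuracyMap:
    """Train on all balanced visible trials, test on balanced occluded trials.

    The non-decoded factor is collapsed simply by classifying on
    ``label_column`` alone. Train and test sets are disjoint phases by
    construction, so the 4 repetitions are redraws of the balancing
    subsample rather than folds.
    """
    if not np.array_equal(train_patterns.voxels, test_patterns.voxels):
        raise ValueError("train and test PatternSets must share one voxel set")
    if train_patterns.grid.dims != test_patterns.grid.dims:
        raise ValueError("train and test PatternSets must share one grid")
    y_tr_lab = train_patterns.labels[label_column].to_numpy()
    y_te_lab = test_patterns.labels[label_column].to_numpy()
    y_tr, classes = _encode_labels(y_tr_lab)
    y_te, classes_te = _encode_labels(y_te_lab)
    if classes != classes_te:
        raise ValueError("train and test label sets differ")

    x_tr = pad_features(np.asarray(train_patterns.matrix, dtype=float))
    x_te = pad_features(np.asarray(test_patterns.matrix, dtype=float))
    members, n_members, centers = _sphere_arrays(spheres, train_patterns.n_voxels)

    rng = substream(seed, "crossphase", analysis_id)
    acc = np.zeros(len(spheres))
    for _ in range(n_repeats):
        tr_keep = _balanced_subsample(y_tr, rng)
        te_keep = _balanced_subsample(y_te, rng)
        pred = batched_lda_predict(
            x_tr[tr_keep], y_tr[tr_keep], x_te[te_keep], members, n_members
        )
        acc += (pred == y_te[te_keep][None, :]).mean(axis=1)
    acc /= n_repeats
    return AccuracyMap(
        analysis_id=analysis_id,
        centers=centers,
        accuracies=acc,
        grid=train_patterns.grid,
    )


def _balanced_subsample(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    m = min((y == 0).sum(), (y == 1).sum())
    keep = [rng.permutation(np.flatnonzero(y == c))[:m] for c in (0, 1)]
    return np.sort(np.concatenate(keep))
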