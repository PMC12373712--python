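"""Design matrices, condition-wise and trial-wise (LSS) beta estimation.

Condition GLM: per run, each condition's onsets are convolved with the
canonical HRF plus its temporal and dispersion derivatives; six motion
regressors, a cosine drift basis (128 s cutoff) and an intercept complete
the model. Ordinary least squares per voxel; only the canonical-HRF
coefficients are carried forward, averaged across the runs in which the
condition occurs.

LSS (least-squares-separate) single-trial GLM: for each trial, one regressor
for that trial's onset, one pooled regressor for all other trials in the
run, plus the same nuisance set; the trial-of-interest coefficient is kept
and the procedure iterates over trials. Because convolution is linear the
pooled regressor is simply the all-trials regressor minus the trial's own.

No prewhitening is applied (plain OLS): the simulator's noise autocorrelation
is a parameter, and OLS keeps the noiseless recovery oracles exact.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import Design
from .hrf import canonical_hrf, event_regressor, hrf_basis
from .simulate import BoldRun, RoiMask, VolumeGrid

__all__ = [
    "DesignMatrix",
    "BetaMap",
    "PatternSet",
    "build_design_matrix",
    "fit_condition_glm",
    "fit_lss_betas",
    "extract_roi_patterns",
    "cosine_drift_basis",
    "save_patterns",
    "load_patterns",
]

logger = logging.getLogger(__name__)

DRIFT_CUTOFF = 128.0  # s, cosine high-pass cutoff
# a trial whose HRF support is truncated by more than half is dropped
_MIN_HRF_SUPPORT = 16.0  # s


@dataclass
class DesignMatrix:
    """Time x regressor matrix for one run, with labeled columns."""

    frame: pd.DataFrame
    run_index: int
    conditions: list[str]

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)


@dataclass
class BetaMap:
    """Canonical-HRF coefficients per label (condition or trial) per voxel."""

    level: str  # "condition" | "trial"
    values: np.ndarray  # (n_labels, n_voxels)
    labels: list[str]
    trial_indices: np.ndarray | None = None  # global trial index, trial level
    chunks: np.ndarray | None = None  # run index per row, trial level
    grid: VolumeGrid | None = None


@dataclass
class PatternSet:
    """Trial x voxel beta matrix restricted to one ROI — the MVPA currency."""

    matrix: np.ndarray  # (n_trials, n_voxels)
    labels: pd.DataFrame  # per-trial condition table
    chunks: np.ndarray  # run index per trial
    voxels: np.ndarray  # flat grid indices of the columns
    grid: VolumeGrid
    region: str
    phase: str
    context: str

    @property
    def n_trials(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.matrix.shape[1]


def cosine_drift_basis(n_volumes: int, tr: float, cutoff: float = DRIFT_CUTOFF):
    """DCT-II low-frequency basis with periods longer than ``cutoff`` seconds."""
    n = np.arange(n_volumes)
    order = int(np.floor(2.0 * n_volumes * tr / cutoff))
    cols = [
        np.sqrt(2.0 / n_volumes) * np.cos(np.pi * k * (2 * n + 1) / (2 * n_volumes))
        for k in range(1, order + 1)
    ]
    return np.column_stack(cols) if cols else np.empty((n_volumes, 0))


def _nuisance_block(
    n_volumes: int, tr: float, motion: pd.DataFrame | np.ndarray, cutoff: float
) -> tuple[np.ndarray, list[str]]:
    motion = np.asarray(motion, dtype=float)
    if motion.shape != (n_volumes, 6):
        raise ValueError(
            f"motion table must be {n_volumes} x 6, got {motion.shape}"
        )
    drift = cosine_drift_basis(n_volumes, tr, cutoff)
    names = [f"motion_{i}" for i in range(6)]
    names += [f"drift_{k + 1}" for k in range(drift.shape[1])]
    names += ["intercept"]
    block = np.column_stack([motion, drift, np.ones(n_volumes)])
    return block, names


def build_design_matrix(
    design: Design,
    run: int,
    motion: pd.DataFrame | np.ndarray,
    drift_cutoff: float = DRIFT_CUTOFF,
) -> DesignMatrix:
    """Condition regressors (HRF + derivatives), motion, drift, intercept."""
    trials = design.run_trials(run)
    if not trials:
        raise ValueError(f"run {run} not present in design")
    n_vol = design.run_length_volumes[run]
    basis = hrf_basis()

    conditions = sorted({t.condition for t in trials})
    cols: list[np.ndarray] = []
    names: list[str] = []
    for cond in conditions:
        onsets = np.array([t.onset for t in trials if t.condition == cond])
        for suffix, kernel in zip(("", "_td", "_dd"), basis):
            cols.append(event_regressor(onsets, n_vol, design.tr, kernel=kernel))
            names.append(cond + suffix)
    nuis, nuis_names = _nuisance_block(n_vol, design.tr, motion, drift_cutoff)
    x = np.column_stack(cols + [nuis])
    frame = pd.DataFrame(x, columns=names + nuis_names)
    return DesignMatrix(frame=frame, run_index=run, conditions=conditions)


def _check_full_rank(x: np.ndarray, names: list[str]) -> None:
    _, r = np.linalg.qr(x)
    diag = np.abs(np.diag(r))
    tol = max(x.shape) * np.finfo(float).eps * max(diag.max(), 1.0)
    bad = [names[i] for i in np.flatnonzero(diag < tol)]
    if bad:
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient; offending columns: {bad}"
        )


def fit_condition_glm(
    runs: list[BoldRun],
    matrices: list[DesignMatrix],
    grid: VolumeGrid | None = None,
) -> BetaMap:
    """Per-run OLS; canonical-HRF betas per condition, averaged across runs."""
    if len(runs) != len(matrices):
        raise ValueError("one design matrix per run required")
    sums: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    for run, dm in zip(runs, matrices):
        y = run.data.reshape(-1, run.n_volumes).T  # (T, n_vox)
        x = dm.values
        if x.shape[0] != y.shape[0]:
            raise ValueError(
                f"run has {y.shape[0]} volumes but matrix has {x.shape[0]} rows"
            )
        _check_full_rank(x, dm.columns)
        beta = np.linalg.lstsq(x, y, rcond=None)[0]
        for cond in dm.conditions:
            b = beta[dm.columns.index(cond)]
            sums[cond] = sums.get(cond, 0.0) + b
            counts[cond] = counts.get(cond, 0) + 1
    labels = sorted(sums)
    values = np.stack([sums[c] / counts[c] for c in labels])
    return BetaMap(level="condition", values=values, labels=labels, grid=grid)


def fit_lss_betas(
    runs: list[BoldRun],
    design: Design,
    drift_cutoff: float = DRIFT_CUTOFF,
    grid: VolumeGrid | None = None,
) -> BetaMap:
    """Least-squares-separate single-trial betas for every retained trial."""
    hrf = canonical_hrf()
    rows: list[np.ndarray] = []
    labels: list[str] = []
    trial_idx: list[int] = []
    chunks: list[int] = []
    for run_i, run in enumerate(runs):
        idx = [i for i, t in enumerate(design.trials) if t.run_index == run_i]
        trials = [design.trials[i] for i in idx]
        n_vol = run.n_volumes
        run_end = n_vol * design.tr
        keep = [
            j
            for j, t in enumerate(trials)
            if t.onset + _MIN_HRF_SUPPORT <= run_end
        ]
        n_dropped = len(trials) - len(keep)
        if n_dropped:
            logger.warning(
                "run %d: dropped %d trial(s) with HRF support truncated > 50%%",
                run_i,
                n_dropped,
            )
        y = run.data.reshape(-1, n_vol).T
        nuis, _ = _nuisance_block(n_vol, design.tr, run.motion_params, drift_cutoff)
        regs = np.column_stack(
            [
                event_regressor(np.array([trials[j].onset]), n_vol, design.tr, kernel=hrf)
                for j in keep
            ]
        )  # (T, n_keep)
        total = regs.sum(axis=1)
        single_trial_run = len(keep) < 2
        if single_trial_run:
            logger.warning(
                "run %d has a single trial; falling back to a plain GLM "
                "without a pooled other-trials regressor",
                run_i,
            )
        for col, j in enumerate(keep):
            if single_trial_run:
                x = np.column_stack([regs[:, col], nuis])
            else:
                x = np.column_stack([regs[:, col], total - regs[:, col], nuis])
            beta = np.linalg.lstsq(x, y, rcond=None)[0]
            rows.append(beta[0])
            labels.append(trials[j].condition)
            trial_idx.append(idx[j])
            chunks.append(run_i)
    return BetaMap(
        level="trial",
        values=np.stack(rows),
        labels=labels,
        trial_indices=np.array(trial_idx),
        chunks=np.array(chunks),
        grid=grid,
    )


def extract_roi_patterns(
    betas: BetaMap, mask: RoiMask, design: Design
) -> PatternSet:
    """Restrict trial betas to an ROI, excluding reappearance voxels."""
    if betas.level != "trial":
        raise ValueError("extract_roi_patterns requires trial-level betas")
    voxels = mask.retained_voxels
    if len(voxels) == 0:
        raise ValueError(
            f"ROI {mask.region}: no voxels remain after reappearance exclusion"
        )
    matrix = betas.values[:, voxels]
    trials = [design.trials[i] for i in betas.trial_indices]
    labels = pd.DataFrame(
        {
            "trial": betas.trial_indices,
            "condition": [t.condition for t in trials],
            "direction": [t.direction for t in trials],
            "velocity": [t.velocity for t in trials],
            "congruency": [t.congruency for t in trials],
            "run": [t.run_index for t in trials],
            "onset": [t.onset for t in trials],
        }
    )
    return PatternSet(
        matrix=matrix,
        labels=labels,
        chunks=np.asarray(betas.chunks),
        voxels=voxels,
        grid=betas.grid if betas.grid is not None else VolumeGrid((1, 1, 1)),
        region=mask.region,
        phase=design.phase,
        context=design.context,
    )


def save_patterns(patterns: PatternSet, tsv_path, json_path) -> None:
    """Write the trial x voxel matrix as TSV plus a JSON sidecar header."""
    df = pd.DataFrame(patterns.matrix, columns=[f"v{v}" for v in patterns.voxels])
    pd.concat([patterns.labels.reset_index(drop=True), df], axis=1).to_csv(
        tsv_path, sep="\t", index=False
    )
    header = {
        "region": patterns.region,
        "phase": patterns.phase,
        "context": patterns.context,
        "grid_dims": list(patterns.grid.dims),
        "voxel_size": patterns.grid.voxel_size,
        "voxels": [int(v) for v in patterns.voxels],
    }
    with open(json_path, "w") as fh:
        json.dump(header, fh)


def load_patterns(tsv_path, json_path) -> PatternSet:
    with open(json_path) as fh:
        header = json.load(fh)
    df = pd.read_csv(tsv_path, sep="\t")
    voxels = np.array(header["voxels"], dtype=int)
    label_cols = [c for c in df.columns if not c.startswith("v")]
    return PatternSet(
        matrix=df[[f"v{v}" for v in voxels]].to_numpy(),
        labels=df[label_cols].copy(),
        chunks=df["run"].to_numpy(),
        voxels=voxels,
        grid=VolumeGrid(tuple(header["grid_dims"]), header["voxel_size"]),
        region=header["region"],
        phase=header["phase"],
        context=header["context"],
    )
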