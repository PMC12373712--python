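"""Shared fixtures: a common grid/mask set and PatternSet builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from slmvpa.design import Design, TrialEvent, generate_design
from slmvpa.glm import PatternSet, extract_roi_patterns, fit_lss_betas
from slmvpa.simulate import (
    EffectSpec,
    NoiseSpec,
    VolumeGrid,
    generate_grid_and_masks,
    simulate_bold,
)


@pytest.fixture(scope="session")
def grid_masks():
    return generate_grid_and_masks((12, 12, 12), seed=0)


def make_patterns(
    matrix: np.ndarray,
    labels: dict[str, np.ndarray],
    chunks: np.ndarray,
    grid: VolumeGrid | None = None,
    voxels: np.ndarray | None = None,
    phase: str = "visible",
) -> PatternSet:
    """Build a PatternSet directly from arrays (line-grid geometry).

    Voxels default to a 1D line of the matrix's columns, which gives small
    5-member searchlights at the 4.4 mm radius — convenient for fast
    MVPA-level tests that skip the BOLD/GLM stages.
    """
    n_trials, n_vox = matrix.shape
    if grid is None:
        grid = VolumeGrid((n_vox, 1, 1))
    if voxels is None:
        voxels = np.arange(n_vox)
    lab = pd.DataFrame({"trial": np.arange(n_trials), **labels})
    lab["run"] = np.asarray(chunks)
    return PatternSet(
        matrix=np.asarray(matrix, dtype=float),
        labels=lab,
        chunks=np.asarray(chunks),
        voxels=np.asarray(voxels),
        grid=grid,
        region="lowerV1",
        phase=phase,
        context="HP",
    )


def two_class_noise_patterns(
    rng: np.random.Generator,
    n_per_class: int = 20,
    n_vox: int = 40,
    n_runs: int = 2,
    label_name: str = "velocity",
    classes: tuple[str, str] = ("fast", "slow"),
) -> PatternSet:
    """Signal-free patterns: labels statistically independent of the data."""
    n = 2 * n_per_class
    matrix = rng.standard_normal((n, n_vox))
    labels = np.array(list(classes) * n_per_class)
    chunks = np.repeat(np.arange(n_runs), n // n_runs)
    return make_patterns(matrix, {label_name: labels}, chunks)


def simulate_subject_patterns(
    seed: int,
    grid,
    masks,
    effects: EffectSpec,
    noise: NoiseSpec,
    context: str = "HP",
    phase: str = "visible",
    trials_per_cell_per_run: int = 5,
    region: int = 0,
):
    """Full simulate -> LSS -> ROI extraction chain for one session."""
    design = generate_design(
        context, phase, seed, trials_per_cell_per_run=trials_per_cell_per_run
    )
    runs = simulate_bold(design, grid, masks, effects, noise, seed)
    betas = fit_lss_betas(runs, design, grid=grid)
    return extract_roi_patterns(betas, masks[region], design), design, runs


def spaced_design(
    onsets_per_run: int = 4,
    spacing: float = 45.0,
    n_runs: int = 1,
    conditions: list[tuple[str, str, str]] | None = None,
    phase: str = "visible",
    context: str = "HP",
) -> Design:
    """Hand-built design with widely spaced trials (no HRF overlap)."""
    if conditions is None:
        conditions = [
            ("up", "fast", "congruent"),
            ("down", "slow", "congruent"),
            ("up", "slow", "congruent"),
            ("down", "fast", "congruent"),
        ]
    trials = []
    lengths = []
    for run in range(n_runs):
        onset = 10.0
        for i in range(onsets_per_run):
            d, v, c = conditions[i % len(conditions)]
            trials.append(
                TrialEvent(
                    run_index=run,
                    onset=onset,
                    horizontal_duration=0.25,
                    vertical_duration=0.4,
                    direction=d,
                    velocity=v,
                    congruency=c,
                    phase=phase,
                    context=context,
                )
            )
            onset += spacing
        lengths.append(int(np.ceil((onset - spacing + 0.65 + 35.0) / 2.0)))
    return Design(trials=trials, n_runs=n_runs, run_length_volumes=lengths)
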