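"""Synthetic 4D BOLD data with planted, recoverable multivoxel patterns.

The simulator emits "preprocessed" volumetric runs on a small isotropic grid
(2.2 mm voxels, TR 2 s by default). Three compact, pairwise-disjoint ROI
blobs stand in for retinotopically delineated lower V1, upper V1 and V5; a
spatially contiguous fraction of each V1 mask is tagged as responsive to the
stimulus reappearance (those voxels are excluded downstream).

Signal model per voxel time series::

    y = baseline + sum_trials a_t * p_v * HRF(t - onset_t) + drift + AR(1) noise

where ``p`` is a condition-specific spatial pattern over mask voxels (one
pattern per direction x velocity cell, plus an additive incongruency
pattern) and ``a_t`` the trial amplitude, optionally incremented on
category-switch trials (CI / IC). Visible- and occluded-phase patterns of
the same condition share a configurable correlation rho, which is what makes
cross-phase decoding learnable in the simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from ._rng import substream
from .design import Design
from .hrf import event_regressor

__all__ = [
    "VolumeGrid",
    "RoiMask",
    "EffectSpec",
    "NoiseSpec",
    "BoldRun",
    "generate_grid_and_masks",
    "simulate_bold",
    "save_bold_nifti",
    "save_mask_nifti",
]

DEFAULT_VOXEL_SIZE = 2.2  # mm, isotropic
REGIONS = ("lowerV1", "upperV1", "V5")


@dataclass(frozen=True)
class VolumeGrid:
    """Voxel grid geometry: 0-based indices, voxel-center mm coordinates."""

    dims: tuple[int, int, int]
    voxel_size: float = DEFAULT_VOXEL_SIZE

    def __post_init__(self):
        if any(d < 1 for d in self.dims):
            raise ValueError("grid dims must all be >= 1")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be > 0")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    def flat_to_ijk(self, flat: np.ndarray) -> np.ndarray:
        return np.stack(np.unravel_index(np.asarray(flat), self.dims), axis=-1)

    def ijk_to_flat(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.asarray(ijk)
        return np.ravel_multi_index((ijk[..., 0], ijk[..., 1], ijk[..., 2]), self.dims)

    def coords_mm(self, flat: np.ndarray) -> np.ndarray:
        return self.flat_to_ijk(flat) * self.voxel_size

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size
        return aff


@dataclass
class RoiMask:
    """A named ROI: member voxels plus the reappearance-responsive subset."""

    region: str
    member_voxels: np.ndarray  # sorted flat indices
    reappearance_voxels: np.ndarray  # subset of member_voxels

    def __post_init__(self):
        self.member_voxels = np.sort(np.asarray(self.member_voxels, dtype=int))
        self.reappearance_voxels = np.sort(
            np.asarray(self.reappearance_voxels, dtype=int)
        )
        if not np.isin(self.reappearance_voxels, self.member_voxels).all():
            raise ValueError("reappearance_voxels must be a subset of member_voxels")

    @property
    def n_voxels(self) -> int:
        return len(self.member_voxels)

    @property
    def retained_voxels(self) -> np.ndarray:
        """Member voxels minus the reappearance-tagged subset."""
        return np.setdiff1d(self.member_voxels, self.reappearance_voxels)


@dataclass
class EffectSpec:
    """Planted effect sizes and pattern structure.

    amplitude : scalar BOLD amplitude of every direction x velocity pattern
        (signal units; with NoiseSpec.white_sd = 1 this is the single-trial
        contrast-to-noise ratio at a unit-pattern voxel).
    incongruency_amplitude : amplitude of the additive pattern distinguishing
        incongruent from congruent trials.
    mean_response : uniform (spatial-mean) response amplitude shared by all
        mask voxels on every trial — the univariate activation component on
        which trial-history modulation is observable (the multivoxel
        patterns are z-scored, hence spatially zero-mean).
    switch_increment : fractional amplitude increase on trials whose
        congruency category differs from the preceding trial's (CI / IC).
    amplitude_jitter_sd : SD of multiplicative trial-to-trial amplitude
        variability (lognormal-free Gaussian factor, floored at 0).
    cross_phase_corr : correlation rho between the visible and occluded
        pattern of the same condition.
    baseline : constant signal offset.
    """

    amplitude: float = 1.0
    incongruency_amplitude: float = 0.0
    mean_response: float = 1.0
    switch_increment: float = 0.0
    amplitude_jitter_sd: float = 0.0
    cross_phase_corr: float = 0.7
    baseline: float = 100.0


@dataclass
class NoiseSpec:
    """AR(1) + white measurement noise and slow sinusoidal drift.

    white_sd is the innovation SD of the AR(1) process (ar_coef = 0 gives
    plain white noise); drift_amplitude scales a cosine of period
    drift_period seconds with a random phase per voxel.
    """

    ar_coef: float = 0.4
    white_sd: float = 1.0
    drift_amplitude: float = 1.0
    drift_period: float = 128.0


@dataclass
class BoldRun:
    """One simulated run: 4D data, motion table and planted ground truth."""

    data: np.ndarray  # (x, y, z, t)
    tr: float
    motion_params: pd.DataFrame  # t rows x 6 columns
    ground_truth: dict = field(default_factory=dict)

    @property
    def n_volumes(self) -> int:
        return self.data.shape[-1]


def generate_grid_and_masks(
    dims: tuple[int, int, int],
    seed: int,
    region_size: int = 160,
    reappearance_fraction: float = 0.1,
    voxel_size: float = DEFAULT_VOXEL_SIZE,
) -> tuple[VolumeGrid, list[RoiMask]]:
    """Build a grid and three disjoint compact ROI blobs.

    Each blob is the ``region_size`` voxels nearest its (slightly jittered)
    center among the voxels for which that center is the closest of the
    three, which makes the blobs compact and pairwise disjoint by
    construction. A contiguous ``reappearance_fraction`` of each V1 mask is
    tagged as reappearance-responsive.
    """
    grid = VolumeGrid(tuple(int(d) for d in dims), voxel_size)
    if region_size < 150:
        raise ValueError("region_size must be >= 150 voxels")
    rng = substream(seed, "masks")

    shape = np.array(grid.dims, dtype=float)
    frac_centers = np.array(
        [[0.28, 0.30, 0.45], [0.28, 0.70, 0.45], [0.75, 0.50, 0.55]]
    )
    centers = frac_centers * (shape - 1) + rng.uniform(-0.3, 0.3, size=(3, 3))

    ijk = np.stack(
        np.meshgrid(*[np.arange(d) for d in grid.dims], indexing="ij"), axis=-1
    ).reshape(-1, 3)
    d2 = ((ijk[:, None, :] - centers[None, :, :]) ** 2).sum(-1)  # (n_vox, 3)
    nearest = d2.argmin(1)

    masks: list[RoiMask] = []
    for r, region in enumerate(REGIONS):
        candidates = np.flatnonzero(nearest == r)
        if len(candidates) < max(150, region_size):
            raise ValueError(
                f"grid dims {grid.dims} too small: region {region} can hold only "
                f"{len(candidates)} voxels (need >= {max(150, region_size)})"
            )
        order = candidates[np.argsort(d2[candidates, r], kind="stable")]
        members = np.sort(order[:region_size])

        reapp = np.array([], dtype=int)
        n_reapp = int(round(reappearance_fraction * len(members)))
        if region != "V5" and n_reapp > 0:
            # contiguous cap: the n_reapp members nearest the most peripheral
            # member voxel (where the reappearing stimulus would map)
            coords = ijk[members]
            peri = coords[np.argmax(((coords - centers[r]) ** 2).sum(1))]
            dd = ((coords - peri) ** 2).sum(1)
            reapp = members[np.argsort(dd, kind="stable")[:n_reapp]]
        masks.append(
            RoiMask(region=region, member_voxels=members, reappearance_voxels=reapp)
        )
    return grid, masks


def _condition_patterns(
    masks: list[RoiMask], effects: EffectSpec, seed: int
) -> dict[str, dict[str, dict[str, np.ndarray]]]:
    """Draw per-region, per-channel pattern pairs for both phases.

    Channels are the four direction x velocity cells plus 'incongruent'.
    Visible patterns are z-scored standard normal draws over mask voxels;
    the occluded partner is rho * visible + sqrt(1 - rho^2) * independent,
    so the pair correlates at ~rho.
    """
    rho = float(effects.cross_phase_corr)
    channels = ["up_fast", "up_slow", "down_fast", "down_slow", "incongruent"]
    out: dict[str, dict[str, dict[str, np.ndarray]]] = {}
    for mask in masks:
        n = mask.n_voxels
        out[mask.region] = {}
        for ch in channels:
            rng = substream(seed, "patterns", mask.region, ch)
            base = rng.standard_normal(n)
            indep = rng.standard_normal(n)
            vis = (base - base.mean()) / base.std()
            ind = (indep - indep.mean()) / indep.std()
            occ = rho * vis + np.sqrt(max(0.0, 1.0 - rho**2)) * ind
            out[mask.region][ch] = {"visible": vis, "occluded": occ}
    return out


def _trial_gain(design: Design, effects: EffectSpec, seed: int) -> np.ndarray:
    """Per-trial multiplicative gain: switch increment x optional jitter."""
    gain = np.ones(design.n_trials)
    prev_run, prev_cong = None, None
    for i, t in enumerate(design.trials):
        if prev_run == t.run_index and prev_cong is not None:
            if t.congruency != prev_cong:
                gain[i] *= 1.0 + float(effects.switch_increment)
        prev_run, prev_cong = t.run_index, t.congruency
    if effects.amplitude_jitter_sd > 0:
        rng = substream(seed, "amplitude-jitter", design.phase)
        jitter = 1.0 + rng.standard_normal(design.n_trials) * float(
            effects.amplitude_jitter_sd
        )
        gain *= np.clip(jitter, 0.0, None)
    return gain


def simulate_bold(
    design: Design,
    grid: VolumeGrid,
    masks: list[RoiMask],
    effects: EffectSpec,
    noise: NoiseSpec,
    seed: int,
) -> list[BoldRun]:
    """Simulate one run list of 4D BOLD data for a design.

    Patterns are drawn from a phase-independent substream of ``seed``, so
    simulating the visible and occluded designs of one subject with the same
    seed plants the correlated cross-phase pattern pairs.
    """
    patterns = _condition_patterns(masks, effects, seed)
    phase = design.phase
    gain = _trial_gain(design, effects, seed)

    runs: list[BoldRun] = []
    for run in range(design.n_runs):
        trial_idx = [i for i, t in enumerate(design.trials) if t.run_index == run]
        trials = [design.trials[i] for i in trial_idx]
        n_vol = design.run_length_volumes[run]
        rng = substream(seed, "bold", phase, run)

        data = np.full((grid.n_voxels, n_vol), float(effects.baseline))

        onsets = np.array([t.onset for t in trials])
        run_gain = gain[trial_idx]
        for mask in masks:
            sig = np.zeros((mask.n_voxels, n_vol))
            # direction x velocity channels
            for ch in ("up_fast", "up_slow", "down_fast", "down_slow"):
                d, v = ch.split("_")
                sel = np.array(
                    [t.direction == d and t.velocity == v for t in trials]
                )
                if sel.any() and effects.amplitude != 0.0:
                    reg = event_regressor(
                        onsets[sel], n_vol, design.tr,
                        amplitudes=run_gain[sel] * float(effects.amplitude),
                    )
                    sig += np.outer(patterns[mask.region][ch][phase], reg)
            # additive incongruency channel
            sel = np.array([t.congruency == "incongruent" for t in trials])
            if sel.any() and effects.incongruency_amplitude != 0.0:
                reg = event_regressor(
                    onsets[sel], n_vol, design.tr,
                    amplitudes=run_gain[sel] * float(effects.incongruency_amplitude),
                )
                sig += np.outer(patterns[mask.region]["incongruent"][phase], reg)
            # uniform (spatial-mean) activation shared by every mask voxel
            if effects.mean_response != 0.0:
                reg = event_regressor(
                    onsets, n_vol, design.tr,
                    amplitudes=run_gain * float(effects.mean_response),
                )
                sig += reg[None, :]
            data[mask.member_voxels] += sig

        if noise.white_sd > 0:
            innov = rng.standard_normal((grid.n_voxels, n_vol)) * noise.white_sd
            data += lfilter([1.0], [1.0, -float(noise.ar_coef)], innov, axis=1)
        if noise.drift_amplitude > 0:
            t_sec = np.arange(n_vol) * design.tr
            omega = 2.0 * np.pi / noise.drift_period
            phase_v = rng.uniform(0, 2 * np.pi, grid.n_voxels)
            data += noise.drift_amplitude * (
                np.outer(np.cos(phase_v), np.cos(omega * t_sec))
                - np.outer(np.sin(phase_v), np.sin(omega * t_sec))
            )

        walk = rng.standard_normal((n_vol, 6)) * 0.01
        motion = pd.DataFrame(
            np.cumsum(walk, axis=0),
            columns=["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"],
        )

        runs.append(
            BoldRun(
                data=data.reshape(*grid.dims, n_vol),
                tr=design.tr,
                motion_params=motion,
                ground_truth={
                    "trial_gain": run_gain,
                    "trial_amplitudes": run_gain * float(effects.amplitude),
                    "trial_indices": np.array(trial_idx),
                    "patterns": patterns,
                },
            )
        )
    return runs


def save_bold_nifti(run: BoldRun, grid: VolumeGrid, path) -> None:
    import nibabel as nib

    nib.save(nib.Nifti1Image(run.data.astype(np.float32), grid.affine), str(path))


def save_mask_nifti(mask: RoiMask, grid: VolumeGrid, path) -> None:
    import nibabel as nib

    vol = np.zeros(grid.n_voxels, dtype=np.int16)
    vol[mask.member_voxels] = 1
    vol[mask.reappearance_voxels] = 2  # tagged-for-exclusion subset
    nib.save(nib.Nifti1Image(vol.reshape(grid.dims), grid.affine), str(path))
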