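"""Experiment designs for the interception (occluded-motion) paradigm.

A trial is a dot travelling horizontally, then turning up or down; the
horizontal velocity (fast, 16.6 deg/s; slow, 14.4 deg/s) predicts the
vertical direction within a run. Each run uses one of two velocity-direction
configurations (up-fast/down-slow or up-slow/down-fast), two runs of each.
In the low-predictability (LP) context, 30% of trials are incongruent: the
dot changes speed at the turning point, and the vertical segment then always
lasts the fixed 0.716 s regardless of the horizontal speed. The
high-predictability (HP) context has congruent trials only.

Paper-faithful trial counts (the generator defaults):

========  ========  ======  ===========
context   phase     trials  incongruent
========  ========  ======  ===========
HP        visible    240      0
HP        occluded   400      0
LP        visible    240     72
LP        occluded   400    120
========  ========  ======  ===========

always over 4 runs, incongruent trials exactly counterbalanced across the
four direction x velocity cells. Inter-trial intervals are integers drawn
from a Poisson(4) law conditioned on the support {2..6} s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream

__all__ = [
    "TrialEvent",
    "Design",
    "generate_design",
    "design_to_events",
    "events_to_design",
    "TR",
    "HORIZONTAL_DURATION",
    "VERTICAL_DURATION_CONGRUENT",
    "VERTICAL_DURATION_INCONGRUENT",
]

TR = 2.0  # s, repetition time

# Stimulus timing from the 200 px trajectories: fast = 800 px/s, slow ~ 445 px/s.
HORIZONTAL_DURATION = {"fast": 0.250, "slow": 0.450}
# Congruent vertical segment (200 px to the mark + 120 px beyond).
VERTICAL_DURATION_CONGRUENT = {"fast": 0.400, "slow": 0.716}
# Incongruent trials change speed at the turn; the vertical segment is held
# at this constant total duration for both speed-up and slow-down trials.
VERTICAL_DURATION_INCONGRUENT = 0.716

RUN_CONFIGURATIONS = ("up-fast/down-slow", "up-slow/down-fast")
_CONFIG_CELLS = {
    "up-fast/down-slow": (("up", "fast"), ("down", "slow")),
    "up-slow/down-fast": (("up", "slow"), ("down", "fast")),
}

_ITI_RATE = 4.0  # Poisson rate for the inter-trial interval, s
_ITI_LOW, _ITI_HIGH = 2, 6
_LEAD_IN = 10.0  # s of rest before the first trial of a run
_TAIL = 20.0  # s appended after the last trial for HRF decay
INCONGRUENT_FRACTION = 0.3


@dataclass(frozen=True)
class TrialEvent:
    """One trial: condition labels plus its timing within a run."""

    run_index: int
    onset: float
    horizontal_duration: float
    vertical_duration: float
    direction: str  # up | down
    velocity: str  # fast | slow (horizontal-trajectory speed)
    congruency: str  # congruent | incongruent
    phase: str  # visible | occluded
    context: str  # HP | LP

    @property
    def duration(self) -> float:
        return self.horizontal_duration + self.vertical_duration

    @property
    def condition(self) -> str:
        return f"{self.direction}_{self.velocity}_{self.congruency}"


@dataclass
class Design:
    """An ordered trial list with run geometry."""

    trials: list[TrialEvent]
    n_runs: int
    run_length_volumes: list[int]
    tr: float = TR
    run_configuration: list[str] = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def run_trials(self, run: int) -> list[TrialEvent]:
        return [t for t in self.trials if t.run_index == run]

    @property
    def conditions(self) -> list[str]:
        return sorted({t.condition for t in self.trials})

    @property
    def phase(self) -> str:
        return self.trials[0].phase

    @property
    def context(self) -> str:
        return self.trials[0].context


def _draw_iti(rng: np.random.Generator) -> int:
    """Integer ITI ~ Poisson(4) conditioned on {2..6} s (rejection draw)."""
    while True:
        k = int(rng.poisson(_ITI_RATE))
        if _ITI_LOW <= k <= _ITI_HIGH:
            return k


def generate_design(
    context: str,
    phase: str,
    seed: int,
    trials_per_cell_per_run: int | None = None,
) -> Design:
    """Generate a counterbalanced design for one context x phase session.

    Parameters
    ----------
    context : "HP" or "LP".
    phase : "visible" or "occluded".
    seed : top-level seed; the design is deterministic given it.
    trials_per_cell_per_run : optional reduced trial count per
        direction-velocity cell per run (paper-faithful defaults: 30 for
        visible, 50 for occluded). When reduced, the 30% incongruent
        fraction of the LP context is kept, rounded per cell.
    """
    if context not in ("HP", "LP"):
        raise ValueError(f"unknown context {context!r}")
    if phase not in ("visible", "occluded"):
        raise ValueError(f"unknown phase {phase!r}")
    rng = substream(seed, "design", context, phase)

    if trials_per_cell_per_run is None:
        trials_per_cell_per_run = 30 if phase == "visible" else 50
    n_cell = int(trials_per_cell_per_run)
    if n_cell < 1:
        raise ValueError("trials_per_cell_per_run must be >= 1")
    # counterbalanced incongruent count per cell per run (exactly 30% at the
    # paper's counts: 9/30 visible, 15/50 occluded)
    n_incong_cell = (
        int(round(INCONGRUENT_FRACTION * n_cell)) if context == "LP" else 0
    )

    configs = [RUN_CONFIGURATIONS[0]] * 2 + [RUN_CONFIGURATIONS[1]] * 2
    order = rng.permutation(4)
    run_configs = [configs[i] for i in order]

    trials: list[TrialEvent] = []
    run_lengths: list[int] = []
    for run in range(4):
        cells = _CONFIG_CELLS[run_configs[run]]
        run_specs: list[tuple[str, str, str]] = []
        for direction, velocity in cells:
            for i in range(n_cell):
                cong = "incongruent" if i < n_incong_cell else "congruent"
                run_specs.append((direction, velocity, cong))
        perm = rng.permutation(len(run_specs))
        onset = _LEAD_IN
        last_end = onset
        for j in perm:
            direction, velocity, cong = run_specs[j]
            h_dur = HORIZONTAL_DURATION[velocity]
            v_dur = (
                VERTICAL_DURATION_INCONGRUENT
                if cong == "incongruent"
                else VERTICAL_DURATION_CONGRUENT[velocity]
            )
            trials.append(
                TrialEvent(
                    run_index=run,
                    onset=onset,
                    horizontal_duration=h_dur,
                    vertical_duration=v_dur,
                    direction=direction,
                    velocity=velocity,
                    congruency=cong,
                    phase=phase,
                    context=context,
                )
            )
            last_end = onset + h_dur + v_dur
            onset = last_end + _draw_iti(rng)
        run_lengths.append(int(math.ceil((last_end + _TAIL) / TR)))

    return Design(
        trials=trials,
        n_runs=4,
        run_length_volumes=run_lengths,
        tr=TR,
        run_configuration=run_configs,
    )


def design_to_events(design: Design) -> pd.DataFrame:
    """Serialize a Design as a BIDS-style events table."""
    rows = [
        {
            "onset": t.onset,
            "duration": t.duration,
            "trial_type": t.condition,
            "run": t.run_index,
            "phase": t.phase,
            "context": t.context,
        }
        for t in design.trials
    ]
    return pd.DataFrame(rows)


def events_to_design(
    events: pd.DataFrame,
    run_length_volumes: list[int],
    tr: float = TR,
) -> Design:
    """Rebuild a Design from an events table (inverse of design_to_events)."""
    trials = []
    for _, row in events.iterrows():
        direction, velocity, cong = str(row["trial_type"]).split("_")
        h_dur = HORIZONTAL_DURATION[velocity]
        trials.append(
            TrialEvent(
                run_index=int(row["run"]),
                onset=float(row["onset"]),
                horizontal_duration=h_dur,
                vertical_duration=float(row["duration"]) - h_dur,
                direction=direction,
                velocity=velocity,
                congruency=cong,
                phase=str(row["phase"]),
                context=str(row["context"]),
            )
        )
    n_runs = int(events["run"].max()) + 1
    return Design(
        trials=trials,
        n_runs=n_runs,
        run_length_volumes=list(run_length_volumes),
        tr=tr,
    )
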