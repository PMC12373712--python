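"""Trial-history (CC / CI / IC / II) labelling and contrasts.

Each trial after the first of a run is labelled by the ordered pair
(previous trial's congruency, current trial's congruency): CC, CI, IC, II,
with C = congruent, I = incongruent. CI therefore names a congruent trial
FOLLOWED BY an incongruent one, and the labelled trial is the second element
of the pair — the pair-order reading of the bracket notation. (The source
literature's figure caption uses the opposite, "after", reading; the two
disagree and the pair-order body text is implemented here. See the methods
note.) Run boundaries are never bridged.

Category differences in mean ROI betas are tested with a one-way
repeated-measures ANOVA over the four categories (statsmodels ``AnovaRM``;
F on (3, 3(n-1)) degrees of freedom, no sphericity correction) plus the six
pairwise paired-t contrasts, Bonferroni-corrected (p x 6, capped at 1).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.anova import AnovaRM

from .design import Design

__all__ = [
    "HistoryLabel",
    "HistorySummary",
    "label_trial_sequences",
    "history_contrasts",
    "CATEGORIES",
]

logger = logging.getLogger(__name__)

CATEGORIES = ("CC", "CI", "IC", "II")
_LETTER = {"congruent": "C", "incongruent": "I"}


@dataclass(frozen=True)
class HistoryLabel:
    """Congruency-pair category of one trial (the pair's second element)."""

    value: str  # CC | CI | IC | II
    trial_index: int  # index into design.trials
    run_index: int


@dataclass
class HistorySummary:
    """Cell means, RM-ANOVA F and Bonferroni-corrected paired contrasts."""

    cell_means: pd.DataFrame  # subject x category
    f_value: float
    df: tuple[int, int]
    p_value: float
    contrasts: pd.DataFrame  # columns: pair, mean_diff, t, p_raw, p_bonf
    n_subjects: int


def label_trial_sequences(design: Design) -> list[HistoryLabel]:
    """Label every non-first-of-run trial with its congruency-pair category."""
    if all(t.congruency == "congruent" for t in design.trials):
        logger.warning(
            "design has no incongruent trials (HP context): all history "
            "labels are CC — degenerate for contrasts"
        )
    labels: list[HistoryLabel] = []
    prev_run: int | None = None
    prev_letter = ""
    for i, t in enumerate(design.trials):
        letter = _LETTER[t.congruency]
        if t.run_index == prev_run:
            labels.append(
                HistoryLabel(
                    value=prev_letter + letter, trial_index=i, run_index=t.run_index
                )
            )
        prev_run, prev_letter = t.run_index, letter
    return labels


def history_contrasts(
    values: np.ndarray,
    categories: np.ndarray,
    subjects: np.ndarray,
) -> HistorySummary:
    """Repeated-measures test of the four history categories.

    Parameters
    ----------
    values : per-trial (or per-cell) mean ROI beta.
    categories : per-entry category in {CC, CI, IC, II}.
    subjects : per-entry subject identifier.

    Entries are first aggregated to subject x category cell means; subjects
    missing a category are excluded with a logged warning.
    """
    df = pd.DataFrame(
        {
            "value": np.asarray(values, dtype=float),
            "category": np.asarray(categories),
            "subject": np.asarray(subjects),
        }
    )
    cells = (
        df.groupby(["subject", "category"], sort=True)["value"]
        .mean()
        .unstack("category")
    )
    missing = cells.index[cells[list(CATEGORIES)].isna().any(axis=1)]
    if len(missing):
        logger.warning(
            "excluding %d subject(s) missing a history category: %s",
            len(missing),
            list(missing),
        )
        cells = cells.drop(index=missing)
    n = len(cells)
    if n < 2:
        raise ValueError("need >= 2 subjects with all four categories")

    df1, df2 = 3, 3 * (n - 1)
    centered = cells[list(CATEGORIES)].to_numpy()
    centered = centered - centered.mean(axis=1, keepdims=True)
    if np.allclose(centered.std(axis=0), 0.0) and np.allclose(
        centered.mean(axis=0), 0.0
    ):
        # identical category profiles for every subject: 0/0 by convention 0
        f_value, p_value = 0.0, 1.0
    else:
        long = cells[list(CATEGORIES)].reset_index().melt(
            id_vars="subject", var_name="category", value_name="value"
        )
        res = AnovaRM(long, "value", "subject", within=["category"]).fit()
        row = res.anova_table.iloc[0]
        f_value = float(row["F Value"])
        df1, df2 = int(row["Num DF"]), int(row["Den DF"])
        p_value = float(row["Pr > F"])

    rows = []
    for a, b in itertools.combinations(CATEGORIES, 2):
        diff = cells[a] - cells[b]
        if np.allclose(diff.std(ddof=1), 0.0):
            t, p = (0.0, 1.0) if np.allclose(diff, 0.0) else (np.inf, 0.0)
        else:
            t, p = stats.ttest_rel(cells[a], cells[b])
        rows.append(
            {
                "pair": f"{a}-{b}",
                "mean_diff": float(diff.mean()),
                "t": float(t),
                "p_raw": float(p),
                "p_bonf": min(1.0, 6.0 * float(p)),
            }
        )
    return HistorySummary(
        cell_means=cells,
        f_value=f_value,
        df=(df1, df2),
        p_value=p_value,
        contrasts=pd.DataFrame(rows),
        n_subjects=n,
    )
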