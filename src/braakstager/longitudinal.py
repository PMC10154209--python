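"""Longitudinal stage-transition summaries and the amyloid-gating analysis.

Subjects with a baseline and a follow-up tau-PET scan contribute a
baseline-stage -> follow-up-stage path.  The summary tabulates the 7x7
transition matrix and four mutually exclusive outcomes: stability
(follow-up == baseline), one-step progression (+1), multi-step progression
(>= +2) and regression (follow-up < baseline; under a hierarchical model
regressions are interpreted as misclassifications).

The gating analysis stratifies per-baseline-stage progression rates by
baseline amyloid-beta status, to test the observation that progression
beyond stage III occurs only in amyloid-positive individuals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

N_STATES = 7  # stages 0..6

INTERVALS = ("1y", "2y")
VISIT_TO_INTERVAL = {"year1": "1y", "year2": "2y"}


@dataclass
class StagePath:
    """One subject's baseline -> follow-up stage pair over a fixed interval."""

    subject_id: str
    baseline_stage: int
    followup_stage: int
    interval: str
    baseline_amyloid_positive: Optional[bool] = None

    def __post_init__(self) -> None:
        for name in ("baseline_stage", "followup_stage"):
            s = getattr(self, name)
            if not 0 <= s <= 6:
                raise ValueError(f"{name} must be in 0..6, got {s}")
        if self.interval not in INTERVALS:
            raise ValueError(f"interval must be one of {INTERVALS}, got {self.interval!r}")


@dataclass
class TransitionSummary:
    """Baseline x follow-up stage counts with outcome fractions."""

    counts: np.ndarray  # (7, 7) int
    interval: str
    n: int
    prop_stable: float
    prop_progress_one: float
    prop_progress_multi: float
    prop_regress: float

    def row_proportions(self) -> np.ndarray:
        """Counts normalized within each nonempty baseline row."""
        totals = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(totals > 0, self.counts / totals, np.nan)


def summarize_transitions(paths: Iterable[StagePath], interval: str) -> TransitionSummary:
    """Tally stage transitions for one follow-up interval.

    Raises if no path matches the interval or a subject appears twice.
    """
    if interval not in INTERVALS:
        raise ValueError(f"interval must be one of {INTERVALS}, got {interval!r}")
    selected = [p for p in paths if p.interval == interval]
    if not selected:
        raise ValueError(f"no stage paths at interval {interval!r}")
    seen = set()
    for p in selected:
        if p.subject_id in seen:
            raise ValueError(f"duplicate subject {p.subject_id!r} within interval {interval!r}")
        seen.add(p.subject_id)

    counts = np.zeros((N_STATES, N_STATES), dtype=int)
    stable = one = multi = regress = 0
    for p in selected:
        counts[p.baseline_stage, p.followup_stage] += 1
        delta = p.followup_stage - p.baseline_stage
        if delta == 0:
            stable += 1
        elif delta == 1:
            one += 1
        elif delta >= 2:
            multi += 1
        else:
            regress += 1
    n = len(selected)
    return TransitionSummary(
        counts=counts,
        interval=interval,
        n=n,
        prop_stable=stable / n,
        prop_progress_one=one / n,
        prop_progress_multi=multi / n,
        prop_regress=regress / n,
    )


def amyloid_gated_progression(paths: Sequence[StagePath]) -> pd.DataFrame:
    """Per-baseline-stage progression rates stratified by amyloid status.

    Returns a table indexed by baseline stage 0..6 with, per amyloid stratum,
    the number at risk, the number who progressed (follow-up > baseline) and
    the progression rate.  A stratum with nobody at risk gets a missing rate
    (NaN), never 0.  The ``abeta_neg_progression`` column flags stages where
    any amyloid-negative subject progressed — under the gating hypothesis this
    should be empty from stage III on.
    """
    missing = [p.subject_id for p in paths if p.baseline_amyloid_positive is None]
    if missing:
        raise ValueError(f"baseline amyloid status missing for subjects: {missing}")

    rows = []
    for stage in range(N_STATES):
        at_stage = [p for p in paths if p.baseline_stage == stage]
        row: dict = {"baseline_stage": stage}
        for label, positive in (("pos", True), ("neg", False)):
            stratum = [p for p in at_stage if p.baseline_amyloid_positive is positive]
            n_risk = len(stratum)
            n_prog = sum(p.followup_stage > p.baseline_stage for p in stratum)
            row[f"n_at_risk_{label}"] = n_risk
            row[f"n_progressed_{label}"] = n_prog
            row[f"rate_{label}"] = n_prog / n_risk if n_risk else np.nan
        row["abeta_neg_progression"] = row["n_progressed_neg"] > 0
        rows.append(row)
    return pd.DataFrame(rows).set_index("baseline_stage")


def gating_report(progression: pd.DataFrame, gate_stage: int = 3) -> dict:
    """Summarize whether amyloid-negative progression occurs at/after the gate."""
    gated = progression.loc[gate_stage:]
    violations = gated.index[gated["abeta_neg_progression"]].tolist()
    return {
        "gate_stage": gate_stage,
        "abeta_neg_progressions_at_or_after_gate": int(
            gated["n_progressed_neg"].sum()
        ),
        "violating_stages": violations,
        "gated": len(violations) == 0,
    }


def paths_from_assignments(
    assignments: pd.DataFrame, amyloid_column: str = "amyloid_pet_positive"
) -> List[StagePath]:
    """Build stage paths from a staged assignments table.

    Expects one row per subject-visit with ``visit`` in {baseline, year1,
    year2}.  Each follow-up visit is paired with the subject's baseline;
    subjects with both follow-ups contribute one path per interval.
    Baseline amyloid status is taken from ``amyloid_column`` at baseline.
    """
    required = {"subject_id", "visit", "stage"}
    if not required.issubset(assignments.columns):
        raise ValueError(f"assignments table needs columns {sorted(required)}")
    baselines = assignments[assignments["visit"] == "baseline"].set_index("subject_id")
    if baselines.index.has_duplicates:
        dups = baselines.index[baselines.index.duplicated()].tolist()
        raise ValueError(f"duplicate baseline rows for subjects: {dups}")
    paths: List[StagePath] = []
    for visit, interval in VISIT_TO_INTERVAL.items():
        for _, row in assignments[assignments["visit"] == visit].iterrows():
            sid = row["subject_id"]
            if sid not in baselines.index:
                raise ValueError(f"subject {sid!r} has visit {visit!r} but no baseline")
            base = baselines.loc[sid]
            amyloid = None
            if amyloid_column in baselines.columns:
                value = base[amyloid_column]
                amyloid = None if pd.isna(value) else bool(value)
            paths.append(
                StagePath(
                    subject_id=str(sid),
                    baseline_stage=int(base["stage"]),
                    followup_stage=int(row["stage"]),
                    interval=interval,
                    baseline_amyloid_positive=amyloid,
                )
            )
    return paths
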