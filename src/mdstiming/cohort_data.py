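"""Panel-observed cohort data model and CSV I/O.

A cohort holds one record per subject.  Intermediate disease states are
observed only at visit times (interval-censored panel observations), while
death times are exact; a censor row marks the end of follow-up alive.
Time is measured in decimal years since subject entry — diagnosis for
natural-history subjects, transplantation for transplanted-cohort subjects.

CSV dialect (one row per observation, UTF-8, dot decimal):

    subject_id, age_at_entry, time_years, state, kind, post_hsct

with ``kind`` in {panel, death, censor} and ``post_hsct`` in {0, 1}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .model_core import Scheme, StateSpace, TransitionStructure, build_state_space

__all__ = [
    "ObsKind",
    "Observation",
    "SubjectRecord",
    "Cohort",
    "read_cohort",
    "write_cohort",
    "validate_cohort",
]

_COLUMNS = ["subject_id", "age_at_entry", "time_years", "state", "kind", "post_hsct"]


class ObsKind(str, Enum):
    PANEL = "panel"
    DEATH = "death"
    CENSOR = "censor"


@dataclass(frozen=True)
class Observation:
    """A single observation of a subject at a point in follow-up time."""

    time: float  # years since subject entry
    state: int  # state index
    kind: ObsKind
    post_hsct: bool  # covariate value at this time


@dataclass
class SubjectRecord:
    subject_id: str
    age_at_entry: float
    observations: list[Observation]
    hsct_time: float | None = None  # time the covariate switches 0 -> 1

    @property
    def entry_state(self) -> int:
        return self.observations[0].state


@dataclass
class Cohort:
    scheme: Scheme
    subjects: list[SubjectRecord]
    label: str = ""

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)


def _subject_from_rows(
    sid: str, rows: pd.DataFrame, space: StateSpace
) -> SubjectRecord:
    obs: list[Observation] = []
    prev_t = None
    seen_terminal = False
    for _, row in rows.iterrows():
        t = float(row.time_years)
        if prev_t is not None and t <= prev_t:
            raise ValueError(
                f"subject {sid}: observation times not strictly increasing at t={t}"
            )
        if seen_terminal:
            raise ValueError(f"subject {sid}: observation after death/censor at t={t}")
        kind = ObsKind(str(row.kind))
        state = space.index(str(row.state))
        if kind is ObsKind.DEATH and state != space.death_index:
            raise ValueError(f"subject {sid}: death observation must be in the Death state")
        if kind is not ObsKind.DEATH and state == space.death_index:
            raise ValueError(f"subject {sid}: non-death observation in the Death state")
        obs.append(Observation(t, state, kind, bool(int(row.post_hsct))))
        if kind in (ObsKind.DEATH, ObsKind.CENSOR):
            seen_terminal = True
        prev_t = t
    # infer hsct_time as the first time the covariate is 1
    hsct_time = None
    for o in obs:
        if o.post_hsct:
            hsct_time = o.time
            break
    return SubjectRecord(
        subject_id=sid,
        age_at_entry=float(rows.age_at_entry.iloc[0]),
        observations=obs,
        hsct_time=hsct_time,
    )


def read_cohort(path: str | Path, scheme: Scheme | str, label: str = "") -> Cohort:
    """Read and validate a cohort CSV; rows grouped by subject, ordered by time."""
    space, _ = build_state_space(scheme)
    df = pd.read_csv(
        path, dtype={"subject_id": str}, comment="#", float_precision="round_trip"
    )
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file {path} missing columns: {missing}")
    df = df.sort_values(["subject_id", "time_years"], kind="stable")
    subjects = [
        _subject_from_rows(sid, rows, space)
        for sid, rows in df.groupby("subject_id", sort=True)
    ]
    return Cohort(scheme=space.scheme, subjects=subjects, label=label)


def write_cohort(cohort: Cohort, path: str | Path) -> Path:
    """Write a cohort in the CSV dialect; deterministic column and row order."""
    space, _ = build_state_space(cohort.scheme)
    rows = []
    for s in sorted(cohort.subjects, key=lambda s: s.subject_id):
        for o in s.observations:
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "age_at_entry": s.age_at_entry,
                    "time_years": o.time,
                    "state": space.states[o.state],
                    "kind": o.kind.value,
                    "post_hsct": int(o.post_hsct),
                }
            )
    df = pd.DataFrame(rows, columns=_COLUMNS)
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.17g")  # exact float round-trip
    return path


def validate_cohort(
    cohort: Cohort, structure: TransitionStructure | None = None
) -> list[str]:
    """Return violations of cohort invariants (empty when valid); pure check.

    Flags risk regressions (observed states must be nondecreasing in the
    risk ordering), non-increasing times, terminal rows not last, and
    covariate flags inconsistent with hsct_time.
    """
    space, default_structure = build_state_space(cohort.scheme)
    violations: list[str] = []
    for s in cohort.subjects:
        if not s.observations:
            violations.append(f"subject {s.subject_id}: no observations")
            continue
        prev = None
        for idx, o in enumerate(s.observations):
            if o.state < 0 or o.state >= space.n_states:
                violations.append(
                    f"subject {s.subject_id}: invalid state index {o.state}"
                )
                continue
            if prev is not None:
                if o.time <= prev.time:
                    violations.append(
                        f"subject {s.subject_id}: non-increasing time at t={o.time}"
                    )
                if o.state < prev.state:
                    violations.append(
                        f"subject {s.subject_id}: risk regression "
                        f"{space.states[prev.state]} -> {space.states[o.state]}"
                    )
                if prev.kind in (ObsKind.DEATH, ObsKind.CENSOR):
                    violations.append(
                        f"subject {s.subject_id}: observation after terminal row"
                    )
            if s.hsct_time is None:
                if o.post_hsct:
                    violations.append(
                        f"subject {s.subject_id}: post_hsct=1 but no hsct_time"
                    )
            else:
                expected = o.time >= s.hsct_time
                if bool(o.post_hsct) != expected:
                    violations.append(
                        f"subject {s.subject_id}: post_hsct flag at t={o.time} "
                        f"inconsistent with hsct_time={s.hsct_time}"
                    )
            prev = o
    return violations
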