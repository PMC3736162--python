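"""Synthetic cohort generation from known true parameters.

The generators emulate the two-cohort design the analysis assumes:

* a supportive-care (natural-history) cohort followed at scheduled visits —
  disease state recorded at each visit, death times exact, administrative
  censoring at end of follow-up, transplant covariate 0 throughout;
* a transplanted cohort observed from transplantation onward — each subject
  enters in a known disease state with covariate 1 and contributes an exact
  death time or a censor at end of follow-up.

All fixture numbers here are invented for testing: they follow the
qualitative structure of real MDS cohorts (death intensities increasing
along the risk ordering, transplant hazard ratios far above 1 in low-risk
states and below 1 in advanced states) but are not estimates from any
published cohort.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from .cohort_data import Cohort, Observation, ObsKind, SubjectRecord
from .model_core import (
    Scheme,
    StateSpace,
    TransitionStructure,
    TransplantEffects,
    apply_transplant_effects,
    build_generator,
    build_state_space,
)

__all__ = [
    "TrueParameters",
    "default_fixture_parameters",
    "generate_natural_history_cohort",
    "generate_transplant_cohort",
]


@dataclass(frozen=True)
class TrueParameters:
    """Ground-truth generator and transplant effects for simulation studies."""

    space: StateSpace
    structure: TransitionStructure
    q: np.ndarray
    effects: TransplantEffects

    @property
    def scheme(self) -> Scheme:
        return self.space.scheme


# invented fixture intensities (per year); death rates strictly increase
# along the risk ordering and the AML death rate is highest
_IPSS_RATES = {
    ("Low", "Int-1"): 0.25, ("Low", "AML"): 0.02, ("Low", "Death"): 0.03,
    ("Int-1", "Int-2"): 0.25, ("Int-1", "AML"): 0.06, ("Int-1", "Death"): 0.08,
    ("Int-2", "High"): 0.30, ("Int-2", "AML"): 0.15, ("Int-2", "Death"): 0.20,
    ("High", "AML"): 0.35, ("High", "Death"): 0.45,
    ("AML", "Death"): 1.2,
}
_IPSS_HRS = {"Low": 3.0, "Int-1": 0.80, "Int-2": 0.60, "High": 0.45, "AML": 0.40}

_WPSS_RATES = {
    ("Very-low", "Low"): 0.20, ("Very-low", "AML"): 0.01, ("Very-low", "Death"): 0.02,
    ("Low", "Intermediate"): 0.22, ("Low", "AML"): 0.03, ("Low", "Death"): 0.05,
    ("Intermediate", "High"): 0.28, ("Intermediate", "AML"): 0.08,
    ("Intermediate", "Death"): 0.12,
    ("High", "Very-high"): 0.30, ("High", "AML"): 0.18, ("High", "Death"): 0.30,
    ("Very-high", "AML"): 0.40, ("Very-high", "Death"): 0.55,
    ("AML", "Death"): 1.2,
}
_WPSS_HRS = {
    "Low": 2.5, "Intermediate": 0.80, "High": 0.55, "Very-high": 0.45, "AML": 0.40,
}

# default entry-state mixes: natural-history subjects skew toward lower risk
# at diagnosis; transplanted subjects toward advanced disease (roughly 30%
# already evolved to AML, as in registry series)
_NH_ENTRY = {
    Scheme.IPSS: {"Low": 0.40, "Int-1": 0.30, "Int-2": 0.20, "High": 0.10},
    Scheme.WPSS: {
        "Very-low": 0.30, "Low": 0.25, "Intermediate": 0.20,
        "High": 0.15, "Very-high": 0.10,
    },
}
_TX_ENTRY = {
    Scheme.IPSS: {"Low": 0.10, "Int-1": 0.20, "Int-2": 0.25, "High": 0.15, "AML": 0.30},
    Scheme.WPSS: {
        "Low": 0.06, "Intermediate": 0.16, "High": 0.40,
        "Very-high": 0.13, "AML": 0.25,
    },
}


def default_fixture_parameters(scheme: Scheme | str) -> TrueParameters:
    """Documented fixture truth for a scheme (invented values, see module docs).

    Death intensities increase strictly with risk; HRs exceed 1 in the
    lowest transplantable state and fall below 1 from the intermediate
    states on, so policy sweeps show delay paying off in low-risk disease
    and immediate transplantation winning at intermediate risk.
    """
    space, structure = build_state_space(scheme)
    if space.scheme is Scheme.IPSS:
        rates, hrs = _IPSS_RATES, _IPSS_HRS
    else:
        rates, hrs = _WPSS_RATES, _WPSS_HRS
    q = build_generator(space, structure, rates)
    effects = TransplantEffects(
        {space.index(lbl): float(np.log(hr)) for lbl, hr in hrs.items()}
    )
    return TrueParameters(space=space, structure=structure, q=q, effects=effects)


def _sample_jump_path(
    q: np.ndarray, start: int, death: int, rng: np.random.Generator
) -> tuple[list[float], list[int]]:
    """Exact jump chain from ``start`` until absorption in ``death``."""
    times = [0.0]
    states = [start]
    s, t = start, 0.0
    while s != death:
        lam = -q[s, s]
        t += rng.exponential(1.0 / lam)
        rates = np.clip(q[s].copy(), 0.0, None)
        rates[s] = 0.0
        s = int(rng.choice(len(rates), p=rates / rates.sum()))
        times.append(t)
        states.append(s)
    return times, states


def _state_at(times: list[float], states: list[int], t: float) -> int:
    idx = int(np.searchsorted(times, t, side="right")) - 1
    return states[idx]


def _entry_sampler(
    space: StateSpace, dist: Mapping[int | str, float] | None, default: dict[str, float],
    rng: np.random.Generator, n: int,
) -> np.ndarray:
    if dist is None:
        dist = default
    idx = np.array(
        [space.index(k) if isinstance(k, str) else int(k) for k in dist], dtype=int
    )
    p = np.asarray(list(dist.values()), dtype=float)
    p = p / p.sum()
    return rng.choice(idx, size=n, p=p)


def generate_natural_history_cohort(
    params: TrueParameters,
    n: int = 660,
    visit_interval: float = 0.5,
    admin_censor: float = 15.0,
    entry_state_dist: Mapping[int | str, float] | None = None,
    age_sampler: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    seed: int | np.random.Generator = 0,
) -> Cohort:
    """Supportive-care cohort observed at scheduled visits.

    Each subject's exact disease path is simulated from the true generator;
    the state is recorded at visit times 0, Δ, 2Δ, ... (panel rows), the
    death time is recorded exactly if it falls before administrative
    censoring, else a censor row closes follow-up.  Covariate 0 throughout.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if visit_interval <= 0:
        raise ValueError("visit_interval must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    space = params.space
    entries = _entry_sampler(space, entry_state_dist, _NH_ENTRY[space.scheme], rng, n)
    ages = (
        age_sampler(rng, n) if age_sampler is not None else rng.uniform(40.0, 75.0, n)
    )
    subjects = []
    for i in range(n):
        times, states = _sample_jump_path(params.q, int(entries[i]), space.death_index, rng)
        death_time = times[-1]
        obs: list[Observation] = []
        t = 0.0
        while t < min(death_time, admin_censor):
            obs.append(Observation(t, _state_at(times, states, t), ObsKind.PANEL, False))
            t += visit_interval
        if death_time <= admin_censor:
            obs.append(Observation(death_time, space.death_index, ObsKind.DEATH, False))
        else:
            obs.append(
                Observation(
                    admin_censor,
                    _state_at(times, states, admin_censor),
                    ObsKind.CENSOR,
                    False,
                )
            )
        subjects.append(
            SubjectRecord(
                subject_id=f"NH{i:05d}",
                age_at_entry=float(np.round(ages[i], 1)),
                observations=obs,
                hsct_time=None,
            )
        )
    return Cohort(scheme=space.scheme, subjects=subjects, label="natural-history")


def generate_transplant_cohort(
    params: TrueParameters,
    n: int = 477,
    state_mix: Mapping[int | str, float] | None = None,
    followup: float = 10.0,
    age_sampler: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    seed: int | np.random.Generator = 0,
) -> Cohort:
    """Transplanted cohort observed from transplantation onward.

    Each subject enters at a transplant state drawn from ``state_mix``
    (covariate 1 from time 0), evolves under the HR-modified generator,
    and contributes an exact death time or a censor at end of follow-up.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    space = params.space
    if state_mix is not None:
        bad = [
            k
            for k in state_mix
            if (space.index(k) if isinstance(k, str) else int(k))
            not in space.transplantable
        ]
        if bad:
            raise ValueError(f"state_mix has mass on non-transplantable state(s): {bad}")
    q1 = apply_transplant_effects(params.q, params.effects, space)
    entries = _entry_sampler(space, state_mix, _TX_ENTRY[space.scheme], rng, n)
    ages = (
        age_sampler(rng, n) if age_sampler is not None else rng.uniform(30.0, 65.0, n)
    )
    subjects = []
    for i in range(n):
        times, states = _sample_jump_path(q1, int(entries[i]), space.death_index, rng)
        death_time = times[-1]
        obs = [Observation(0.0, int(entries[i]), ObsKind.PANEL, True)]
        if death_time <= followup:
            obs.append(Observation(death_time, space.death_index, ObsKind.DEATH, True))
        else:
            obs.append(
                Observation(followup, _state_at(times, states, followup), ObsKind.CENSOR, True)
            )
        subjects.append(
            SubjectRecord(
                subject_id=f"TX{i:05d}",
                age_at_entry=float(np.round(ages[i], 1)),
                observations=obs,
                hsct_time=0.0,
            )
        )
    return Cohort(scheme=space.scheme, subjects=subjects, label="transplanted")
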