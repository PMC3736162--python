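"""Expected survival under delayed-transplantation policies, computed algebraically.

A policy is "transplant on reaching the threshold state s* after a delay of
t months, or immediately on progression past s*; never after the
eligibility age".  Under a time-homogeneous Markov model the value of such
a policy decomposes into three phases:

1. below the threshold the subject is never transplanted, so the expected
   (utility-weighted) time spent there is a plain phase-type expectation;
2. once transplanted the remaining lifetime is again phase-type, under the
   HR-modified generator;
3. the only calendar dependence sits in the threshold sojourn (the delay
   deadline and the eligibility deadline) and in the entry time into the
   threshold, handled by analytic integration over the exponential sojourn
   and quadrature of the phase-type entry-time density.

The same semantics are implemented event-by-event in :mod:`mdstiming.microsim`,
which serves as the independent Monte-Carlo validation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .likelihood import FittedModel
from .model_core import (
    Scheme,
    StateSpace,
    TransplantEffects,
    apply_transplant_effects,
)

__all__ = [
    "NEVER",
    "TransplantPolicy",
    "Utilities",
    "PolicyValue",
    "default_utilities",
    "phase_type_expected_time",
    "no_transplant_value",
    "posttransplant_value",
    "policy_expected_survival",
    "policy_gain",
    "policy_table",
    "format_policy_table",
]

NEVER = "NEVER"  # sentinel threshold: no transplantation ever


@dataclass(frozen=True)
class TransplantPolicy:
    """Delayed-transplantation policy.

    ``threshold_state`` is the state index in which transplantation is
    planned (or :data:`NEVER`); ``delay_months`` the waiting time after
    first entry into it; ``age_at_diagnosis`` fixes the calendar clock for
    the eligibility cutoff (no transplant at or beyond ``eligibility_age``).
    ``initial_state`` defaults to the scheme's lowest risk state.
    """

    threshold_state: int | str
    delay_months: float
    age_at_diagnosis: float
    eligibility_age: float = 65.0
    initial_state: int = 0

    @property
    def delay_years(self) -> float:
        return float(self.delay_months) / 12.0

    @property
    def eligibility_horizon(self) -> float:
        """Years from diagnosis until transplant eligibility is lost."""
        return self.eligibility_age - self.age_at_diagnosis


@dataclass(frozen=True)
class Utilities:
    """QALY utilities: per-state pre-transplant weights and a constant
    post-transplant weight (chronic GvHD averaged in)."""

    pre_transplant: Mapping[int, float]
    post_transplant: float

    def pre_vector(self, space: StateSpace) -> np.ndarray:
        w = np.zeros(space.n_states)
        for k, u in self.pre_transplant.items():
            if not 0.0 <= u <= 1.0:
                raise ValueError(f"utility for state {k} outside [0, 1]: {u}")
            w[k] = u
        return w


def default_utilities(space: StateSpace) -> Utilities:
    """Published-style utilities: 1 for very-low WPSS; 0.95 for low and
    intermediate WPSS / low and int-1 IPSS; 0.90 for high and very-high
    WPSS / int-2 and high IPSS; 0.85 after evolution to AML; 0.9 for
    post-transplant survival."""
    if space.scheme is Scheme.IPSS:
        by_label = {"Low": 0.95, "Int-1": 0.95, "Int-2": 0.90, "High": 0.90, "AML": 0.85}
    else:
        by_label = {
            "Very-low": 1.0,
            "Low": 0.95,
            "Intermediate": 0.95,
            "High": 0.90,
            "Very-high": 0.90,
            "AML": 0.85,
        }
    pre = {space.index(lbl): u for lbl, u in by_label.items()}
    return Utilities(pre_transplant=pre, post_transplant=0.9)


@dataclass(frozen=True)
class PolicyValue:
    """Expected survival under a policy, plain and QALY-adjusted."""

    life_expectancy: float
    qaly: float | None
    gain_vs_no_transplant: float
    method: str  # "algebraic" | "microsim"
    tolerance: float  # quadrature tolerance (algebraic) or MC SE (microsim)


# ---------------------------------------------------------------------------
# phase-type building blocks
# ---------------------------------------------------------------------------

def phase_type_expected_time(
    subgenerator: np.ndarray,
    initial: np.ndarray,
    weights: np.ndarray | None = None,
) -> float:
    """Expected weighted time to absorption: initial' (-A)^-1 weights.

    ``subgenerator`` is the transient-state block A of a generator whose
    missing mass flows to absorbing states; absorption must be certain
    (-A nonsingular), else an error is raised.
    """
    a = np.asarray(subgenerator, dtype=float)
    initial = np.asarray(initial, dtype=float)
    n = a.shape[0]
    if weights is None:
        weights = np.ones(n)
    weights = np.asarray(weights, dtype=float)
    try:
        x = np.linalg.solve(-a, weights)
    except np.linalg.LinAlgError:
        raise ValueError("absorption not certain: -subgenerator is singular") from None
    if not np.all(np.isfinite(x)) or np.linalg.cond(-a) > 1e12:
        raise ValueError("absorption not certain: -subgenerator is singular")
    return float(initial @ x)


def _expected_times_all_states(
    q: np.ndarray, space: StateSpace, weights: np.ndarray
) -> np.ndarray:
    """Vector of expected weighted times to death from every transient state."""
    tr = list(space.transient)
    a = q[np.ix_(tr, tr)]
    x = np.linalg.solve(-a, weights[tr])
    out = np.zeros(space.n_states)
    out[tr] = x
    return out


def no_transplant_value(
    fitted: FittedModel, from_state: int, utilities: Utilities | None = None
) -> float:
    """Expected (weighted) survival from a state with no transplantation."""
    space = fitted.state_space
    w = utilities.pre_vector(space) if utilities else np.ones(space.n_states)
    w[space.death_index] = 0.0
    return float(_expected_times_all_states(fitted.q_hat, space, w)[from_state])


def posttransplant_value(
    fitted: FittedModel, state_at_transplant: int, utilities: Utilities | None = None
) -> float:
    """Expected (weighted) residual survival after transplantation in a state."""
    space = fitted.state_space
    if state_at_transplant not in space.transplantable:
        raise ValueError(
            f"state {space.states[state_at_transplant]} is not transplantable"
        )
    q1 = apply_transplant_effects(fitted.q_hat, fitted.effects_hat, space)
    w = np.ones(space.n_states)
    if utilities is not None:
        w *= utilities.post_transplant
    w[space.death_index] = 0.0
    return float(_expected_times_all_states(q1, space, w)[state_at_transplant])


# ---------------------------------------------------------------------------
# policy value
# ---------------------------------------------------------------------------

def _threshold_sojourn_value(
    u: np.ndarray,
    q0: np.ndarray,
    space: StateSpace,
    s_star: int,
    delay: float,
    t_elig: float,
    w_pre: np.ndarray,
    v1: np.ndarray,
    v0: np.ndarray,
) -> np.ndarray:
    """Residual value G(u) on first entry into the threshold state at time u.

    While in s* the sojourn is exponential with the baseline exit rate; the
    race is between the scheduled transplant (at u + delay, only scheduled
    if it falls before the eligibility horizon), progression (immediate
    transplant while eligible) and death.  After the eligibility horizon
    the remainder is the plain no-transplant value.
    """
    u = np.asarray(u, dtype=float)
    lam = -q0[s_star, s_star]
    d_idx = space.death_index
    if lam <= 0:
        raise ValueError("absorption not certain: threshold state has no exits")
    # progression destinations (anything above s*, excluding death)
    dests = [m for m in space.transient if m > s_star and q0[s_star, m] > 0]
    j_val = sum(q0[s_star, m] * v1[m] for m in dests) / lam
    w = w_pre[s_star]

    out = np.empty_like(u)
    # entered after eligibility lost: never transplanted
    late = u >= t_elig
    out[late] = v0[s_star]
    # schedule fits before the eligibility horizon
    fits = (~late) & (u + delay < t_elig)
    ed = np.exp(-lam * delay)
    out[fits] = w * (1 - ed) / lam + ed * v1[s_star] + (1 - ed) * j_val
    # eligible now but the schedule would land past the horizon: no schedule,
    # progression before the horizon still triggers immediate transplant
    mid = (~late) & (~fits)
    h = t_elig - u[mid]
    eh = np.exp(-lam * h)
    out[mid] = w * (1 - eh) / lam + eh * v0[s_star] + (1 - eh) * j_val
    return out


def _piecewise_grid(a: float, b: float, step: float) -> np.ndarray:
    n = max(2, int(np.ceil((b - a) / step)) + 1)
    return np.linspace(a, b, n)


def _policy_value_once(
    q0: np.ndarray,
    q1: np.ndarray,
    space: StateSpace,
    policy: TransplantPolicy,
    w_pre: np.ndarray,
    w_post: float,
    step: float,
) -> float:
    d_idx = space.death_index
    i0 = policy.initial_state
    t_elig = policy.eligibility_horizon
    v0 = _expected_times_all_states(q0, space, w_pre)
    never = (
        policy.threshold_state == NEVER
        or policy.threshold_state is None
        or t_elig <= 0
    )
    if never:
        return float(v0[i0])
    s_star = int(policy.threshold_state)

    w_post_vec = np.full(space.n_states, w_post)
    w_post_vec[d_idx] = 0.0
    v1 = _expected_times_all_states(q1, space, w_post_vec)

    if i0 > s_star:
        return float(v1[i0])  # immediate transplant at diagnosis (eligible)
    if i0 == s_star:
        return float(
            _threshold_sojourn_value(
                np.array([0.0]), q0, space, s_star, policy.delay_years,
                t_elig, w_pre, v1, v0,
            )[0]
        )

    # pre-threshold phase: states strictly below s*
    b_states = list(range(i0, s_star))
    a_mat = q0[np.ix_(b_states, b_states)]
    alpha = np.zeros(len(b_states))
    alpha[0] = 1.0
    neg_a_inv = np.linalg.inv(-a_mat)
    value = float(alpha @ neg_a_inv @ w_pre[b_states])  # weighted time below s*

    # exits from the pre-threshold phase (threshold entry, AML bypass)
    exit_targets = []
    for j in space.transient:
        if j in b_states:
            continue
        r_j = q0[b_states, j]
        if np.any(r_j > 0):
            exit_targets.append((j, r_j))

    delay = policy.delay_years
    t_break = t_elig - delay

    def residual(j: int, u: np.ndarray) -> np.ndarray:
        if j == s_star:
            return _threshold_sojourn_value(
                u, q0, space, s_star, delay, t_elig, w_pre, v1, v0
            )
        # bypass progression past s*: immediate transplant while eligible
        return np.where(u < t_elig, v1[j], v0[j])

    # quadrature of the entry-time density over [0, t_elig], split at the
    # breakpoint where the scheduled transplant stops fitting the horizon
    pieces = [0.0]
    if 0.0 < t_break < t_elig:
        pieces.append(t_break)
    pieces.append(t_elig)

    for ua, ub in zip(pieces[:-1], pieces[1:]):
        grid = _piecewise_grid(ua, ub, step)
        h = grid[1] - grid[0]
        m_step = expm(a_mat * h)
        rows = np.empty((len(grid), len(b_states)))
        rows[0] = alpha @ expm(a_mat * ua)
        for k in range(1, len(grid)):
            rows[k] = rows[k - 1] @ m_step
        for j, r_j in exit_targets:
            f = rows @ r_j  # entry-time density into j
            integrand = f * residual(j, grid)
            value += float(np.trapezoid(integrand, grid))

    # tail: exit after the eligibility horizon -> no transplant ever
    row_e = alpha @ expm(a_mat * t_elig)
    for j, r_j in exit_targets:
        tail_mass = float(row_e @ neg_a_inv @ r_j)
        value += tail_mass * float(v0[j])
    return value


def policy_expected_survival(
    fitted: FittedModel,
    policy: TransplantPolicy,
    utilities: Utilities | None = None,
    step: float = 0.01,
    richardson: bool = True,
) -> PolicyValue:
    """Expected survival from diagnosis under a delayed-transplant policy.

    Returns both plain life expectancy and (if utilities are given) the
    QALY-adjusted value; ``tolerance`` is the Richardson estimate of the
    quadrature error obtained by halving the grid step.
    """
    space = fitted.state_space
    if policy.threshold_state != NEVER and policy.threshold_state is not None:
        s = int(policy.threshold_state)
        if s >= space.death_index:
            raise ValueError("threshold must be a risk state or AML")
    q0 = fitted.q_hat
    q1 = apply_transplant_effects(q0, fitted.effects_hat, space)

    ones = np.ones(space.n_states)
    ones[space.death_index] = 0.0

    le = _policy_value_once(q0, q1, space, policy, ones, 1.0, step)
    tol = 0.0
    if richardson:
        le2 = _policy_value_once(q0, q1, space, policy, ones, 1.0, step / 2)
        tol = abs(le - le2)
        le = le2
    qaly = None
    if utilities is not None:
        w = utilities.pre_vector(space)
        w[space.death_index] = 0.0
        qaly = _policy_value_once(
            q0, q1, space, policy, w, utilities.post_transplant,
            step / 2 if richardson else step,
        )
    gain = le - no_transplant_value(fitted, policy.initial_state, None)
    return PolicyValue(
        life_expectancy=float(le),
        qaly=None if qaly is None else float(qaly),
        gain_vs_no_transplant=float(gain),
        method="algebraic",
        tolerance=float(tol),
    )


def policy_gain(
    fitted: FittedModel,
    policy: TransplantPolicy,
    utilities: Utilities | None = None,
    **kwargs,
) -> float:
    """Gain (possibly negative) in expected survival vs never transplanting."""
    pv = policy_expected_survival(fitted, policy, utilities, **kwargs)
    if utilities is not None:
        base = no_transplant_value(fitted, policy.initial_state, utilities)
        return float(pv.qaly - base)
    return float(pv.gain_vs_no_transplant)


def default_policy_thresholds(space: StateSpace) -> list[int]:
    """The three published policy thresholds per scheme.

    IPSS: low, int-1, int-2 risk; WPSS: low, intermediate, high risk
    (very-low WPSS is not transplantable, so WPSS policy 1 starts at low).
    """
    if space.scheme is Scheme.IPSS:
        labels = ["Low", "Int-1", "Int-2"]
    else:
        labels = ["Low", "Intermediate", "High"]
    return [space.index(lbl) for lbl in labels]


def policy_table(
    fitted: FittedModel,
    ages: Sequence[float] | None = None,
    delays_months: Sequence[float] | None = None,
    thresholds: Sequence[int] | None = None,
    utilities: Utilities | None = None,
    eligibility_age: float = 65.0,
    initial_state: int = 0,
    step: float = 0.01,
) -> pd.DataFrame:
    """Gain-in-life-expectancy table over (policy, delay, age) cells.

    Default grids: ages 30-65 by 5 years, delays {0, 12, 24, 48, 60}
    months, the scheme's three policy thresholds.
    """
    space = fitted.state_space
    if ages is None:
        ages = list(range(30, 70, 5))
    if delays_months is None:
        delays_months = [0, 12, 24, 48, 60]
    if thresholds is None:
        thresholds = default_policy_thresholds(space)
    if not len(ages) or not len(delays_months) or not len(thresholds):
        raise ValueError("ages, delays and thresholds must be nonempty")

    rows = []
    for p_idx, thr in enumerate(thresholds, start=1):
        for delay in delays_months:
            for age in ages:
                pol = TransplantPolicy(
                    threshold_state=int(thr),
                    delay_months=float(delay),
                    age_at_diagnosis=float(age),
                    eligibility_age=float(eligibility_age),
                    initial_state=int(initial_state),
                )
                pv = policy_expected_survival(
                    fitted, pol, utilities, step=step, richardson=False
                )
                rows.append(
                    {
                        "scheme": space.scheme.value,
                        "policy": p_idx,
                        "threshold": space.states[int(thr)],
                        "delay_months": float(delay),
                        "age": float(age),
                        "life_expectancy": pv.life_expectancy,
                        "qaly": pv.qaly,
                        "gain": pv.gain_vs_no_transplant,
                    }
                )
    return pd.DataFrame(rows)


def format_policy_table(table: pd.DataFrame, value: str = "gain") -> str:
    """Render a policy table as aligned text, delays as rows, ages as columns."""
    lines = []
    for (p_idx, thr), sub in table.groupby(["policy", "threshold"], sort=True):
        lines.append(f"Policy {p_idx}: transplantation in {thr} risk")
        pivot = sub.pivot_table(index="delay_months", columns="age", values=value)
        header = "  delay(mo) " + "".join(f"{int(a):>9d}" for a in pivot.columns)
        lines.append(header)
        for delay, row in pivot.iterrows():
            lines.append(
                f"  {delay:>9.0f} " + "".join(f"{v:>9.2f}" for v in row.to_numpy())
            )
        lines.append("")
    return "\n".join(lines)
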