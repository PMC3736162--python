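"""Individual-trajectory Monte-Carlo simulation under a transplant policy.

Each path is an exact-event realisation of the continuous-time chain:
sojourns are exponential with the state's total exit rate, destinations
categorical on the off-diagonal rates (equivalent in law to per-transition
exponential competing risks, with fewer draws).  Deterministic interrupts
implement the policy semantics of :mod:`mdstiming.policy` — the scheduled
transplant time and the eligibility cutoff — so the simulator serves as an
independent validation of the algebraic engine.

Because the chain is progressive (states only move up the risk ordering),
a path has at most ``n_states`` jumps plus one transplant interrupt, and a
whole batch can be simulated with a handful of vectorised sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core import StateSpace, TransplantEffects, apply_transplant_effects
from .policy import NEVER, TransplantPolicy, Utilities

__all__ = ["Path", "simulate_path", "microsim_value"]


@dataclass
class Path:
    """One simulated trajectory: event times with the states entered."""

    times: list[float]
    states: list[int]
    transplant_time: float | None
    death_time: float | None  # None = censored at the horizon
    seed: int | None = None


def _policy_setup(policy: TransplantPolicy):
    t_elig = policy.eligibility_horizon
    never = (
        policy.threshold_state == NEVER
        or policy.threshold_state is None
        or t_elig <= 0
    )
    s_star = -1 if never else int(policy.threshold_state)
    return never, s_star, t_elig, policy.delay_years


def _simulate_batch(
    q0: np.ndarray,
    q1: np.ndarray,
    space: StateSpace,
    policy: TransplantPolicy,
    rng: np.random.Generator,
    n: int,
    horizon: float,
    weights_pre: np.ndarray | None = None,
    weight_post: float = 1.0,
    record: bool = False,
) -> dict:
    """Simulate n paths; returns accrued values and terminal summaries."""
    n_states = space.n_states
    d_idx = space.death_index
    never, s_star, t_elig, delay = _policy_setup(policy)

    lam = np.stack([-np.diag(q0), -np.diag(q1)])  # (2, n_states)
    dest_cum = np.zeros((2, n_states, n_states))
    for c, q in enumerate((q0, q1)):
        for s in range(n_states):
            rates = np.clip(q[s].copy(), 0.0, None)
            rates[s] = 0.0
            tot = rates.sum()
            if tot > 0:
                dest_cum[c, s] = np.cumsum(rates / tot)
    if weights_pre is None:
        weights_pre = np.ones(n_states)
    w_pre = np.asarray(weights_pre, dtype=float).copy()
    w_pre[d_idx] = 0.0

    state = np.full(n, policy.initial_state, dtype=np.int64)
    time = np.zeros(n)
    transplanted = np.zeros(n, dtype=bool)
    sched = np.full(n, np.inf)
    entered = np.zeros(n, dtype=bool)
    value = np.zeros(n)
    death_time = np.full(n, np.nan)
    transplant_time = np.full(n, np.nan)
    alive = np.ones(n, dtype=bool)

    events: list[list[tuple[float, int]]] = [[] for _ in range(n)] if record else []

    # policy events at diagnosis
    if not never:
        if policy.initial_state > s_star:
            transplanted[:] = True
            transplant_time[:] = 0.0
        elif policy.initial_state == s_star:
            entered[:] = True
            if delay < t_elig:
                sched[:] = delay

    while alive.any():
        idx = np.flatnonzero(alive)
        s = state[idx]
        cov = transplanted[idx].astype(np.int64)
        rate = lam[cov, s]
        stuck = rate <= 0  # defensive: transient state with no exits
        tau = np.full(len(idx), np.inf)
        ok = ~stuck
        tau[ok] = rng.exponential(1.0 / rate[ok])
        t_event = time[idx] + tau

        seg_w = np.where(transplanted[idx], weight_post, w_pre[s])

        # scheduled transplant interrupt wins the race
        interrupt = (~transplanted[idx]) & (sched[idx] < t_event) & (sched[idx] < horizon)
        gi = idx[interrupt]
        if gi.size:
            value[gi] += seg_w[interrupt] * (sched[gi] - time[gi])
            time[gi] = sched[gi]
            transplant_time[gi] = sched[gi]
            transplanted[gi] = True
            sched[gi] = np.inf

        rest = idx[~interrupt]
        t_rest = t_event[~interrupt]
        w_rest = seg_w[~interrupt]

        # horizon truncation (censored alive)
        over = t_rest >= horizon
        go = rest[over]
        if go.size:
            value[go] += w_rest[over] * (horizon - time[go])
            alive[go] = False

        # jumps
        jump = rest[~over]
        if jump.size:
            t_j = t_rest[~over]
            value[jump] += w_rest[~over] * (t_j - time[jump])
            time[jump] = t_j
            cum = dest_cum[transplanted[jump].astype(np.int64), state[jump], :]
            u = rng.random(len(jump))
            dest = (u[:, None] > cum).sum(axis=1)
            state[jump] = dest
            if record:
                for g, dd in zip(jump, dest):
                    events[g].append((time[g], int(dd)))

            died = dest == d_idx
            gd = jump[died]
            death_time[gd] = time[gd]
            alive[gd] = False

            if not never:
                live = jump[~died]
                dl = dest[~died]
                can = live[~transplanted[live]]
                dl = dl[~transplanted[live]]
                # first entry into the threshold state: start the delay clock
                enter = (dl == s_star) & (~entered[can])
                ge = can[enter]
                if ge.size:
                    entered[ge] = True
                    fits = time[ge] + delay < t_elig
                    sched[ge[fits]] = time[ge[fits]] + delay
                # progression past the threshold: immediate transplant if eligible
                past = dl > s_star
                gp = can[past]
                gp = gp[time[gp] < t_elig]
                if gp.size:
                    transplanted[gp] = True
                    transplant_time[gp] = time[gp]
                    sched[gp] = np.inf

    return {
        "value": value,
        "death_time": death_time,
        "transplant_time": transplant_time,
        "events": events,
        "n_truncated": int(np.isnan(death_time).sum()),
    }


def simulate_path(
    q: np.ndarray,
    effects: TransplantEffects,
    policy: TransplantPolicy,
    space: StateSpace,
    rng: np.random.Generator | int,
    horizon: float = 120.0,
) -> Path:
    """Simulate one trajectory under the policy; bitwise reproducible by seed."""
    seed = rng if isinstance(rng, int) else None
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    q1 = apply_transplant_effects(q, effects, space)
    out = _simulate_batch(q, q1, space, policy, rng, 1, horizon, record=True)
    times = [0.0] + [t for t, _ in out["events"][0]]
    states = [policy.initial_state] + [s for _, s in out["events"][0]]
    tt = out["transplant_time"][0]
    dt = out["death_time"][0]
    return Path(
        times=times,
        states=states,
        transplant_time=None if np.isnan(tt) else float(tt),
        death_time=None if np.isnan(dt) else float(dt),
        seed=seed,
    )


def microsim_value(
    q: np.ndarray,
    effects: TransplantEffects,
    policy: TransplantPolicy,
    space: StateSpace,
    utilities: Utilities | None = None,
    n: int = 200_000,
    rng: np.random.Generator | int | None = None,
    horizon: float = 120.0,
) -> tuple[float, float]:
    """Monte-Carlo mean (utility-weighted) survival under a policy, with SE.

    Paths truncated at the horizon contribute their truncated value; a
    warning is emitted if more than 0.1% of paths are truncated.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if rng is None or isinstance(rng, int):
        rng = np.random.default_rng(rng)
    q1 = apply_transplant_effects(q, effects, space)
    w_pre = utilities.pre_vector(space) if utilities else None
    w_post = utilities.post_transplant if utilities else 1.0
    out = _simulate_batch(
        q, q1, space, policy, rng, n, horizon,
        weights_pre=w_pre, weight_post=w_post,
    )
    if out["n_truncated"] > 0.001 * n:
        import warnings

        warnings.warn(
            f"{out['n_truncated']} of {n} paths truncated at the {horizon}-year "
            "horizon; mean is biased low",
            stacklevel=2,
        )
    vals = out["value"]
    mean = float(vals.mean())
    se = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return mean, se
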