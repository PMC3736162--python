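"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's matrix-exponential code path: the
chain is discretized with one-step transition matrix I + Q*h and interval
probabilities are path sums obtained by repeated multiplication.
"""

import numpy as np

from mdstiming.cohort_data import ObsKind
from mdstiming.model_core import apply_transplant_effects


def discrete_step_power(q, dt, h):
    """Discretized-chain path-probability sum over round(dt/h) steps.

    The one-step matrix is the truncated Taylor series I + Qh + (Qh)^2/2
    (the plain Euler step I + Qh has O(h) error of ~2e-3 per unit time at
    exit rates near 2/yr, too coarse for a 1e-3 oracle tolerance).
    """
    n_steps = int(round(dt / h))
    qh = q * h
    step = np.eye(q.shape[0]) + qh + qh @ qh / 2
    out = np.eye(q.shape[0])
    base = step
    k = n_steps
    while k:  # binary powering keeps the oracle fast at h = 1e-3
        if k & 1:
            out = out @ base
        base = base @ base
        k >>= 1
    return out


def discretized_cohort_loglik(cohorts, q, effects, space, h=1e-3):
    """Cohort log-likelihood from the discretized chain (error O(h))."""
    q1 = apply_transplant_effects(q, effects, space)
    d = space.death_index
    total = 0.0
    for cohort in cohorts:
        for s in cohort.subjects:
            for a, b in zip(s.observations[:-1], s.observations[1:]):
                qq = q1 if a.post_hsct else q
                p_mat = discrete_step_power(qq, b.time - a.time, h)
                if b.kind is ObsKind.PANEL:
                    p = p_mat[a.state, b.state]
                elif b.kind is ObsKind.DEATH:
                    p = float(p_mat[a.state] @ qq[:, d])
                else:
                    p = 1.0 - p_mat[a.state, d]
                total += np.log(p)
    return total
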