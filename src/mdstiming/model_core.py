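"""State spaces, transition structures and generator-matrix algebra.

The disease course of MDS is modelled as a continuous-time Markov chain
whose states are the risk categories of a prognostic score (IPSS or WPSS),
leukemic evolution (AML) and death.  Progression is one-directional: from
any risk state the chain can move to the next risk state, to AML or to
death; AML can only move to death; death is absorbing.

Allogeneic transplantation acts as a time-dependent covariate that
multiplies each state's death intensity by a state-specific hazard ratio.
Progression intensities are left unchanged (see :func:`apply_transplant_effects`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import expm

__all__ = [
    "Scheme",
    "StateSpace",
    "TransitionStructure",
    "TransplantEffects",
    "build_state_space",
    "validate_generator",
    "apply_transplant_effects",
    "transition_probability_matrix",
    "build_generator",
]


class Scheme(str, Enum):
    """Risk-scoring system defining the model's state space."""

    IPSS = "IPSS"
    WPSS = "WPSS"


_IPSS_STATES = ("Low", "Int-1", "Int-2", "High", "AML", "Death")
_WPSS_STATES = ("Very-low", "Low", "Intermediate", "High", "Very-high", "AML", "Death")


@dataclass(frozen=True)
class StateSpace:
    """Ordered states of a risk scheme, with AML next-to-last and Death last.

    ``transplantable`` is the set of state indices in which transplantation
    may be performed.  For WPSS the very-low risk state is excluded:
    transplantation is not an option there, so no hazard ratio is modelled
    for it.  AML is transplantable under both schemes.
    """

    scheme: Scheme
    states: tuple[str, ...]
    aml_index: int
    death_index: int
    transplantable: frozenset[int]

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def risk_states(self) -> tuple[int, ...]:
        """Indices of the risk states (everything before AML)."""
        return tuple(range(self.aml_index))

    @property
    def transient(self) -> tuple[int, ...]:
        """Indices of all non-death states."""
        return tuple(range(self.death_index))

    def index(self, label: str) -> int:
        try:
            return self.states.index(label)
        except ValueError:
            raise KeyError(
                f"unknown state {label!r} for scheme {self.scheme.value}; "
                f"valid states: {', '.join(self.states)}"
            ) from None


@dataclass(frozen=True)
class TransitionStructure:
    """Set of allowed directed transitions (ordered index pairs)."""

    allowed: frozenset[tuple[int, int]]

    def is_allowed(self, i: int, j: int) -> bool:
        return (i, j) in self.allowed


@dataclass(frozen=True)
class TransplantEffects:
    """Per-state log hazard ratios of post-transplant mortality.

    ``log_hr[k]`` multiplies the k -> Death intensity by ``exp(log_hr[k])``
    once the subject has been transplanted.  Keys must be exactly the
    transplantable states of the state space the effects are used with.
    """

    log_hr: Mapping[int, float]

    def hr(self, k: int) -> float:
        return float(np.exp(self.log_hr[k]))

    @staticmethod
    def null(space: StateSpace) -> "TransplantEffects":
        """HR = 1 in every transplantable state (no transplant effect)."""
        return TransplantEffects({k: 0.0 for k in sorted(space.transplantable)})


def build_state_space(scheme: Scheme | str) -> tuple[StateSpace, TransitionStructure]:
    """Return the canonical state space and allowed transitions for a scheme.

    Allowed exits from risk state k are k -> k+1 (next risk state, if any),
    k -> AML and k -> Death; AML -> Death only; Death is absorbing.
    """
    try:
        scheme = Scheme(scheme)
    except ValueError:
        valid = ", ".join(s.value for s in Scheme)
        raise ValueError(f"unknown scheme {scheme!r}; valid schemes: {valid}") from None

    states = _IPSS_STATES if scheme is Scheme.IPSS else _WPSS_STATES
    aml = len(states) - 2
    death = len(states) - 1

    allowed: set[tuple[int, int]] = set()
    for k in range(aml):  # risk states
        if k + 1 < aml:
            allowed.add((k, k + 1))
        allowed.add((k, aml))
        allowed.add((k, death))
    allowed.add((aml, death))

    transplantable = set(range(aml + 1))  # risk states + AML
    if scheme is Scheme.WPSS:
        transplantable.discard(0)  # very-low risk: transplant not an option

    space = StateSpace(
        scheme=scheme,
        states=states,
        aml_index=aml,
        death_index=death,
        transplantable=frozenset(transplantable),
    )
    return space, TransitionStructure(allowed=frozenset(allowed))


def build_generator(
    space: StateSpace,
    structure: TransitionStructure,
    intensities: Mapping[tuple[int, int] | tuple[str, str], float],
) -> np.ndarray:
    """Assemble a generator matrix from per-transition intensities (per year).

    Keys may be index pairs or state-label pairs.  Missing allowed
    transitions default to 0; disallowed keys raise.
    """
    q = np.zeros((space.n_states, space.n_states))
    for key, rate in intensities.items():
        i, j = key
        if isinstance(i, str):
            i = space.index(i)
        if isinstance(j, str):
            j = space.index(j)
        if not structure.is_allowed(i, j):
            raise ValueError(f"transition {key!r} is not allowed by the structure")
        if rate < 0:
            raise ValueError(f"negative intensity for transition {key!r}")
        q[i, j] = rate
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def validate_generator(
    q: np.ndarray, structure: TransitionStructure, atol: float = 1e-10
) -> list[str]:
    """Check generator invariants against a transition structure.

    Returns a list of human-readable violations (empty when valid):
    nonnegative allowed off-diagonals, zero disallowed entries, rows
    summing to zero, absorbing death row.
    """
    q = np.asarray(q, dtype=float)
    if q.ndim != 2 or q.shape[0] != q.shape[1]:
        raise ValueError(f"generator must be square, got shape {q.shape}")
    n = q.shape[0]
    max_idx = max((max(i, j) for i, j in structure.allowed), default=-1)
    if max_idx >= n:
        raise ValueError(
            f"dimension mismatch: structure references state {max_idx} "
            f"but generator is {n}x{n}"
        )

    violations: list[str] = []
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if structure.is_allowed(i, j):
                if q[i, j] < -atol:
                    violations.append(f"negative intensity at ({i},{j}): {q[i, j]:g}")
            elif abs(q[i, j]) > atol:
                violations.append(f"disallowed transition ({i},{j}) has intensity {q[i, j]:g}")
    row_sums = q.sum(axis=1)
    for i in range(n):
        if abs(row_sums[i]) > 1e-8:
            violations.append(f"row {i} sums to {row_sums[i]:g}, expected 0")
    # death = last row must be identically zero (absorbing)
    if np.abs(q[n - 1]).max() > atol:
        violations.append("death row is not identically zero (death must be absorbing)")
    return violations


def apply_transplant_effects(
    q: np.ndarray,
    effects: TransplantEffects,
    space: StateSpace,
) -> np.ndarray:
    """Return the post-transplant generator.

    Each transplantable state's death intensity is multiplied by its hazard
    ratio exp(beta_k); progression intensities are unchanged; diagonals are
    recomputed.  The input is not mutated.
    """
    extra = set(effects.log_hr) - set(space.transplantable)
    if extra:
        labels = ", ".join(space.states[k] for k in sorted(extra))
        raise ValueError(
            f"transplant effect supplied for non-transplantable state(s): {labels}"
        )
    qp = np.array(q, dtype=float, copy=True)
    d = space.death_index
    for k, beta in effects.log_hr.items():
        qp[k, d] = q[k, d] * float(np.exp(beta))
    np.fill_diagonal(qp, 0.0)
    np.fill_diagonal(qp, -qp.sum(axis=1))
    return qp


def transition_probability_matrix(q: np.ndarray, dt: float) -> np.ndarray:
    """Transition probability matrix P(dt) = exp(q*dt) of the chain.

    Computed by scipy's dense scaling-and-squaring matrix exponential;
    matrices here are at most 7x7.
    """
    if dt < 0:
        raise ValueError(f"dt must be nonnegative, got {dt}")
    q = np.asarray(q, dtype=float)
    if dt == 0:
        return np.eye(q.shape[0])
    p = expm(q * dt)
    # clip tiny numerical negatives, renormalise rows
    p = np.clip(p, 0.0, None)
    p /= p.sum(axis=1, keepdims=True)
    return p


class SpectralPropagator:
    """Fast evaluator of exp(q*t) entries for many t at once.

    The generator of a progressive (upper-triangular under the risk
    ordering) chain has its eigenvalues on the diagonal.  When they are
    distinct the chain is diagonalisable and P(t) = V diag(e^{lambda t}) V^-1
    can be broadcast over thousands of interval lengths in one shot.  When
    the decomposition is ill-conditioned (near-coincident exit rates) the
    evaluator falls back to per-time scipy expm calls.
    """

    def __init__(self, q: np.ndarray, check_t: float = 1.0, rtol: float = 1e-9):
        self.q = np.asarray(q, dtype=float)
        self.n = self.q.shape[0]
        self._ok = False
        try:
            lam, v = np.linalg.eig(self.q)
            vinv = np.linalg.inv(v)
        except np.linalg.LinAlgError:
            return
        # verify against the robust route at a representative horizon
        ref = expm(self.q * check_t)
        approx = (v * np.exp(lam * check_t)) @ vinv
        if np.max(np.abs(approx.real - ref)) < max(rtol, rtol * np.abs(ref).max()) + 1e-9:
            self.lam = lam
            self.v = v
            self.vinv = vinv
            self._ok = True

    def matrices(self, ts: np.ndarray) -> np.ndarray:
        """P(t) for each t in ts, shape (len(ts), n, n)."""
        ts = np.asarray(ts, dtype=float)
        if self._ok:
            e = np.exp(self.lam[None, :] * ts[:, None])  # (T, n)
            out = np.einsum("ik,tk,kj->tij", self.v, e, self.vinv).real
        else:
            out = np.stack([expm(self.q * t) for t in ts])
        out = np.clip(out, 0.0, None)
        out /= out.sum(axis=2, keepdims=True)
        return out

    def entries(self, i: np.ndarray, j: np.ndarray, ts: np.ndarray) -> np.ndarray:
        """P(t)[i, j] for aligned arrays of rows, columns and times."""
        i = np.asarray(i)
        j = np.asarray(j)
        ts = np.asarray(ts, dtype=float)
        if self._ok:
            c = self.v[i, :] * self.vinv[:, j].T  # (N, n)
            vals = np.sum(c * np.exp(self.lam[None, :] * ts[:, None]), axis=1).real
            return np.clip(vals, 0.0, 1.0)
        out = np.empty(len(ts))
        for k, t in enumerate(ts):
            out[k] = expm(self.q * t)[i[k], j[k]]
        return np.clip(out, 0.0, 1.0)

    def rows_dot(self, i: np.ndarray, ts: np.ndarray, w: np.ndarray) -> np.ndarray:
        """sum_m P(t)[i, m] * w[m] for aligned rows and times."""
        i = np.asarray(i)
        ts = np.asarray(ts, dtype=float)
        w = np.asarray(w, dtype=float)
        if self._ok:
            u = self.vinv @ w  # (n,)
            c = self.v[i, :] * u[None, :]
            vals = np.sum(c * np.exp(self.lam[None, :] * ts[:, None]), axis=1).real
            return np.clip(vals, 0.0, None)
        out = np.empty(len(ts))
        for k, t in enumerate(ts):
            out[k] = float(expm(self.q * t)[i[k]] @ w)
        return np.clip(out, 0.0, None)
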