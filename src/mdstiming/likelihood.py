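"""Maximum-likelihood estimation of transition intensities and transplant HRs.

The likelihood is the standard one for panel-observed multistate Markov
data: a subject observed in state i at time t and in state j at time t+dt
contributes P_ij(dt); an exactly observed death at t+dt contributes
sum_m P_im(dt) q_mD (the state just before death is unknown); a censor row
contributes the probability of being alive, 1 - P_iD(dt).  Transplantation
switches the generator to its HR-modified version from hsct_time onward;
intervals containing the switch are split at it.

Both cohorts enter one joint likelihood: natural-history subjects
contribute covariate-0 intervals, transplanted-cohort subjects enter at
their transplant state and contribute covariate-1 intervals only.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml
from scipy.optimize import minimize

from .cohort_data import Cohort, Observation, ObsKind, SubjectRecord
from .model_core import (
    Scheme,
    SpectralPropagator,
    StateSpace,
    TransitionStructure,
    TransplantEffects,
    apply_transplant_effects,
    build_state_space,
    transition_probability_matrix,
    validate_generator,
)

__all__ = [
    "FittedModel",
    "interval_log_likelihood",
    "cohort_log_likelihood",
    "fit_model",
    "hazard_ratios",
    "model_survival_curve",
    "km_estimator",
]

_KIND_CODE = {ObsKind.PANEL: 0, ObsKind.DEATH: 1, ObsKind.CENSOR: 2}
_LOG_FLOOR = 1e-300


@dataclass
class FittedModel:
    """MLE of a multistate model with transplant effects.

    ``q_hat`` is the baseline (covariate = 0) generator; ``effects_hat``
    the per-state log hazard ratios; ``covariance`` is over the
    log-parameter vector (log intensities then log HRs, in ``param_names``
    order).
    """

    state_space: StateSpace
    structure: TransitionStructure
    q_hat: np.ndarray
    effects_hat: TransplantEffects
    covariance: np.ndarray | None
    log_likelihood: float
    n_subjects: int
    n_intervals: int
    converged: bool
    param_names: list[str]
    theta_hat: np.ndarray
    warnings: list[str] = field(default_factory=list)
    optimizer_message: str = ""
    n_evaluations: int = 0

    @staticmethod
    def from_parameters(
        space: StateSpace,
        structure: TransitionStructure,
        q: np.ndarray,
        effects: TransplantEffects,
    ) -> "FittedModel":
        """Wrap known parameters (e.g. simulation truth) as a fitted model."""
        trans_keys = sorted(structure.allowed)
        hr_keys = sorted(effects.log_hr)
        theta = np.array(
            [np.log(q[i, j]) if q[i, j] > 0 else -np.inf for i, j in trans_keys]
            + [effects.log_hr[k] for k in hr_keys]
        )
        names = [f"log q[{space.states[i]}->{space.states[j]}]" for i, j in trans_keys]
        names += [f"log HR[{space.states[k]}]" for k in hr_keys]
        return FittedModel(
            state_space=space,
            structure=structure,
            q_hat=np.asarray(q, dtype=float),
            effects_hat=effects,
            covariance=None,
            log_likelihood=float("nan"),
            n_subjects=0,
            n_intervals=0,
            converged=True,
            param_names=names,
            theta_hat=theta,
        )

    # ---- serialization (labeled structured text) -------------------------
    def save(self, path: str | Path) -> Path:
        space = self.state_space
        doc = {
            "scheme": space.scheme.value,
            "log_likelihood": float(self.log_likelihood),
            "n_subjects": int(self.n_subjects),
            "n_intervals": int(self.n_intervals),
            "converged": bool(self.converged),
            "optimizer_message": self.optimizer_message,
            "warnings": list(self.warnings),
            "intensities": {
                f"{space.states[i]}->{space.states[j]}": float(self.q_hat[i, j])
                for (i, j) in sorted(self.structure.allowed)
            },
            "log_hr": {
                space.states[k]: float(b) for k, b in sorted(self.effects_hat.log_hr.items())
            },
            "param_names": list(self.param_names),
            "theta_hat": [float(x) for x in self.theta_hat],
            "covariance": None
            if self.covariance is None
            else [[float(x) for x in row] for row in self.covariance],
        }
        path = Path(path)
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
        return path

    @staticmethod
    def load(path: str | Path) -> "FittedModel":
        doc = yaml.safe_load(Path(path).read_text())
        space, structure = build_state_space(doc["scheme"])
        from .model_core import build_generator

        q = build_generator(
            space,
            structure,
            {tuple(k.split("->")): v for k, v in doc["intensities"].items()},
        )
        effects = TransplantEffects(
            {space.index(k): float(v) for k, v in doc["log_hr"].items()}
        )
        cov = doc.get("covariance")
        return FittedModel(
            state_space=space,
            structure=structure,
            q_hat=q,
            effects_hat=effects,
            covariance=None if cov is None else np.asarray(cov, dtype=float),
            log_likelihood=float(doc["log_likelihood"]),
            n_subjects=int(doc["n_subjects"]),
            n_intervals=int(doc["n_intervals"]),
            converged=bool(doc["converged"]),
            param_names=list(doc["param_names"]),
            theta_hat=np.asarray(doc["theta_hat"], dtype=float),
            warnings=list(doc.get("warnings", [])),
            optimizer_message=str(doc.get("optimizer_message", "")),
        )


# ---------------------------------------------------------------------------
# single-interval and whole-cohort likelihood (reference path)
# ---------------------------------------------------------------------------

def interval_log_likelihood(
    from_state: int,
    to_obs: Observation,
    dt: float,
    q: np.ndarray,
    post_hsct: bool,
    effects: TransplantEffects,
    space: StateSpace,
) -> float:
    """Log-likelihood contribution of one observation interval.

    panel  -> log P[from, obs_state](dt)
    death  -> log sum_m P[from, m](dt) * q_eff[m, Death]
    censor -> log sum_{m != Death} P[from, m](dt)
    """
    if dt <= 0:
        raise ValueError(f"interval length must be positive, got dt={dt}")
    q_eff = apply_transplant_effects(q, effects, space) if post_hsct else q
    p_mat = transition_probability_matrix(q_eff, dt)
    d = space.death_index
    if to_obs.kind is ObsKind.PANEL:
        p = p_mat[from_state, to_obs.state]
    elif to_obs.kind is ObsKind.DEATH:
        p = float(p_mat[from_state, :] @ q_eff[:, d])
    else:  # censor: alive at dt
        p = 1.0 - p_mat[from_state, d]
    if p <= 0:
        return -np.inf
    return float(np.log(p))


def _subject_intervals(
    s: SubjectRecord,
) -> Iterable[tuple[Observation, Observation, float, float | None]]:
    """Yield (from_obs, to_obs, dt, split) per consecutive pair.

    ``split`` is the offset inside the interval at which the transplant
    covariate switches 0 -> 1, or None if the covariate is constant.
    """
    h = s.hsct_time
    for a, b in zip(s.observations[:-1], s.observations[1:]):
        dt = b.time - a.time
        if h is not None and a.time < h < b.time:
            yield a, b, dt, h - a.time
        else:
            yield a, b, dt, None


def cohort_log_likelihood(
    cohorts: Sequence[Cohort],
    q: np.ndarray,
    effects: TransplantEffects,
    space: StateSpace,
) -> float:
    """Joint log-likelihood of one or more cohorts (reference implementation).

    Sums interval contributions over consecutive observation pairs of every
    subject; an interval containing the transplant switch is split at
    hsct_time, propagating the state distribution across the two pieces.
    """
    total = 0.0
    q1 = apply_transplant_effects(q, effects, space)
    d = space.death_index
    for cohort in cohorts:
        for s in cohort.subjects:
            for a, b, dt, split in _subject_intervals(s):
                if split is None:
                    ll = interval_log_likelihood(
                        a.state, b, dt, q, a.post_hsct, effects, space
                    )
                else:
                    # distribution just before the switch, then post-HSCT piece
                    row = transition_probability_matrix(q, split)[a.state, :]
                    p1 = transition_probability_matrix(q1, dt - split)
                    if b.kind is ObsKind.PANEL:
                        p = float(row @ p1[:, b.state])
                    elif b.kind is ObsKind.DEATH:
                        p = float(row @ (p1 @ q1[:, d]))
                    else:
                        p = float(row @ (1.0 - p1[:, d]))
                    ll = float(np.log(p)) if p > 0 else -np.inf
                if not np.isfinite(ll):
                    raise FloatingPointError(
                        f"zero-probability observation for subject {s.subject_id} "
                        f"at t={b.time} (kind={b.kind.value})"
                    )
                total += ll
    return total


# ---------------------------------------------------------------------------
# compiled likelihood for optimization (vectorised over intervals)
# ---------------------------------------------------------------------------

class _CompiledData:
    """Cohort intervals flattened into arrays, grouped by covariate value."""

    def __init__(self, cohorts: Sequence[Cohort], space: StateSpace):
        self.space = space
        by_cov: dict[int, list[tuple[int, int, float, int]]] = {0: [], 1: []}
        self.split_intervals: list[tuple[int, Observation, float, float]] = []
        n_subj = 0
        n_int = 0
        for cohort in cohorts:
            for s in cohort.subjects:
                n_subj += 1
                for a, b, dt, split in _subject_intervals(s):
                    n_int += 1
                    if split is not None:
                        self.split_intervals.append((a.state, b, dt, split))
                    else:
                        by_cov[int(a.post_hsct)].append(
                            (a.state, b.state, dt, _KIND_CODE[b.kind])
                        )
        self.n_subjects = n_subj
        self.n_intervals = n_int
        self.batches: dict[int, dict[str, np.ndarray]] = {}
        for cov, rows in by_cov.items():
            if not rows:
                continue
            arr = np.array(rows, dtype=float)
            self.batches[cov] = {
                "from": arr[:, 0].astype(int),
                "to": arr[:, 1].astype(int),
                "dt": arr[:, 2],
                "kind": arr[:, 3].astype(int),
            }

    def log_likelihood(
        self, q0: np.ndarray, q1: np.ndarray, *, floor: bool = True
    ) -> float:
        space = self.space
        d = space.death_index
        total = 0.0
        for cov, batch in self.batches.items():
            q = q1 if cov else q0
            pr = SpectralPropagator(q)
            kind = batch["kind"]
            frm, to, dt = batch["from"], batch["to"], batch["dt"]
            p = np.empty(len(dt))
            m = kind == 0
            if m.any():
                p[m] = pr.entries(frm[m], to[m], dt[m])
            m = kind == 1
            if m.any():
                p[m] = pr.rows_dot(frm[m], dt[m], q[:, d])
            m = kind == 2
            if m.any():
                death_col = np.full(m.sum(), d)
                p[m] = 1.0 - pr.entries(frm[m], death_col, dt[m])
            if floor:
                p = np.maximum(p, _LOG_FLOOR)
            elif (p <= 0).any():
                return -np.inf
            total += float(np.log(p).sum())
        # rare: intervals straddling the transplant switch
        for from_state, b, dt, split in self.split_intervals:
            row = transition_probability_matrix(q0, split)[from_state, :]
            p1 = transition_probability_matrix(q1, dt - split)
            if b.kind is ObsKind.PANEL:
                p = float(row @ p1[:, b.state])
            elif b.kind is ObsKind.DEATH:
                p = float(row @ (p1 @ q1[:, d]))
            else:
                p = float(row @ (1.0 - p1[:, d]))
            total += float(np.log(max(p, _LOG_FLOOR)))
        return total


def _theta_to_matrices(
    theta: np.ndarray,
    space: StateSpace,
    trans_keys: list[tuple[int, int]],
    hr_keys: list[int],
) -> tuple[np.ndarray, np.ndarray, TransplantEffects]:
    n = space.n_states
    q0 = np.zeros((n, n))
    rates = np.exp(theta[: len(trans_keys)])
    for (i, j), r in zip(trans_keys, rates):
        q0[i, j] = r
    np.fill_diagonal(q0, -q0.sum(axis=1))
    effects = TransplantEffects(dict(zip(hr_keys, theta[len(trans_keys):])))
    q1 = apply_transplant_effects(q0, effects, space)
    return q0, q1, effects


def fit_model(
    cohorts: Sequence[Cohort],
    space: StateSpace,
    structure: TransitionStructure,
    init_q: np.ndarray | None = None,
    init_effects: TransplantEffects | None = None,
    options: dict | None = None,
) -> FittedModel:
    """Fit intensities and log-HRs by joint maximum likelihood.

    Parameterization is on the log scale (positivity enforced by
    construction); the optimizer is L-BFGS-B with finite-difference
    gradients — the parameter dimension never exceeds ~20 here.
    Deterministic given data, init and options.  Non-convergence is flagged
    on the result rather than raised; intensities estimated at (numerically)
    zero get a boundary warning.
    """
    opts = dict(options or {})
    ftol = opts.pop("ftol", 1e-8)
    gtol = opts.pop("gtol", 1e-7)
    maxiter = opts.pop("maxiter", 500)
    fd_scheme = opts.pop("fd", "2-point")
    compute_cov = opts.pop("covariance", True)

    trans_keys = sorted(structure.allowed)
    hr_keys = sorted(space.transplantable)
    n_rates = len(trans_keys)

    theta0 = np.empty(n_rates + len(hr_keys))
    if init_q is not None:
        for idx, (i, j) in enumerate(trans_keys):
            theta0[idx] = np.log(max(init_q[i, j], 1e-6))
    else:
        theta0[:n_rates] = np.log(0.1)
    if init_effects is not None:
        for idx, k in enumerate(hr_keys):
            theta0[n_rates + idx] = init_effects.log_hr.get(k, 0.0)
    else:
        theta0[n_rates:] = 0.0

    data = _CompiledData(cohorts, space)

    n_eval = 0

    def neg_ll(theta: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        q0, q1, _ = _theta_to_matrices(theta, space, trans_keys, hr_keys)
        return -data.log_likelihood(q0, q1)

    res = minimize(
        neg_ll,
        theta0,
        method="L-BFGS-B",
        jac=fd_scheme,
        options={"ftol": ftol, "gtol": gtol, "maxiter": maxiter},
    )

    theta_hat = res.x
    q_hat, _, effects_hat = _theta_to_matrices(theta_hat, space, trans_keys, hr_keys)

    warnings_list: list[str] = []
    for (i, j) in trans_keys:
        if q_hat[i, j] < 1e-6:
            warnings_list.append(
                f"intensity {space.states[i]}->{space.states[j]} estimated at the "
                f"zero boundary ({q_hat[i, j]:.2e}); no events observed for this transition?"
            )

    cov = None
    if compute_cov:
        from statsmodels.tools.numdiff import approx_hess

        try:
            hess = approx_hess(theta_hat, neg_ll)
            hess = 0.5 * (hess + hess.T)
            cov = np.linalg.pinv(hess)
            # symmetric PSD projection guard
            eigvals = np.linalg.eigvalsh(cov)
            if eigvals.min() < -1e-8 * max(1.0, eigvals.max()):
                warnings_list.append("covariance not positive semi-definite; use with care")
        except Exception as exc:  # pragma: no cover - numerical guard
            warnings_list.append(f"covariance computation failed: {exc}")

    names = [f"log q[{space.states[i]}->{space.states[j]}]" for i, j in trans_keys]
    names += [f"log HR[{space.states[k]}]" for k in hr_keys]

    return FittedModel(
        state_space=space,
        structure=structure,
        q_hat=q_hat,
        effects_hat=effects_hat,
        covariance=cov,
        log_likelihood=float(-res.fun),
        n_subjects=data.n_subjects,
        n_intervals=data.n_intervals,
        converged=bool(res.success),
        param_names=names,
        theta_hat=theta_hat,
        warnings=warnings_list,
        optimizer_message=str(res.message),
        n_evaluations=n_eval,
    )


def hazard_ratios(fitted: FittedModel) -> "pd.DataFrame":
    """Table of per-state transplant hazard ratios with 95% Wald CIs.

    HR = exp(beta_hat); CI = exp(beta_hat +/- 1.96 SE).  Without a
    covariance the CI columns are NaN.
    """
    import pandas as pd

    space = fitted.state_space
    hr_keys = sorted(fitted.effects_hat.log_hr)
    n_rates = len(fitted.param_names) - len(hr_keys)
    rows = []
    for idx, k in enumerate(hr_keys):
        beta = fitted.effects_hat.log_hr[k]
        se = np.nan
        if fitted.covariance is not None:
            var = fitted.covariance[n_rates + idx, n_rates + idx]
            se = float(np.sqrt(max(var, 0.0)))
        lo = np.exp(beta - 1.96 * se) if np.isfinite(se) else np.nan
        hi = np.exp(beta + 1.96 * se) if np.isfinite(se) else np.nan
        rows.append(
            {
                "state": space.states[k],
                "hr": float(np.exp(beta)),
                "ci_low": lo,
                "ci_high": hi,
                "log_hr": float(beta),
                "se_log_hr": se,
            }
        )
    return pd.DataFrame(rows)


def model_survival_curve(
    fitted: FittedModel, from_state: int, grid: np.ndarray
) -> np.ndarray:
    """Model-based survival S(t) = 1 - P[from, Death](t) at covariate 0."""
    grid = np.asarray(grid, dtype=float)
    if (np.diff(grid) < 0).any() or (grid < 0).any():
        raise ValueError("time grid must be nonnegative and nondecreasing")
    pr = SpectralPropagator(fitted.q_hat)
    d = fitted.state_space.death_index
    mats = pr.matrices(grid)
    return 1.0 - mats[:, from_state, d]


def km_estimator(
    times: Sequence[float], events: Sequence[bool]
) -> tuple[np.ndarray, np.ndarray]:
    """Kaplan-Meier product-limit survival estimate with right censoring.

    Returns (timeline, survival) step-function arrays, via lifelines.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("km_estimator requires at least one observation")
    if times.shape != events.shape:
        raise ValueError("times and events must be aligned")
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    return sf.index.to_numpy(dtype=float), sf.iloc[:, 0].to_numpy(dtype=float)
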