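"""Maximum-likelihood and empirical-Bayes estimation of the hybrid model.

The likelihood of a session multiplies, over non-aborted trials, the softmax
probability of the observed stage-1 colour (hybrid net value with precision β
and perseverance π) and of the observed stage-2 shape (β over the offered
pair's cached values — the same β, since the model has exactly five free
parameters).  Values are updated along the observed choices in trial order,
so the likelihood is a deterministic function of the parameters.

Estimation works on an unconstrained scale — logit for α, λ, ω, log for β,
identity for π — with multistart bounded quasi-Newton optimisation.  The
hierarchical fit is an empirical-Bayes EM: subjects are MAP-fitted under a
Gaussian prior on the transformed parameters, the prior's mean and dispersion
are re-estimated from the subject posteriors (Laplace approximation), and the
loop stops when the group means settle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

from .agents import AgentParams, QState, update_model_free
from .rpe import plan_values
from .task import SessionLog

__all__ = [
    "FitResult",
    "GroupPrior",
    "QTrajectory",
    "session_nll",
    "fit_subject",
    "fit_hierarchical",
    "latent_trajectory",
    "to_transformed",
    "from_transformed",
]

PARAM_NAMES = ("alpha", "lam", "omega", "beta", "pi")
_EPS = 1e-9


def to_transformed(params: AgentParams) -> np.ndarray:
    """Map parameters to the unconstrained optimisation scale."""
    clip = lambda x: min(max(x, _EPS), 1.0 - _EPS)
    return np.array(
        [
            logit(clip(params.alpha)),
            logit(clip(params.lam)),
            logit(clip(params.omega)),
            math.log(max(params.beta, _EPS)),
            params.pi,
        ]
    )


def from_transformed(theta: np.ndarray) -> AgentParams:
    """Inverse of :func:`to_transformed`."""
    return AgentParams(
        alpha=float(expit(theta[0])),
        lam=float(expit(theta[1])),
        omega=float(expit(theta[2])),
        beta=float(math.exp(theta[3])),
        pi=float(theta[4]),
    )


@dataclass
class FitResult:
    params: AgentParams
    nll: float
    se: np.ndarray  # per-parameter SEs on the transformed scale
    converged: bool
    n_trials_used: int
    theta: np.ndarray = field(default=None, repr=False)
    posterior_var: np.ndarray = field(default=None, repr=False)


@dataclass
class GroupPrior:
    """Gaussian prior on the transformed parameters (the hierarchical level)."""

    mean: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 0.0, math.log(3.0), 0.0]))
    sd: np.ndarray = field(default_factory=lambda: np.array([1.5, 1.5, 1.5, 1.0, 1.5]))

    def validate(self) -> None:
        if np.any(self.sd <= 0):
            raise ValueError("prior dispersions must be positive")

    def penalty(self, theta: np.ndarray) -> float:
        z = (theta - self.mean) / self.sd
        return 0.5 * float(z @ z)


@dataclass
class QTrajectory:
    """Pre-decision / pre-outcome latent value snapshots along a session.

    All of a trial's value updates are applied together once the outcome is
    known, so the pre-decision and pre-outcome snapshots coincide; both views
    are exposed for clarity at the call sites.
    """

    q_mf_s1: np.ndarray  # (n, 2)
    q_s2: np.ndarray  # (n, 4)
    q_mb_s1: np.ndarray  # (n, 2)

    @property
    def n_trials(self) -> int:
        return len(self.q_mf_s1)

    # pre-outcome aliases (identical snapshots; see class docstring)
    @property
    def q_mf_s1_pre_outcome(self) -> np.ndarray:
        return self.q_mf_s1

    @property
    def q_s2_pre_outcome(self) -> np.ndarray:
        return self.q_s2


def _usable(session: SessionLog):
    return [tr for tr in session.trials if not tr.aborted]


def session_nll(params: AgentParams, session: SessionLog) -> float:
    """Negative log-likelihood of the observed choices under the hybrid model."""
    p_common = session.config.p_common
    alpha, lam, omega, beta, pi = (
        params.alpha,
        params.lam,
        params.omega,
        params.beta,
        params.pi,
    )
    q_mf = [0.0, 0.0]
    q2 = [0.0, 0.0, 0.0, 0.0]
    prev = -1
    nll = 0.0
    for tr in session.trials:
        if tr.aborted:
            continue
        best0 = q2[0] if q2[0] > q2[1] else q2[1]
        best1 = q2[2] if q2[2] > q2[3] else q2[3]
        qmb0 = p_common * best0 + (1.0 - p_common) * best1
        qmb1 = p_common * best1 + (1.0 - p_common) * best0
        u0 = beta * (omega * qmb0 + (1.0 - omega) * q_mf[0])
        u1 = beta * (omega * qmb1 + (1.0 - omega) * q_mf[1])
        if prev == 0:
            u0 += pi
        elif prev == 1:
            u1 += pi
        c = tr.chosen_colour
        d = (u1 - u0) if c == 0 else (u0 - u1)
        # -log softmax prob of the chosen colour = log(1 + exp(-(u_c - u_other)))
        nll += math.log1p(math.exp(d)) if d < 30 else d

        s = tr.s2_state
        a, b = 2 * s, 2 * s + 1
        ch = tr.s2_chosen_shape
        other = b if ch == a else a
        d2 = beta * (q2[other] - q2[ch])
        nll += math.log1p(math.exp(d2)) if d2 < 30 else d2

        q2_old = q2[ch]
        q_mf[c] += alpha * (q2_old - q_mf[c]) + alpha * lam * (tr.reward - q2_old)
        q2[ch] += alpha * (tr.reward - q2_old)
        prev = c
    if not math.isfinite(nll):
        raise FloatingPointError("non-finite likelihood: invalid parameters")
    return nll


def _objective(theta: np.ndarray, session: SessionLog, prior: Optional[GroupPrior]) -> float:
    try:
        val = session_nll(from_transformed(theta), session)
    except (OverflowError, FloatingPointError):
        return 1e12
    if prior is not None:
        val += prior.penalty(theta)
    return val


def _numeric_hessian(f, x: np.ndarray, h: float = 1e-3) -> np.ndarray:
    n = len(x)
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = h
            ej[j] = h
            if i == j:
                H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h**2
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4 * h**2)
    return H


_DEFAULT_START = np.array([0.0, 0.0, 0.0, math.log(3.0), 0.0])
_BOUNDS = [(-6, 6), (-6, 6), (-6, 6), (-4, 4), (-5, 5)]


def fit_subject(
    session: SessionLog,
    prior: Optional[GroupPrior] = None,
    restarts: int = 10,
    seed: int = 0,
    starts: Optional[Sequence[np.ndarray]] = None,
) -> FitResult:
    """Point estimate of the five parameters for one session.

    Maximum likelihood, or MAP when ``prior`` is given, over the transformed
    scale with ``restarts`` multistarts; ties broken by lowest objective then
    lowest parameter norm.  Standard errors come from the inverse numerical
    Hessian at the optimum (Laplace approximation); non-convergence is
    flagged, never raised.
    """
    usable = _usable(session)
    if len(usable) < 2:
        raise ValueError("need at least 2 usable trials to fit")
    rng = np.random.default_rng(seed)
    if starts is None:
        starts = [_DEFAULT_START]
        centre = prior.mean if prior is not None else _DEFAULT_START
        sd = prior.sd if prior is not None else np.array([1.5, 1.5, 1.5, 0.8, 1.0])
        for _ in range(max(restarts - 1, 0)):
            starts.append(centre + sd * rng.standard_normal(5))

    best = None
    any_ok = False
    for x0 in starts:
        res = minimize(
            _objective,
            np.clip(x0, [b[0] for b in _BOUNDS], [b[1] for b in _BOUNDS]),
            args=(session, prior),
            method="L-BFGS-B",
            bounds=_BOUNDS,
        )
        any_ok = any_ok or res.success
        key = (round(res.fun, 6), float(np.linalg.norm(res.x)))
        if best is None or key < best[0]:
            best = (key, res)
    res = best[1]
    theta = res.x

    H = _numeric_hessian(lambda th: _objective(th, session, prior), theta)
    se = np.full(5, np.nan)
    post_var = np.full(5, np.nan)
    try:
        cov = np.linalg.inv(H)
        diag = np.diag(cov)
        if np.all(diag > 0):
            se = np.sqrt(diag)
            post_var = diag.copy()
    except np.linalg.LinAlgError:
        pass
    # fall back to a wide but finite posterior variance where curvature failed
    fallback = (prior.sd**2) if prior is not None else np.full(5, 2.25)
    bad = ~np.isfinite(post_var)
    post_var[bad] = fallback[bad]

    params = from_transformed(theta)
    nll = session_nll(params, session)
    return FitResult(
        params=params,
        nll=float(nll),
        se=se,
        converged=bool(any_ok and np.all(np.isfinite(se))),
        n_trials_used=len(usable),
        theta=theta,
        posterior_var=post_var,
    )


VAR_FLOOR = 1e-3


def fit_hierarchical(
    cohort: Sequence[SessionLog],
    max_iter: int = 5,
    tol: float = 0.05,
    seed: int = 0,
    restarts: int = 4,
) -> Tuple[GroupPrior, List[FitResult]]:
    """Empirical-Bayes EM over a cohort.

    Alternates MAP subject fits under the current Gaussian group prior with
    re-estimation of the group mean and dispersion from the subject Laplace
    posteriors.  Dispersions are floored at a small positive constant.  Stops
    when the largest group-mean change falls below ``tol`` (so a very large
    ``tol`` yields exactly one round of MAP fits under the initial prior).
    """
    if len(cohort) < 2:
        raise ValueError("hierarchical fit needs at least 2 subjects")
    prior = GroupPrior()
    ss = np.random.SeedSequence(seed)
    fits: List[FitResult] = []
    for it in range(max_iter):
        sub_seeds = ss.spawn(len(cohort))
        n_restarts = restarts if it == 0 else max(restarts // 2, 1)
        fits = []
        for sess, sseed in zip(cohort, sub_seeds):
            extra = None
            if it > 0:
                # warm-start from the previous round's estimate
                prev_theta = next(
                    f.theta for f, s in zip(prev_fits, cohort) if s is sess
                )
                extra = [prev_theta, prior.mean.copy()]
            fits.append(
                fit_subject(
                    sess,
                    prior=prior,
                    restarts=n_restarts,
                    seed=np.random.default_rng(sseed).integers(2**31),
                    starts=extra,
                )
            )
        thetas = np.array([f.theta for f in fits])
        post_vars = np.array([f.posterior_var for f in fits])
        new_mean = thetas.mean(axis=0)
        new_var = ((thetas - new_mean) ** 2).mean(axis=0) + post_vars.mean(axis=0)
        new_var = np.maximum(new_var, VAR_FLOOR)
        delta = float(np.max(np.abs(new_mean - prior.mean)))
        prior = GroupPrior(mean=new_mean, sd=np.sqrt(new_var))
        prev_fits = fits
        if delta < tol:
            break
    return prior, fits


def latent_trajectory(params: AgentParams, session: SessionLog) -> QTrajectory:
    """Deterministic replay of the value updates along the observed choices.

    Snapshots are taken immediately before each decision; because updates are
    applied only once the outcome is known, these equal the pre-outcome values
    used by the RPE definitions.
    """
    params.validate()
    p_common = session.config.p_common
    qs = QState()
    snaps_mf, snaps_s2, snaps_mb = [], [], []
    for tr in session.trials:
        if tr.aborted:
            continue
        snaps_mf.append(qs.q_mf_s1.copy())
        snaps_s2.append(qs.q_s2.copy())
        snaps_mb.append(plan_values(qs.q_s2, p_common))
        update_model_free(qs, tr.chosen_colour, tr.s2_chosen_shape, tr.reward, params)
    return QTrajectory(
        q_mf_s1=np.array(snaps_mf).reshape(-1, 2),
        q_s2=np.array(snaps_s2).reshape(-1, 4),
        q_mb_s1=np.array(snaps_mb).reshape(-1, 2),
    )
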