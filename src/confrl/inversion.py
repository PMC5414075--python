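"""Per-session model inversion: MAP estimation and Laplace model evidence.

Each model's free parameters are mapped to an unconstrained space (logit for
unit-interval parameters, log for positive ones), given independent Gaussian
priors there, and fit by multi-start quasi-Newton maximisation of the log
joint. The log model evidence is approximated at the MAP by the Laplace
formula

    log p(y | m) ~ log p(y | th*) + log p(th*) + (d/2) log 2*pi
                   - (1/2) log det H,

with ``H`` the negative Hessian of the log joint at the optimum in
transformed space. By default ``H`` is the empirical information matrix
(outer product of per-trial scores plus the prior precision): the choice
likelihood is only piecewise smooth -- the confirmatory/contradictory
outcome split flips discretely as cue values cross zero -- so a
second-difference Hessian is unreliable at the optimum, while the score
outer product needs only first derivatives and is positive definite by
construction. A full finite-difference Hessian remains available for smooth
problems. The evidence trades off goodness of fit against effective degrees
of freedom, which is what the group-level model selection consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy import optimize
from scipy.special import expit, logit
from sklearn.base import BaseEstimator

from . import _engine
from .models import (
    DEFAULT_MODULATION_FORM,
    LatentTrajectory,
    ModelSpec,
    ParamSet,
)
from .task import Session, _kernel_args

__all__ = [
    "PriorSpec",
    "FitResult",
    "NumericalFailure",
    "session_log_likelihood",
    "compute_trajectory",
    "fit_map",
    "laplace_log_evidence",
    "opg_log_evidence",
    "MapLaplaceFitter",
    "to_native",
    "to_transformed",
]

#: Parameters constrained to the unit interval use a logit transform; the
#: strictly positive ones use a log transform.
_LOGIT_PARAMS = {"alpha0", "C0", "gamma"}
_LOG_PARAMS = {"beta0", "kappa", "kappa_alpha", "kappa_beta"}

DEFAULT_PRIOR_VAR = 3.0


class NumericalFailure(RuntimeError):
    """Likelihood evaluation produced non-finite latents."""

    def __init__(self, trial_index: int):
        self.trial_index = trial_index
        super().__init__(
            f"non-finite latent variable at trial {trial_index}"
        )


def to_native(name: str, x: float) -> float:
    """Map one parameter from transformed (unconstrained) to native scale."""
    if name in _LOGIT_PARAMS:
        return float(expit(x))
    if name in _LOG_PARAMS:
        return float(np.exp(x))
    raise KeyError(name)


def to_transformed(name: str, v: float) -> float:
    """Map one parameter from native scale to the unconstrained space."""
    if name in _LOGIT_PARAMS:
        return float(logit(v))
    if name in _LOG_PARAMS:
        return float(np.log(v))
    raise KeyError(name)


@dataclass
class PriorSpec:
    """Independent Gaussian priors in transformed space.

    Defaults are weakly informative standard choices (mean 0, variance 3):
    symmetric around alpha0 = C0 = gamma = 0.5 and beta0 = kappa = 1 on the
    native scale.
    """

    mean: dict[str, float] = field(default_factory=dict)
    var: dict[str, float] = field(default_factory=dict)

    @classmethod
    def default(cls, spec: ModelSpec) -> "PriorSpec":
        names = spec.free_params
        return cls(
            mean={n: 0.0 for n in names},
            var={n: DEFAULT_PRIOR_VAR for n in names},
        )

    def validate_for(self, spec: ModelSpec) -> None:
        for n in spec.free_params:
            if n not in self.mean or n not in self.var:
                raise ValueError(f"prior missing for parameter {n}")
            if self.var[n] <= 0:
                raise ValueError(f"prior variance for {n} must be positive")

    def log_pdf(self, spec: ModelSpec, x: np.ndarray) -> float:
        names = spec.free_params
        mu = np.array([self.mean[n] for n in names])
        var = np.array([self.var[n] for n in names])
        return float(
            -0.5 * np.sum((x - mu) ** 2 / var)
            - 0.5 * np.sum(np.log(2.0 * np.pi * var))
        )


@dataclass
class FitResult:
    """Outcome of inverting one model on one session."""

    spec: ModelSpec
    theta_map: ParamSet
    x_map: np.ndarray
    log_likelihood: float
    log_joint: float
    log_evidence: float
    hessian_logdet: float
    n_restarts_used: int
    trajectory: LatentTrajectory
    converged: bool
    hessian_jittered: bool = False
    used_bic_fallback: bool = False


def _theta_from_x(spec: ModelSpec, x: np.ndarray) -> ParamSet:
    d = {n: to_native(n, xi) for n, xi in zip(spec.free_params, x)}
    return ParamSet.from_dict(d)


def _x_from_theta(spec: ModelSpec, theta: ParamSet) -> np.ndarray:
    return np.array(
        [to_transformed(n, getattr(theta, n)) for n in spec.free_params]
    )


def _run_kernel(
    session: Session,
    spec: ModelSpec,
    theta: ParamSet,
    form: str = DEFAULT_MODULATION_FORM,
):
    cue, choice, outcome, optim = session.arrays()
    n = len(session)
    lat = [np.empty(n) for _ in range(7)]
    ll = _engine.run_session(
        cue, choice, outcome, optim, *_kernel_args(spec, theta, form), *lat
    )
    return float(ll), LatentTrajectory(*lat)


def session_log_likelihood(
    session: Session,
    spec: ModelSpec,
    theta: ParamSet,
    form: str = DEFAULT_MODULATION_FORM,
) -> float:
    """Summed log probability of the session's observed choices under the
    model; evaluation has no side effects on the session."""
    ll, traj = _run_kernel(session, spec, theta, form)
    if not np.isfinite(ll):
        bad = ~np.isfinite(traj.p_choice)
        idx = int(np.argmax(bad)) if bad.any() else 0
        raise NumericalFailure(idx)
    return ll


def compute_trajectory(
    session: Session,
    spec: ModelSpec,
    theta: ParamSet,
    form: str = DEFAULT_MODULATION_FORM,
) -> LatentTrajectory:
    """Latent trajectories (values, confidence, modulated parameters,
    prediction errors, choice probabilities) when replaying the session."""
    return _run_kernel(session, spec, theta, form)[1]


def _fd_hessian(
    f: Callable[[np.ndarray], float], x: np.ndarray, step: float
) -> np.ndarray:
    """Central finite-difference Hessian of a scalar function."""
    d = len(x)
    H = np.empty((d, d))
    f0 = f(x)
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = step
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / step**2
        for j in range(i + 1, d):
            ej = np.zeros(d)
            ej[j] = step
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej)
                + f(x - ei - ej)
            ) / (4.0 * step**2)
    return H


def _score_matrix(
    logpc: Callable[[np.ndarray], np.ndarray], x: np.ndarray, step: float
) -> np.ndarray:
    """Per-trial score vectors d log p(choice_t)/dx by central differences."""
    d = len(x)
    G = None
    for i in range(d):
        e = np.zeros(d)
        e[i] = step
        gi = (logpc(x + e) - logpc(x - e)) / (2.0 * step)
        if G is None:
            G = np.empty((len(gi), d))
        G[:, i] = gi
    return G


def opg_log_evidence(
    log_joint_value: float,
    logpc: Callable[[np.ndarray], np.ndarray],
    x_map: np.ndarray,
    prior_var: np.ndarray,
    step: float = 1e-3,
) -> tuple[float, dict]:
    """Laplace-style evidence with an outer-product-of-scores curvature.

    The negative Hessian of the log joint is approximated by the empirical
    information matrix ``sum_t g_t g_t' + diag(1/prior_var)`` with ``g_t``
    the per-trial score of the choice likelihood. Unlike a second-difference
    Hessian this needs only first derivatives, and it is positive definite
    by construction — which matters here because the confirmatory /
    contradictory outcome split makes the likelihood only piecewise smooth,
    and MAP points frequently sit on the piece boundaries where
    second differences blow up.
    """
    x_map = np.asarray(x_map, dtype=float)
    d = len(x_map)
    G = _score_matrix(logpc, x_map, step)
    # winsorize: a finite difference straddling a likelihood discontinuity
    # produces a spurious O(jump/step) score for that trial; genuine scores
    # of a single Bernoulli trial are orders of magnitude smaller
    norms = np.linalg.norm(G, axis=1)
    cap = max(20.0, 10.0 * float(np.quantile(norms, 0.95)))
    over = norms > cap
    if over.any():
        G[over] *= (cap / norms[over])[:, None]
    H = G.T @ G + np.diag(1.0 / np.asarray(prior_var, dtype=float))
    eigvals = np.linalg.eigvalsh(0.5 * (H + H.T))
    jittered = False
    floor = 1e-10
    if np.any(eigvals <= floor):
        jittered = True
        eigvals = np.maximum(eigvals, floor)
    logdet = float(np.sum(np.log(eigvals)))
    if not np.isfinite(logdet):
        raise FloatingPointError("non-finite information log determinant")
    le = log_joint_value + 0.5 * d * np.log(2.0 * np.pi) - 0.5 * logdet
    return le, {"hessian_logdet": logdet, "jittered": jittered}


def laplace_log_evidence(
    log_joint: Callable[[np.ndarray], float],
    x_map: np.ndarray,
    step: float = 1e-4,
) -> tuple[float, dict]:
    """Laplace approximation to the log marginal around a mode of an
    arbitrary log-joint function.

    Returns ``(log_evidence, info)`` where ``info`` records the negative
    Hessian's log determinant and whether a positive-definiteness repair
    (eigenvalue clipping) was applied. Raises ``FloatingPointError`` when the
    curvature is unusable even after repair; callers may then fall back to a
    BIC-style penalty.
    """
    x_map = np.asarray(x_map, dtype=float)
    d = len(x_map)
    H = -_fd_hessian(log_joint, x_map, step)
    jittered = False
    eigvals, eigvecs = np.linalg.eigh(0.5 * (H + H.T))
    floor = 1e-6 * max(1.0, float(np.max(np.abs(eigvals)))) if d else 1.0
    if np.any(eigvals <= floor):
        jittered = True
        eigvals = np.maximum(eigvals, floor)
    logdet = float(np.sum(np.log(eigvals)))
    if not np.isfinite(logdet):
        raise FloatingPointError("non-finite Hessian log determinant")
    lj = float(log_joint(x_map))
    le = lj + 0.5 * d * np.log(2.0 * np.pi) - 0.5 * logdet
    return le, {"hessian_logdet": logdet, "jittered": jittered}


def fit_map(
    session: Session,
    spec: ModelSpec,
    priors: Optional[PriorSpec] = None,
    n_restarts: int = 8,
    seed: Optional[int] = None,
    hessian_step: float = 1e-4,
    form: str = DEFAULT_MODULATION_FORM,
    hessian_method: str = "opg",
) -> FitResult:
    """MAP-fit one model to one session and attach its Laplace evidence.

    Optimisation runs in transformed space with L-BFGS-B and numerical
    gradients; the first start is the prior mean, the remaining
    ``n_restarts - 1`` are prior draws, and the best optimum is kept.
    Reproducible given (session, spec, priors, seed).

    ``hessian_method`` selects the curvature used in the evidence:
    ``"opg"`` (default) builds the empirical information matrix from
    per-trial scores plus the prior precision (robust to the piecewise
    smoothness of the choice likelihood); ``"fd"`` uses the full central
    finite-difference Hessian of the log joint with step ``hessian_step``.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    priors = PriorSpec.default(spec) if priors is None else priors
    priors.validate_for(spec)
    names = spec.free_params
    d = len(names)
    cue, choice, outcome, optim = session.arrays()
    lat = [np.empty(len(session)) for _ in range(7)]

    def log_joint(x: np.ndarray) -> float:
        # clip keeps native parameters strictly inside their open ranges
        # when the optimizer probes extreme transformed values
        x = np.clip(x, -30.0, 30.0)
        theta = _theta_from_x(spec, x)
        ll = _engine.run_session(
            cue, choice, outcome, optim,
            *_kernel_args(spec, theta, form), *lat
        )
        return float(ll) + priors.log_pdf(spec, x)

    def objective(x: np.ndarray) -> float:
        v = log_joint(x)
        return -v if np.isfinite(v) else 1e12

    rng = np.random.default_rng(seed)
    mu = np.array([priors.mean[n] for n in names])
    sd = np.sqrt(np.array([priors.var[n] for n in names]))
    # screen a pool of prior draws and keep the most promising as starts:
    # with long sessions the posterior is sharp and unscreened draws rarely
    # reach its basin
    pool = mu + sd * rng.standard_normal((max(20, 12 * n_restarts), d))
    pool_vals = np.array([objective(x) for x in pool])
    order = np.argsort(pool_vals)
    starts = [mu] + [pool[i] for i in order[: n_restarts - 1]]

    results = []
    failures = []
    for x0 in starts:
        try:
            res = optimize.minimize(
                objective,
                x0,
                jac="3-point",
                method="L-BFGS-B",
                options={"maxiter": 500, "ftol": 1e-9, "gtol": 1e-6},
            )
        except Exception as exc:  # pragma: no cover - optimizer pathologies
            failures.append(repr(exc))
            continue
        if not np.isfinite(res.fun):
            failures.append("non-finite objective at optimum")
            continue
        results.append(res)
    if not results:
        raise RuntimeError(
            f"all {n_restarts} restarts failed for {spec.model_id}: "
            + "; ".join(failures)
        )
    # simplex polish of the leading optima: gradient-based steps stall on
    # the piecewise-smooth likelihood (the confirmatory/contradictory
    # split), Nelder-Mead does not
    results.sort(key=lambda r: r.fun)
    best = results[0]
    for res in results[: min(3, n_restarts)]:
        polish = optimize.minimize(
            objective,
            res.x,
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 200 * d},
        )
        if np.isfinite(polish.fun) and polish.fun < best.fun:
            best = polish

    x_map = np.clip(np.asarray(best.x, dtype=float), -30.0, 30.0)
    theta_map = _theta_from_x(spec, x_map)
    lj = float(log_joint(x_map))
    ll = lj - priors.log_pdf(spec, x_map)
    traj = compute_trajectory(session, spec, theta_map, form)

    jittered = False
    used_bic = False

    def logpc(x: np.ndarray) -> np.ndarray:
        x = np.clip(x, -30.0, 30.0)
        theta = _theta_from_x(spec, x)
        _engine.run_session(
            cue, choice, outcome, optim,
            *_kernel_args(spec, theta, form), *lat
        )
        return np.log(lat[6])

    try:
        if hessian_method == "opg":
            prior_var = np.array([priors.var[n] for n in names])
            le, info = opg_log_evidence(lj, logpc, x_map, prior_var)
        elif hessian_method == "fd":
            le, info = laplace_log_evidence(
                log_joint, x_map, step=hessian_step
            )
        else:
            raise ValueError(
                f"unknown hessian_method {hessian_method!r}"
            )
        logdet = info["hessian_logdet"]
        jittered = info["jittered"]
    except FloatingPointError:
        warnings.warn(
            f"Hessian unusable for {spec.model_id}; falling back to BIC",
            RuntimeWarning,
        )
        le = ll - 0.5 * d * np.log(len(session))
        logdet = np.nan
        used_bic = True

    return FitResult(
        spec=spec,
        theta_map=theta_map,
        x_map=x_map,
        log_likelihood=ll,
        log_joint=lj,
        log_evidence=le,
        hessian_logdet=logdet,
        n_restarts_used=len(starts),
        trajectory=traj,
        converged=bool(best.success),
        hessian_jittered=jittered,
        used_bic_fallback=used_bic,
    )


class MapLaplaceFitter(BaseEstimator):
    """Sklearn-style wrapper around :func:`fit_map`.

    Parameters
    ----------
    spec : ModelSpec or str
        The model to invert (a spec or its string id).
    priors : PriorSpec, optional
        Gaussian priors in transformed space; defaults to mean 0, variance 3
        on every free parameter.
    n_restarts : int
        Number of optimisation starts (prior mean + prior draws).
    random_state : int, optional
        Seed for the restart draws.

    Attributes (after ``fit``)
    --------------------------
    theta_map_ : ParamSet
    log_evidence_ : float
    log_likelihood_ : float
    trajectory_ : LatentTrajectory
    converged_ : bool
    result_ : FitResult
    """

    def __init__(
        self,
        spec: ModelSpec | str,
        priors: Optional[PriorSpec] = None,
        n_restarts: int = 8,
        random_state: Optional[int] = None,
        hessian_step: float = 1e-4,
        form: str = DEFAULT_MODULATION_FORM,
        hessian_method: str = "opg",
    ):
        self.spec = spec
        self.priors = priors
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.hessian_step = hessian_step
        self.form = form
        self.hessian_method = hessian_method

    def _resolved_spec(self) -> ModelSpec:
        return (
            ModelSpec.from_id(self.spec)
            if isinstance(self.spec, str)
            else self.spec
        )

    def fit(self, session: Session, y=None) -> "MapLaplaceFitter":
        result = fit_map(
            session,
            self._resolved_spec(),
            priors=self.priors,
            n_restarts=self.n_restarts,
            seed=self.random_state,
            hessian_step=self.hessian_step,
            form=self.form,
            hessian_method=self.hessian_method,
        )
        self.result_ = result
        self.theta_map_ = result.theta_map
        self.log_evidence_ = result.log_evidence
        self.log_likelihood_ = result.log_likelihood
        self.trajectory_ = result.trajectory
        self.converged_ = result.converged
        return self

    def score(self, session: Session, y=None) -> float:
        """Log-likelihood of a session under the fitted parameters."""
        return session_log_likelihood(
            session, self._resolved_spec(), self.theta_map_, self.form
        )
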