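"""Maximum-likelihood estimation of latent class models by EM.

Fits the finite mixture of Bernoulli products, either unconditional (class
proportions gamma) or with a one-step covariate (multinomial logistic
structural model estimated simultaneously with the measurement model). The
E-step computes posterior class memberships; the M-step has closed forms for
the CRPs and class proportions, and an inner Newton solver for the
posterior-weighted multinomial logistic regression when a covariate is
present. Convergence follows the study rule: at most 500 iterations, stop
when the log-likelihood changes by less than 1e-7.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .datagen import Dataset
from .design import PopulationSpec, proportions_to_intercepts

#: a class whose total posterior mass falls below DEGENERATE_FLOOR * n has
#: effectively emptied out; estimation cannot continue meaningfully
DEGENERATE_FLOOR = 1e-6


class DegenerateClassError(RuntimeError):
    """Raised by the M-step when a class loses essentially all posterior mass."""


@dataclass
class ParameterSet:
    """Parameters of a fitted (or starting) latent class model.

    Unconditional models carry ``gamma``; covariate models carry the
    multinomial-logistic ``beta0``/``beta1`` (reference class last, fixed at
    zero) and ``gamma`` holds the implied class proportions at the covariate
    mean. Estimated CRPs may sit exactly at the 0/1 boundary.
    """

    gamma: np.ndarray
    crp: np.ndarray
    beta0: np.ndarray | None = None
    beta1: np.ndarray | None = None
    has_covariate: bool = False

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.crp = np.atleast_2d(np.asarray(self.crp, dtype=float))
        if self.beta0 is not None:
            self.beta0 = np.asarray(self.beta0, dtype=float)
        if self.beta1 is not None:
            self.beta1 = np.asarray(self.beta1, dtype=float)
        if self.has_covariate and (self.beta0 is None or self.beta1 is None):
            raise ValueError("covariate model requires beta0 and beta1")

    @property
    def n_classes(self) -> int:
        return self.crp.shape[0]

    @property
    def n_indicators(self) -> int:
        return self.crp.shape[1]

    @classmethod
    def from_spec(cls, spec: PopulationSpec) -> "ParameterSet":
        """Starting values at the true population parameters."""
        return cls(
            gamma=spec.gamma.copy(),
            crp=spec.crp.copy(),
            beta0=spec.beta0.copy(),
            beta1=spec.beta1.copy(),
            has_covariate=spec.has_covariate,
        )

    def permuted(self, perm: tuple[int, ...]) -> "ParameterSet":
        """Relabel classes: new class k is old class perm[k] (0-based)."""
        idx = np.asarray(perm)
        gamma = self.gamma[idx]
        crp = self.crp[idx]
        if self.has_covariate:
            b0, b1 = self.beta0[idx], self.beta1[idx]
            # re-anchor the (new) last class as reference
            b0 = b0 - b0[-1]
            b1 = b1 - b1[-1]
            return ParameterSet(gamma, crp, b0, b1, True)
        return ParameterSet(gamma, crp, has_covariate=False)


@dataclass
class FitResult:
    estimate: ParameterSet
    posterior: np.ndarray
    loglik_trace: np.ndarray
    converged: bool
    n_iterations: int
    boundary_mask: np.ndarray
    boundary_count: int
    failure_reason: str | None = None

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])


def _log_prior(params: ParameterSet, d: Dataset) -> np.ndarray:
    """Log class-membership probabilities, (n, C)."""
    if params.has_covariate:
        if d.covariate is None:
            raise ValueError("covariate model requires a dataset with a covariate")
        eta = params.beta0[None, :] + np.outer(d.covariate, params.beta1)
        return eta - logsumexp(eta, axis=1, keepdims=True)
    with np.errstate(divide="ignore"):
        lg = np.log(params.gamma)
    return np.broadcast_to(lg, (d.n, params.n_classes))


def _log_joint(params: ParameterSet, d: Dataset) -> np.ndarray:
    """log P(class c, responses_i) per observation and class, (n, C).

    Boundary CRPs (exactly 0 or 1) are handled exactly: an impossible
    response contributes -inf, a certain one contributes 0.
    """
    y = d.responses
    out = np.array(_log_prior(params, d))
    with np.errstate(divide="ignore"):
        lp = np.log(params.crp)
        lq = np.log1p(-params.crp)
    for c in range(params.n_classes):
        out[:, c] += np.where(y == 1, lp[c], lq[c]).sum(axis=1)
    return out


def loglikelihood(params: ParameterSet, d: Dataset) -> float:
    """Observed-data log-likelihood; -inf if any observation has probability 0."""
    return float(logsumexp(_log_joint(params, d), axis=1).sum())


def e_step(params: ParameterSet, d: Dataset) -> np.ndarray:
    """Posterior class-membership probabilities, rows summing to 1."""
    lj = _log_joint(params, d)
    norm = logsumexp(lj, axis=1)
    bad = ~np.isfinite(norm)
    if bad.any():
        raise ValueError(
            f"observation {int(np.flatnonzero(bad)[0])} has zero probability under every class"
        )
    return np.exp(lj - norm[:, None])


def _weighted_multinomial_logit(
    post: np.ndarray,
    x: np.ndarray,
    beta0: np.ndarray,
    beta1: np.ndarray,
    grad_tol: float = 1e-10,
    max_iter: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """Newton solver for the posterior-weighted multinomial logistic M-step.

    Maximizes sum_i sum_c post[i,c] log softmax_c(beta0 + beta1 x_i) over the
    2(C-1) free parameters (reference class last, fixed at zero). The
    problem is concave; warm starts from the previous EM iteration keep the
    inner loop short.
    """
    n, C = post.shape
    K = C - 1
    Z = np.column_stack([np.ones(n), x])          # (n, 2)
    theta = np.concatenate([beta0[:K], beta1[:K]])

    for _ in range(max_iter):
        b0 = np.append(theta[:K], 0.0)
        b1 = np.append(theta[K:], 0.0)
        eta = b0[None, :] + np.outer(x, b1)
        eta -= eta.max(axis=1, keepdims=True)
        pi = np.exp(eta)
        pi /= pi.sum(axis=1, keepdims=True)

        resid = post[:, :K] - pi[:, :K]           # (n, K)
        grad = (Z.T @ resid)                      # (2, K): rows = intercept, slope
        g = np.concatenate([grad[0], grad[1]])    # order matches theta
        if np.linalg.norm(g) < grad_tol:
            break

        # Hessian blocks: H[(a,c),(b,d)] = -sum_i Z_ia Z_ib pi_ic (delta_cd - pi_id)
        H = np.empty((2 * K, 2 * K))
        for c in range(K):
            for dcl in range(K):
                w = pi[:, c] * ((1.0 if c == dcl else 0.0) - pi[:, dcl])
                blk = Z.T @ (w[:, None] * Z)      # (2, 2)
                H[c, dcl] = blk[0, 0]
                H[c, K + dcl] = blk[0, 1]
                H[K + c, dcl] = blk[1, 0]
                H[K + c, K + dcl] = blk[1, 1]
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError as exc:
            raise DegenerateClassError("singular Hessian in logistic M-step") from exc
        theta = theta + step

    return np.append(theta[:K], 0.0), np.append(theta[K:], 0.0)


def m_step(posterior: np.ndarray, d: Dataset, has_covariate: bool,
           warm: ParameterSet | None = None) -> ParameterSet:
    """Closed-form update of CRPs and class proportions; Newton update of the
    structural logistic model when a covariate is present."""
    mass = posterior.sum(axis=0)
    if np.any(mass < DEGENERATE_FLOOR * posterior.shape[0]):
        raise DegenerateClassError(
            f"class {int(np.argmin(mass)) + 1} has vanishing posterior mass"
        )
    # float error in the weighted mean can stray a hair outside [0, 1]
    crp = np.clip((posterior.T @ d.responses) / mass[:, None], 0.0, 1.0)
    if not has_covariate:
        return ParameterSet(gamma=mass / mass.sum(), crp=crp, has_covariate=False)

    C = posterior.shape[1]
    if warm is not None and warm.has_covariate:
        b0, b1 = warm.beta0, warm.beta1
    else:
        b0 = proportions_to_intercepts(mass / mass.sum())
        b1 = np.zeros(C)
    beta0, beta1 = _weighted_multinomial_logit(posterior, d.covariate, b0, b1)
    # implied class proportions at the covariate mean (x = 0)
    g = np.exp(beta0 - beta0.max())
    return ParameterSet(gamma=g / g.sum(), crp=crp, beta0=beta0, beta1=beta1,
                        has_covariate=True)


def fit(d: Dataset, start: ParameterSet, max_iter: int = 500, tol: float = 1e-7) -> FitResult:
    """EM fit from the supplied starting values.

    Alternates E and M steps until the absolute log-likelihood change falls
    below ``tol`` or ``max_iter`` iterations elapse. A class emptying out
    during the M-step is recorded as non-convergence rather than raised.
    """
    params = start
    trace: list[float] = []
    converged = False
    reason: str | None = None
    posterior = None

    for it in range(1, max_iter + 1):
        lj = _log_joint(params, d)
        norm = logsumexp(lj, axis=1)
        if not np.all(np.isfinite(norm)):
            reason = "zero-probability observation"
            break
        posterior = np.exp(lj - norm[:, None])
        ll = float(norm.sum())
        trace.append(ll)
        if it > 1 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
        try:
            params = m_step(posterior, d, params.has_covariate, warm=params)
        except DegenerateClassError as exc:
            reason = str(exc)
            break

    if posterior is None:
        posterior = np.full((d.n, params.n_classes), np.nan)
        trace = [-np.inf]
    mask, count = detect_boundary(params)
    return FitResult(
        estimate=params,
        posterior=posterior,
        loglik_trace=np.asarray(trace),
        converged=converged,
        n_iterations=len(trace),
        boundary_mask=mask,
        boundary_count=count,
        failure_reason=reason,
    )


def detect_boundary(est: ParameterSet, eps: float = 1e-4) -> tuple[np.ndarray, int]:
    """Flag CRPs within ``eps`` of 0 or 1 (boundary estimates)."""
    mask = (est.crp <= eps) | (est.crp >= 1 - eps)
    return mask, int(mask.sum())
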