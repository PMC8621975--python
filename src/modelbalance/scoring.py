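"""Quadratic score primitives, the alpha-relaxed enzyme penalty, Gaussian
prior-likelihood combination, and assembly of the posterior score R(y).

All quantities live on natural-log scale. The posterior score is

    R(y) = quad(q - q_po, H_q) + sum_s quad(x_s - x_po_s, sigma_x)
         + sum_s quad_alpha(z_s(y) - z_po_s, sigma_z, alpha)

where the first block may carry a full precision matrix H_q (kinetic data
enter through linear design rows of the dependency schema), the x blocks
are diagonal, and the enzyme term is the per-component alpha-truncated
quadratic. Enzyme terms for zero-flux reactions are omitted entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinetics import log_enzyme_demand_and_gradient, log_enzyme_demand_hessians


@dataclass
class GaussianSpec:
    """Gaussian on log scale: mean plus either diagonal stds or a full
    covariance (stds still kept for reporting)."""

    mean: np.ndarray
    std: np.ndarray | None = None
    cov: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        if self.std is not None:
            self.std = np.broadcast_to(
                np.asarray(self.std, dtype=float), self.mean.shape
            ).copy()
            if np.any(self.std <= 0):
                raise ValueError("standard deviations must be positive")
        if self.cov is not None:
            self.cov = np.asarray(self.cov, dtype=float)
            if not np.allclose(self.cov, self.cov.T):
                raise ValueError("covariance must be symmetric")
            if np.any(np.linalg.eigvalsh(self.cov) <= 0):
                raise ValueError("covariance must be positive definite")
        if self.std is None and self.cov is None:
            raise ValueError("need std or cov")

    @property
    def precision(self) -> np.ndarray:
        if self.cov is not None:
            return np.linalg.inv(self.cov)
        return np.diag(1.0 / self.std**2)


def quad(a: np.ndarray, sigma: GaussianSpec | np.ndarray | float) -> float:
    """``quad(a, Sigma) = a^T Sigma^{-1} a / 2``."""
    a = np.atleast_1d(np.asarray(a, dtype=float))
    if isinstance(sigma, GaussianSpec):
        if sigma.cov is not None:
            return 0.5 * float(a @ np.linalg.solve(sigma.cov, a))
        std = sigma.std
    else:
        std = np.broadcast_to(np.asarray(sigma, dtype=float), a.shape)
    if np.any(std <= 0):
        raise ValueError("singular covariance")
    return 0.5 * float(np.sum((a / std) ** 2))


def quad_alpha(
    a: np.ndarray,
    sigma: GaussianSpec | np.ndarray | float,
    alpha: float,
) -> float:
    """Alpha-relaxed quadratic: components with negative residual are scaled
    by alpha in [0, 1]; ``quad_alpha(.., 1)`` equals :func:`quad` and the
    alpha=0 variant vanishes on negative residuals."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    a = np.atleast_1d(np.asarray(a, dtype=float))
    if isinstance(sigma, GaussianSpec):
        if sigma.cov is not None:
            raise ValueError("quad_alpha requires a diagonal covariance")
        std = sigma.std
    else:
        std = np.broadcast_to(np.asarray(sigma, dtype=float), a.shape)
    w = np.where(a >= 0, 1.0, alpha)
    return 0.5 * float(np.sum(w * (a / std) ** 2))


def quad_alpha_grad(a: np.ndarray, std: np.ndarray, alpha: float) -> np.ndarray:
    """Gradient of :func:`quad_alpha` with respect to the residual."""
    a = np.asarray(a, dtype=float)
    std = np.broadcast_to(np.asarray(std, dtype=float), a.shape)
    w = np.where(a >= 0, 1.0, alpha)
    return w * a / std**2


def implied_std_inflation(alpha: float) -> float:
    """Factor by which the effective std of the below-mean branch grows when
    the stringency is lowered from 1 to ``alpha``.

    Computed from quad_alpha itself: a Gaussian penalty s(a) = (a/sigma_eff)^2/2
    matching quad_alpha on the negative branch has sigma_eff = |a| / sqrt(2 s).
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    a = -1.0
    s_alpha = quad_alpha(np.array([a]), 1.0, alpha)
    s_one = quad_alpha(np.array([a]), 1.0, 1.0)
    return float((abs(a) / np.sqrt(2 * s_alpha)) / (abs(a) / np.sqrt(2 * s_one)))


@dataclass
class Observation:
    """One measurement of component ``index`` (or of the linear combination
    ``row @ variables`` when a design row is given)."""

    mean: float
    std: float
    index: int | None = None
    row: np.ndarray | None = None


def combine_gaussians(
    prior: GaussianSpec, observations: list[Observation] | GaussianSpec | None
) -> GaussianSpec:
    """Precision-weighted combination of a diagonal prior with observations.

    Missing components (no observation) keep their prior; duplicate
    observations of one component each add their precision. A
    ``GaussianSpec`` may be passed for the fully observed one-measurement
    case. Returns the preposterior as a GaussianSpec (full covariance when
    any observation carries a design row, diagonal otherwise).
    """
    if prior.std is None:
        raise ValueError("prior must be diagonal")
    n = prior.mean.size
    if observations is None:
        observations = []
    if isinstance(observations, GaussianSpec):
        observations = [
            Observation(mean=m, std=s, index=i)
            for i, (m, s) in enumerate(zip(observations.mean, observations.std))
        ]

    has_rows = any(o.row is not None for o in observations)
    if not has_rows:
        prec = 1.0 / prior.std**2
        wsum = prior.mean * prec
        for o in observations:
            if o.std <= 0:
                raise ValueError("observation std must be positive")
            prec[o.index] += 1.0 / o.std**2
            wsum[o.index] += o.mean / o.std**2
        var = 1.0 / prec
        return GaussianSpec(mean=wsum * var, std=np.sqrt(var))

    H = np.diag(1.0 / prior.std**2)
    hmu = prior.mean / prior.std**2
    for o in observations:
        row = np.zeros(n)
        if o.row is not None:
            row[:] = o.row
        else:
            row[o.index] = 1.0
        H += np.outer(row, row) / o.std**2
        hmu += row * o.mean / o.std**2
    cov = np.linalg.inv(H)
    cov = 0.5 * (cov + cov.T)
    return GaussianSpec(mean=cov @ hmu, std=np.sqrt(np.diag(cov)), cov=cov)


@dataclass
class PreposteriorSpec:
    """Block preposterior: basic kinetic block (possibly full covariance),
    one diagonal x block per state, one diagonal z block per state over the
    active reactions of that state."""

    q: GaussianSpec
    x: list[GaussianSpec]
    z: list[GaussianSpec]  # indexed like the active reactions per state
    z_active: list[np.ndarray]  # reaction indices backing each z block

    @property
    def q_precision(self) -> np.ndarray:
        return self.q.precision


@dataclass
class ScoreBreakdown:
    """Posterior score decomposition; total is the sum of the parts."""

    basic: float
    x_terms: list[float]
    enzyme_terms: list[float]
    alpha: float
    total: float = field(init=False)

    def __post_init__(self) -> None:
        self.total = self.basic + float(np.sum(self.x_terms)) + float(
            np.sum(self.enzyme_terms)
        )


def assemble_posterior_score(problem, y: np.ndarray, strict: bool = True):
    """Evaluate R(y) and its gradient for a :class:`~modelbalance.balancer.
    BalancingProblem`.

    Returns ``(breakdown, gradient)``. With ``strict=True`` a point outside
    the polytope (beyond tolerance 1e-8) raises
    :class:`~modelbalance.kinetics.DomainError`.
    """
    from .kinetics import DomainError  # local to avoid cycle at import time

    poly = problem.polytope
    y = np.asarray(y, dtype=float)
    if strict and not poly.contains(y, tol=1e-8):
        raise DomainError("point outside the feasible polytope")

    pre = problem.preposterior
    q, x = poly.split(y)
    grad = np.zeros(poly.n_var)

    # basic kinetic block (full precision)
    dq = q - pre.q.mean
    Hq = problem.q_precision
    grad[: poly.n_basic] += Hq @ dq
    basic = 0.5 * float(dq @ Hq @ dq)

    x_terms: list[float] = []
    enzyme_terms: list[float] = []
    for s in range(poly.n_states):
        sl = poly.x_slice(s)
        dx = x[:, s] - pre.x[s].mean
        x_terms.append(quad(dx, pre.x[s]))
        grad[sl] += dx / pre.x[s].std ** 2

        active, z, Jq, Jx = log_enzyme_demand_and_gradient(
            problem.schema, q, x[:, s], problem.fluxes[:, s], strict=strict
        )
        assert np.array_equal(active, pre.z_active[s])
        dz = z - pre.z[s].mean
        enzyme_terms.append(quad_alpha(dz, pre.z[s].std, problem.alpha))
        gz = quad_alpha_grad(dz, pre.z[s].std, problem.alpha)
        grad[: poly.n_basic] += gz @ Jq
        grad[sl] += gz @ Jx

    return ScoreBreakdown(basic, x_terms, enzyme_terms, problem.alpha), grad


def posterior_score_hessian(problem, y: np.ndarray) -> np.ndarray:
    """Exact Hessian of R(y) (piecewise: the alpha weights switch at zero
    enzyme residual, where the Hessian jumps but R stays C^1)."""
    poly = problem.polytope
    y = np.asarray(y, dtype=float)
    pre = problem.preposterior
    q, x = poly.split(y)
    nb = poly.n_basic
    n_met = poly.n_met
    H = np.zeros((poly.n_var, poly.n_var))
    H[:nb, :nb] += problem.q_precision

    for s in range(poly.n_states):
        sl = poly.x_slice(s)
        idx = np.r_[np.arange(nb), np.arange(sl.start, sl.stop)]
        H[sl, sl] += np.diag(1.0 / pre.x[s].std ** 2)

        active, z, Jq, Jx = log_enzyme_demand_and_gradient(
            problem.schema, q, x[:, s], problem.fluxes[:, s], strict=False
        )
        hess_local = log_enzyme_demand_hessians(
            problem.schema, q, x[:, s], problem.fluxes[:, s]
        )
        dz = z - pre.z[s].mean
        w = np.where(dz >= 0, 1.0, problem.alpha) / pre.z[s].std ** 2
        gz = w * dz
        J = np.hstack([Jq, Jx])  # local (q, x_s) coordinates
        Hs = (J * w[:, None]).T @ J
        for i, Hz in enumerate(hess_local):
            Hs += gz[i] * Hz
        H[np.ix_(idx, idx)] += Hs
    return H
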