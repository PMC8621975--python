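"""Assembly and solution of the model-balancing optimisation.

``make_problem`` bundles network, dependency schema, per-state fluxes,
priors, data, bounds, and the stringency parameter alpha into a
:class:`BalancingProblem`; ``balance`` minimises the posterior score over
the feasible polytope with analytic gradients (scipy trust-constr on the
linear inequality system). At alpha > 0 the default is a continuation
schedule: solve the strictly convex alpha = 0 problem first, then
warm-start the target. Individual coordinates (basic constants or state
log concentrations) can be pinned via ``fixed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import LinearConstraint, minimize

from .kinetics import log_enzyme_demand_and_gradient
from .network_schema import (
    DependencySchema,
    KineticConstantSet,
    MetabolicNetwork,
    build_schema,
    expand_constants,
)
from .scoring import (
    GaussianSpec,
    Observation,
    PreposteriorSpec,
    ScoreBreakdown,
    assemble_posterior_score,
    combine_gaussians,
    posterior_score_hessian,
)
from .synthetic_data import PriorCatalogue
from .tables import QUANTITY_NAMES
from .thermo import (
    BoundsConfig,
    FeasiblePolytope,
    InfeasibleFluxError,
    build_polytope,
    check_flux_feasibility,
    driving_forces,
)


#: interior margin used when projecting the starting point into the polytope
INIT_MARGIN = 0.05


class ConvergenceError(RuntimeError):
    """Solver failed to converge; the best iterate is attached."""

    def __init__(self, message: str, best: np.ndarray | None = None):
        super().__init__(message)
        self.best = best


@dataclass
class SolverOptions:
    gtol: float = 1e-6
    xtol: float = 1e-9
    maxiter: int = 3000
    seed: int = 1
    multistart: int | None = None  # None: 5 at alpha == 0, else 1
    multistart_tol: float = 1e-4
    continuation: bool = True


@dataclass
class BalancingProblem:
    network: MetabolicNetwork
    schema: DependencySchema
    fluxes: np.ndarray  # (n_reactions, n_states)
    state_ids: list[str]
    priors: PriorCatalogue
    bounds: BoundsConfig
    alpha: float
    polytope: FeasiblePolytope
    preposterior: PreposteriorSpec
    q_precision: np.ndarray
    options: SolverOptions = field(default_factory=SolverOptions)
    fixed: dict[int, float] = field(default_factory=dict)
    has_data: bool = False
    data: pd.DataFrame | None = None

    @property
    def n_states(self) -> int:
        return self.fluxes.shape[1]

    def basic_index(self, name: str) -> int:
        return self.schema.basic_names.index(name)

    def x_index(self, state: int, metabolite: str) -> int:
        return (
            self.schema.n_basic
            + state * self.network.n_metabolites
            + self.network.metabolite_index(metabolite)
        )

    def free_mask(self) -> np.ndarray:
        mask = np.ones(self.polytope.n_var, dtype=bool)
        for idx in self.fixed:
            mask[idx] = False
        return mask

    def embed(self, y_free: np.ndarray) -> np.ndarray:
        y = np.zeros(self.polytope.n_var)
        y[self.free_mask()] = y_free
        for idx, val in self.fixed.items():
            y[idx] = val
        return y


def _gather_observations(
    problem_data: pd.DataFrame | None,
    network: MetabolicNetwork,
    schema: DependencySchema,
    state_ids: list[str],
    fluxes: np.ndarray,
):
    """Split data rows into basic-block observations (with design rows),
    per-state concentration observations, and per-state enzyme observations
    keyed by reaction index. Enzyme rows for zero-flux reactions are
    dropped."""
    q_obs: list[Observation] = []
    x_obs: list[list[Observation]] = [[] for _ in state_ids]
    z_obs: list[dict[int, list[Observation]]] = [{} for _ in state_ids]
    if problem_data is None or problem_data.empty:
        return q_obs, x_obs, z_obs

    name_to_kind = {v: k for k, v in QUANTITY_NAMES.items()}
    for _, row in problem_data.iterrows():
        kind = name_to_kind.get(row["!QuantityType"], row["!QuantityType"])
        if kind == "flux":
            continue
        mean = float(row["!Mean"])
        gsd = float(row["!GeometricStd"])
        if not np.isfinite(gsd) or gsd <= 1.0:
            raise ValueError(
                f"data row for {row['!QuantityType']} needs a GeometricStd > 1"
            )
        std = np.log(gsd)
        if kind in ("keq", "kv", "kcat_fwd", "kcat_bwd", "km"):
            l = network.reaction_index(row["!Reaction"])
            if kind == "km":
                i = network.metabolite_index(row["!Compound"])
                drow = schema.design_row("km", l, i)
            else:
                drow = schema.design_row(kind, l)
            q_obs.append(Observation(mean=np.log(mean), std=std, row=drow))
        elif kind == "conc":
            s = state_ids.index(row["!State"])
            i = network.metabolite_index(row["!Compound"])
            x_obs[s].append(Observation(mean=np.log(mean), std=std, index=i))
        elif kind == "enzyme":
            s = state_ids.index(row["!State"])
            l = network.reaction_index(row["!Reaction"])
            if fluxes[l, s] == 0:
                continue  # zero-flux reaction: datum ignored
            z_obs[s].setdefault(l, []).append(
                Observation(mean=np.log(mean), std=std)
            )
        else:
            raise ValueError(f"unsupported quantity type {kind!r}")
    return q_obs, x_obs, z_obs


def make_problem(
    network: MetabolicNetwork,
    fluxes: pd.DataFrame | np.ndarray,
    data: pd.DataFrame | None = None,
    priors: PriorCatalogue | None = None,
    bounds: BoundsConfig | None = None,
    alpha: float = 0.5,
    options: SolverOptions | None = None,
    fixed: dict[int, float] | None = None,
    prior_inflation: float = 1.0,
) -> BalancingProblem:
    """Build a :class:`BalancingProblem`.

    ``fluxes``: DataFrame (reactions x states, index = reaction ids) or
    plain array. Every state's flux vector must be thermodynamically
    feasible. ``prior_inflation`` multiplies all prior log-stds (used for
    the maximum-likelihood mode).
    """
    priors = priors or PriorCatalogue()
    bounds = bounds or BoundsConfig()
    options = options or SolverOptions()

    if isinstance(fluxes, pd.DataFrame):
        fluxes = fluxes.reindex(network.reaction_ids)
        state_ids = list(fluxes.columns)
        flux_arr = fluxes.to_numpy(dtype=float)
    else:
        flux_arr = np.atleast_2d(np.asarray(fluxes, dtype=float))
        if flux_arr.shape[0] != network.n_reactions:
            flux_arr = flux_arr.T
        state_ids = [f"state{s + 1}" for s in range(flux_arr.shape[1])]

    for s in range(flux_arr.shape[1]):
        res = check_flux_feasibility(network, flux_arr[:, s], bounds)
        if not res.feasible:
            raise InfeasibleFluxError(
                f"state {state_ids[s]}: fluxes infeasible ({res.message})"
            )

    schema = build_schema(network)
    polytope = build_polytope(
        network, schema, flux_arr, bounds, check_feasibility=False
    )

    infl = float(prior_inflation)
    n_met = network.n_metabolites

    # diagonal prior over the basic vector
    q_mean = np.concatenate(
        [
            np.zeros(n_met),
            np.full(schema.n_km, priors.log_mean("km")),
            np.full(network.n_reactions, priors.log_mean("kv")),
        ]
    )
    q_std = np.concatenate(
        [
            np.full(n_met, priors.log_std("g")),
            np.full(schema.n_km, priors.log_std("km")),
            np.full(network.n_reactions, priors.log_std("kv")),
        ]
    ) * infl
    q_prior = GaussianSpec(mean=q_mean, std=q_std)

    q_obs, x_obs, z_obs = _gather_observations(
        data, network, schema, state_ids, flux_arr
    )
    q_post = combine_gaussians(q_prior, q_obs)

    x_post: list[GaussianSpec] = []
    z_post: list[GaussianSpec] = []
    z_active: list[np.ndarray] = []
    for s in range(flux_arr.shape[1]):
        x_prior = GaussianSpec(
            mean=np.full(n_met, priors.log_mean("conc")),
            std=np.full(n_met, priors.log_std("conc")) * infl,
        )
        x_post.append(combine_gaussians(x_prior, x_obs[s]))

        active = np.flatnonzero(flux_arr[:, s] != 0)
        z_active.append(active)
        z_prior = GaussianSpec(
            mean=np.full(active.size, priors.log_mean("enzyme")),
            std=np.full(active.size, priors.log_std("enzyme")) * infl,
        )
        obs = []
        for l, obs_list in z_obs[s].items():
            pos = int(np.searchsorted(active, l))
            for o in obs_list:
                obs.append(Observation(mean=o.mean, std=o.std, index=pos))
        z_post.append(combine_gaussians(z_prior, obs))

    pre = PreposteriorSpec(q=q_post, x=x_post, z=z_post, z_active=z_active)
    return BalancingProblem(
        network=network,
        schema=schema,
        fluxes=flux_arr,
        state_ids=state_ids,
        priors=priors,
        bounds=bounds,
        alpha=alpha,
        polytope=polytope,
        preposterior=pre,
        q_precision=q_post.precision,
        options=options,
        fixed=dict(fixed or {}),
        has_data=data is not None and not data.empty,
        data=data,
    )


def _reduced_system(problem: BalancingProblem):
    """Polytope rows restricted to free coordinates, with fixed-coordinate
    contributions folded into the right-hand side."""
    poly = problem.polytope
    mask = problem.free_mask()
    A, b = poly.A, poly.b.copy()
    if problem.fixed:
        y_fix = np.zeros(poly.n_var)
        for idx, val in problem.fixed.items():
            y_fix[idx] = val
        b = b - A[:, ~mask] @ y_fix[~mask]
    A_red = A[:, mask]
    keep = np.any(A_red != 0, axis=1)
    if np.any(b[~keep] < -1e-9):
        raise InfeasibleFluxError("fixed coordinates violate the polytope")
    return A_red[keep], b[keep]


def _chebyshev_free(problem: BalancingProblem):
    from scipy.optimize import linprog

    A, b = _reduced_system(problem)
    n = A.shape[1]
    norms = np.linalg.norm(A, axis=1)
    c = np.zeros(n + 1)
    c[-1] = -1.0
    res = linprog(
        c,
        A_ub=np.hstack([A, norms[:, None]]),
        b_ub=b,
        bounds=[(None, None)] * n + [(0, None)],
        method="highs",
    )
    if not res.success or res.x[-1] <= 0:
        raise InfeasibleFluxError("empty polytope")
    return res.x[:-1].copy(), float(res.x[-1])


def initialize(problem: BalancingProblem) -> np.ndarray:
    """Strictly interior starting point.

    The preposterior means of (q, x) are used directly when interior;
    otherwise they are projected onto a slightly shrunk polytope by a
    minimal-squared-displacement QP started from the Chebyshev centre.
    """
    poly = problem.polytope
    pre = problem.preposterior
    mu = np.zeros(poly.n_var)
    mu[: poly.n_basic] = pre.q.mean
    for s in range(poly.n_states):
        mu[poly.x_slice(s)] = pre.x[s].mean
    for idx, val in problem.fixed.items():
        mu[idx] = val

    mask = problem.free_mask()
    A, b = _reduced_system(problem)
    center, radius = _chebyshev_free(problem)
    # keep the start comfortably off the force-margin cliffs, where the
    # enzyme-demand gradient blows up like 1/margin
    delta = min(INIT_MARGIN, 0.5 * radius)

    mu_free = mu[mask]
    if np.all(A @ mu_free <= b - delta):
        return mu

    def fun(yf):
        d = yf - mu_free
        return 0.5 * float(d @ d), d

    res = minimize(
        fun,
        center,
        jac=True,
        method="trust-constr",
        constraints=[LinearConstraint(A, -np.inf, b - delta, keep_feasible=True)],
        options={"gtol": 1e-10, "xtol": 1e-12, "maxiter": 2000},
    )
    return problem.embed(res.x)


@dataclass
class BalancingResult:
    y_star: np.ndarray
    constants: KineticConstantSet
    x: pd.DataFrame  # metabolites x states, log scale
    z: dict[str, pd.Series]  # per state: log enzyme over active reactions
    theta: pd.DataFrame  # reactions x states
    breakdown: ScoreBreakdown
    diagnostics: dict
    multistart_agreement: bool | None = None


def _kkt_optimality(grad: np.ndarray, A: np.ndarray, b: np.ndarray, yf: np.ndarray) -> float:
    """Stationarity residual: norm of the gradient with its components along
    active constraint normals (pointing outward) removed by NNLS."""
    from scipy.optimize import nnls

    act = np.flatnonzero(b - A @ yf < 1e-7)
    if act.size == 0:
        return float(np.linalg.norm(grad))
    lam, _ = nnls(A[act].T, -grad)
    return float(np.linalg.norm(grad + A[act].T @ lam))


def _solve_from(problem: BalancingProblem, y0: np.ndarray, alpha: float):
    """Single minimisation run. SLSQP is the workhorse (its iterates stay
    inside the polytope because the constraints are linear and the start is
    feasible); trust-constr with a sparse constraint matrix is the fallback
    when SLSQP fails or drifts out of the polytope."""
    import scipy.sparse as sp

    prob = replace(problem, alpha=alpha)
    mask = problem.free_mask()
    A, b = _reduced_system(problem)
    opts = problem.options

    def fun(yf):
        y = problem.embed(yf)
        breakdown, grad = assemble_posterior_score(prob, y, strict=False)
        return breakdown.total, grad[mask]

    res = minimize(
        fun,
        np.asarray(y0)[mask],
        jac=True,
        method="SLSQP",
        constraints=[{"type": "ineq", "fun": lambda yf: b - A @ yf, "jac": lambda yf: -A}],
        options={"ftol": 1e-12, "maxiter": min(1000, opts.maxiter)},
    )
    def hess(yf):
        H = posterior_score_hessian(prob, problem.embed(yf))
        return H[np.ix_(mask, mask)]

    # trust-constr rejects starts that violate any row even by 1e-15, so
    # blend the SLSQP iterate toward the known-feasible y0 if needed
    start = np.asarray(y0)[mask]
    if np.all(A @ res.x <= b + 1e-9):
        cand = res.x
        for t in (0.0, 1e-9, 1e-6, 1e-4, 1e-2, 0.1):
            blend = (1 - t) * cand + t * start
            if np.all(A @ blend <= b):
                start = blend
                break
    polish = minimize(
        fun,
        start,
        jac=True,
        hess=hess,
        method="trust-constr",
        constraints=[
            LinearConstraint(sp.csc_matrix(A), -np.inf, b, keep_feasible=True)
        ],
        options={
            "gtol": max(opts.gtol, 1e-8),
            "xtol": opts.xtol,
            "maxiter": opts.maxiter,
        },
    )
    polish.optimality = _kkt_optimality(fun(polish.x)[1], A, b, polish.x)
    if polish.status == 0 and polish.optimality > 1e-3:
        raise ConvergenceError(
            f"solver did not converge: {polish.message} "
            f"(optimality {polish.optimality:.3g})",
            best=problem.embed(polish.x),
        )
    return problem.embed(polish.x), polish


def balance(problem: BalancingProblem) -> BalancingResult:
    """Minimise the posterior score over the feasible polytope.

    At alpha = 0 the problem is strictly convex; by default 5 random
    interior multistarts are run and checked for coordinate-wise agreement.
    At alpha > 0 a single continuation run is used: solve at alpha = 0,
    then warm-start the target alpha.
    """
    opts = problem.options
    n_starts = opts.multistart
    if n_starts is None:
        n_starts = 5 if problem.alpha == 0 else 1

    y0 = initialize(problem)
    starts = [y0]
    if n_starts > 1:
        rng = np.random.default_rng(opts.seed)
        A, b = _reduced_system(problem)
        center, _ = _chebyshev_free(problem)
        mask = problem.free_mask()
        red_poly = FeasiblePolytope(
            A=A, b=b, row_labels=[], n_basic=int(mask.sum()), n_met=0,
            n_states=0, schema=problem.schema,
        )
        for _ in range(n_starts - 1):
            yf = red_poly.random_interior_point(rng, center=center)
            starts.append(problem.embed(yf))

    solutions = []
    for start in starts:
        if problem.alpha > 0 and opts.continuation:
            y_mid, _ = _solve_from(problem, start, alpha=0.0)
            y_star, res = _solve_from(problem, y_mid, alpha=problem.alpha)
        else:
            y_star, res = _solve_from(problem, start, alpha=problem.alpha)
        solutions.append((y_star, res))

    y_star, res = solutions[0]
    agreement = None
    if len(solutions) > 1:
        spread = max(
            float(np.max(np.abs(sol[0] - y_star))) for sol in solutions[1:]
        )
        agreement = spread <= opts.multistart_tol
        # return the best-scoring solution
        scores = [
            assemble_posterior_score(problem, sol[0], strict=False)[0].total
            for sol in solutions
        ]
        best = int(np.argmin(scores))
        y_star, res = solutions[best]

    return _package_result(problem, y_star, res, agreement)


def _package_result(problem, y_star, res, agreement) -> BalancingResult:
    poly = problem.polytope
    q, x = poly.split(y_star)
    constants = expand_constants(problem.schema, q)
    net = problem.network
    x_df = pd.DataFrame(x, index=net.metabolite_ids, columns=problem.state_ids)
    theta = driving_forces(constants.ln_keq, net.S, x)
    theta_df = pd.DataFrame(theta, index=net.reaction_ids, columns=problem.state_ids)

    z: dict[str, pd.Series] = {}
    for s, sid in enumerate(problem.state_ids):
        active, z_vals, _, _ = log_enzyme_demand_and_gradient(
            problem.schema, q, x[:, s], problem.fluxes[:, s]
        )
        z[sid] = pd.Series(
            z_vals, index=[net.reaction_ids[l] for l in active], name=sid
        )

    breakdown, grad = assemble_posterior_score(problem, y_star, strict=False)
    diagnostics = {
        "optimality": float(getattr(res, "optimality", np.nan)),
        "n_iter": int(getattr(res, "niter", -1)),
        "status": int(res.status),
        "message": str(res.message),
        "in_polytope": bool(poly.contains(y_star, tol=1e-8)),
        "prior_insensitive": not problem.has_data,
    }
    return BalancingResult(
        y_star=y_star,
        constants=constants,
        x=x_df,
        z=z,
        theta=theta_df,
        breakdown=breakdown,
        diagnostics=diagnostics,
        multistart_agreement=agreement,
    )


def maximum_likelihood_mode(
    problem: BalancingProblem, inflation: float = 1e3
) -> BalancingResult:
    """Re-run :func:`balance` with prior log-stds inflated by ``inflation``
    (default 1e3), approximating flat priors while keeping all bounds and
    the original data precision."""
    flat = make_problem(
        network=problem.network,
        fluxes=pd.DataFrame(
            problem.fluxes, index=problem.network.reaction_ids,
            columns=problem.state_ids,
        ),
        data=problem.data,
        priors=problem.priors,
        bounds=problem.bounds,
        alpha=problem.alpha,
        options=problem.options,
        fixed=problem.fixed,
        prior_inflation=inflation,
    )
    result = balance(flat)
    result.diagnostics["mode"] = "maximum_likelihood"
    result.diagnostics["prior_insensitive"] = not problem.has_data
    return result
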