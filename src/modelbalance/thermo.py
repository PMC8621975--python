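"""Thermodynamic forces, flux-sign feasibility, and the convex feasible
polytope over basic kinetic variables and per-state log concentrations.

The joint variable vector is laid out as ``y = (q_basic, x_1, ..., x_S)``
with one log-concentration block per metabolic state. The polytope collects
box bounds on all coordinates and, per state, the margin constraints
``sign(v_l) * theta_l >= eps`` for reactions with nonzero flux.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .network_schema import DependencySchema, MetabolicNetwork



class InfeasibleFluxError(ValueError):
    """Raised when a flux vector admits no thermodynamically consistent state."""


@dataclass
class BoundsConfig:
    """Bounds and margins defining the feasible polytope.

    Concentrations in mM, kV in 1/s; ``force_margin`` in RT units.
    Per-metabolite overrides map metabolite id -> value.
    """

    conc_min: float = 1e-6
    conc_max: float = 1e2
    force_margin: float = 1e-3
    g_max: float = 50.0
    km_min: float = 1e-8
    km_max: float = 1e4
    kv_min: float = 1e-8
    kv_max: float = 1e8
    conc_min_override: dict[str, float] = field(default_factory=dict)
    conc_max_override: dict[str, float] = field(default_factory=dict)

    def x_bounds(self, network: MetabolicNetwork) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array(
            [
                np.log(self.conc_min_override.get(m, self.conc_min))
                for m in network.metabolite_ids
            ]
        )
        hi = np.array(
            [
                np.log(self.conc_max_override.get(m, self.conc_max))
                for m in network.metabolite_ids
            ]
        )
        if np.any(lo >= hi):
            bad = [
                network.metabolite_ids[i]
                for i in np.flatnonzero(lo >= hi)
            ]
            raise ValueError(f"conc_min >= conc_max for metabolites {bad}")
        return lo, hi


def read_bounds(path) -> BoundsConfig:
    """Read a key-value bounds file (tab- or equals-separated).

    Keys: ``conc_min``, ``conc_max``, ``force_margin``, ``g_max``,
    ``km_min``, ``km_max``, ``kv_min``, ``kv_max``; per-metabolite
    overrides as ``conc_min[MET]`` / ``conc_max[MET]``.
    """
    cfg = BoundsConfig()
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "\t" in line:
                key, val = line.split("\t", 1)
            elif "=" in line:
                key, val = line.split("=", 1)
            else:
                raise ValueError(f"malformed bounds line: {raw!r}")
            key, val = key.strip(), float(val.strip())
            if key.startswith("conc_min[") and key.endswith("]"):
                cfg.conc_min_override[key[9:-1]] = val
            elif key.startswith("conc_max[") and key.endswith("]"):
                cfg.conc_max_override[key[9:-1]] = val
            elif hasattr(cfg, key):
                setattr(cfg, key, val)
            else:
                raise ValueError(f"unknown bounds key: {key!r}")
    return cfg


def driving_forces(ln_keq: np.ndarray, S: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Thermodynamic forces ``theta = ln Keq - S^T x`` (RT units).

    ``x`` may be a vector (one state) or a matrix with one column per state,
    in which case a matrix of forces is returned.
    """
    ln_keq = np.asarray(ln_keq, dtype=float)
    x = np.asarray(x, dtype=float)
    if S.shape[1] != ln_keq.shape[0] or S.shape[0] != x.shape[0]:
        raise ValueError("dimension mismatch between ln_keq, S, and x")
    if x.ndim == 1:
        return ln_keq - S.T @ x
    return ln_keq[:, None] - S.T @ x


@dataclass
class FeasibilityResult:
    feasible: bool
    slack: float
    g: np.ndarray | None = None
    x: np.ndarray | None = None
    message: str = ""


def check_flux_feasibility(
    network: MetabolicNetwork,
    v: np.ndarray,
    bounds: BoundsConfig | None = None,
) -> FeasibilityResult:
    """Decide whether a flux vector is thermodynamically realisable.

    Solves an LP over (g, x) maximising the minimal slack t in
    ``sign(v_l) * theta_l >= eps + t`` for all active reactions, subject to
    the box bounds. Feasible iff the optimal t is >= 0; the witness
    (g, x) is then an interior point usable as an optimiser start.
    Zero flux vectors are always feasible.
    """
    bounds = bounds or BoundsConfig()
    v = np.asarray(v, dtype=float)
    n_met, n_rxn = network.n_metabolites, network.n_reactions
    active = np.flatnonzero(v != 0)
    x_lo, x_hi = bounds.x_bounds(network)
    if active.size == 0:
        x0 = 0.5 * (x_lo + x_hi)
        return FeasibilityResult(True, np.inf, np.zeros(n_met), x0, "no active reactions")

    # variables: [g (n_met), x (n_met), t]
    n_var = 2 * n_met + 1
    # sign(v_l)*(-S^T g - S^T x)_l >= eps + t
    # => sign(v_l)*(S^T g + S^T x)_l + t <= -eps
    A_ub = np.zeros((active.size, n_var))
    sgn = np.sign(v[active])
    A_ub[:, :n_met] = sgn[:, None] * network.S.T[active]
    A_ub[:, n_met : 2 * n_met] = sgn[:, None] * network.S.T[active]
    A_ub[:, -1] = 1.0
    b_ub = np.full(active.size, -bounds.force_margin)
    var_bounds = (
        [(-bounds.g_max, bounds.g_max)] * n_met
        + list(zip(x_lo, x_hi))
        + [(None, 2 * bounds.g_max)]
    )
    c = np.zeros(n_var)
    c[-1] = -1.0  # maximise t
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=var_bounds, method="highs")
    if not res.success:
        return FeasibilityResult(False, -np.inf, message=f"LP failed: {res.message}")
    t = res.x[-1]
    if t < 0:
        return FeasibilityResult(False, float(t), message="flux signs admit no feasible forces")
    return FeasibilityResult(
        True, float(t), res.x[:n_met].copy(), res.x[n_met : 2 * n_met].copy()
    )


@dataclass
class FeasiblePolytope:
    """Linear inequality system ``A y <= b`` over ``y = (q_basic, x per state)``."""

    A: np.ndarray
    b: np.ndarray
    row_labels: list[str]
    n_basic: int
    n_met: int
    n_states: int
    schema: DependencySchema

    @property
    def n_var(self) -> int:
        return self.n_basic + self.n_states * self.n_met

    def x_slice(self, state: int) -> slice:
        start = self.n_basic + state * self.n_met
        return slice(start, start + self.n_met)

    def split(self, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(q_basic, x matrix of shape (n_met, n_states))."""
        y = np.asarray(y, dtype=float)
        q = y[: self.n_basic]
        x = y[self.n_basic :].reshape(self.n_states, self.n_met).T
        return q, x

    def join(self, q_basic: np.ndarray, x: np.ndarray) -> np.ndarray:
        return np.concatenate([q_basic, np.asarray(x).T.ravel()])

    def margins(self, y: np.ndarray) -> np.ndarray:
        return self.b - self.A @ y

    def contains(self, y: np.ndarray, tol: float = 1e-8) -> bool:
        return bool(np.all(self.margins(y) >= -tol))

    def chebyshev_center(self) -> tuple[np.ndarray, float]:
        """Centre and radius of the largest inscribed ball (row-normalised)."""
        norms = np.linalg.norm(self.A, axis=1)
        n = self.n_var
        c = np.zeros(n + 1)
        c[-1] = -1.0
        A_ub = np.hstack([self.A, norms[:, None]])
        res = linprog(
            c, A_ub=A_ub, b_ub=self.b, bounds=[(None, None)] * n + [(0, None)],
            method="highs",
        )
        if not res.success:
            raise InfeasibleFluxError(f"empty polytope: {res.message}")
        return res.x[:-1].copy(), float(res.x[-1])

    def random_interior_point(
        self, rng: np.random.Generator, center: np.ndarray | None = None, frac: float = 0.8
    ) -> np.ndarray:
        """Random strictly interior point: step from the centre along a
        random direction, a fraction of the way to the boundary."""
        if center is None:
            center, _ = self.chebyshev_center()
        d = rng.standard_normal(self.n_var)
        d /= np.linalg.norm(d)
        Ad = self.A @ d
        slack = self.b - self.A @ center
        with np.errstate(divide="ignore"):
            steps = np.where(Ad > 1e-12, slack / Ad, np.inf)
        t_max = float(np.min(steps))
        if not np.isfinite(t_max):
            t_max = 1.0
        return center + frac * rng.uniform(0, 1) * t_max * d


def build_polytope(
    network: MetabolicNetwork,
    schema: DependencySchema,
    fluxes: np.ndarray,
    bounds: BoundsConfig | None = None,
    check_feasibility: bool = True,
) -> FeasiblePolytope:
    """Assemble the feasible polytope for a set of per-state flux vectors.

    ``fluxes`` has shape (n_reactions, n_states). Zero-flux reactions
    contribute no sign constraint in that state.
    """
    bounds = bounds or BoundsConfig()
    fluxes = np.atleast_2d(np.asarray(fluxes, dtype=float))
    if fluxes.shape[0] != network.n_reactions:
        fluxes = fluxes.T
    n_rxn, n_states = fluxes.shape
    if n_rxn != network.n_reactions:
        raise ValueError("flux array does not match reaction count")

    if check_feasibility:
        for s in range(n_states):
            res = check_flux_feasibility(network, fluxes[:, s], bounds)
            if not res.feasible:
                raise InfeasibleFluxError(
                    f"fluxes of state {s} are thermodynamically infeasible: {res.message}"
                )

    n_met = network.n_metabolites
    n_basic = schema.n_basic
    n_km = schema.n_km
    n_var = n_basic + n_states * n_met
    x_lo, x_hi = bounds.x_bounds(network)

    rows: list[np.ndarray] = []
    rhs: list[float] = []
    labels: list[str] = []

    def _box(idx: int, lo: float, hi: float, name: str) -> None:
        r = np.zeros(n_var)
        r[idx] = 1.0
        rows.append(r)
        rhs.append(hi)
        labels.append(f"{name}<=hi")
        r = np.zeros(n_var)
        r[idx] = -1.0
        rows.append(r)
        rhs.append(-lo)
        labels.append(f"{name}>=lo")

    for i, name in enumerate(schema.basic_names[: n_met]):
        _box(i, -bounds.g_max, bounds.g_max, name)
    for k in range(n_km):
        _box(n_met + k, np.log(bounds.km_min), np.log(bounds.km_max),
             schema.basic_names[n_met + k])
    for l in range(n_rxn):
        _box(n_met + n_km + l, np.log(bounds.kv_min), np.log(bounds.kv_max),
             schema.basic_names[n_met + n_km + l])
    for s in range(n_states):
        off = n_basic + s * n_met
        for i in range(n_met):
            _box(off + i, x_lo[i], x_hi[i], f"x[{s}]:{network.metabolite_ids[i]}")

    # sign constraints: sigma*(S^T g + S^T x_s)_l <= -eps
    for s in range(n_states):
        off = n_basic + s * n_met
        for l in np.flatnonzero(fluxes[:, s] != 0):
            sgn = np.sign(fluxes[l, s])
            r = np.zeros(n_var)
            r[:n_met] = sgn * network.S[:, l]
            r[off : off + n_met] = sgn * network.S[:, l]
            rows.append(r)
            rhs.append(-bounds.force_margin)
            labels.append(f"force[{s}]:{network.reaction_ids[l]}")

    return FeasiblePolytope(
        A=np.array(rows),
        b=np.array(rhs),
        row_labels=labels,
        n_basic=n_basic,
        n_met=n_met,
        n_states=n_states,
        schema=schema,
    )
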