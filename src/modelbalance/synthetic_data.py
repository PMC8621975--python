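"""Ground-truth model generation, steady-state simulation, and noisy data
tables for artificial-data recovery tests.

True kinetic constants are drawn from the same broad lognormal
distributions that serve as priors; metabolic states are obtained by
drawing enzyme levels and external concentrations at random and integrating
the kinetic model to steady state. State data are perturbed with a
configurable geometric standard deviation (1.2 in the noisy scenarios) and
kinetic data with another (1.5); a gsd of 1 leaves values untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import tables
from .kinetics import catalytic_rate_cm
from .network_schema import (
    DependencySchema,
    KineticConstantSet,
    MetabolicNetwork,
    build_schema,
    expand_constants,
)
from .thermo import BoundsConfig, driving_forces

LN10 = np.log(10.0)


@dataclass
class PriorCatalogue:
    """Medians (linear scale) and geometric standard deviations per quantity.

    The ``g`` entry governs the per-metabolite chemical-potential-like basic
    variable; its default spread is chosen so that a uni-uni equilibrium
    constant (the difference of two g draws) has a geometric std of 10.
    """

    entries: dict[str, tuple[float, float]] = field(default_factory=dict)

    DEFAULTS = {
        "keq": (1.0, 10.0),
        "kv": (10.0, 10.0),
        "km": (0.1, 10.0),
        "conc": (0.1, 10.0),
        "enzyme": (1e-3, 10.0),
        "g": (1.0, float(np.exp(LN10 / np.sqrt(2.0)))),
    }

    def __post_init__(self) -> None:
        merged = dict(self.DEFAULTS)
        merged.update(self.entries)
        self.entries = merged
        for kind, (med, gsd) in self.entries.items():
            if med <= 0:
                raise ValueError(f"{kind}: median must be positive")
            if gsd <= 1:
                raise ValueError(f"{kind}: geometric std must exceed 1")

    def median(self, kind: str) -> float:
        return self.entries[kind][0]

    def gsd(self, kind: str) -> float:
        return self.entries[kind][1]

    def log_mean(self, kind: str) -> float:
        return float(np.log(self.entries[kind][0]))

    def log_std(self, kind: str) -> float:
        return float(np.log(self.entries[kind][1]))


@dataclass
class MetabolicState:
    """One simulated steady state: log concentrations (all metabolites),
    log enzyme levels, and fluxes."""

    x: np.ndarray
    z: np.ndarray
    v: np.ndarray


@dataclass
class TruthBundle:
    network: MetabolicNetwork
    schema: DependencySchema
    q_basic: np.ndarray
    constants: KineticConstantSet
    states: list[MetabolicState]
    state_ids: list[str]

    @property
    def fluxes(self) -> np.ndarray:
        return np.column_stack([st.v for st in self.states])


@dataclass
class Scenario:
    """Artificial-data scenario: which kinetic rows are exposed and how
    noisy the tables are.

    ``name`` is one of S1 (all kinetic constants given as data), S1K
    (equilibrium constants only), S2 (no kinetic data). Noise-free
    variants use gsd 1.
    """

    name: str
    state_gsd: float = 1.0
    kinetic_gsd: float = 1.0
    flux_gsd: float = 1.0
    n_states: int = 6
    seed: int = 1

    def __post_init__(self) -> None:
        if self.name not in ("S1", "S1K", "S2"):
            raise ValueError(f"unknown scenario {self.name!r}")
        for g in (self.state_gsd, self.kinetic_gsd, self.flux_gsd):
            if g < 1:
                raise ValueError("geometric std must be >= 1")

    @property
    def kinetic_kinds(self) -> tuple[str, ...]:
        if self.name == "S1":
            return ("keq", "kcat_fwd", "kcat_bwd", "km")
        if self.name == "S1K":
            return ("keq",)
        return ()


def sample_basic_vector(
    schema: DependencySchema, priors: PriorCatalogue, rng: np.random.Generator
) -> np.ndarray:
    n_met = schema.network.n_metabolites
    g = rng.normal(0.0, priors.log_std("g"), n_met)
    lnkm = rng.normal(priors.log_mean("km"), priors.log_std("km"), schema.n_km)
    lnkv = rng.normal(priors.log_mean("kv"), priors.log_std("kv"), schema.network.n_reactions)
    return np.concatenate([g, lnkm, lnkv])


def sample_true_model(
    network: MetabolicNetwork,
    priors: PriorCatalogue | None = None,
    seed: int | np.random.Generator = 1,
) -> tuple[KineticConstantSet, np.ndarray]:
    """Draw a Haldane/Wegscheider-consistent true constant set.

    Returns the expanded set and the underlying basic vector.
    """
    priors = priors or PriorCatalogue()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    schema = build_schema(network)
    q_basic = sample_basic_vector(schema, priors, rng)
    return expand_constants(schema, q_basic), q_basic


def _rates(network: MetabolicNetwork, constants: KineticConstantSet, x: np.ndarray) -> np.ndarray:
    return np.array(
        [catalytic_rate_cm(constants, x, l) for l in range(network.n_reactions)]
    )


class SteadyStateError(RuntimeError):
    pass


def simulate_steady_state(
    network: MetabolicNetwork,
    constants: KineticConstantSet,
    enzymes: np.ndarray,
    x_external: np.ndarray,
    x0_internal: np.ndarray | None = None,
    rel_tol: float = 1e-9,
    t_max: float = 1e9,
    max_rhs_evals: int = 60_000,
) -> MetabolicState:
    """Integrate the kinetic model to steady state.

    ``enzymes`` are linear-scale levels per reaction (mM); ``x_external``
    holds log concentrations for the external metabolites (clamped).
    Integration runs on log internal concentrations (guaranteeing
    positivity) until ``max |dc_i/dt| / c_i < rel_tol`` (1/s).
    """
    internal = np.flatnonzero(network.is_internal)
    external = np.flatnonzero(~network.is_internal)
    if x_external.shape != (external.size,):
        raise ValueError("x_external must match the number of external metabolites")
    enzymes = np.asarray(enzymes, dtype=float)
    if np.any(enzymes <= 0):
        raise ValueError("enzymes must be positive")
    S_int = network.S[internal, :]

    x_full = np.zeros(network.n_metabolites)
    x_full[external] = x_external

    n_evals = 0

    def rhs(_t, u):
        nonlocal n_evals
        n_evals += 1
        if n_evals > max_rhs_evals:  # pathological stiffness: give up fast
            raise SteadyStateError("integration budget exhausted")
        x_full[internal] = u
        v = enzymes * _rates(network, constants, x_full)
        return (S_int @ v) * np.exp(-u)  # d ln c / dt

    u = (
        np.asarray(x0_internal, dtype=float)
        if x0_internal is not None
        else np.full(internal.size, np.log(0.1))
    )
    t_end = 1e2
    while t_end <= t_max:
        sol = solve_ivp(rhs, (0.0, t_end), u, method="LSODA", rtol=1e-10, atol=1e-12)
        if not sol.success:
            raise SteadyStateError(f"integration failed: {sol.message}")
        u = sol.y[:, -1]
        if np.max(np.abs(rhs(0.0, u))) < rel_tol:
            break
        t_end *= 10.0
    else:
        raise SteadyStateError("no steady state within time budget")

    x_full[internal] = u
    v = enzymes * _rates(network, constants, x_full)
    resid = np.linalg.norm(S_int @ v)
    if resid > 1e-8 * max(np.linalg.norm(v), 1e-12):
        raise SteadyStateError(f"flux imbalance {resid:.3g} at steady state")
    theta = driving_forces(constants.ln_keq, network.S, x_full)
    if np.any(np.sign(v[v != 0]) != np.sign(theta[v != 0])):
        raise SteadyStateError("flux/force sign mismatch at steady state")
    return MetabolicState(x=x_full.copy(), z=np.log(enzymes), v=v)


def _state_ok(
    network: MetabolicNetwork,
    constants: KineticConstantSet,
    state: MetabolicState,
    bounds: BoundsConfig,
    min_abs_flux: float,
) -> bool:
    x_lo, x_hi = bounds.x_bounds(network)
    if np.any(state.x < x_lo + 0.1) or np.any(state.x > x_hi - 0.1):
        return False
    if np.any(np.abs(state.v) < min_abs_flux):
        return False
    theta = driving_forces(constants.ln_keq, network.S, state.x)
    active = state.v != 0
    return bool(np.all(np.abs(theta[active]) >= 2 * bounds.force_margin))


def sample_states(
    network: MetabolicNetwork,
    constants: KineticConstantSet,
    n_states: int,
    priors: PriorCatalogue,
    rng: np.random.Generator,
    bounds: BoundsConfig | None = None,
    max_retries: int = 10,
    min_abs_flux: float = 1e-9,
) -> list[MetabolicState]:
    """Draw enzymes and external concentrations at random and simulate
    steady states; retries with fresh draws on failure."""
    bounds = bounds or BoundsConfig()
    external = np.flatnonzero(~network.is_internal)
    states: list[MetabolicState] = []
    for _ in range(n_states):
        for attempt in range(max_retries):
            e = np.exp(
                rng.normal(
                    priors.log_mean("enzyme"),
                    priors.log_std("enzyme"),
                    network.n_reactions,
                )
            )
            x_ext = rng.normal(
                priors.log_mean("conc"), priors.log_std("conc"), external.size
            )
            x_lo, x_hi = bounds.x_bounds(network)
            x_ext = np.clip(x_ext, x_lo[external] + 0.5, x_hi[external] - 0.5)
            try:
                st = simulate_steady_state(network, constants, e, x_ext)
            except SteadyStateError:
                continue
            if _state_ok(network, constants, st, bounds, min_abs_flux):
                states.append(st)
                break
        else:
            raise SteadyStateError(
                f"could not generate a valid state in {max_retries} attempts"
            )
    return states


def add_noise(
    values: np.ndarray, gsd: float, seed: int | np.random.Generator = 1
) -> np.ndarray:
    """Multiply positive values by lognormal noise with geometric std ``gsd``."""
    values = np.asarray(values, dtype=float)
    if np.any(values <= 0):
        raise ValueError("values must be positive")
    if gsd < 1:
        raise ValueError("geometric std must be >= 1")
    if gsd == 1:
        return values.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return values * np.exp(rng.normal(0.0, np.log(gsd), values.shape))


@dataclass
class ScenarioDataset:
    truth: TruthBundle
    data: pd.DataFrame
    fluxes: pd.DataFrame
    scenario: Scenario


# geometric-std floor written into data tables for noise-free values, so the
# likelihood stays proper (a gsd of exactly 1 would mean infinite precision)
NOISE_FLOOR_GSD = 1.05


def make_scenario_dataset(
    network: MetabolicNetwork,
    scenario: Scenario,
    priors: PriorCatalogue | None = None,
    bounds: BoundsConfig | None = None,
    max_model_retries: int = 10,
) -> ScenarioDataset:
    """Generate a ground-truth bundle plus data tables for one scenario.

    The data table exposes concentration and enzyme rows for every state
    (perturbed by ``state_gsd``) and kinetic rows filtered per scenario
    (perturbed by ``kinetic_gsd``). Fluxes are emitted noise-free unless
    ``flux_gsd`` > 1. Deterministic for a fixed scenario seed.
    """
    priors = priors or PriorCatalogue()
    bounds = bounds or BoundsConfig()
    rng = np.random.default_rng(scenario.seed)
    schema = build_schema(network)

    truth: TruthBundle | None = None
    for _ in range(max_model_retries):
        q_basic = sample_basic_vector(schema, priors, rng)
        constants = expand_constants(schema, q_basic)
        try:
            states = sample_states(
                network, constants, scenario.n_states, priors, rng, bounds
            )
        except SteadyStateError:
            continue
        truth = TruthBundle(
            network=network,
            schema=schema,
            q_basic=q_basic,
            constants=constants,
            states=states,
            state_ids=[f"state{i + 1}" for i in range(scenario.n_states)],
        )
        break
    if truth is None:
        raise SteadyStateError("could not generate a valid true model")

    rows: list[dict] = []
    state_noise_gsd = max(scenario.state_gsd, NOISE_FLOOR_GSD)
    kin_noise_gsd = max(scenario.kinetic_gsd, NOISE_FLOOR_GSD)

    for sid, st in zip(truth.state_ids, truth.states):
        conc = add_noise(np.exp(st.x), scenario.state_gsd, rng)
        for i, mid in enumerate(network.metabolite_ids):
            rows.append(
                tables.data_row("conc", conc[i], state_noise_gsd, compound=mid, state=sid)
            )
        active = np.flatnonzero(st.v != 0)
        enz = add_noise(np.exp(st.z[active]), scenario.state_gsd, rng)
        for j, l in enumerate(active):
            rows.append(
                tables.data_row(
                    "enzyme", enz[j], state_noise_gsd,
                    reaction=network.reaction_ids[l], state=sid,
                )
            )

    kinds = scenario.kinetic_kinds
    if "keq" in kinds:
        vals = add_noise(np.exp(truth.constants.ln_keq), scenario.kinetic_gsd, rng)
        for l, rid in enumerate(network.reaction_ids):
            rows.append(tables.data_row("keq", vals[l], kin_noise_gsd, reaction=rid))
    if "kcat_fwd" in kinds:
        fwd = add_noise(np.exp(truth.constants.ln_kcat_fwd), scenario.kinetic_gsd, rng)
        bwd = add_noise(np.exp(truth.constants.ln_kcat_bwd), scenario.kinetic_gsd, rng)
        for l, rid in enumerate(network.reaction_ids):
            rows.append(tables.data_row("kcat_fwd", fwd[l], kin_noise_gsd, reaction=rid))
            rows.append(tables.data_row("kcat_bwd", bwd[l], kin_noise_gsd, reaction=rid))
    if "km" in kinds:
        vals = add_noise(np.exp(truth.constants.ln_km), scenario.kinetic_gsd, rng)
        for k, (l, i) in enumerate(schema.km_pairs):
            rows.append(
                tables.data_row(
                    "km", vals[k], kin_noise_gsd,
                    reaction=network.reaction_ids[l],
                    compound=network.metabolite_ids[i],
                )
            )

    data = pd.DataFrame(rows, columns=tables.DATA_COLUMNS)

    flux_vals = truth.fluxes.copy()
    if scenario.flux_gsd > 1:
        flux_vals = np.sign(flux_vals) * add_noise(
            np.abs(flux_vals), scenario.flux_gsd, rng
        )
    fluxes = pd.DataFrame(
        flux_vals, index=network.reaction_ids, columns=truth.state_ids
    )
    return ScenarioDataset(truth=truth, data=data, fluxes=fluxes, scenario=scenario)


def chain_network(n_reactions: int, external_ends: bool = True) -> MetabolicNetwork:
    """Linear chain M1 -> M2 -> ... with clamped terminal metabolites."""
    n_met = n_reactions + 1
    mets = [f"M{i + 1}" for i in range(n_met)]
    rxns = [f"R{i + 1}" for i in range(n_reactions)]
    S = np.zeros((n_met, n_reactions), dtype=int)
    for j in range(n_reactions):
        S[j, j] = -1
        S[j + 1, j] = 1
    is_internal = np.ones(n_met, dtype=bool)
    if external_ends:
        is_internal[0] = is_internal[-1] = False
    return MetabolicNetwork(mets, rxns, S, is_internal)


def branched_network() -> MetabolicNetwork:
    """Small branched test network: X1 -> A -> B, B -> X2, B -> X3 (5 reactions)."""
    mets = ["X1", "A", "B", "X2", "X3"]
    rxns = ["R1", "R2", "R3", "R4", "R5"]
    #           R1  R2  R3  R4  R5
    S = np.array(
        [
            [-1,  0,  0,  0,  0],   # X1
            [ 1, -1,  0,  0,  0],   # A
            [ 0,  1, -1, -1,  0],   # B
            [ 0,  0,  1,  0, -1],   # X2 internal hub -> exported
            [ 0,  0,  0,  1,  0],   # X3
        ],
        dtype=int,
    )
    # R5 exports X2 to a sink metabolite
    mets.append("X4")
    S = np.vstack([S, np.array([[0, 0, 0, 0, 1]])])
    is_internal = np.array([False, True, True, True, False, False])
    return MetabolicNetwork(mets, rxns, S, is_internal)
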