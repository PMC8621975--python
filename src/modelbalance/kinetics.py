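"""Modular reversible rate laws and the enzyme-demand function.

The default rate law is the common modular (CM) law; for a uni-uni
reaction it reduces to reversible Michaelis-Menten,

    k = (kcat+ s/Ks - kcat- p/Kp) / (1 + s/Ks + p/Kp).

Any Haldane-consistent parameter set factorises as
``k = kcat+ * eta_rev * eta_sat`` with ``eta_rev = 1 - exp(-theta)`` and a
saturation term in (0, 1]. The log enzyme demand ``z = ln v - ln k`` is
evaluated in log space (softplus / log-sum-exp) so polytope corners with
extreme concentrations do not overflow, and its gradient with respect to
the basic variables and log concentrations is analytic.
"""

from __future__ import annotations

import numpy as np

from .network_schema import DependencySchema, KineticConstantSet
from .thermo import driving_forces


class ThermodynamicInconsistencyError(ValueError):
    """Flux and catalytic rate (or force) disagree in sign."""


class DomainError(ValueError):
    """Evaluation requested outside the feasible domain."""


def _softplus(u):
    return np.logaddexp(0.0, u)


def _sigmoid(u):
    out = np.empty_like(np.asarray(u, dtype=float))
    u = np.asarray(u, dtype=float)
    pos = u >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-u[pos]))
    eu = np.exp(u[~pos])
    out[~pos] = eu / (1.0 + eu)
    return out


def catalytic_rate_cm(constants: KineticConstantSet, x: np.ndarray, l: int) -> float:
    """Catalytic rate k (1/s) of reaction ``l`` under the CM rate law.

    Direct linear-scale evaluation of the printed law; ``x`` is the full
    log-concentration vector in ln(mM).
    """
    net = constants.schema.network
    mets, lnkm = constants.km_for_reaction(l)
    if mets.size != np.count_nonzero(net.S[:, l]):
        raise ValueError(f"missing KM entries for reaction {l}")
    s_coef = net.S[mets, l]
    ratio = np.exp(np.asarray(x, dtype=float)[mets] - lnkm)  # c_i / KM_i
    subs = s_coef < 0
    prods = s_coef > 0
    num = np.exp(constants.ln_kcat_fwd[l]) * np.prod(ratio[subs] ** (-s_coef[subs])) - np.exp(
        constants.ln_kcat_bwd[l]
    ) * np.prod(ratio[prods] ** s_coef[prods])
    denom = (
        np.prod((1.0 + ratio[subs]) ** (-s_coef[subs]))
        + np.prod((1.0 + ratio[prods]) ** s_coef[prods])
        - 1.0
    )
    return float(num / denom)


def eta_rev(theta) -> np.ndarray | float:
    """Reversibility efficiency ``1 - exp(-theta)``; negative for theta < 0."""
    return -np.expm1(-np.asarray(theta, dtype=float))


def eta_sat(constants: KineticConstantSet, x: np.ndarray, l: int) -> float:
    """Saturation efficiency in (0, 1]: forward substrate occupancy over the
    CM denominator."""
    net = constants.schema.network
    mets, lnkm = constants.km_for_reaction(l)
    s_coef = net.S[mets, l]
    ratio = np.exp(np.asarray(x, dtype=float)[mets] - lnkm)
    subs = s_coef < 0
    prods = s_coef > 0
    numer = np.prod(ratio[subs] ** (-s_coef[subs]))
    denom = (
        np.prod((1.0 + ratio[subs]) ** (-s_coef[subs]))
        + np.prod((1.0 + ratio[prods]) ** s_coef[prods])
        - 1.0
    )
    return float(numer / denom)


def enzyme_demand(v_l: float, k_l: float) -> float:
    """Enzyme concentration e = v / k (mM) required to carry flux v."""
    if k_l == 0 or np.sign(v_l) != np.sign(k_l):
        raise ThermodynamicInconsistencyError(
            f"flux {v_l} and catalytic rate {k_l} disagree in sign"
        )
    return float(v_l / k_l)


def log_enzyme_demand_and_gradient(
    schema: DependencySchema,
    q_basic: np.ndarray,
    x: np.ndarray,
    v: np.ndarray,
    strict: bool = True,
):
    """Log enzyme demand for one state and its Jacobians.

    Parameters
    ----------
    q_basic : basic kinetic vector (length ``schema.n_basic``)
    x : log concentrations for the state, ln(mM)
    v : flux vector; reactions with v == 0 are skipped
    strict : raise :class:`DomainError` when a directed force is
        non-positive; with ``strict=False`` forces are floored at a tiny
        positive value (used by line searches touching the boundary).

    Returns
    -------
    active : indices of reactions with nonzero flux
    z : log enzyme demand per active reaction, ln(mM)
    Jq : Jacobian dz/dq_basic, shape (n_active, n_basic)
    Jx : Jacobian dz/dx, shape (n_active, n_met)
    """
    q_basic = np.asarray(q_basic, dtype=float)
    x = np.asarray(x, dtype=float)
    v = np.asarray(v, dtype=float)
    net = schema.network
    n_rxn = net.n_reactions
    n_met = net.n_metabolites
    q_all = schema.expand_all(q_basic)
    ln_keq = q_all[schema.rows_keq]
    ln_km = q_all[schema.rows_km]
    theta = driving_forces(ln_keq, net.S, x)

    active = np.flatnonzero(v != 0)
    n_a = active.size
    if n_a == 0:
        return active, np.zeros(0), np.zeros((0, schema.n_basic)), np.zeros((0, n_met))

    # flat (reaction, metabolite) geometry over all KM entries
    km_l = np.fromiter((l for l, _ in schema.km_pairs), dtype=int, count=schema.n_km)
    km_i = np.fromiter((i for _, i in schema.km_pairs), dtype=int, count=schema.n_km)
    s_coef = net.S[km_i, km_l].astype(float)
    m_abs = np.abs(s_coef)

    sgn = np.sign(v)
    th_dir = sgn[active] * theta[active]
    if np.any(th_dir <= 0):
        if strict:
            l_bad = active[int(np.argmin(th_dir))]
            raise DomainError(
                f"directed force for reaction {net.reaction_ids[l_bad]} is "
                f"{float(np.min(th_dir)):.3g} <= 0; point outside the feasible polytope"
            )
        th_dir = np.maximum(th_dir, 1e-12)

    sel = v[km_l] != 0
    dirc = sgn[km_l] * s_coef
    subs = sel & (dirc < 0)
    prods = sel & (dirc > 0)

    u = x[km_i] - ln_km
    sp = _softplus(u)
    A = np.zeros(n_rxn)
    B = np.zeros(n_rxn)
    np.add.at(A, km_l[subs], (m_abs * sp)[subs])
    np.add.at(B, km_l[prods], (m_abs * sp)[prods])
    m0 = np.maximum(A, B)
    lnD = m0 + np.log(np.exp(A - m0) + np.exp(B - m0) - np.exp(-m0))

    sum_sub_mu = np.zeros(n_rxn)
    np.add.at(sum_sub_mu, km_l[subs], (m_abs * u)[subs])
    ln_eta_sat = sum_sub_mu - lnD

    small = th_dir <= 1e-8
    ln_eta_rev = np.empty(n_a)
    ln_eta_rev[~small] = np.log1p(-np.exp(-th_dir[~small]))
    ln_eta_rev[small] = np.log(-np.expm1(-th_dir[small]))

    ln_kcat_dir = np.where(
        sgn > 0, q_all[schema.rows_kcat_fwd], q_all[schema.rows_kcat_bwd]
    )
    z = (
        np.log(np.abs(v[active]))
        - ln_kcat_dir[active]
        - ln_eta_rev
        - ln_eta_sat[active]
    )

    # partials
    # -1/(e^th - 1), written overflow-safe for large th
    dz_dth = np.exp(-th_dir) / np.expm1(-th_dir)
    sig = _sigmoid(u)
    wA = np.exp(A - lnD)
    wB = np.exp(B - lnD)
    dz_du = np.zeros(schema.n_km)
    dz_du[subs] = (-m_abs + wA[km_l] * m_abs * sig)[subs]
    dz_du[prods] = (wB[km_l] * m_abs * sig)[prods]

    keq_rows = schema.M[schema.rows_keq]
    kcat_dir_rows = np.where(
        (sgn > 0)[:, None], schema.M[schema.rows_kcat_fwd], schema.M[schema.rows_kcat_bwd]
    )
    Jq = -kcat_dir_rows[active] + (dz_dth * sgn[active])[:, None] * keq_rows[active]
    # KM basic entries sit right after the g block in q_basic
    pos_of = np.full(n_rxn, -1)
    pos_of[active] = np.arange(n_a)
    k_idx = np.flatnonzero(sel)
    Jq[pos_of[km_l[k_idx]], n_met + k_idx] -= dz_du[k_idx]

    Jx = np.zeros((n_a, n_met))
    np.add.at(Jx, (pos_of[km_l[k_idx]], km_i[k_idx]), dz_du[k_idx])
    Jx -= (dz_dth * sgn[active])[:, None] * net.S[:, active].T

    return active, z, Jq, Jx


def log_enzyme_demand_hessians(
    schema: DependencySchema,
    q_basic: np.ndarray,
    x: np.ndarray,
    v: np.ndarray,
) -> list[np.ndarray]:
    """Exact Hessians of the log enzyme demand, one per active reaction.

    Each Hessian is over the local coordinates ``(q_basic, x)`` of one state
    (size ``n_basic + n_met``). The demand splits into a linear part, the
    force term -ln(1 - exp(-theta_dir)) (one-dimensional curvature along the
    linear force direction), and the saturation term whose curvature lives
    in the reactant coordinates ``u = x - ln KM``.
    """
    q_basic = np.asarray(q_basic, dtype=float)
    x = np.asarray(x, dtype=float)
    v = np.asarray(v, dtype=float)
    net = schema.network
    n_met = net.n_metabolites
    nb = schema.n_basic
    nv = nb + n_met
    q_all = schema.expand_all(q_basic)
    ln_keq = q_all[schema.rows_keq]
    ln_km = q_all[schema.rows_km]
    theta = driving_forces(ln_keq, net.S, x)
    keq_rows = schema.M[schema.rows_keq]

    km_l = np.fromiter((l for l, _ in schema.km_pairs), dtype=int, count=schema.n_km)
    km_i = np.fromiter((i for _, i in schema.km_pairs), dtype=int, count=schema.n_km)

    hessians: list[np.ndarray] = []
    for l in np.flatnonzero(v != 0):
        sgn = np.sign(v[l])
        th = max(sgn * theta[l], 1e-12)
        H = np.zeros((nv, nv))

        # force curvature: d^2/dth^2 of -ln(1 - e^-th) = e^-th / (1-e^-th)^2
        g_th = np.zeros(nv)
        g_th[:nb] = sgn * keq_rows[l]
        g_th[nb:] = -sgn * net.S[:, l]
        h_th = np.exp(-th) / np.expm1(-th) ** 2
        H += h_th * np.outer(g_th, g_th)

        # saturation curvature in the u coordinates of this reaction
        ks = np.flatnonzero(km_l == l)
        mets = km_i[ks]
        s_coef = net.S[mets, l].astype(float)
        m_abs = np.abs(s_coef)
        u = x[mets] - ln_km[ks]
        sig = _sigmoid(u)
        subs = sgn * s_coef < 0
        A = float(np.sum((m_abs * _softplus(u))[subs]))
        B = float(np.sum((m_abs * _softplus(u))[~subs]))
        m0 = max(A, B)
        lnD = m0 + np.log(np.exp(A - m0) + np.exp(B - m0) - np.exp(-m0))
        wA, wB = np.exp(A - lnD), np.exp(B - lnD)
        a = np.where(subs, m_abs * sig, 0.0)
        bb = np.where(~subs, m_abs * sig, 0.0)
        ap = np.where(subs, m_abs * sig * (1 - sig), 0.0)
        bp = np.where(~subs, m_abs * sig * (1 - sig), 0.0)
        d = wA * a + wB * bb
        Hu = (
            wA * (np.outer(a, a) + np.diag(ap))
            + wB * (np.outer(bb, bb) + np.diag(bp))
            - np.outer(d, d)
        )
        # gradients of u_k in local coordinates: +1 on x_met, -1 on KM basic
        G = np.zeros((len(ks), nv))
        for j, (k, i) in enumerate(zip(ks, mets)):
            G[j, n_met + k] = -1.0  # KM block starts after g block in q_basic
            G[j, nb + i] = 1.0
        H += G.T @ Hu @ G
        hessians.append(H)
    return hessians
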