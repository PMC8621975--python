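import numpy as np
import pandas as pd
import pytest

from modelbalance import (
    SolverOptions,
    assemble_posterior_score,
    balance,
    initialize,
    make_problem,
    maximum_likelihood_mode,
)
from modelbalance import tables
from modelbalance.balancer import INIT_MARGIN, _reduced_system
from modelbalance.kinetics import DomainError
from modelbalance.scoring import posterior_score_hessian
from modelbalance.synthetic_data import (
    Scenario,
    chain_network,
    make_scenario_dataset,
)
from modelbalance.thermo import InfeasibleFluxError


def single_opts():
    return SolverOptions(multistart=1)


@pytest.fixture(scope="module")
def s1_dataset():
    net = chain_network(3)
    sc = Scenario(name="S1", n_states=2, seed=7)
    return net, sc, make_scenario_dataset(net, sc)


@pytest.fixture(scope="module")
def s1_result(s1_dataset):
    net, sc, ds = s1_dataset
    prob = make_problem(net, ds.fluxes, data=ds.data, alpha=0.5, options=single_opts())
    return prob, balance(prob)


class TestScoreAssembly:
    def test_gradient_finite_differences(self, s1_dataset):
        net, _, ds = s1_dataset
        prob = make_problem(net, ds.fluxes, data=ds.data, alpha=0.5)
        y = initialize(prob)
        _, grad = assemble_posterior_score(prob, y)
        h = 1e-6
        rng = np.random.default_rng(0)
        for j in rng.choice(len(y), size=10, replace=False):
            yp, ym = y.copy(), y.copy()
            yp[j] += h
            ym[j] -= h
            fp, _ = assemble_posterior_score(prob, yp, strict=False)
            fm, _ = assemble_posterior_score(prob, ym, strict=False)
            fd = (fp.total - fm.total) / (2 * h)
            assert np.isclose(fd, grad[j], rtol=1e-5, atol=1e-7)

    def test_hessian_finite_differences(self, s1_dataset):
        net, _, ds = s1_dataset
        prob = make_problem(net, ds.fluxes, data=ds.data, alpha=0.5)
        y = initialize(prob)
        H = posterior_score_hessian(prob, y)
        assert np.allclose(H, H.T)
        h = 1e-6
        rng = np.random.default_rng(1)
        for j in rng.choice(len(y), size=6, replace=False):
            yp, ym = y.copy(), y.copy()
            yp[j] += h
            ym[j] -= h
            _, gp = assemble_posterior_score(prob, yp, strict=False)
            _, gm = assemble_posterior_score(prob, ym, strict=False)
            fd = (gp - gm) / (2 * h)
            assert np.allclose(fd, H[:, j], rtol=1e-4, atol=1e-5)

    def test_breakdown_total_is_sum(self, s1_result):
        prob, res = s1_result
        bd = res.breakdown
        assert np.isclose(
            bd.total, bd.basic + np.sum(bd.x_terms) + np.sum(bd.enzyme_terms)
        )

    def test_monotone_in_alpha(self, s1_dataset):
        net, _, ds = s1_dataset
        vals = []
        for alpha in (0.0, 0.25, 0.5, 0.75, 1.0):
            prob = make_problem(net, ds.fluxes, data=ds.data, alpha=alpha)
            y = initialize(prob)
            bd, _ = assemble_posterior_score(prob, y)
            vals.append(bd.total)
        assert np.all(np.diff(vals) >= -1e-12)

    def test_outside_polytope_raises(self, s1_dataset):
        net, _, ds = s1_dataset
        prob = make_problem(net, ds.fluxes, data=ds.data)
        y = initialize(prob)
        y[-1] = np.log(prob.bounds.conc_max) + 5.0
        with pytest.raises(DomainError):
            assemble_posterior_score(prob, y)


class TestInitialize:
    def test_interior_mean_returned_exactly(self, chain3):
        # with all-zero fluxes the polytope is a plain box and the prior
        # mean is strictly interior, so the start is the mean itself
        prob = make_problem(chain3, np.zeros((3, 1)), data=None)
        y0 = initialize(prob)
        pre = prob.preposterior
        assert np.allclose(y0[: prob.polytope.n_basic], pre.q.mean)
        assert np.allclose(y0[prob.polytope.x_slice(0)], pre.x[0].mean)

    def test_projection_is_minimal_displacement(self, chain3):
        # force an infeasible preposterior mean by concentration data that
        # contradicts the flux direction, then check the QP oracle: no
        # feasible point is closer to the mean than the returned start
        ds = make_scenario_dataset(chain3, Scenario(name="S2", n_states=1, seed=21))
        rows = [
            tables.data_row("conc", 1e-4, 1.01, compound="M2", state=ds.fluxes.columns[0]),
            tables.data_row("conc", 50.0, 1.01, compound="M3", state=ds.fluxes.columns[0]),
        ]
        if ds.truth.states[0].v[1] < 0:  # make the data oppose the flux sign
            rows = [
                tables.data_row("conc", 50.0, 1.01, compound="M2", state=ds.fluxes.columns[0]),
                tables.data_row("conc", 1e-4, 1.01, compound="M3", state=ds.fluxes.columns[0]),
            ]
        data = pd.DataFrame(rows, columns=tables.DATA_COLUMNS)
        prob = make_problem(chain3, ds.fluxes, data=data)
        y0 = initialize(prob)
        assert prob.polytope.contains(y0)
        pre = prob.preposterior
        mu = y0.copy()
        mu[: prob.polytope.n_basic] = pre.q.mean
        mu[prob.polytope.x_slice(0)] = pre.x[0].mean
        d0 = np.linalg.norm(y0 - mu)
        rng = np.random.default_rng(3)
        center, _ = prob.polytope.chebyshev_center()
        for _ in range(200):
            y = prob.polytope.random_interior_point(rng, center=center)
            A, b = _reduced_system(prob)
            if np.all(A @ y <= b - min(INIT_MARGIN, 1e-6)):
                assert np.linalg.norm(y - mu) >= d0 - 1e-6

    def test_empty_polytope_raises(self, chain3):
        # pinning a coordinate outside its box empties the feasible set
        prob = make_problem(chain3, np.ones((3, 1)))
        prob.fixed[prob.x_index(0, "M2")] = np.log(prob.bounds.conc_max) + 1.0
        with pytest.raises(InfeasibleFluxError):
            initialize(prob)


class TestBalance:
    def test_no_data_plausible_state(self, chain3):
        prob = make_problem(chain3, np.ones((3, 1)), data=None, alpha=0.5,
                            options=single_opts())
        res = balance(prob)
        assert res.diagnostics["prior_insensitive"]
        assert res.diagnostics["in_polytope"]
        # forces follow the flux signs
        assert np.all(res.theta.to_numpy()[:, 0] > 0)
        # y* stays near the prior means (no data pulls it away)
        assert np.all(np.abs(res.constants.ln_kv - prob.priors.log_mean("kv")) < 3)

    def test_score_at_optimum_not_above_start_and_truth(self, s1_dataset, s1_result):
        net, _, ds = s1_dataset
        prob, res = s1_result
        y0 = initialize(prob)
        bd0, _ = assemble_posterior_score(prob, y0, strict=False)
        assert res.breakdown.total <= bd0.total + 1e-9
        y_true = prob.polytope.join(
            ds.truth.q_basic, np.column_stack([st.x for st in ds.truth.states])
        )
        if prob.polytope.contains(y_true):
            bd_true, _ = assemble_posterior_score(prob, y_true)
            assert res.breakdown.total <= bd_true.total + 1e-9

    def test_constraints_satisfied_at_optimum(self, s1_result):
        prob, res = s1_result
        assert prob.polytope.contains(res.y_star, tol=1e-8)

    def test_z_consistent_with_demand(self, s1_result):
        prob, res = s1_result
        from modelbalance.kinetics import log_enzyme_demand_and_gradient

        q, x = prob.polytope.split(res.y_star)
        for s, sid in enumerate(prob.state_ids):
            active, z, _, _ = log_enzyme_demand_and_gradient(
                prob.schema, q, x[:, s], prob.fluxes[:, s]
            )
            assert np.allclose(res.z[sid].to_numpy(), z)

    def test_haldane_wegscheider_at_optimum(self, s1_result):
        from modelbalance import check_wegscheider

        prob, res = s1_result
        assert res.constants.haldane_residual() < 1e-10
        assert check_wegscheider(res.constants.ln_keq, prob.network) < 1e-10

    def test_noise_free_recovery(self, s1_dataset, s1_result):
        from modelbalance import build_report

        net, sc, ds = s1_dataset
        _, res = s1_result
        rep = build_report(ds.truth, res, sc).metrics.set_index("quantity")
        assert (rep["r_log"] >= 0.95).all()

    def test_multistart_agreement_alpha0(self, s1_dataset):
        net, _, ds = s1_dataset
        prob = make_problem(net, ds.fluxes, data=ds.data, alpha=0.0,
                            options=SolverOptions(multistart=3))
        res = balance(prob)
        assert res.multistart_agreement

    def test_infeasible_fluxes_rejected(self):
        from modelbalance import MetabolicNetwork

        S = np.array([[-1, 1], [1, -1]])
        net = MetabolicNetwork(["A", "B"], ["R1", "R2"], S, np.ones(2, bool))
        with pytest.raises(InfeasibleFluxError):
            make_problem(net, np.ones((2, 1)))


class TestZeroFlux:
    def test_enzyme_absent_and_estimates_unchanged(self, chain3):
        sc = Scenario(name="S1", n_states=2, seed=3)
        ds = make_scenario_dataset(chain3, sc)
        flux = ds.fluxes.copy()
        flux.iloc[2, 1] = 0.0
        prob_a = make_problem(chain3, flux, data=ds.data, alpha=0.5, options=single_opts())
        res_a = balance(prob_a)
        sid = prob_a.state_ids[1]
        assert "R3" not in res_a.z[sid].index
        # removing the (ignored) enzyme datum manually changes nothing
        d = ds.data
        keep = ~(
            (d["!QuantityType"] == "enzyme concentration")
            & (d["!Reaction"] == "R3")
            & (d["!State"] == sid)
        )
        prob_b = make_problem(chain3, flux, data=d[keep], alpha=0.5, options=single_opts())
        res_b = balance(prob_b)
        assert np.allclose(res_a.y_star, res_b.y_star, atol=1e-12)


class TestMaximumLikelihood:
    def test_ml_close_to_posterior_with_rich_exact_data(self, s1_dataset):
        net, _, ds = s1_dataset
        prob = make_problem(net, ds.fluxes, data=ds.data, alpha=0.5, options=single_opts())
        res = balance(prob)
        res_ml = maximum_likelihood_mode(prob)
        # complete precise data dominate both runs
        assert np.max(np.abs(res.y_star - res_ml.y_star)) < 0.2

    def test_flat_priors_move_data_free_quantities_most(self, chain3):
        # S1K exposes Keq data only; KM and kV estimates ride on the priors
        sc = Scenario(name="S1K", n_states=2, seed=9)
        ds = make_scenario_dataset(chain3, sc)
        # drop enzyme rows so kV is truly data-free
        d = ds.data[ds.data["!QuantityType"] != "enzyme concentration"]
        prob = make_problem(chain3, ds.fluxes, data=d, alpha=0.5, options=single_opts())
        res = balance(prob)
        res_ml = maximum_likelihood_mode(prob)
        schema = prob.schema
        shift = np.abs(res.y_star - res_ml.y_star)
        shift_keq = np.max(np.abs(res.constants.ln_keq - res_ml.constants.ln_keq))
        shift_km = np.max(shift[schema.sl_km])
        assert shift_km > shift_keq

    def test_no_data_flagged_prior_insensitive(self, chain3):
        prob = make_problem(chain3, np.ones((3, 1)), data=None, options=single_opts())
        res = maximum_likelihood_mode(prob)
        assert res.diagnostics["prior_insensitive"]


class TestMonotoneDataEffect:
    def test_exact_datum_reduces_error(self):
        """Adding an exact Keq datum should not worsen that Keq's estimate
        (statistically, over repeats on noise-free synthetic problems)."""
        net = chain_network(2)
        violations, total = 0, 0
        for seed in range(12):
            sc = Scenario(name="S2", n_states=2, seed=100 + seed)
            try:
                ds = make_scenario_dataset(net, sc)
            except Exception:
                continue
            true_keq = ds.truth.constants.ln_keq[0]
            prob0 = make_problem(net, ds.fluxes, data=ds.data, alpha=0.5,
                                 options=single_opts())
            res0 = balance(prob0)
            row = tables.data_row("keq", float(np.exp(true_keq)), 1.01, reaction="R1")
            d1 = pd.concat([ds.data, pd.DataFrame([row])], ignore_index=True)
            prob1 = make_problem(net, ds.fluxes, data=d1, alpha=0.5,
                                 options=single_opts())
            res1 = balance(prob1)
            err0 = abs(res0.constants.ln_keq[0] - true_keq)
            err1 = abs(res1.constants.ln_keq[0] - true_keq)
            total += 1
            if err1 > err0 + 1e-6:
                violations += 1
        assert total >= 8
        assert violations / total <= 0.1
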