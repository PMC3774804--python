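"""MaxEnt tilting: dual-primal agreement, closed forms, ranking, maps."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

import itkmaxent as im
from itkmaxent.ensemble import ObservableTable


def make_table(tau_p, R, A, model_id="MX"):
    df = pd.DataFrame(
        {
            "sample": np.arange(len(tau_p)),
            "tau_p": tau_p,
            "R": R,
            "A": A,
            "status": "OK",
        }
    )
    return ObservableTable(model_id=model_id, records=df)


def primal_dkl(F, targets):
    """Brute-force primal oracle: minimize sum p*log10(p/q) over the simplex
    subject to the moment constraints, via SLSQP on the raw probabilities."""
    n = F.shape[0]
    q = np.full(n, 1.0 / n)

    def obj(p):
        p = np.clip(p, 1e-300, None)
        return float(np.sum(p * np.log10(p / q)))

    cons = [{"type": "eq", "fun": lambda p: p.sum() - 1.0}]
    for j in range(F.shape[1]):
        cons.append({"type": "eq", "fun": lambda p, j=j: p @ F[:, j] - targets[j]})
    res = minimize(
        obj, q, method="SLSQP", bounds=[(0.0, 1.0)] * n, constraints=cons,
        options={"maxiter": 2000, "ftol": 1e-14},
    )
    assert res.success
    return obj(res.x)


def test_targets_at_means_give_uniform_weights():
    rng = np.random.default_rng(0)
    tab = make_table(rng.uniform(1, 3, 40), rng.uniform(1, 5, 40), rng.uniform(10, 60, 40))
    v = tab.valid
    cons = im.Constraints(
        tau_p_avg=v["tau_p"].mean(), R_avg=v["R"].mean(), A_avg=v["A"].mean()
    )
    sol = im.solve_maxent(tab, cons)
    assert sol.converged and sol.feasible
    assert np.allclose(sol.lambdas, 0.0, atol=1e-8)
    assert np.allclose(sol.weights, 1.0 / 40, atol=1e-10)
    assert sol.D_KL == pytest.approx(0.0, abs=1e-12)


def test_kl_to_uniform_closed_forms():
    assert im.kl_to_uniform(np.full(17, 1 / 17)) == pytest.approx(0.0, abs=1e-12)
    w = np.zeros(10)
    w[3] = 1.0
    assert im.kl_to_uniform(w) == pytest.approx(1.0)
    assert im.kl_to_uniform([0.5, 0.5, 0.0, 0.0]) == pytest.approx(np.log10(2))
    with pytest.raises(ValueError):
        im.kl_to_uniform([0.5, 0.4])
    with pytest.raises(ValueError):
        im.kl_to_uniform([1.5, -0.5])


def test_single_constraint_matches_primal_oracle():
    rng = np.random.default_rng(1)
    x = rng.uniform(1.0, 4.0, 5)
    target = x.mean() + 0.3
    sol = im.solve_tilt(x[:, None], [target])
    d_primal = primal_dkl(x[:, None], np.array([target]))
    assert sol.feasible and sol.converged
    assert sol.D_KL == pytest.approx(d_primal, abs=1e-6)
    assert (sol.weights @ x) == pytest.approx(target, rel=1e-6)


def test_correlated_two_constraint_problem_matches_primal_oracle():
    rng = np.random.default_rng(2)
    x = rng.uniform(1, 3, 20)
    y = 0.8 * x + rng.uniform(0, 0.5, 20)  # strongly correlated constraints
    F = np.column_stack([x, y])
    targets = np.array([x.mean() + 0.15, y.mean() + 0.10])
    cons = im.Constraints(tau_p_avg=targets[0], R_avg=targets[1])
    df = pd.DataFrame({"tau_p": x, "R": y})
    sol = im.solve_maxent(df, cons)
    assert sol.converged
    assert sol.weights @ x == pytest.approx(targets[0], rel=1e-6)
    assert sol.weights @ y == pytest.approx(targets[1], rel=1e-6)
    assert sol.D_KL == pytest.approx(primal_dkl(F, targets), abs=1e-6)


def test_adding_a_constraint_never_decreases_dkl():
    rng = np.random.default_rng(3)
    tab = make_table(rng.uniform(1, 3, 60), rng.uniform(1, 8, 60), rng.uniform(5, 80, 60))
    v = tab.valid
    two = im.Constraints(tau_p_avg=v["tau_p"].mean() * 1.1, R_avg=v["R"].mean() * 0.9)
    three = im.Constraints(
        tau_p_avg=two.tau_p_avg, R_avg=two.R_avg, A_avg=v["A"].mean() * 1.2
    )
    s2 = im.solve_maxent(tab, two)
    s3 = im.solve_maxent(tab, three)
    assert s2.converged and s3.converged
    assert s3.D_KL >= s2.D_KL - 1e-9


def test_infeasible_targets_are_flagged_not_silently_large():
    rng = np.random.default_rng(4)
    tab = make_table(rng.uniform(1, 2, 30), rng.uniform(1, 3, 30), rng.uniform(5, 20, 30))
    sol = im.solve_maxent(tab, im.Constraints(tau_p_avg=9.0, R_avg=2.0, A_avg=10.0))
    assert not sol.feasible
    assert np.isinf(sol.D_KL)
    assert "reason" in sol.diagnostics


def test_rank_models_ordering():
    rng = np.random.default_rng(5)
    # model A: R tightly clustered at the target; model B: widely dispersed
    target = 2.0
    a = make_table(np.full(50, 2.0), rng.normal(target, 0.05, 50),
                   np.full(50, 30.0), "MA")
    b = make_table(np.full(50, 2.0), rng.uniform(1.0, 40.0, 50),
                   np.full(50, 30.0), "MB")
    cons = im.Constraints(tau_p_avg=2.0, R_avg=target)
    sols = {"MB": im.solve_maxent(b, cons), "MA": im.solve_maxent(a, cons)}
    assert im.rank_models(sols) == ["MA", "MB"]

    single = {"MB": sols["MB"]}
    assert im.rank_models(single) == ["MB"]


def test_rank_puts_infeasible_last():
    rng = np.random.default_rng(6)
    good = make_table(rng.uniform(1, 3, 30), rng.uniform(1, 3, 30),
                      rng.uniform(10, 50, 30), "MG")
    bad = make_table(rng.uniform(5, 6, 30), rng.uniform(10, 30, 30),
                     rng.uniform(100, 200, 30), "MB")
    cons = im.Constraints(tau_p_avg=2.0, R_avg=2.0, A_avg=30.0)
    sols = {"MB": im.solve_maxent(bad, cons), "MG": im.solve_maxent(good, cons)}
    assert im.rank_models(sols) == ["MG", "MB"]


def test_robustness_map_single_model_and_single_cell():
    rng = np.random.default_rng(7)
    tab = make_table(rng.uniform(1, 3, 80), rng.uniform(1, 6, 80),
                     rng.uniform(10, 70, 80), "MA")
    rmap = im.robustness_map({"MA": tab}, R_grid=[2.0, 3.0], A_grid=[30.0, 50.0],
                             tau_p_avg=2.0)
    assert rmap.D_KL.shape == (2, 2, 1)
    feasible = rmap.feasibility_mask
    assert np.all(rmap.best_model[feasible] == "MA")

    # a 1x1 grid is exactly one solve + rank
    one = im.robustness_map({"MA": tab}, R_grid=[2.0], A_grid=[30.0], tau_p_avg=2.0)
    direct = im.solve_maxent(tab, im.Constraints(2.0, 2.0, 30.0))
    assert one.D_KL[0, 0, 0] == pytest.approx(direct.D_KL, abs=1e-12)


def test_map_cell_feasible_for_one_model_only():
    rng = np.random.default_rng(8)
    wide = make_table(rng.uniform(1, 3, 50), rng.uniform(1, 10, 50),
                      rng.uniform(10, 90, 50), "MW")
    narrow = make_table(rng.uniform(1.9, 2.1, 50), rng.uniform(1.9, 2.1, 50),
                        rng.uniform(28, 32, 50), "MN")
    rmap = im.robustness_map({"MW": wide, "MN": narrow},
                             R_grid=[8.0], A_grid=[70.0], tau_p_avg=2.0)
    assert rmap.best_model[0, 0] == "MW"


def test_no_amplitude_variant_drops_third_multiplier():
    rng = np.random.default_rng(9)
    tab = make_table(rng.uniform(1, 3, 50), rng.uniform(1, 6, 50),
                     rng.uniform(10, 70, 50))
    v = tab.valid
    sol = im.solve_maxent(
        tab, im.Constraints(tau_p_avg=v["tau_p"].mean() * 1.05,
                            R_avg=v["R"].mean() * 0.95)
    )
    assert sol.converged
    assert len(sol.lambdas) == 2
    assert sol.constraint_names == ("tau_p", "R")
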