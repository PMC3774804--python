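"""ODE and Gillespie simulation: conservation, equilibria, exactness."""

import numpy as np
import pytest
from scipy.linalg import expm

import itkmaxent as im
from itkmaxent.simulate import _Kinetics
from itkmaxent.models import resolve_rates

from conftest import random_positive_params


def test_no_itk_means_no_signal(specs):
    init = im.InitialState(Itk0=0, PIP3_0=100, PIP2_0=1000)
    for m in ("M1", "M4", "M5"):
        traj = im.integrate_ode(
            specs[m], im.base_parameters(m), init,
            im.SimulationConfig(t_end=50.0, horizon_policy="fixed"),
        )
        assert np.allclose(traj.readout, 0.0, atol=1e-9)
        assert np.allclose(traj.species_series("PIP3"), 100.0, atol=1e-6)
        assert np.allclose(traj.species_series("PIP2"), 1000.0, atol=1e-6)


def test_m6_binding_equilibrium_matches_quadratic(specs, tight_sim):
    """With catalysis off and a single ligand, the bound fraction at long
    times is the root of K_D*x = (Itk0-x)(PIP3_0-x)."""
    k_on, k_off = 0.01, 0.5
    itk0, pip3 = 50.0, 80.0
    params = im.ParameterSet(rates={"k_on": k_on, "k_off": k_off, "k_cat": 1e-14})
    init = im.InitialState(Itk0=50, PIP3_0=80, PIP2_0=0)
    traj = im.integrate_ode(
        specs["M6"], params, init,
        im.SimulationConfig(t_end=400.0, horizon_policy="fixed",
                            rel_tol=1e-12, abs_tol=1e-13),
    )
    kd = k_off / k_on
    b = itk0 + pip3 + kd
    x = (b - np.sqrt(b * b - 4 * itk0 * pip3)) / 2.0
    assert traj.readout[-1] == pytest.approx(x, rel=1e-6)


def test_m3_calibrated_transient_shape(m3_calibrated_trajectory):
    """Rise from ~0, one interior maximum, decay to a small value."""
    r = m3_calibrated_trajectory.readout
    i_max = int(np.argmax(r))
    assert r[0] == 0.0
    assert 0 < i_max < len(r) - 1
    assert r[-1] < 0.25 * r[i_max]
    # single-peaked at the resolution of the grid: above half-max the
    # series is one contiguous block
    above = r >= 0.5 * r[i_max]
    runs = np.diff(above.astype(int))
    assert (runs == 1).sum() == 1 and (runs == -1).sum() == 1


def test_conservation_laws_over_random_draws(specs):
    rng = np.random.default_rng(7)
    init = im.InitialState(Itk0=60, PIP3_0=200, PIP2_0=5000)
    for m in im.MODEL_IDS:
        params = random_positive_params(m, rng)
        traj = im.integrate_ode(
            specs[m], params, init,
            im.SimulationConfig(t_end=100.0, horizon_policy="fixed",
                                rel_tol=1e-10, abs_tol=1e-12),
        )
        C = specs[m].conservation_matrix()
        q = traj.counts @ C.T
        drift = np.max(np.abs(q - q[0]) / np.abs(q[0]), axis=0)
        assert np.all(drift <= 1e-8), (m, drift)


def test_solver_failure_is_flagged(specs):
    # an absurdly stiff rate should either integrate or raise the typed error
    params = im.ParameterSet(
        rates={"k_on": 1e12, "k_off": 1e-12, "k_cat": 1e12}
    )
    init = im.InitialState(Itk0=100, PIP3_0=100, PIP2_0=17000)
    try:
        im.integrate_ode(specs["M6"], params, init, im.SimulationConfig(t_end=10.0))
    except im.simulate.SimulationError:
        pass


def test_ssa_zero_count_propensity(specs):
    spec = specs["M6"]
    kin = _Kinetics(spec, resolve_rates(spec, im.base_parameters("M6")))
    y = np.zeros(len(spec.species))
    assert np.all(kin.propensities(y) == 0.0)


def test_ssa_seed_reproducibility(specs):
    params = im.base_parameters("M3")
    init = im.InitialState(Itk0=20, PIP3_0=50, PIP2_0=1000)
    t1 = im.run_ssa(specs["M3"], params, init, seed=42, t_end=5.0)
    t2 = im.run_ssa(specs["M3"], params, init, seed=42, t_end=5.0)
    assert np.array_equal(t1.counts, t2.counts)
    t3 = im.run_ssa(specs["M3"], params, init, seed=43, t_end=5.0)
    assert not np.array_equal(t1.counts, t3.counts)


def test_ssa_rejects_non_integer_init(specs):
    init = im.InitialState.__new__(im.InitialState)
    object.__setattr__(init, "Itk0", 2.5)
    object.__setattr__(init, "PIP3_0", 5)
    object.__setattr__(init, "PIP2_0", 5)
    object.__setattr__(init, "IP4_0", 0)
    with pytest.raises(ValueError):
        im.run_ssa(specs["M6"], im.base_parameters("M6"), init, seed=0, t_end=1.0)


def test_ssa_conserves_exactly(specs):
    params = im.base_parameters("M3")
    init = im.InitialState(Itk0=20, PIP3_0=50, PIP2_0=500)
    traj = im.run_ssa(specs["M3"], params, init, seed=3, t_end=20.0)
    C = specs["M3"].conservation_matrix()
    q = traj.counts @ C.T
    assert np.array_equal(q, np.tile(q[0], (len(q), 1)))


def test_ensemble_mean_single_realization_is_identity(specs):
    params = im.base_parameters("M6")
    init = im.InitialState(Itk0=10, PIP3_0=20, PIP2_0=100)
    mean, sem = im.ssa_ensemble_mean(specs["M6"], params, init, 1, seed=9, t_end=5.0)
    assert np.all(sem == 0.0)


def test_sem_scales_as_inverse_sqrt_n(specs):
    """Quadrupling the number of realizations halves the standard error."""
    params = im.ParameterSet(rates={"k_on": 0.05, "k_off": 0.3, "k_cat": 1e-12})
    init = im.InitialState(Itk0=5, PIP3_0=8, PIP2_0=0)
    grid = np.array([0.0, 2.0, 10.0])
    _, sem1 = im.ssa_ensemble_mean(specs["M6"], params, init, 200, seed=1,
                                   t_end=10.0, output_grid=grid)
    _, sem2 = im.ssa_ensemble_mean(specs["M6"], params, init, 800, seed=2,
                                   t_end=10.0, output_grid=grid)
    assert sem2[-1] == pytest.approx(0.5 * sem1[-1], rel=0.35)


def test_ssa_mean_matches_exact_master_equation(specs):
    """Direct-method sampler against the matrix-exponential solution of the
    chemical master equation for reversible binding at small counts."""
    k_on, k_off = 0.05, 0.3
    params = im.ParameterSet(rates={"k_on": k_on, "k_off": k_off, "k_cat": 1e-12})
    init = im.InitialState(Itk0=5, PIP3_0=8, PIP2_0=0)
    n_max = 5
    Q = np.zeros((n_max + 1, n_max + 1))
    for n in range(n_max + 1):
        if n < n_max:
            r = k_on * (5 - n) * (8 - n)
            Q[n + 1, n] += r
            Q[n, n] -= r
        if n > 0:
            Q[n - 1, n] += k_off * n
            Q[n, n] -= k_off * n
    p0 = np.zeros(n_max + 1)
    p0[0] = 1.0
    grid = np.array([0.0, 1.0, 5.0, 20.0])
    mean, sem = im.ssa_ensemble_mean(specs["M6"], params, init, 4000, seed=5,
                                     t_end=20.0, output_grid=grid)
    for i, t in enumerate(grid[1:], start=1):
        exact = np.arange(n_max + 1) @ (expm(Q * t) @ p0)
        assert abs(mean.readout[i] - exact) <= 4 * sem[i] + 1e-9


def test_ssa_converges_to_ode_at_scaled_counts(specs):
    """Mean-field agreement improves as copy numbers scale up."""
    params = im.base_parameters("M3")
    grid = np.linspace(0.0, 10.0, 21)
    devs = []
    for scale in (1, 10):
        init = im.InitialState(Itk0=20 * scale, PIP3_0=50 * scale,
                               PIP2_0=17000 * scale)
        mean, _ = im.ssa_ensemble_mean(specs["M3"], params, init, 60, seed=13,
                                       t_end=10.0, output_grid=grid)
        ode = im.integrate_ode(
            specs["M3"], params, init,
            im.SimulationConfig(t_end=10.0, horizon_policy="fixed",
                                rel_tol=1e-10, abs_tol=1e-12),
        )
        og = np.interp(grid, ode.times, ode.readout)
        # relative deviation against the peak, per scale
        devs.append(np.max(np.abs(mean.readout - og)) / og.max())
    assert devs[1] < devs[0]


def test_horizon_extension_flags_censoring(specs):
    """A pure binding system never decays below half max: the horizon policy
    must extend to the cap and flag the trajectory."""
    params = im.ParameterSet(rates={"k_on": 0.01, "k_off": 0.1, "k_cat": 1e-14})
    init = im.InitialState(Itk0=50, PIP3_0=100, PIP2_0=0)
    traj = im.integrate_ode(
        specs["M6"], params, init,
        im.SimulationConfig(t_end=50.0, horizon_cap=400.0),
    )
    assert traj.censored
    assert traj.times[-1] == pytest.approx(400.0)


def test_trajectory_csv_round_trip(specs, tmp_path):
    params = im.base_parameters("M6")
    init = im.InitialState(Itk0=10, PIP3_0=20, PIP2_0=100)
    traj = im.integrate_ode(specs["M6"], params, init,
                            im.SimulationConfig(t_end=5.0, horizon_policy="fixed"))
    path = tmp_path / "traj.csv"
    traj.to_frame().to_csv(path, index=False)
    import pandas as pd

    back = im.Trajectory.from_frame(pd.read_csv(path), specs["M6"])
    assert np.allclose(back.counts, traj.counts)
    assert np.allclose(back.readout, traj.readout)
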