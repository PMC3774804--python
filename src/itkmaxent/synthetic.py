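"""Synthetic data with the statistical structure the analysis assumes.

Three generators make every pipeline stage testable without measured data:

* cell populations with extrinsic parameter variation (per-cell rates and
  abundances drawn as in the ensemble module) whose population-mean readout
  emulates what a blot on pooled cells reports;
* blot-like densitometry series -- a known unimodal pulse (log-normal in
  time) or a supplied population mean, sampled on a blot grid and corrupted
  by multiplicative lognormal measurement noise on both the phospho and
  total channels;
* an end-to-end recovery harness that generates an observable table from a
  chosen model, runs the MaxEnt tilt against targets taken from the
  generated data, and checks constraint recovery and model ranking.

What these generators do not emulate: gel chemistry, antibody saturation,
and intrinsic-noise correlations between the two blot channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .defaults import base_parameters
from .ensemble import EnsembleConfig, ObservableTable, draw_ensemble, evaluate_ensemble
from .experiment import DensitometrySeries, normalize_series, summarize_experiment
from .maxent import Constraints, MaxEntSolution, rank_models, solve_maxent
from .models import InitialState, ModelSpec, ParameterSet, build_model
from .shapes import (
    TrajectorySummary,
    lognormal_pulse,
    lognormal_pulse_width,
    lognormal_sigma_for_width,
    summarize,
)
from .simulate import SimulationConfig, integrate_ode, run_ssa

__all__ = [
    "PopulationConfig",
    "PulseSpec",
    "generate_cell_population",
    "generate_blot_series",
    "recovery_experiment",
]


@dataclass(frozen=True)
class PopulationConfig:
    n_cells: int = 50
    rate_span: tuple[float, float] = (0.1, 10.0)
    conc_window: float = 0.35
    intrinsic_noise: bool = False  # SSA per cell instead of the ODE solution
    measurement_noise_sigma: float = 0.15
    time_grid: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.measurement_noise_sigma < 0:
            raise ValueError("measurement_noise_sigma must be >= 0")


@dataclass(frozen=True)
class PulseSpec:
    """Phenomenological unimodal transient with exact shape statistics."""

    A: float
    tau_p: float
    sigma_shape: float

    def __post_init__(self):
        if not (self.A > 0 and self.tau_p > 0 and self.sigma_shape > 0):
            raise ValueError("A, tau_p and sigma_shape must be positive")

    @property
    def tau_w(self) -> float:
        return lognormal_pulse_width(self.tau_p, self.sigma_shape)

    @classmethod
    def from_width(cls, A: float, tau_p: float, tau_w: float) -> "PulseSpec":
        return cls(A=A, tau_p=tau_p, sigma_shape=lognormal_sigma_for_width(tau_p, tau_w))

    def evaluate(self, t) -> np.ndarray:
        return lognormal_pulse(t, self.A, self.tau_p, self.sigma_shape)


@dataclass
class CellPopulation:
    times: np.ndarray
    per_cell_readout: np.ndarray  # (n_cells, n_times)
    mean_readout: np.ndarray
    per_cell_summaries: list[TrajectorySummary]
    seed: int


def generate_cell_population(
    spec: ModelSpec,
    base_params: ParameterSet,
    base_init: InitialState,
    config: PopulationConfig,
) -> CellPopulation:
    """Simulate a population of cells with extrinsic parameter variation.

    Per-cell parameters are drawn exactly as in the ensemble module; each
    cell is simulated (deterministically, or with the Gillespie sampler when
    ``intrinsic_noise`` is set) and the population mean of the readout is
    formed on a common grid -- the quantity a pooled-cell blot reports.
    """
    ens_config = EnsembleConfig(
        base_params=base_params,
        base_init=base_init,
        n_samples=config.n_cells,
        seed=config.seed,
        rate_span=config.rate_span,
        conc_window=config.conc_window,
    )
    samples = draw_ensemble(ens_config, spec.model_id)
    if config.time_grid is not None:
        grid = np.asarray(config.time_grid, dtype=float)
    else:
        grid = np.linspace(0.0, 30.0, 301)
    per_cell = np.empty((config.n_cells, len(grid)))
    summaries = []
    rng = np.random.default_rng(config.seed + 1)
    for c, (params, init) in enumerate(samples):
        if config.intrinsic_noise:
            traj = run_ssa(
                spec, params, init,
                seed=int(rng.integers(2**31)),
                t_end=float(grid[-1]), output_grid=grid,
            )
            per_cell[c] = traj.readout
        else:
            traj = integrate_ode(
                spec, params, init,
                SimulationConfig(t_end=max(float(grid[-1]), 1.0), rel_tol=1e-7, abs_tol=1e-9),
            )
            per_cell[c] = np.interp(grid, traj.times, traj.readout)
        try:
            summaries.append(summarize(traj.times, traj.readout))
        except ValueError:
            summaries.append(None)
    return CellPopulation(
        times=grid,
        per_cell_readout=per_cell,
        mean_readout=per_cell.mean(axis=0),
        per_cell_summaries=summaries,
        seed=config.seed,
    )


def generate_blot_series(
    pulse,
    noise_sigma: float,
    time_grid,
    seed: int,
) -> tuple[DensitometrySeries, TrajectorySummary]:
    """Emulate a densitometry readout of a known underlying transient.

    ``pulse`` is either a :class:`PulseSpec` or a ``(times, values)`` pair
    (e.g. a population mean).  The underlying fold-change curve is the pulse
    offset to the baseline 1 of an unstimulated sample; both channels receive
    i.i.d. multiplicative lognormal noise so that the phospho/total
    normalization reproduces the noisy fold change.  Returns the series and
    the noiseless ground-truth summary on the same grid.
    """
    grid = np.asarray(time_grid, dtype=float)
    if grid[0] != 0.0:
        raise ValueError("time grid must start at the unstimulated t = 0 sample")
    if isinstance(pulse, PulseSpec):
        curve = 1.0 + pulse.evaluate(grid)
    else:
        t_src, v_src = pulse
        curve = 1.0 + np.interp(grid, np.asarray(t_src, float), np.asarray(v_src, float))
    rng = np.random.default_rng(seed)
    total = 100.0 * rng.lognormal(0.0, noise_sigma, size=len(grid))
    phospho = curve * total * rng.lognormal(0.0, noise_sigma, size=len(grid))
    # anchor the t=0 ratio so fold_change(0)=1 maps the noise into t>0 points
    series = DensitometrySeries(times=grid, phospho=phospho, total=total)
    truth = summarize(grid, curve)
    return normalize_series(series), truth


def recovery_experiment(
    generating_model: ModelSpec | str,
    base_init: InitialState,
    n_samples: int = 300,
    seed: int = 0,
    target_offset: float = 0.0,
    all_models: bool = False,
    sim_config: SimulationConfig | None = None,
) -> dict:
    """End-to-end validation: ensemble -> observables -> MaxEnt recovery.

    Generates an observable table under ``generating_model``, sets targets to
    the generated means shifted by ``target_offset`` (as a fraction of each
    observable's spread), solves the tilt, and reports constraint residuals
    and D_KL.  With ``all_models`` the same targets are applied to tables
    from all seven models and the resulting ranking is included.
    """
    spec = build_model(generating_model) if isinstance(generating_model, str) else generating_model
    cfg = EnsembleConfig(
        base_params=base_parameters(spec.model_id),
        base_init=base_init,
        n_samples=n_samples,
        seed=seed,
    )
    table = evaluate_ensemble(spec, draw_ensemble(cfg, spec.model_id), sim_config, cfg)
    valid = table.valid
    means = valid[["tau_p", "R", "A"]].mean()
    spread = valid[["tau_p", "R", "A"]].std()
    targets = means + target_offset * spread
    cons = Constraints(
        tau_p_avg=float(targets["tau_p"]),
        R_avg=float(targets["R"]),
        A_avg=float(targets["A"]),
    )
    sol = solve_maxent(table, cons)
    report = {
        "generating_model": spec.model_id,
        "constraints": cons,
        "solution": sol,
        "n_valid": table.n_valid,
    }
    if all_models:
        solutions: dict[str, MaxEntSolution] = {spec.model_id: sol}
        from .models import MODEL_IDS

        for m in MODEL_IDS:
            if m == spec.model_id:
                continue
            m_spec = build_model(m)
            m_cfg = EnsembleConfig(
                base_params=base_parameters(m),
                base_init=base_init,
                n_samples=n_samples,
                seed=seed,
            )
            m_table = evaluate_ensemble(m_spec, draw_ensemble(m_cfg, m), sim_config, m_cfg)
            solutions[m] = solve_maxent(m_table, cons)
        report["ranking"] = rank_models(solutions)
        report["solutions"] = solutions
    return report
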