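"""Deterministic and stochastic simulation of the Itk recruitment networks.

The deterministic path integrates the mass-action rate equations generated
from a :class:`~itkmaxent.models.ModelSpec` with LSODA (stiff-capable); the
stochastic path is an exact Gillespie direct-method sampler of the same
network.  Both report the PIP3-bound-Itk readout alongside the full species
counts.

Because the no-feedback models can decay extremely slowly, the default
horizon policy keeps doubling the end time until the readout has fallen below
half of its running maximum (or a hard cap is reached, in which case the
trajectory is flagged as censored for the width statistic).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import odeint

from .models import InitialState, ModelSpec, ParameterSet, active_count, resolve_rates

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "SimulationError",
    "integrate_ode",
    "run_ssa",
    "ssa_ensemble_mean",
]


class SimulationError(RuntimeError):
    """Raised when the ODE solver fails to converge; carries diagnostics."""


@dataclass(frozen=True)
class SimulationConfig:
    t_end: float = 200.0
    #: target spacing (min) of the uniform grid covering signal onset
    onset_dt: float = 0.02
    onset_window: float = 30.0
    #: points on the geometric grid from the onset window to t_end
    n_tail: int = 400
    rel_tol: float = 1e-8
    abs_tol: float = 1e-10
    horizon_policy: str = "extend_x2_until_decay"  # or "fixed"
    horizon_cap: float = 5000.0
    #: local near-peak refinement factor for resolving tau_p
    refine_points: int = 200

    def __post_init__(self):
        if not self.t_end > 0:
            raise ValueError("t_end must be positive")
        if not (self.rel_tol > 0 and self.abs_tol > 0):
            raise ValueError("tolerances must be positive")
        if self.horizon_cap < self.t_end:
            raise ValueError("horizon_cap must be >= t_end")
        if self.horizon_policy not in ("extend_x2_until_decay", "fixed"):
            raise ValueError(f"unknown horizon policy {self.horizon_policy!r}")


@dataclass
class Trajectory:
    times: np.ndarray
    counts: np.ndarray  # (n_times, n_species)
    species: tuple[str, ...]
    readout: np.ndarray  # PIP3-bound Itk series
    censored: bool = False
    meta: dict = field(default_factory=dict)

    def species_series(self, name: str) -> np.ndarray:
        return self.counts[:, self.species.index(name)]

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.counts, columns=list(self.species))
        df.insert(0, "time_min", self.times)
        df["readout"] = self.readout
        return df

    @classmethod
    def from_frame(cls, df, model_spec: ModelSpec) -> "Trajectory":
        counts = df[list(model_spec.species)].to_numpy(dtype=float)
        return cls(
            times=df["time_min"].to_numpy(dtype=float),
            counts=counts,
            species=tuple(model_spec.species),
            readout=df["readout"].to_numpy(dtype=float),
        )


# --- compiled mass-action kinetics ------------------------------------------


class _Kinetics:
    """Index arrays and stoichiometry for fast propensity/RHS evaluation."""

    def __init__(self, spec: ModelSpec, rates: dict[str, float]):
        idx = spec.species_index()
        n_r = len(spec.reactions)
        n_s = len(spec.species)
        self.k = np.empty(n_r)
        self.r1 = np.empty(n_r, dtype=np.intp)
        self.r2 = np.full(n_r, -1, dtype=np.intp)
        self.S = np.zeros((n_s, n_r))
        for j, rx in enumerate(spec.reactions):
            self.k[j] = rates[rx.rate_name] * rx.multiplicity
            self.r1[j] = idx[rx.reactants[0]]
            if rx.order == 2:
                self.r2[j] = idx[rx.reactants[1]]
            for s in rx.reactants:
                self.S[idx[s], j] -= 1.0
            for s in rx.products:
                self.S[idx[s], j] += 1.0
        self.second = self.r2 >= 0
        self.identical = self.second & (self.r1 == self.r2)
        self.ST = np.ascontiguousarray(self.S.T)

    def rates_ode(self, y: np.ndarray) -> np.ndarray:
        v = self.k * y[self.r1]
        v[self.second] *= y[self.r2[self.second]]
        return v

    def rhs(self, y: np.ndarray, t: float) -> np.ndarray:
        return self.rates_ode(y) @ self.ST

    def jac(self, y: np.ndarray, t: float) -> np.ndarray:
        n_s = self.S.shape[0]
        dv = np.zeros((len(self.k), n_s))
        rows = np.arange(len(self.k))
        contrib1 = self.k.copy()
        contrib1[self.second] *= y[self.r2[self.second]]
        dv[rows, self.r1] += contrib1
        sec = np.where(self.second)[0]
        dv[sec, self.r2[sec]] += self.k[sec] * y[self.r1[sec]]
        return self.S @ dv

    def propensities(self, y: np.ndarray) -> np.ndarray:
        """SSA propensities with the n*(n-1) convention for identical pairs."""
        v = self.k * y[self.r1]
        v[self.second] *= y[self.r2[self.second]]
        v[self.identical] = (
            self.k[self.identical]
            * y[self.r1[self.identical]]
            * (y[self.r1[self.identical]] - 1.0)
        )
        return np.maximum(v, 0.0)


def _make_grid(t0: float, t1: float, config: SimulationConfig) -> np.ndarray:
    """Grid dense near onset, geometric in the tail."""
    onset_end = min(t1, t0 + config.onset_window)
    n_onset = max(int(np.ceil((onset_end - t0) / config.onset_dt)), 2)
    # cap the uniform part to keep solves cheap on long horizons
    n_onset = min(n_onset, 2000)
    grid = np.linspace(t0, onset_end, n_onset + 1)
    if t1 > onset_end:
        tail = np.geomspace(onset_end, t1, config.n_tail + 1)[1:]
        grid = np.concatenate([grid, tail])
    return grid


def _integrate_segment(kin: _Kinetics, y0: np.ndarray, grid: np.ndarray, config):
    y, info = odeint(
        kin.rhs,
        y0,
        grid,
        Dfun=kin.jac,
        rtol=config.rel_tol,
        atol=config.abs_tol,
        full_output=True,
        mxstep=100000,
    )
    if info["message"] != "Integration successful.":
        raise SimulationError(f"ODE integration failed: {info['message']}")
    return y


def integrate_ode(
    spec: ModelSpec,
    params: ParameterSet,
    init: InitialState,
    config: SimulationConfig | None = None,
) -> Trajectory:
    """Integrate the mass-action ODEs for one model instance.

    Returns a trajectory on a grid dense enough near the peak that the peak
    time of the readout is resolved to well under 1%.
    """
    config = config or SimulationConfig()
    rates = resolve_rates(spec, params)
    kin = _Kinetics(spec, rates)
    y0 = init.vector(spec).astype(float)
    active_idx = [spec.species_index()[s] for s in spec.active_species]

    grid = _make_grid(0.0, config.t_end, config)
    y = _integrate_segment(kin, y0, grid, config)
    times, counts = grid, y

    censored = False
    if config.horizon_policy == "extend_x2_until_decay":
        t_end = config.t_end
        while True:
            readout = counts[:, active_idx].sum(axis=1)
            peak = readout.max()
            if peak <= 0 or readout[-1] <= 0.5 * peak:
                break
            if t_end >= config.horizon_cap:
                censored = True
                break
            new_end = min(2.0 * t_end, config.horizon_cap)
            ext = np.geomspace(t_end, new_end, config.n_tail // 2 + 1)
            y_ext = _integrate_segment(kin, counts[-1], ext, config)
            times = np.concatenate([times, ext[1:]])
            counts = np.vstack([counts, y_ext[1:]])
            t_end = new_end

    # near-peak refinement: re-integrate with extra points bracketing the
    # coarse peak so tau_p is resolved locally
    readout = counts[:, active_idx].sum(axis=1)
    i_peak = int(np.argmax(readout))
    if 0 < i_peak < len(times) - 1:
        lo, hi = times[i_peak - 1], times[i_peak + 1]
        if (hi - lo) > 0.002 * max(times[i_peak], 1e-6):
            fine = np.linspace(lo, hi, config.refine_points)
            seg_grid = np.concatenate([[times[0]], fine])
            y_fine = _integrate_segment(kin, counts[0], seg_grid, config)[1:]
            insert_at = np.searchsorted(times, fine)
            times = np.insert(times, insert_at, fine)
            counts = np.insert(counts, insert_at, y_fine, axis=0)
            # drop duplicate time points from the merge
            keep = np.concatenate([[True], np.diff(times) > 0])
            times, counts = times[keep], counts[keep]
            readout = counts[:, active_idx].sum(axis=1)

    counts = np.clip(counts, 0.0, None)
    readout = counts[:, active_idx].sum(axis=1)
    return Trajectory(
        times=times,
        counts=counts,
        species=tuple(spec.species),
        readout=readout,
        censored=censored,
        meta={"model_id": spec.model_id, "t_end": float(times[-1])},
    )


def run_ssa(
    spec: ModelSpec,
    params: ParameterSet,
    init: InitialState,
    seed: int,
    t_end: float = 200.0,
    output_grid: np.ndarray | None = None,
) -> Trajectory:
    """One exact stochastic realization (Gillespie direct method).

    Counts are recorded on ``output_grid`` (default: 400 uniform points on
    [0, t_end]) by sampling the piecewise-constant state.
    """
    for name in ("Itk0", "PIP3_0", "PIP2_0", "IP4_0"):
        v = getattr(init, name)
        if int(v) != v:
            raise ValueError(f"SSA requires integer initial counts; {name}={v}")
    rng = np.random.default_rng(seed)
    rates = resolve_rates(spec, params)
    kin = _Kinetics(spec, rates)
    y = init.vector(spec).astype(float)
    if output_grid is None:
        output_grid = np.linspace(0.0, t_end, 401)
    out = np.empty((len(output_grid), len(y)))
    t = 0.0
    gi = 0
    while gi < len(output_grid) and output_grid[gi] <= t:
        out[gi] = y
        gi += 1
    while t < t_end:
        a = kin.propensities(y)
        a_tot = a.sum()
        if a_tot <= 0:
            break
        t = t + rng.exponential(1.0 / a_tot)
        while gi < len(output_grid) and output_grid[gi] < t:
            out[gi] = y
            gi += 1
        if t >= t_end:
            break
        j = np.searchsorted(np.cumsum(a), rng.uniform(0, a_tot))
        y = y + kin.S[:, j]
    while gi < len(output_grid):
        out[gi] = y
        gi += 1
    active_idx = [spec.species_index()[s] for s in spec.active_species]
    return Trajectory(
        times=np.asarray(output_grid, dtype=float),
        counts=out,
        species=tuple(spec.species),
        readout=out[:, active_idx].sum(axis=1),
        meta={"model_id": spec.model_id, "seed": seed},
    )


def ssa_ensemble_mean(
    spec: ModelSpec,
    params: ParameterSet,
    init: InitialState,
    n_realizations: int,
    seed: int,
    t_end: float = 200.0,
    output_grid: np.ndarray | None = None,
) -> tuple[Trajectory, np.ndarray]:
    """Pointwise mean readout over stochastic realizations, plus its
    standard error at every grid time."""
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    if output_grid is None:
        output_grid = np.linspace(0.0, t_end, 401)
    seeds = np.random.SeedSequence(seed).spawn(n_realizations)
    acc = np.zeros((len(output_grid), len(spec.species)))
    read_sum = np.zeros(len(output_grid))
    read_sq = np.zeros(len(output_grid))
    for ss in seeds:
        traj = run_ssa(
            spec, params, init,
            seed=int(ss.generate_state(1)[0] % (2**31)),
            t_end=t_end, output_grid=output_grid,
        )
        acc += traj.counts
        read_sum += traj.readout
        read_sq += traj.readout**2
    mean_counts = acc / n_realizations
    mean_read = read_sum / n_realizations
    if n_realizations > 1:
        var = (read_sq - n_realizations * mean_read**2) / (n_realizations - 1)
        sem = np.sqrt(np.maximum(var, 0.0) / n_realizations)
    else:
        sem = np.zeros_like(mean_read)
    traj = Trajectory(
        times=np.asarray(output_grid, dtype=float),
        counts=mean_counts,
        species=tuple(spec.species),
        readout=mean_read,
        meta={"model_id": spec.model_id, "n_realizations": n_realizations, "seed": seed},
    )
    return traj, sem
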