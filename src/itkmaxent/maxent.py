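"""Maximum-entropy reweighting of parameter ensembles and robustness ranking.

Given an ensemble of in-silico cells with observables f_i = (tau_p, R, A)
(amplitude optional), the maximum-entropy distribution matching the
population-average constraints f_avg is the exponential tilt

    w_i  proportional to  exp(-lambda . f_i),

with Lagrange multipliers lambda fixed by the constraint equations
sum_i w_i f_i = f_avg.  The multipliers are found by minimizing the convex
dual

    F(lambda) = log sum_i exp(-lambda . (f_i - f_avg)),

whose gradient is f_avg - E_w[f].  The Kullback-Leibler distance of the
tilted distribution from the uniform prior over the n valid samples,

    D_KL = sum_i w_i log10(w_i * n),

reported in log10 units, quantifies how far a model must be pushed from
parameter-indifference to satisfy the constraints: the smaller D_KL, the more
robust the model.  Models are rank-ordered by D_KL; maps over a grid of
(R_avg, A_avg) targets locate the most robust model per constraint cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from .ensemble import ObservableTable

__all__ = [
    "Constraints",
    "MaxEntSolution",
    "RobustnessMap",
    "solve_maxent",
    "solve_tilt",
    "kl_to_uniform",
    "rank_models",
    "robustness_map",
]

_LN10 = np.log(10.0)


@dataclass(frozen=True)
class Constraints:
    """Population-average targets.  Omitting ``A_avg`` reproduces the
    shape-only (no-amplitude) variant of the analysis."""

    tau_p_avg: float
    R_avg: float
    A_avg: float | None = None

    def __post_init__(self):
        for name in ("tau_p_avg", "R_avg", "A_avg"):
            v = getattr(self, name)
            if v is not None and not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and positive")

    @property
    def names(self) -> tuple[str, ...]:
        return ("tau_p", "R", "A") if self.A_avg is not None else ("tau_p", "R")

    @property
    def targets(self) -> np.ndarray:
        vals = [self.tau_p_avg, self.R_avg]
        if self.A_avg is not None:
            vals.append(self.A_avg)
        return np.asarray(vals, dtype=float)


@dataclass
class MaxEntSolution:
    lambdas: np.ndarray
    weights: np.ndarray | None
    log_partition: float
    entropy_S: float
    D_KL: float
    converged: bool
    feasible: bool
    residuals: np.ndarray
    n_valid: int
    constraint_names: tuple[str, ...] = ()
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "lambdas": None if self.lambdas is None else list(map(float, self.lambdas)),
            "D_KL": float(self.D_KL) if np.isfinite(self.D_KL) else None,
            "entropy_S": float(self.entropy_S) if np.isfinite(self.entropy_S) else None,
            "converged": bool(self.converged),
            "feasible": bool(self.feasible),
            "residuals": list(map(float, np.atleast_1d(self.residuals))),
            "n_valid": int(self.n_valid),
            "constraint_names": list(self.constraint_names),
            "diagnostics": self.diagnostics,
        }


def kl_to_uniform(weights) -> float:
    """Kullback-Leibler distance (log10 units) of a weight vector on the
    simplex from the uniform distribution over its support size N,
    sum_i w_i log10(w_i N), with 0 log 0 = 0."""
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    if abs(w.sum() - 1.0) > 1e-8:
        raise ValueError("weights must sum to 1")
    n = len(w)
    pos = w > 0
    return float(np.sum(w[pos] * np.log10(w[pos] * n)))


def _infeasible(n_valid, names, reason) -> MaxEntSolution:
    k = len(names)
    return MaxEntSolution(
        lambdas=np.full(k, np.nan),
        weights=None,
        log_partition=np.nan,
        entropy_S=np.nan,
        D_KL=np.inf,
        converged=False,
        feasible=False,
        residuals=np.full(k, np.nan),
        n_valid=n_valid,
        constraint_names=tuple(names),
        diagnostics={"reason": reason},
    )


def solve_maxent(
    table: ObservableTable | pd.DataFrame | np.ndarray,
    constraints: Constraints,
    tol: float = 1e-6,
) -> MaxEntSolution:
    """Exponentially tilt a sample table to match population-average targets.

    ``table`` may be an :class:`ObservableTable` (only OK rows are used), a
    DataFrame with the constraint columns, or a bare (n, k) feature matrix in
    constraint order.  Targets lying outside the sampled range of any
    observable are infeasible (no tilt can reach them) and reported as such.
    """
    names = constraints.names
    if isinstance(table, ObservableTable):
        F = table.valid[list(names)].to_numpy(dtype=float)
    elif isinstance(table, pd.DataFrame):
        F = table[list(names)].to_numpy(dtype=float)
    else:
        F = np.asarray(table, dtype=float)
        if F.ndim == 1:
            F = F[:, None]
    return solve_tilt(F, constraints.targets, tol=tol, names=names)


def solve_tilt(
    F: np.ndarray,
    targets,
    tol: float = 1e-6,
    names: tuple[str, ...] | None = None,
) -> MaxEntSolution:
    """Core exponential-tilt solver on a bare (n, k) feature matrix."""
    F = np.asarray(F, dtype=float)
    if F.ndim == 1:
        F = F[:, None]
    targets = np.asarray(targets, dtype=float)
    n, k = F.shape
    if names is None:
        names = tuple(f"f{j}" for j in range(k))
    if k != len(targets):
        raise ValueError("feature matrix width does not match constraint count")
    if n == 0:
        return _infeasible(0, names, "no valid samples")

    # per-axis feasibility screen: a tilt can only reach targets strictly
    # inside the convex hull of the samples; check the axis-aligned box first
    fmin, fmax = F.min(axis=0), F.max(axis=0)
    inside = (targets > fmin) & (targets < fmax)
    at_vertex = np.isclose(fmin, fmax) & np.isclose(targets, fmin)
    if not np.all(inside | at_vertex):
        bad = [names[i] for i in range(k) if not (inside[i] or at_vertex[i])]
        return _infeasible(n, names, f"targets outside sampled range: {bad}")

    # standardize for conditioning; lambda is rescaled back afterwards
    scale = F.std(axis=0, ddof=0)
    scale[scale == 0] = 1.0
    G = (F - targets) / scale

    def objective(lam):
        z = -G @ lam
        val = logsumexp(z) - np.log(n)
        p = np.exp(z - logsumexp(z))
        grad = -(p @ G)
        return val, grad

    with np.errstate(over="ignore", invalid="ignore"):
        res = minimize(
            objective, np.zeros(k), jac=True, method="BFGS",
            options={"gtol": 1e-12, "maxiter": 2000},
        )
    lam_scaled = res.x
    z = -G @ lam_scaled
    logw = z - logsumexp(z)
    w = np.exp(logw)
    means = w @ F
    residuals = (means - targets) / targets
    converged = bool(np.max(np.abs(residuals)) <= tol)
    # divergent multipliers signal a jointly infeasible target (the tilt
    # pushes all weight to a face of the hull without attaining the target)
    if not converged and (np.linalg.norm(lam_scaled) > 1e6 or not res.success):
        return _infeasible(n, names, "dual did not converge (jointly infeasible target)")

    d_kl = kl_to_uniform(w)
    entropy_nats = -float(np.sum(w[w > 0] * np.log(w[w > 0])))
    return MaxEntSolution(
        lambdas=lam_scaled / scale,
        weights=w,
        log_partition=float(logsumexp(z)),
        entropy_S=entropy_nats,
        D_KL=d_kl,
        converged=converged,
        feasible=True,
        residuals=residuals,
        n_valid=n,
        constraint_names=tuple(names),
        diagnostics={"n_iter": int(res.nit), "dual_value": float(res.fun)},
    )


def rank_models(solutions: dict[str, MaxEntSolution]) -> list[str]:
    """Model ids in ascending D_KL order; infeasible models last; ties broken
    by model index."""
    feasible = [m for m, s in solutions.items() if s.feasible and np.isfinite(s.D_KL)]
    infeasible = [m for m in solutions if m not in feasible]
    feasible.sort(key=lambda m: (solutions[m].D_KL, m))
    infeasible.sort()
    return feasible + infeasible


@dataclass
class RobustnessMap:
    R_grid: np.ndarray
    A_grid: np.ndarray  # length 1 with value nan for the no-amplitude variant
    tau_p_avg: float
    model_ids: tuple[str, ...]
    D_KL: np.ndarray  # (len(R_grid), len(A_grid), n_models); inf = infeasible
    best_model: np.ndarray  # object array of model ids, None where no model feasible

    @property
    def feasibility_mask(self) -> np.ndarray:
        """True where at least one model is feasible."""
        return np.isfinite(self.D_KL).any(axis=2)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, r in enumerate(self.R_grid):
            for j, a in enumerate(self.A_grid):
                row = {"R_avg": r, "A_avg": a, "best_model": self.best_model[i, j]}
                for m_idx, m in enumerate(self.model_ids):
                    row[f"D_KL_{m}"] = self.D_KL[i, j, m_idx]
                rows.append(row)
        return pd.DataFrame(rows)


def robustness_map(
    tables: dict[str, ObservableTable],
    R_grid,
    A_grid=None,
    tau_p_avg: float = 2.0,
    tol: float = 1e-6,
) -> RobustnessMap:
    """Most-robust-model map over a lattice of (R_avg, A_avg) targets at
    fixed tau_p_avg.  ``A_grid=None`` collapses the amplitude axis (the
    shape-only variant)."""
    R_grid = np.atleast_1d(np.asarray(R_grid, dtype=float))
    no_amplitude = A_grid is None
    A_vals = np.array([np.nan]) if no_amplitude else np.atleast_1d(np.asarray(A_grid, float))
    if len(R_grid) == 0 or len(A_vals) == 0:
        raise ValueError("grids must be nonempty")
    model_ids = tuple(tables)
    D = np.full((len(R_grid), len(A_vals), len(model_ids)), np.inf)
    best = np.full((len(R_grid), len(A_vals)), None, dtype=object)
    for i, r in enumerate(R_grid):
        for j, a in enumerate(A_vals):
            cons = Constraints(
                tau_p_avg=tau_p_avg, R_avg=float(r),
                A_avg=None if no_amplitude else float(a),
            )
            sols = {m: solve_maxent(tables[m], cons, tol=tol) for m in model_ids}
            for m_idx, m in enumerate(model_ids):
                if sols[m].feasible and sols[m].converged:
                    D[i, j, m_idx] = sols[m].D_KL
            ranking = rank_models(
                {m: s for m, s in sols.items() if s.feasible and s.converged}
            )
            best[i, j] = ranking[0] if ranking else None
    return RobustnessMap(
        R_grid=R_grid, A_grid=A_vals, tau_p_avg=tau_p_avg,
        model_ids=model_ids, D_KL=D, best_model=best,
    )
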