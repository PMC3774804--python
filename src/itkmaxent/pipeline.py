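"""End-to-end orchestration of the robustness analysis.

These functions are the package's batch interface: each one composes the
module-level operations (model building, ensemble evaluation, MaxEnt
reweighting, map construction) into a reproducible run keyed by a seed and a
config hash, optionally persisting CSV/JSON artifacts.  The ``examples/``
scripts and ``scripts/acceptance.py`` are thin drivers over this module.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import __version__
from .defaults import base_parameters
from .ensemble import EnsembleConfig, ObservableTable, draw_ensemble, evaluate_ensemble
from .experiment import PIP2_0_DEFAULT, STIMULUS_MAP
from .maxent import Constraints, MaxEntSolution, RobustnessMap, rank_models, robustness_map, solve_maxent
from .models import MODEL_IDS, InitialState, ParameterSet, build_model
from .shapes import SummaryStatus, summarize
from .simulate import SimulationConfig, integrate_ode

__all__ = [
    "stimulus_init",
    "build_tables",
    "run_robustness_analysis",
    "run_robustness_map",
    "calibrate",
]


def stimulus_init(stimulus: str) -> InitialState:
    """Initial molecule counts for a named stimulus condition."""
    itk0, pip3_0 = STIMULUS_MAP[stimulus]
    return InitialState(Itk0=itk0, PIP3_0=pip3_0, PIP2_0=PIP2_0_DEFAULT)


def _manifest(seed: int, extra: dict) -> dict:
    return {"package_version": __version__, "seed": seed, **extra}


def build_tables(
    model_ids,
    base_init: InitialState,
    n_samples: int,
    seed: int,
    sim_config: SimulationConfig | None = None,
) -> dict[str, ObservableTable]:
    """Evaluate one parameter ensemble per model (independent per-model
    seed streams derived from ``seed``)."""
    tables = {}
    child_seeds = np.random.SeedSequence(seed).spawn(len(list(model_ids)))
    for m, ss in zip(model_ids, child_seeds):
        cfg = EnsembleConfig(
            base_params=base_parameters(m),
            base_init=base_init,
            n_samples=n_samples,
            seed=int(ss.generate_state(1)[0] % (2**31)),
        )
        spec = build_model(m)
        tables[m] = evaluate_ensemble(spec, draw_ensemble(cfg, m), sim_config, cfg)
    return tables


def run_robustness_analysis(
    constraints: Constraints,
    base_init: InitialState,
    model_ids=MODEL_IDS,
    n_samples: int = 2000,
    seed: int = 0,
    out_dir: str | Path | None = None,
    tables: dict[str, ObservableTable] | None = None,
) -> dict:
    """Rank all requested models by D_KL under one set of constraints."""
    if tables is None:
        tables = build_tables(model_ids, base_init, n_samples, seed)
    solutions: dict[str, MaxEntSolution] = {
        m: solve_maxent(tables[m], constraints) for m in tables
    }
    ranking = rank_models(solutions)
    result = {
        "constraints": asdict(constraints),
        "ranking": ranking,
        "solutions": solutions,
        "manifest": _manifest(seed, {"n_samples": n_samples, "init": asdict(base_init)}),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for m, table in tables.items():
            table.to_csv(out / f"observables_{m}.csv")
        payload = {
            "constraints": result["constraints"],
            "ranking": ranking,
            "D_KL": {m: s.to_dict() for m, s in solutions.items()},
            "manifest": result["manifest"],
        }
        (out / "maxent_results.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    return result


def run_robustness_map(
    base_init: InitialState,
    R_grid,
    A_grid=None,
    tau_p_avg: float = 2.0,
    model_ids=MODEL_IDS,
    n_samples: int = 2000,
    seed: int = 0,
    out_dir: str | Path | None = None,
    tables: dict[str, ObservableTable] | None = None,
) -> RobustnessMap:
    """Best-model map over (R_avg, A_avg) constraint targets."""
    if tables is None:
        tables = build_tables(model_ids, base_init, n_samples, seed)
    rmap = robustness_map(tables, R_grid, A_grid, tau_p_avg=tau_p_avg)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rmap.to_frame().to_csv(out / "robustness_map.csv", index=False)
        (out / "map_manifest.json").write_text(
            json.dumps(_manifest(seed, {"n_samples": n_samples}), indent=2, sort_keys=True)
        )
    return rmap


def calibrate(
    model_id: str = "M3",
    init: InitialState | None = None,
    tau_p_target: float = 2.0,
    R_target: float = 2.0,
    n_refine: int = 2,
) -> dict:
    """Fit the shared base rates so the reference model hits the target
    transient shape at the calibration stimulus.

    A coarse log-grid search over (k_on_low, k_cat) -- the rates that control
    the rise time and the negative-feedback strength -- minimizes
    log-distance to (tau_p_target, R_target), then zooms twice.  Returns the
    fitted :class:`ParameterSet` and the achieved summary; the shipped
    defaults in :mod:`itkmaxent.defaults` are the frozen output of this
    procedure.
    """
    init = init or InitialState(Itk0=100, PIP3_0=370, PIP2_0=17000)
    spec = build_model(model_id)
    base = base_parameters(model_id)
    sim = SimulationConfig(rel_tol=1e-8, abs_tol=1e-10)

    def loss_and_summary(k_on_low, k_cat):
        rates = dict(base.rates)
        scale = k_on_low / rates["k_on_low"]
        rates["k_on_low"] = k_on_low
        rates["k_on_high"] = rates["k_on_high"] * scale
        rates["k_cat"] = k_cat
        params = ParameterSet(rates=rates, alpha=base.alpha)
        traj = integrate_ode(spec, params, init, sim)
        s = summarize(traj.times, traj.readout)
        if s.status is not SummaryStatus.OK:
            return np.inf, s, params
        loss = np.log(s.tau_p / tau_p_target) ** 2 + np.log(s.R / R_target) ** 2
        return loss, s, params

    center = (np.log10(base.rates["k_on_low"]), np.log10(base.rates["k_cat"]))
    half_width = 1.0
    best = (np.inf, None, None)
    for _ in range(n_refine + 1):
        g1 = np.linspace(center[0] - half_width, center[0] + half_width, 7)
        g2 = np.linspace(center[1] - half_width, center[1] + half_width, 7)
        for l1 in g1:
            for l2 in g2:
                loss, s, params = loss_and_summary(10.0**l1, 10.0**l2)
                if loss < best[0]:
                    best = (loss, s, params)
                    center = (l1, l2)
        half_width /= 3.0
    loss, s, params = best
    return {"params": params, "summary": s, "loss": float(loss), "init": init}
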