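"""Parameter ensembles representing cell-to-cell (extrinsic) variability.

Population measurements average over cells whose rate constants and protein
or lipid abundances differ.  The ensemble emulates that variability by
drawing, per in-silico cell, every free rate constant uniformly between 1/10
and 10 times its base value, every initial concentration uniformly within a
+/-35% window around its base, and -- for the allosteric dimer models -- the
K_D ratio alpha uniformly over its model-specific range (M1-M3: [1, 4000];
M7: [1, 50]), with the high-affinity off-rate derived from alpha so that
K_D_low = alpha * K_D_high holds by construction.

Each draw is simulated deterministically and reduced to the shape statistics
(tau_p, R, A); the resulting table is the input to the MaxEnt reweighting.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .models import ALPHA_MODELS, InitialState, ModelSpec, ParameterSet
from .shapes import SummaryStatus, summarize
from .simulate import SimulationConfig, SimulationError, integrate_ode

__all__ = [
    "EnsembleConfig",
    "ObservableTable",
    "DEFAULT_ALPHA_RANGES",
    "draw_ensemble",
    "evaluate_ensemble",
]

DEFAULT_ALPHA_RANGES = {
    "M1": (1.0, 4000.0),
    "M2": (1.0, 4000.0),
    "M3": (1.0, 4000.0),
    "M7": (1.0, 50.0),
}


@dataclass(frozen=True)
class EnsembleConfig:
    base_params: ParameterSet
    base_init: InitialState
    n_samples: int = 100_000
    seed: int = 0
    #: multiplicative bounds on each free base rate, uniform on the linear scale
    rate_span: tuple[float, float] = (0.1, 10.0)
    #: fractional half-width of the uniform window around base concentrations
    conc_window: float = 0.35
    alpha_range: tuple[float, float] | None = None

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not self.rate_span[0] < self.rate_span[1]:
            raise ValueError("rate_span bounds must be ordered")
        if not 0 <= self.conc_window < 1:
            raise ValueError("conc_window must lie in [0, 1)")
        if self.alpha_range is not None and not (
            1 <= self.alpha_range[0] < self.alpha_range[1]
        ):
            raise ValueError("alpha_range must be ordered and >= 1")

    def to_yaml(self, path) -> None:
        import yaml

        payload = {
            "base_params": {"rates": dict(self.base_params.rates),
                            "alpha": self.base_params.alpha},
            "base_init": asdict(self.base_init),
            "n_samples": self.n_samples,
            "seed": self.seed,
            "rate_span": list(self.rate_span),
            "conc_window": self.conc_window,
            "alpha_range": None if self.alpha_range is None else list(self.alpha_range),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "EnsembleConfig":
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(
            base_params=ParameterSet(rates=payload["base_params"]["rates"],
                                     alpha=payload["base_params"]["alpha"]),
            base_init=InitialState(**payload["base_init"]),
            n_samples=payload["n_samples"],
            seed=payload["seed"],
            rate_span=tuple(payload["rate_span"]),
            conc_window=payload["conc_window"],
            alpha_range=None if payload["alpha_range"] is None
            else tuple(payload["alpha_range"]),
        )

    def config_hash(self) -> str:
        payload = {
            "rates": dict(self.base_params.rates),
            "alpha": self.base_params.alpha,
            "init": asdict(self.base_init),
            "n_samples": self.n_samples,
            "seed": self.seed,
            "rate_span": self.rate_span,
            "conc_window": self.conc_window,
            "alpha_range": self.alpha_range,
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class ObservableTable:
    """Per-sample shape statistics for one model's parameter ensemble."""

    model_id: str
    records: pd.DataFrame  # columns: sample, tau_p, R, A, status
    provenance: dict = field(default_factory=dict)

    @property
    def valid(self) -> pd.DataFrame:
        """Rows with a full (tau_p, R, A) triple; only these enter MaxEnt."""
        return self.records[self.records["status"] == SummaryStatus.OK.value]

    @property
    def n_valid(self) -> int:
        return len(self.valid)

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, model_id: str) -> "ObservableTable":
        return cls(model_id=model_id, records=pd.read_csv(path))


def _free_rate_names(model_id: str, base_params: ParameterSet) -> list[str]:
    names = list(base_params.rates)
    if model_id in ALPHA_MODELS and "k_off_high" in names:
        names.remove("k_off_high")  # derived from alpha, never sampled
    return names


def draw_ensemble(
    config: EnsembleConfig, model_id: str
) -> list[tuple[ParameterSet, InitialState]]:
    """Draw ``n_samples`` (parameters, initial state) pairs for one model.

    Fully reproducible from ``config.seed``; concentrations are rounded to
    whole molecules.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.rate_span
    w = config.conc_window
    free = _free_rate_names(model_id, config.base_params)
    for name in free:
        if not config.base_params.rates[name] > 0:
            raise ValueError(f"base rate {name!r} must be positive")
    alpha_range = config.alpha_range
    if model_id in ALPHA_MODELS and alpha_range is None:
        alpha_range = DEFAULT_ALPHA_RANGES[model_id]

    base_init = config.base_init
    samples = []
    for _ in range(config.n_samples):
        rates = {
            name: rng.uniform(lo * config.base_params.rates[name],
                              hi * config.base_params.rates[name])
            for name in free
        }
        alpha = None
        if model_id in ALPHA_MODELS:
            alpha = float(rng.uniform(*alpha_range))
        init = InitialState(
            Itk0=int(round(rng.uniform((1 - w) * base_init.Itk0, (1 + w) * base_init.Itk0))),
            PIP3_0=int(round(rng.uniform((1 - w) * base_init.PIP3_0, (1 + w) * base_init.PIP3_0))),
            PIP2_0=int(round(rng.uniform((1 - w) * base_init.PIP2_0, (1 + w) * base_init.PIP2_0))),
            IP4_0=base_init.IP4_0,
        )
        samples.append((ParameterSet(rates=rates, alpha=alpha), init))
    return samples


def evaluate_ensemble(
    spec: ModelSpec,
    samples: list[tuple[ParameterSet, InitialState]],
    sim_config: SimulationConfig | None = None,
    config: EnsembleConfig | None = None,
) -> ObservableTable:
    """Simulate every sample and tabulate its shape statistics.

    Failures and non-OK summaries are recorded per sample (status column),
    never dropped silently; the result is independent of evaluation order.
    """
    sim_config = sim_config or SimulationConfig(rel_tol=1e-7, abs_tol=1e-9)
    rows = []
    for i, (params, init) in enumerate(samples):
        try:
            traj = integrate_ode(spec, params, init, sim_config)
            if traj.censored:
                rows.append((i, np.nan, np.nan, np.nan, "CENSORED_WIDTH"))
                continue
            s = summarize(traj.times, traj.readout)
            if s.status is SummaryStatus.OK:
                rows.append((i, s.tau_p, s.R, s.A, s.status.value))
            else:
                rows.append((i, np.nan, np.nan, np.nan, s.status.value))
        except SimulationError:
            rows.append((i, np.nan, np.nan, np.nan, "SOLVER_FAILED"))
    records = pd.DataFrame(rows, columns=["sample", "tau_p", "R", "A", "status"])
    provenance = {"model_id": spec.model_id}
    if config is not None:
        provenance.update(seed=config.seed, config_hash=config.config_hash())
    return ObservableTable(model_id=spec.model_id, records=records, provenance=provenance)
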