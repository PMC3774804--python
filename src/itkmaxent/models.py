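"""Candidate reaction networks for IP4/PIP3-regulated Itk membrane recruitment.

Seven mass-action networks (M1--M7) describe how the Tec-family kinase Itk is
recruited to membrane PIP3 via its PH domain, and how the soluble PIP3 analog
IP4 -- produced downstream of active (PIP3-bound) Itk -- feeds back on that
recruitment.  The models differ in whether Itk carries one PH-domain site
(monomers: M4, M6) or two (dimers: M1--M3, M5, M7), and in whether ligand
binding to one site allosterically raises the affinity of the partner site
(positive feedback: M1--M4, M7) or not (M5, M6).  In every model IP4 competes
with PIP3 for the same sites, which is the shared negative feedback: once the
catalysis reaction (PIP3-bound Itk + PIP2 -> IP4) has flooded the cell with
IP4, Itk is sequestered in IP4-only complexes and the membrane-bound readout
decays.

Species are molecule counts in a single well-mixed box; first-order rate
constants are per minute, second-order per molecule per minute.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "SiteOccupancy",
    "Affinity",
    "ReactionSpec",
    "ModelSpec",
    "ParameterSet",
    "InitialState",
    "MODEL_IDS",
    "DIMER_MODELS",
    "MONOMER_MODELS",
    "FEEDBACK_MODELS",
    "affinity_class",
    "build_model",
    "with_inert_reactions",
    "active_count",
    "resolve_rates",
]

MODEL_IDS = ("M1", "M2", "M3", "M4", "M5", "M6", "M7")
DIMER_MODELS = frozenset({"M1", "M2", "M3", "M5", "M7"})
MONOMER_MODELS = frozenset({"M4", "M6"})
#: models with an IP4/PIP3-induced affinity increase (positive feedback)
FEEDBACK_MODELS = frozenset({"M1", "M2", "M3", "M4", "M7"})
#: dimer models whose high-affinity off-rate is tied to the sampled K_D ratio alpha
ALPHA_MODELS = frozenset({"M1", "M2", "M3", "M7"})

POOLS = ("PIP3", "IP4", "PIP2")


class SiteOccupancy(str, Enum):
    """Ligand state of a single PH-domain site."""

    EMPTY = "E"
    IP4 = "I"
    PIP3 = "P"


class Affinity(str, Enum):
    LOW = "LOW"
    HIGH = "HIGH"


# Allostery tables: (partner occupancy, incoming/bound ligand) -> affinity class.
# The class governs both the on-rate of an incoming ligand and the off-rate of
# a bound ligand, evaluated from the partner site's occupancy at the moment of
# the event.  An unoccupied partner is always the weak-affinity baseline.
_E, _I, _P = SiteOccupancy.EMPTY, SiteOccupancy.IP4, SiteOccupancy.PIP3
_L, _H = Affinity.LOW, Affinity.HIGH

_ALLOSTERY: dict[str, dict[tuple[SiteOccupancy, SiteOccupancy], Affinity]] = {
    # partner IP4 -> HIGH for both ligands in every feedback dimer model;
    # the models differ only in what a PIP3-occupied partner does.
    "M1": {(_I, _I): _H, (_I, _P): _H, (_P, _I): _H, (_P, _P): _H},
    "M2": {(_I, _I): _H, (_I, _P): _H, (_P, _I): _L, (_P, _P): _L},
    "M3": {(_I, _I): _H, (_I, _P): _H, (_P, _I): _H, (_P, _P): _L},
    "M7": {(_I, _I): _H, (_I, _P): _H, (_P, _I): _L, (_P, _P): _H},
    "M5": {(_I, _I): _L, (_I, _P): _L, (_P, _I): _L, (_P, _P): _L},
}


def affinity_class(
    model_id: str, partner: SiteOccupancy, incoming_ligand: SiteOccupancy
) -> Affinity:
    """Affinity class of a ligand event on one site of an Itk dimer.

    ``partner`` is the occupancy of the other PH domain in the dimer at the
    moment of the event; ``incoming_ligand`` is the ligand binding to (or bound
    at) the site in question, IP4 or PIP3.  Monomer models have no partner
    site and are rejected.
    """
    if model_id not in DIMER_MODELS:
        raise ValueError(f"{model_id!r} is not a dimer model; no partner site exists")
    incoming_ligand = SiteOccupancy(incoming_ligand)
    if incoming_ligand is SiteOccupancy.EMPTY:
        raise ValueError("incoming ligand must be IP4 or PIP3")
    partner = SiteOccupancy(partner)
    if partner is SiteOccupancy.EMPTY:
        return Affinity.LOW
    return _ALLOSTERY[model_id][(partner, incoming_ligand)]


@dataclass(frozen=True)
class ReactionSpec:
    """One elementary mass-action reaction.

    ``multiplicity`` is the statistical factor from indistinguishable sites
    (e.g. an empty-empty dimer offers two equivalent sites to a ligand), folded
    into the effective rate constant at evaluation time.
    """

    reactants: tuple[str, ...]
    products: tuple[str, ...]
    rate_name: str
    multiplicity: int = 1

    @property
    def order(self) -> int:
        return len(self.reactants)

    def __post_init__(self):
        if self.order not in (1, 2):
            raise ValueError("only first- and second-order reactions are supported")


@dataclass(frozen=True)
class ModelSpec:
    model_id: str
    species: tuple[str, ...]
    reactions: tuple[ReactionSpec, ...]
    rate_parameter_names: tuple[str, ...]
    #: per-species number of PIP3-occupied sites / IP4-occupied sites
    pip3_sites: Mapping[str, int] = field(default_factory=dict)
    ip4_sites: Mapping[str, int] = field(default_factory=dict)

    @property
    def itk_species(self) -> tuple[str, ...]:
        return tuple(s for s in self.species if s not in POOLS)

    @property
    def active_species(self) -> tuple[str, ...]:
        """Itk species with at least one PIP3-bound site (the readout)."""
        return tuple(s for s in self.itk_species if self.pip3_sites.get(s, 0) >= 1)

    def species_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.species)}

    def conservation_matrix(self) -> np.ndarray:
        """Rows: Itk total; PIP3 total (free + bound); inositol units
        (free IP4 + bound IP4 + PIP2).  Each row is constant along any
        trajectory of the network."""
        idx = self.species_index()
        C = np.zeros((3, len(self.species)))
        for s in self.itk_species:
            C[0, idx[s]] = 1.0
        C[1, idx["PIP3"]] = 1.0
        C[2, idx["IP4"]] = 1.0
        C[2, idx["PIP2"]] = 1.0
        for s in self.itk_species:
            C[1, idx[s]] = self.pip3_sites.get(s, 0)
            C[2, idx[s]] = self.ip4_sites.get(s, 0)
        return C

    def to_json(self) -> str:
        return json.dumps(
            {
                "model_id": self.model_id,
                "species": list(self.species),
                "rate_parameter_names": list(self.rate_parameter_names),
                "reactions": [
                    {
                        "reactants": list(r.reactants),
                        "products": list(r.products),
                        "rate_name": r.rate_name,
                        "multiplicity": r.multiplicity,
                        "order": r.order,
                    }
                    for r in self.reactions
                ],
            },
            indent=2,
        )


@dataclass(frozen=True)
class ParameterSet:
    """Rate constants for one model instance.

    ``rates`` is keyed by the model's ``rate_parameter_names``.  For the
    allosteric dimer models (M1--M3, M7) the high-affinity off-rate is not an
    independent knob: it is derived from the dimensionless K_D ratio ``alpha``
    via K_D_low = alpha * K_D_high, i.e.
    k_off_high = k_on_high * k_off_low / (k_on_low * alpha).
    """

    rates: Mapping[str, float]
    alpha: float | None = None

    def __post_init__(self):
        for name, v in self.rates.items():
            if not v > 0:
                raise ValueError(f"rate {name!r} must be strictly positive, got {v}")
        if self.alpha is not None and not self.alpha > 0:
            raise ValueError("alpha must be strictly positive")


def resolve_rates(spec: ModelSpec, params: ParameterSet) -> dict[str, float]:
    """Full rate dictionary for ``spec``, deriving k_off_high from alpha
    where the model couples the two affinity classes."""
    rates = dict(params.rates)
    if spec.model_id in ALPHA_MODELS:
        if params.alpha is None:
            raise ValueError(f"{spec.model_id} requires alpha (K_D ratio)")
        rates["k_off_high"] = (
            rates["k_on_high"] * rates["k_off_low"] / (rates["k_on_low"] * params.alpha)
        )
    missing = [n for n in spec.rate_parameter_names if n not in rates]
    if missing:
        raise ValueError(f"missing rate constants: {missing}")
    return rates


@dataclass(frozen=True)
class InitialState:
    """Initial molecule counts.  IP4 starts at zero by default: the models do
    not resolve the kinetics that generate any pre-signaling threshold IP4."""

    Itk0: int
    PIP3_0: int
    PIP2_0: int
    IP4_0: int = 0

    def __post_init__(self):
        for name in ("Itk0", "PIP3_0", "PIP2_0", "IP4_0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def vector(self, spec: ModelSpec) -> np.ndarray:
        """Counts vector in species order; all Itk starts unliganded."""
        idx = spec.species_index()
        y0 = np.zeros(len(spec.species))
        free = "Itk_EE" if spec.model_id in DIMER_MODELS else "Itk"
        y0[idx[free]] = self.Itk0
        y0[idx["PIP3"]] = self.PIP3_0
        y0[idx["PIP2"]] = self.PIP2_0
        y0[idx["IP4"]] = self.IP4_0
        return y0


# --- model construction -----------------------------------------------------

_LIGAND_POOL = {SiteOccupancy.IP4: "IP4", SiteOccupancy.PIP3: "PIP3"}

_DIMER_STATES = ("EE", "EI", "EP", "II", "IP", "PP")


def _dimer_name(a: SiteOccupancy, b: SiteOccupancy) -> str:
    pair = "".join(sorted((a.value, b.value)))
    return f"Itk_{pair}"


def _rate_name(model_id: str, kind: str, cls: Affinity) -> str:
    # M5/M6 have a single affinity class and drop the suffix.
    if model_id in ("M5", "M6"):
        return {"on": "k_on", "off": "k_off"}[kind]
    return f"k_{kind}_{cls.value.lower()}"


def _build_dimer(model_id: str) -> ModelSpec:
    species = tuple(f"Itk_{s}" for s in _DIMER_STATES) + POOLS
    pip3_sites = {f"Itk_{s}": s.count("P") for s in _DIMER_STATES}
    ip4_sites = {f"Itk_{s}": s.count("I") for s in _DIMER_STATES}
    reactions: list[ReactionSpec] = []

    occ = {"E": _E, "I": _I, "P": _P}
    states = [tuple(occ[c] for c in s) for s in _DIMER_STATES]

    for a, b in states:
        # binding into each empty site
        for site, partner in ((a, b), (b, a)):
            if site is not _E:
                continue
            for lig in (_I, _P):
                cls = affinity_class(model_id, partner, lig)
                mult = 2 if (a is _E and b is _E) else 1
                reactions.append(
                    ReactionSpec(
                        reactants=(_dimer_name(a, b), _LIGAND_POOL[lig]),
                        products=(_dimer_name(lig, partner),),
                        rate_name=_rate_name(model_id, "on", cls),
                        multiplicity=mult,
                    )
                )
            break  # the two empty sites of EE are equivalent: emit once with mult 2
        # unbinding of each distinct bound ligand
        seen: set[SiteOccupancy] = set()
        for site, partner in ((a, b), (b, a)):
            if site is _E or site in seen:
                continue
            seen.add(site)
            cls = affinity_class(model_id, partner, site)
            mult = 2 if a is b else 1
            reactions.append(
                ReactionSpec(
                    reactants=(_dimer_name(a, b),),
                    products=(_dimer_name(_E, partner), _LIGAND_POOL[site]),
                    rate_name=_rate_name(model_id, "off", cls),
                    multiplicity=mult,
                )
            )

    # catalysis: any PIP3-bound Itk converts PIP2 into IP4, once per molecule
    for s in _DIMER_STATES:
        if "P" in s:
            name = f"Itk_{s}"
            reactions.append(
                ReactionSpec(
                    reactants=(name, "PIP2"),
                    products=(name, "IP4"),
                    rate_name="k_cat",
                )
            )

    if model_id in ALPHA_MODELS:
        rate_names = ("k_on_low", "k_off_low", "k_on_high", "k_off_high", "k_cat")
    else:  # M5
        rate_names = ("k_on", "k_off", "k_cat")
    return ModelSpec(
        model_id=model_id,
        species=species,
        reactions=tuple(reactions),
        rate_parameter_names=rate_names,
        pip3_sites=pip3_sites,
        ip4_sites=ip4_sites,
    )


def _build_monomer(model_id: str) -> ModelSpec:
    species = ("Itk", "Itk_I", "Itk_P") + POOLS
    pip3_sites = {"Itk": 0, "Itk_I": 0, "Itk_P": 1}
    ip4_sites = {"Itk": 0, "Itk_I": 1, "Itk_P": 0}
    if model_id == "M4":
        # Weak binding flips Itk into a high-affinity conformation (Itk*),
        # represented implicitly by the bound states; direct ligand
        # replacement then proceeds with high affinity in both directions.
        reactions = (
            ReactionSpec(("Itk", "IP4"), ("Itk_I",), "k_on"),
            ReactionSpec(("Itk", "PIP3"), ("Itk_P",), "k_on"),
            ReactionSpec(("Itk_I",), ("Itk", "IP4"), "k_off"),
            ReactionSpec(("Itk_P",), ("Itk", "PIP3"), "k_off"),
            ReactionSpec(("Itk_I", "PIP3"), ("Itk_P", "IP4"), "k_replace"),
            ReactionSpec(("Itk_P", "IP4"), ("Itk_I", "PIP3"), "k_replace"),
            ReactionSpec(("Itk_P", "PIP2"), ("Itk_P", "IP4"), "k_cat"),
        )
        rate_names = ("k_on", "k_off", "k_replace", "k_cat")
    else:  # M6: monomer, single always-weak affinity, no feedback
        reactions = (
            ReactionSpec(("Itk", "IP4"), ("Itk_I",), "k_on"),
            ReactionSpec(("Itk", "PIP3"), ("Itk_P",), "k_on"),
            ReactionSpec(("Itk_I",), ("Itk", "IP4"), "k_off"),
            ReactionSpec(("Itk_P",), ("Itk", "PIP3"), "k_off"),
            ReactionSpec(("Itk_P", "PIP2"), ("Itk_P", "IP4"), "k_cat"),
        )
        rate_names = ("k_on", "k_off", "k_cat")
    return ModelSpec(
        model_id=model_id,
        species=species,
        reactions=reactions,
        rate_parameter_names=rate_names,
        pip3_sites=pip3_sites,
        ip4_sites=ip4_sites,
    )


def build_model(model_id: str) -> ModelSpec:
    """Construct the full species/reaction enumeration for one model."""
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model id {model_id!r}; expected one of {MODEL_IDS}")
    if model_id in DIMER_MODELS:
        return _build_dimer(model_id)
    return _build_monomer(model_id)


def with_inert_reactions(spec: ModelSpec, rate_name: str = "k_inert") -> ModelSpec:
    """Augment a model with a slow reversible shadow conversion of free Itk.

    The extra species and rate constant have no appreciable effect on the
    readout when the rate is small; the augmented model probes whether the
    robustness measure is inflated merely by adding parameters that do not
    influence the measured observables (it is not).
    """
    free = "Itk_EE" if spec.model_id in DIMER_MODELS else "Itk"
    shadow = f"{free}_shadow"
    pip3 = dict(spec.pip3_sites)
    ip4 = dict(spec.ip4_sites)
    pip3[shadow] = 0
    ip4[shadow] = 0
    return ModelSpec(
        model_id=spec.model_id,
        species=spec.itk_species + (shadow,) + POOLS,
        reactions=spec.reactions
        + (
            ReactionSpec((free,), (shadow,), rate_name),
            ReactionSpec((shadow,), (free,), rate_name),
        ),
        rate_parameter_names=spec.rate_parameter_names + (rate_name,),
        pip3_sites=pip3,
        ip4_sites=ip4,
    )


def active_count(spec: ModelSpec, state: Mapping[str, float] | Sequence[float]) -> float:
    """Total count of Itk molecules with at least one PIP3-occupied site.

    Itk saturated with IP4 on every site (and unliganded Itk) does not
    activate PLCgamma1 and contributes zero.
    """
    if isinstance(state, Mapping):
        values = {s: state.get(s, 0.0) for s in spec.species}
    else:
        arr = np.asarray(state, dtype=float)
        if arr.shape[-1] != len(spec.species):
            raise ValueError("state vector length does not match species count")
        values = {s: arr[..., i] for i, s in enumerate(spec.species)}
    total = 0.0
    for s in spec.active_species:
        v = values[s]
        if np.any(np.asarray(v) < 0):
            raise ValueError(f"negative count for species {s!r}")
        total = total + v
    return total
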