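# itkmaxent

Model discrimination for TCR-proximal Itk membrane recruitment by
maximum-entropy robustness ranking.

## The problem

During thymocyte selection, the Tec-family kinase Itk is recruited to the
plasma membrane by binding of its PH domain to the lipid PIP3, and then
activates PLCγ1. The soluble messenger IP4 — itself produced downstream of
active Itk — binds the same PH domain: at low dose it *promotes* PIP3
binding, at high dose it *competes* with it. Which molecular circuit
produces this biphasic control is unresolved, because the underlying
binding constants and the oligomeric state of Itk are hard to measure.
This package implements an in-silico route around that impasse: it encodes
seven candidate reaction networks (M1–M7) that differ in whether Itk PH
domains act as dimers or monomers and whether ligand binding allosterically
raises the partner site's affinity, and asks which network most *robustly*
reproduces the population-level PLCγ1 phosphorylation kinetics under
cell-to-cell parameter variability.

It is a library for systems biologists: import it, build a model, simulate
it deterministically (mass-action ODEs) or exactly stochastically
(Gillespie), reduce transients to shape statistics, and rank models.
Short narrative scripts in `examples/` walk through each capability.

## The method

Every transient of the readout — the number of Itk molecules bound to
membrane PIP3 — is summarized by its peak amplitude *A*, peak time τ_p,
peak width τ_w (time spent at or above half the peak), and the asymmetry
ratio *R* = τ_w/τ_p. Cell-to-cell (extrinsic) variability is emulated by
drawing each rate constant uniformly within ×[1/10, 10] of its base value
and each initial abundance within ±35%, with the K_D ratio α of the
allosteric models drawn uniformly (M1–M3: [1, 4000]; M7: [1, 50]) and the
high-affinity off-rate tied to it via K_D^low = α·K_D^high.

Given ensemble observables f_i = (τ_p, R, A)_i and population-level targets
f̄ (e.g. τ_p = 2 min, R = 1.9, A = 40 molecules for high-affinity
stimulation), the maximum-entropy distribution over the sampled cells is
the exponential tilt

    w_i ∝ exp(−λ₁ τ_p,i − λ₂ R_i − λ₃ A_i),

with multipliers λ solving the moment constraints Σ w_i f_i = f̄ (found by
minimizing the convex dual of the log-partition function). The
Kullback-Leibler distance to the uniform prior over the n valid samples,

    D_KL = Σ w_i log₁₀(w_i n),

measures how much parameter freedom a model must sacrifice to meet the
constraints: **the smaller D_KL, the more robust the model.** Models are
rank-ordered by D_KL; targets outside a model's attainable range are
reported as infeasible rather than as a large number.

## Worked example

```
$ python examples/04_robustness_ranking.py
constraints: tau_p=2.0 min, R=1.9, A=40.0

M3: D_KL =  1.149  (n_valid = 287)
M1: infeasible — targets outside sampled range: ['R']
M2: infeasible — dual did not converge (jointly infeasible target)
M4: infeasible — targets outside sampled range: ['tau_p', 'R']
M5: infeasible — targets outside sampled range: ['tau_p', 'R']
M6: infeasible — targets outside sampled range: ['tau_p', 'R']
M7: infeasible — targets outside sampled range: ['R']

most robust model: M3
```

At this reduced ensemble size (300 cells per model) the allosteric dimer
model M3 meets the population constraints at D_KL ≈ 1.15 — it can hold
them while retaining most of its parameter freedom — while the monomeric
(M4) and no-feedback (M5, M6) models cannot reach a 2-minute peak or an
asymmetry ratio of 1.9 anywhere in their sampled parameter space. At
larger ensembles (2,000+ cells per model, as in `tests/test_acceptance.py`)
M1 and M2 become feasible too, with D_KL between 1.3 and 2.6, and every
feasible allosteric dimer model beats every other class: the ranking that
favors dimeric Itk with competing IP4 feedbacks.

`examples/02_transient_shapes.py` shows why: at calibrated base parameters
the dimer feedback models produce compact pulses (R ≈ 2.2–7.4), the
monomeric feedback model an intermediate one (R ≈ 30), and the no-feedback
models nearly non-decaying signals (R ≈ 150–240).

## Layout

| module | contents |
| --- | --- |
| `itkmaxent.models` | the seven reaction networks, allostery tables, conservation laws |
| `itkmaxent.simulate` | stiff ODE integration and exact Gillespie sampling |
| `itkmaxent.shapes` | peak statistics (A, τ_p, τ_w, R) with validity flags |
| `itkmaxent.ensemble` | extrinsic-variability parameter ensembles → observable tables |
| `itkmaxent.maxent` | exponential tilting, D_KL, model ranking, robustness maps |
| `itkmaxent.experiment` | blot normalization, published constants, stimulus presets |
| `itkmaxent.synthetic` | cell-population and blot-series generators with ground truth |
| `itkmaxent.pipeline` | end-to-end orchestration, calibration, reproducible artifacts |

See `docs/methods.md` for modeling assumptions, parameter choices and
numerical details.
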