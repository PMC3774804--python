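# Methods

## Reaction networks

All seven models share the same skeleton: Itk units (dimers with two
equivalent PH-domain sites in M1–M3, M5, M7; monomers with one site in M4,
M6) bind the membrane lipid PIP3 and its soluble analog IP4 at those
sites; any Itk unit with at least one PIP3-bound site is "active" and is
the model readout (the proxy for PLCγ1-phosphorylating, membrane-recruited
Itk); active Itk converts the abundant PIP2 pool into IP4 through a single
collapsed second-order reaction that stands in for the whole
PLCγ1 → IP3 → ItpkB chain. IP4 competes with PIP3 for the same sites, so
IP4 accumulation eventually sequesters Itk in IP4-only states — the
universal negative feedback that terminates the pulse.

Dimer occupancy is an unordered pair over {empty, IP4, PIP3}, giving six
Itk species (EE, EI, EP, II, IP, PP) plus the three pools. Binding and
unbinding rates come in two affinity classes, LOW and HIGH; a per-model
allostery table maps (partner-site occupancy, ligand) to a class, and the
table is applied at the moment of each event — including unbinding, whose
class is read from the partner's *current* occupancy. An empty partner is
always LOW. M1: any occupied partner raises both ligands' affinities. M2:
only an IP4-bound partner does. M3: an IP4-bound partner raises both, a
PIP3-bound partner raises only IP4's. M7: like M3 but with the PIP3 row
mirrored (raises only PIP3's). M5: no allostery at all. M4 (monomer) has
no partner site; its positive feedback is a high-affinity ligand
*replacement* on the bound (conformationally switched) state, with free
Itk always reverting to the weak-affinity conformation. M6 is the monomer
with a single always-weak affinity and no feedback.

Statistical factors for indistinguishable sites (two ways to bind EE, two
identical ligands leaving II or PP) are carried as reaction
multiplicities. Catalysis is per active molecule: a doubly-PIP3-bound
dimer catalyzes at the same rate as a singly bound one. This is one of two
defensible readings (the other being per occupied site); it follows from
treating "PIP3-bound Itk" as the catalytic unit and only rescales k_cat
between the readings for PP-rich regimes.

Both compartments (membrane, cytosol) are collapsed into one well-mixed
box in molecule counts; first-order rates are min⁻¹, second-order rates
molecule⁻¹ min⁻¹. IP4 starts at zero everywhere, including M5/M6: the
kinetics that would generate any pre-signaling threshold IP4 level are not
resolved, binding is simply always permitted.

### Parameterization

The allosteric dimer models expose five named rate constants
{k_on_low, k_off_low, k_on_high, k_off_high, k_cat}, but k_off_high is
never free: it is derived from the dimensionless K_D ratio
α = K_D^low / K_D^high as k_off_high = k_on_high·k_off_low/(k_on_low·α),
so the sampled parameters are the four remaining rates plus α. M4 has
{k_on, k_off, k_replace, k_cat}; M5/M6 have {k_on, k_off, k_cat}. This
matches the 5/4/3 rate-constant counts of the model classes.

### Base values (calibration)

In vivo rates for thymocytes are not measurable, so base values are set by
calibration (`pipeline.calibrate`): a zoomed log-grid search over
(k_on_low, k_cat) targeting a transient with peak time ≈ 2 min, asymmetry
ratio ≈ 2 and amplitude in the tens of molecules for the reference
allosteric model M3 at the moderate stimulus (Itk⁰ = 100, PIP3⁰ = 370,
PIP2⁰ = 17000 molecules) — the shape measured for PLCγ1 phosphorylation in
cell populations. The frozen result, shared across models:

| parameter | value | unit |
| --- | --- | --- |
| k_on_low | 8.0·10⁻⁴ | molecule⁻¹ min⁻¹ |
| k_off_low | 10.0 | min⁻¹ |
| k_on_high | 8.0·10⁻³ | molecule⁻¹ min⁻¹ |
| k_cat | 6.0·10⁻³ | molecule⁻¹ min⁻¹ |
| α (base) | 100 (M1–M3), 25 (M7) | – |
| k_replace (M4) | 8.0·10⁻³ | molecule⁻¹ min⁻¹ |
| k_off (M4) | 4.0 | min⁻¹ |

M5/M6 reuse the weak-affinity pair (their only class). M4's off-rate is
the one deliberate departure from full sharing: with the dimer's 10 min⁻¹
the monomer's single weak site barely populates; 4 min⁻¹ gives it
appreciable occupancy and places its persistence (R in the tens) between
the dimer-feedback class (R ≈ 2–7) and the no-feedback class
(R ≈ 150–240), the qualitative ordering the classes are expected to show.
These are modeling choices fixed once at calibration time, not fitted to
any downstream ranking.

## Simulation

Deterministic trajectories integrate the mass-action rate equations with
LSODA (via `scipy.integrate.odeint`) and an analytic Jacobian assembled
from the stoichiometry. The output grid is uniform (0.02 min) over the
onset window and geometric in the tail; after a first pass the
neighborhood of the coarse peak is re-integrated with ~200 extra points so
τ_p is resolved locally to well under 1%. Default tolerances are
rtol 10⁻⁸/atol 10⁻¹⁰ (10⁻⁷/10⁻⁹ inside ensemble sweeps, 10⁻¹⁰/10⁻¹² in
conservation checks). The three linear conservation laws — total Itk,
total PIP3 (free + bound), total inositol units (free IP4 + bound IP4 +
PIP2) — are monitored as the package's main integration-quality invariant
and hold to ≤10⁻⁸ relative drift over 200 min across random parameter
draws.

No-feedback models can decay extremely slowly, leaving the width
statistic undefined on any fixed horizon. The default horizon policy
doubles t_end (initially 200 min) until the readout falls below half its
running maximum, up to a hard cap of 5000 min; trajectories still above
half-max at the cap are flagged `CENSORED_WIDTH` and excluded from
MaxEnt (with counts retained in the table).

Stochastic trajectories use the exact Gillespie direct method on integer
counts, with propensities k·n₁·n₂ (k·n·(n−1) for identical pairs — a case
the current networks do not contain) and NumPy `default_rng` seeding; the
sampler is validated against a matrix-exponential solution of the chemical
master equation on a small binding system. Ensemble means carry a
per-time standard error. At the lowest stimulus (20 Itk, 50 PIP3) the
readout averages below one molecule and the mass-action ODE deviates from
the true master-equation mean by up to ~0.1 molecule in places — a real
mean-field effect, not sampler error; the deviation shrinks as copy
numbers scale up.

## Shape statistics

A is the global maximum of the readout; τ_p the time of its first
attainment (ties resolve to the earliest time); τ_w the total Lebesgue
measure of {t : readout ≥ A/2} under piecewise-linear interpolation
between samples — identical to the first-to-last-crossing span for
unimodal curves but robust to small noise-induced multimodality; and
R = τ_w/τ_p. The half-max threshold is measured from zero, not from a
baseline: for experimental fold-change series (baseline 1) the width is
therefore wider than that of the baseline-subtracted pulse, and the
synthetic generator returns ground truth computed the same way. A series
that ends at or above half-max is `CENSORED_WIDTH`; a constant series or
one whose maximum sits at the first sample is `DEGENERATE`. Both are
excluded from downstream inference and counted.

## Ensembles

Per in-silico cell, every free rate is drawn uniformly (linear scale) in
[base/10, 10·base]; each initial abundance uniformly within ±35% of its
base (read as half-width 0.35, the cited magnitude of extrinsic
expression noise); α per-draw uniformly over its model range. Initial
abundances are rounded to whole molecules. Draws are fully reproducible
from (seed, config) and evaluation is order-independent; solver failures
and invalid summaries become per-sample status codes, never silent drops.
The reference analyses in this package use 2,000–10,000 samples per model;
the statistics are stable in that range (checked by disjoint-block
comparison), while full-scale analyses of this kind conventionally use
100,000 (the package default for `EnsembleConfig.n_samples`).

## Maximum-entropy reweighting

The uniform prior q is the empirical uniform over the n valid samples, so
the constrained problem is finite-dimensional: maximize entropy subject to
Σ w_i f_i = f̄, solved in the dual — minimize
log Σ exp(−λ·(f_i − f̄)) by BFGS with analytic gradient, observables
standardized internally for conditioning (output-invariant), λ initialized
at 0. Convergence requires every constraint's relative residual ≤ 10⁻⁶.
D_KL = Σ w_i log₁₀(w_i n) (entropy is kept in nats internally; the
distance is reported in log10 units). Infeasibility is screened per axis
(a target outside the sampled range of that observable is unattainable by
any tilt) and detected jointly (divergent multipliers with unmet
residuals); both are reported distinctly and rank below every feasible
model, with ties in D_KL broken by model index. Correctness is pinned to a
brute-force primal minimizer of Σ p log₁₀(p/q) over the simplex on small
tables (agreement to 10⁻⁶ in D_KL).

Omitting the amplitude target reproduces the shape-only variant of the
analysis (two multipliers). Robustness maps evaluate the solver per cell
of an (R_avg, A_avg) grid at fixed τ_p_avg and record the best (lowest
D_KL) feasible model per cell plus a feasibility mask.

## Synthetic data

The population generator draws per-cell parameters exactly as the
ensemble module does, simulates each cell (ODE, or SSA when intrinsic
noise is requested), and averages the readout on a common grid — the
quantity a blot on pooled cells reports. The blot generator samples a
known unimodal curve (log-normal pulse, the simplest strictly unimodal
family with independently tunable τ_p and τ_w via
τ_w = 2 τ_p sinh(σ√(2 ln 2)), offset to fold-change baseline 1, or a
supplied population mean) on a blot grid and multiplies both channels by
i.i.d. lognormal noise (σ default 0.15, a typical densitometry
repeatability scale; no measured noise model exists for these assays, so
multiplicative lognormal is the package's choice). What passing these tests shows: the measurement path
(normalization → summarization → MaxEnt) recovers known ground truth.
What they do not show: gel chemistry, antibody saturation, channel-
correlated noise, or single-cell measurement feasibility — none of which
the generators emulate.

## Experimental constants

The stimulus map ties each condition to initial molecule counts
(OVA → 140/530, Q4R7 → 100/370, Q4H7 → 40/130, G4 → 20/50; anti-CD3 and
anti-CD3/CD4 doses reuse these tiers; PIP2⁰ = 17000 throughout). The
published peak-shape table for the four tetramer ligands (τ_p = 2.0 min
for all; τ_w = 3.9/8.6/7.5/4.3 min; R = 1.9/4.3/3.8/2.1) ships as a
fixture; the package reports unrounded R and uses IEEE round-half-even at
one decimal when comparing to the printed values (which that convention
reproduces exactly, including 3.75 → 3.8). The experimental sampling grid
is not published; {0, 1, 2, 5, 10, 15, 30, 60} min is the configurable
default, consistent with a 1-min rise, 2-min peak and 60-min decay.
Constraint presets: τ_p_avg = 2 min with A_avg ∈ {40, 20, 10, 3} for
tetramer stimulation, τ_p_avg = 1 or 5 min with A_avg ∈ {16, 60, 80} for
antibody stimulation; A_avg is a scanned axis, not a measured count, since
blot fold changes relate to molecule numbers only up to an assay-dependent
constant.

## Known limitations

* Mechanisms of Itk dimer formation, signalosome composition, Lck-mediated
  kinase activation and spatial effects are outside all seven models.
* The base rate constants are calibration products, not measurements; all
  downstream statements are about relative robustness of circuit
  topologies under those shared bases, which is the quantity designed to
  be insensitive to them.
* Exact SBML export is not provided; models serialize to JSON.
* At sub-molecule signal levels the deterministic readout is a mean-field
  approximation; single-cell claims at the weakest stimulus should use the
  stochastic path.
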