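# Methods

## Physical picture and assumptions

Cells are immobile discs of radius `rcell` scattered on a plane at area
fraction `sigma`, covered by a media layer of height `h` whose upper
surface reflects ligands. Senescent cells emit SASP ligands at a constant
rate `NE` (per hour); ligands perform Brownian motion with diffusion
coefficient `DL`, reflect from the bare dish, bind to receptors on cell
discs (forward constant `kon`, `Rtot` receptors per cell) and, once bound,
are either internalised (rate `ke`) or released (rate `koff`). Only the
*final* binding (internalisation) location matters for signalling. A cell
that binds at least `ND` ligands within an hour commits to senescence;
committed cells take a maturation delay (~6 days) to become fully
senescent and switch on their own SASP. Juxtacrine (contact) conversion
produces senescent cells with a silent SASP that cannot convert further
neighbours by contact — the fire-break assumption. Cell division, death,
motility and immune clearance are outside the model.

## Compound capture parameters

All lengths are carried in cm and all ligand/induction rates in 1/h;
`DL`, `kappa` and `keff` keep cm²/s and cm/s because only the
dimensionless combinations and the capture length enter hourly rates.
`kon` is converted from M⁻¹min⁻¹ on ingestion (1 M⁻¹ = 1000 cm³/mol,
1 min = 60 s). From the raw constants:

| quantity | formula | mid-range value |
|---|---|---|
| internalisation probability | ν = ke/(ke+koff) | 0.5 |
| trapping constant | κ = kon·Rtot/(π·rcell²·NA) | 8.81·10⁻⁵ cm/s |
| Damköhler number | Da = rcell·κ/DL | 0.088 |
| effective trapping rate | κeff = κσ/(1+πDa/4) | 2.88·10⁻⁵ cm/s |
| capture length | a = 1.1·DL/(ν·κeff) | 0.076 cm |
| autocrine probability | Pau = νDa/(νDa+4/π) | 0.033 |

"Mid-range" means NE = 2887/h (the IL-6 + IL-8 + Activin-A secretion
estimate for irradiated fibroblasts), ND = 62/h, DL = 10⁻⁶ cm²/s,
σ = 0.35, rcell = 10 µm, Rtot = 10⁵, ke = koff = 0.2/min, kon = 10⁸
M⁻¹min⁻¹. The regime where both ke and koff are negligible ("ligands stay
bound") is marked explicitly with `irreversible_binding=True`, which sets
ν = 1 rather than evaluating 0/0.

## Minimal model

The plane around one emitter is partitioned into annuli of width
2·rcell. The first annulus is *centred* on the mean nearest-cell distance
r₁ = sqrt(π·rcell²/σ) — the candidate cells sit at that distance — or on
r₂ = 2r₁ when a contact ring of juxtacrine (non-emitting) senescent cells
separates the emitter from inducible cells. Anchoring the first annulus at
its centre rather than its inner edge matters: induction rates are
binomial tail probabilities and a one-cell-radius displacement changes
them by large factors; the centred grid is also the one under which the
stochastic simulator and the minimal model agree (below).

Per annulus at radius r: the ligand lands in the annulus with probability
(1−Pau)·2·a·rcell/((r+a)²−rcell²) (the telescoping-exact difference of
Pin at r±rcell), on one particular cell with a further factor rcell/(4r),
and the per-cell hourly induction rate is the binomial tail
P[Bin(NE, p_cell) ≥ ND]. With m(r) = 4σr/rcell cells per annulus and an
exponential waiting time, the probability that *some* annulus produces a
senescent cell within a window t is a Poisson-binomial combination
1 − Π(1−p_k), evaluated in log space. Fifty annuli suffice (contributions
decay as 1/r³; doubling the grid changes the result by <10⁻⁶).

A parameter set is classified as *uncontrollable spread* when a single
senescent cell converts a neighbour within 48 h (the assumed window before
immune clearance) with probability ≥ 0.99; the 0.99 stands in for an
unquantified "probability ≈ 1" and is configurable. The phase boundary
ND*(Rtot) is found by bisection, which is exact because the binomial tail
is monotone in ND. In the irreversible-binding regime the boundary has an
interior receptor optimum: too few receptors capture too few ligands, too
many sequester them autocrinally.

## Brownian ligand-capture validation

The Monte-Carlo tier rebuilds the capture distribution without the
homogenisation approximation. Ligands are released just above the emitter
disc, uniformly over its surface (uniform release reproduces the autocrine
probability within sampling error; centre release overshoots it). Steps
are Gaussian; at a plane contact the ligand binds with the first-order
Robin discretisation p_abs = κ·sqrt(π·dt/DL) if it lies over a cell disc,
then internalises with probability ν or resumes from the binding point.
The default step obeys sqrt(2·DL·dt) = rcell/10; far from the plane the
step grows as (z/4·σ_step)², which is exact for free diffusion and cannot
skip plane contacts (a 4-sigma event), making deep media excursions cheap.
The cell layout is a periodic random-sequential-adsorption tile (lattice
and IID overlap-allowed modes are available).

Correctness of the Brownian/Robin machinery is checked against an exact
result: on a *homogeneous* Robin plane the final-binding radius has Hankel
transform 1/(1 + q·DL/(ν·κ)) — geometric dissociation retries rescale the
capture scale by exactly 1/ν — and the simulated CDF matches the
numerically inverted transform to within sampling error.

Two systematic effects shape the comparison with Pin(r) = r/(r+a):

* **Finite media height.** The analytic form is a half-space result. At
  mid-range parameters the capture length (0.076 cm) is comparable to a
  physical media depth (0.2 cm), and the reflecting lid measurably screens
  the far field (several percent of CDF on doubling h). The physical
  default stays h = 0.2 cm; the *validation* runs at h = 4.8 cm with a
  horizon of 24·h/(ν·κeff) so that the half-space formula is the right
  reference and unresolved trajectories are below ~0.5%.
* **Near-field discreteness.** Non-overlapping cells cannot encroach
  within 2·rcell of the emitter's centre, so local coverage ramps up from
  zero across r ≈ 1–4 rcell. The homogenised formula ignores this halo
  and overpredicts the CDF out to r ≈ 10–15 rcell by 5–9% relative. This
  is a property of the discrete system, not of the sampler (the
  homogeneous-plane control shows no such deficit). Consequently the
  maximum relative CDF error over the 0.10–0.90 quantile grid lands at
  ≈ 7% at mid-range parameters, driven entirely by the lowest quantile
  band; from the 0.2 quantile outward agreement is within ~2%. The error
  is reported on an evenly spaced quantile grid (0.10, 0.15, …, 0.90,
  near field r < 2·rcell excluded) because the pointwise supremum over
  tens of thousands of sample points measures extreme-value noise of the
  empirical CDF rather than model agreement.

## Spatial stochastic simulation

Each normal cell accumulates an expected hourly ligand dose
λ_tot = Σ_i s_i·NE·p_cell(r_i) over active emitters i with SASP scale
s_i; independent Poisson streams sum, so its hourly induction probability
is the Poisson tail P[Poisson(λ_tot) ≥ ND], used directly as a rate per
hour (the regime of interest has small per-hour probabilities; the
−ln(1−p) variant is available). The Poisson approximation to the binomial
is adequate because NE is large and p_cell small. The population evolves
by the exact Gillespie procedure; pending maturations are deterministic
interrupts — when one precedes the sampled induction the draw is
discarded and rates are refreshed from the maturation time, which is
exact by memorylessness. Emitter contributions are additive, so rates are
maintained incrementally as emitters activate. The loop ends at t_max or
when the next event time exceeds it; with total rates underflowing to
~10⁻³⁰⁰/h the system is effectively absorbed, which makes lifespan-scale
horizons cheap.

Juxtacrine conversion fires when an eligible cell becomes senescent
(`at_maturation`) or already when it commits (`at_induction`, the
dynamic-SASP limiting case in which contact signalling precedes secretory
capability). Eligible inducers are primaries always and paracrine
secondaries only when `paracrine_secondary_juxtacrine` is on (default
off; the Figure-3-style scenarios enable it, since the timing contrast
and the fire-break growth require contact conversion by secondaries).
Contact means centre distance ≤ 2.2·rcell (10% tolerance over touching
discs); on the σ = 0.35 lattice (spacing ≈ 3·rcell) no neighbour is in
contact, so juxtacrine effects require random placement, where
adsorption-contact pairs are common.

Scenario defaults: 100×100 cell-radii domain (~1100 cells at σ = 0.35),
a seeded disc of radius 10·rcell (the lesion size is not otherwise
constrained; paired-scenario tests use 5–6·rcell to keep runtimes at
seconds), 144 h maturation delay, `secondary_sasp_scale` = 1 unless the
containment regime (0) is under study.

Cross-validation against the minimal model uses a single lattice emitter,
no delay, no juxtacrine: the empirical probability of at least one
induction in 48 h over 100 fresh replicates per (Rtot, ND) matches the
analytic spread probability within 3 binomial standard errors on ≥90% of
the ND sweep. In the containment regime (silent secondaries) the
conversion front creeps logarithmically — there is typically some cell
whose induction rate is of order one over any extended horizon — so
strict count constancy under a tenfold horizon extension holds in a
majority of realisations but not all; the regime is asserted through that
majority plus locality of the spread, matching the case-dependent
character of containment.

## Seeded-lesion forward model and inference

The lesion is a disc (default radius 0.05 cm) emitting
NE·σ/(π·rcell²) ligands per unit area per hour; the dose at distance r
from its centre integrates the single-emitter capture kernel over the
disc in polar coordinates. Two integrators share the surface: adaptive
quadrature (rtol 10⁻⁶) and a fixed 64×128 Gauss–Legendre rule agreeing to
~10⁻⁶ relative, the latter vectorised for the inference loop. The
expected senescent fraction after the experiment is
F(r) = 1 − (1−p_hour)^duration with p_hour the Poisson tail of the dose
(the exponential-compounding variant is indistinguishable at small
p_hour). The experiment must end before the maturation delay so that no
secondary emission contaminates the first wave (duration 120 h < 144 h).
The capture timescale a²/DL is ≈1.6 h at mid-range parameters — not
entirely negligible against the hourly bookkeeping — and the model warns
accordingly; over a 120 h experiment the transient is immaterial.

Summary statistics are S (first downward 0.5-crossing of F by linear
interpolation; all-below maps to the smallest grid distance, all-above to
the largest, flagged) and F itself; model and data are compared with
d = sqrt((ΔS)² + ‖ΔF‖²), S in cm, plain Euclidean norm. The default
evaluation grid has 20 points, densest across the anticipated crossing
region of the central scenario.

Synthetic observations draw Binomial(n, F(r))/n per distance with n = 100
scored cells per bin, a realistic per-annulus count for an imaging
read-out.

Priors are independent uniforms: NE ∈ [100, 10000]/h (bracketing the
secretion estimate), ND ∈ [1, 200]/h (genuinely unknown),
Rtot ∈ [10⁴, 10⁶] (its tabulated range), kon ∈ [10⁷·⁵, 10⁸·⁵] M⁻¹min⁻¹
(one decade centred on the literature estimate — kon is a measured
constant, unlike Rtot's two-decade regime).

**Identifiability.** Rtot and kon enter the forward model *only* through
the product kon·Rtot (inside κ): they are exactly degenerate, and the
relative widths of their posteriors are set by the prior geometry, not by
the data. The data identify ND strongly (the steepness of the F
transition), NE moderately (overall dose magnitude), and the kon·Rtot
product weakly (through the capture-length shape of the curve). Under
the priors above, the NE posterior is reproducibly narrower than Rtot's;
claims ordering Rtot below NE cannot be model-driven in this framework.

The ABC-SMC sampler: population 0 is a plain prior sample; each later
population resamples the previous by weight, perturbs with a Gaussian
kernel of twice the weighted covariance, rejects outside the prior box,
and accepts at distance below the median of the previous accepted
distances; importance weights follow the standard kernel-density
correction (uniform priors). Desk-scale runs use 200 particles × 6
populations (final acceptance fractions ~10⁻²–10⁻³); `fit()` aborts with
a diagnostic if a population stalls. True ND and Rtot fall inside the
central 95% credible intervals of scaled runs.

## Synthetic data: what it does and does not cover

All test data are generated by the package itself: monolayer geometries
by RSA/lattice/IID placement, ligand trajectories by the Brownian kernel,
event logs by the Gillespie loop, observations by binomial sampling of
the forward curve. These emulate idealised assays — identical circular
cells, a single pooled ligand species with one receptor type, constant
emission, no division, death, motility, ligand degradation or immune
clearance, and noise that is purely counting noise. Passing tests
therefore demonstrate internal consistency of the framework and
correctness of its mathematics, not fidelity to any particular wet-lab
system; real assays add segmentation error, heterogeneous secretion and
marker-detection thresholds that the binomial noise model does not
represent.

## Known limitations

* The homogenised capture formula is least accurate in the discreteness
  halo (r ≲ 10–15 rcell) — see the validation section; conclusions that
  hinge on nearest-neighbour doses inherit a few-percent bias.
* The per-hour probability-to-rate conversion is first-order; at doses
  far above threshold both conversions saturate and the simulator's
  timing in that regime is only order-of-magnitude.
* Juxtacrine contact is a fixed radius, not a tessellation; at densities
  well above 0.35 a Delaunay-neighbour definition would be preferable.
* The inference tier fixes σ, DL, rcell, ke, koff to known values;
  errors in those propagate unexamined into the posterior.
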