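# Methods

## Model structure and assumptions

The network couples six dynamic species — FT (leaf), AGL24, SOC1, LFY, AP1,
FD (meristem) — through Hill-type regulation: activation x^n/(K^n + x^n),
repression K/(K + x). FLC and SVP are external forcings (leaf and meristem
profiles each), because nothing inside the network regulates them. The
equations encode: SVP and FLC repressing *FT* (leaf) and *SOC1* (meristem)
as dimers, represented by multiplied repression gates; FT·FD complex
formation activating *SOC1* and *AP1*, represented by a product of the two
activation terms; AGL24, SOC1 self-activation and FT·FD jointly driving
*SOC1*; AGL24, SOC1 and the AP1 feedback independently driving *LFY*;
cooperative LFY activation of *AP1* (Hill coefficient n = 3; every other
exponent is 1, since expression data showed no evidence of cooperativity
elsewhere); and LFY driving *FD*. Spatial structure is ignored except FT
transport: meristem equations read leaf FT at t − Δ. mRNA and protein are
not distinguished (one species per gene, linear mRNA→protein assumed), and
bridging factors such as 14-3-3 proteins are taken as non-limiting.

Units: abundances in nM (anchored by the 500 nM normalisation ceiling, an
average cellular protein abundance), time in days after germination,
horizon days 0–20.

An alternative LFY wiring ("dimer_only") replaces the two independent
activation terms by a single heterodimer term
β7·hill(AGL24; K10)·hill(SOC1; K11) with β6 structurally absent. The
printed variant equation is not available, so this product-of-Hills form —
mirroring the FT·FD treatment — is this package's documented convention.

## Numerical integration of the delayed system

Only FT is delayed, and the leaf-FT equation depends solely on the external
inputs. The system is therefore triangular in the delayed variable: leaf FT
is integrated first over the whole horizon (LSODA, rtol 1e−6, atol 1e−9 nM),
and the five meristem species are then integrated against the lagged FT
interpolant. This closes the method-of-steps recursion in one pass and is
exact for this wiring. Pre-horizon FT history is the constant initial FT
value. Output is sampled on a 0.05-day grid unioned with requested
observation days; solver undershoot below zero (order atol) is clipped.
Clamped species (mutants) are held at k_mut with derivative zero; an FT
clamp applies to the leaf equation and every delayed occurrence.

## Normalisation

Relative expression per record is E = 2^ΔCt with ΔCt = Ct_target −
Ct_reference, taken as printed in the source protocol; the widely used
opposite convention 2^−ΔCt is available via `sign_convention="conventional"`
and neither is asserted as correct. The scaling factor is defined by its net
effect: s = max_abundance / max(E), so the dataset maximum is exactly the
ceiling (500 nM default). Replicates are summarised by mean and sample sd
(n−1); single-replicate days carry no sd rather than sd 0.

## Two-stage parameter estimation

Stage 1 (decoupled): each equation is fitted on its own, with every
regulator trajectory (including self-activation occurrences) interpolated
from the replicate means (natural cubic spline by default, clipped at 0; a
global polynomial of configurable degree is available). Each decoupled
equation is then *linear* in its own state, dx/dt = P(t; θ) − d·x, and is
solved exactly by an integrating-factor quadrature on a 401-point uniform
grid (exponential-trapezoid recurrence, evaluated as an IIR filter). That
makes one objective evaluation a few vectorised array operations, so
multistart is cheap. Optimisation is bounded least squares (scipy TRF) from
seeded random starts: β and Δ uniform, K and d log-uniform within bounds.
Default bounds, scaled to the data ceiling a: β ∈ [0, 10a] nM/day,
K ∈ [10⁻³, 10a] nM, d ∈ [10⁻³, 10] /day, Δ ∈ [0, 5] d. The transport delay
is a free parameter of the SOC1 equation fit (where the lagged leaf-FT data
interpolant enters); the AP1 fit reuses that single estimate, so Δ has one
stage-1 value.

Stage 2 (coupled refinement): the concatenated stage-1 estimates start a
bounded least-squares fit of the fully coupled simulation against all six
time courses at once (unweighted replicate means by default; 1/sd weights by
flag). Failed trial integrations contribute a large penalty residual. The
returned set never has a larger coupled objective than the starting point.

Goodness of fit: NRMSE = RMSE/(x_max − x_min) per gene, residuals at the
observation days against replicate means. A constant observed series has no
defined NRMSE (error in the public function; NaN in batch diagnostics).

Hill-coefficient selection refits the model for each candidate n (the
LFY→AP1 term only) and returns the n minimising AP1 NRMSE, with the full
table reported. Selection can be scored on the decoupled stage alone
(`refine=False`), which is what the bundled tests use: only the AP1 equation
depends on n, the decoupled AP1 NRMSE already separates candidates cleanly
on noise-free data, and it runs an order of magnitude faster.

### Identifiability caveats

* The transport delay Δ is weakly identified: it enters only through the
  lagged-FT activation terms, whose shape changes slowly with Δ. Recovered
  trajectories are accurate even when Δ lands away from the truth (it can
  hit its bound on noisy data); do not over-interpret the Δ estimate.
* The dimer-only LFY variant is *not* automatically penalised on data
  generated under independent regulation: when one activator dominates or
  the AGL24/SOC1 trajectories are near-proportional (structurally common,
  since AGL24 is itself SOC1-driven), the product term can collapse one
  Hill gate (K at its floor) and mimic a single-activator term. A fit
  penalty appears only when both activators contribute comparably with
  distinguishable dynamics. The behavioural signature is more robust:
  under dimer-only wiring, *soc1* and *agl24* knockouts produce identical
  LFY trajectories, which contradicts observation.

## Mutants, expression changes, significance

Knockouts clamp a gene at 0, knockdowns at a configurable fraction (default
10%) of the wild-type first time point, overexpressors at 2500 nM (five
times the ceiling; a constant-in-time 35S idealisation). FLC/SVP mutants
rewrite both tissue input profiles instead of clamping a state. Network-wide
effects are summarised per gene by the relative change of the trapezoid
integral of expression over days 0–20 against wild type. Correlations
between predicted and observed vectors get a permutation p-value:
p = (1 + #{|r*| ≥ |r|})/(1 + permutations), permuting the observed vector
under a fixed seed.

## Flowering-time readout

The wild-type simulation is anchored at day 12.6 — the observed mean
wild-type rosette-leaf count — and the simulated AP1 level there defines a
threshold assumed invariant across genotypes and conditions. A mutant's
transition day is the *first* up-crossing of that threshold (sub-grid linear
interpolation); trajectories that never cross within the horizon return a
no-flowering sentinel (inf). Days map to rosette leaves affinely, anchored
at (12.6 d, 12.6 RL); the slope is not identified by the anchor and defaults
to 1 RL/day, making days and leaves numerically interchangeable at the
anchor. Literature flowering times measured under other conditions are
rescaled by the factor that maps that study's wild type onto 12.6 RL.

## Synthetic studies

The generator reproduces the real study design: 13 near-daily sampling
points over days 0–20 (round(linspace) onto integer days), duplicate
replicates, multiplicative mean-one log-normal noise (default CV 10%;
additive Gaussian by flag), and a final rescaling putting the dataset
maximum at 500 nM. FLC/SVP inputs are smoothly declining sigmoids (floral
repressors waning over the vegetative phase) with seeded variation in
amplitude, midpoint and width; leaf amplitudes exceed meristem amplitudes.

The fixed reference parameter set was chosen once, on realism grounds: FT
rises in the leaf as its repressors decline; SOC1, AGL24 and LFY build up
through the mutually reinforcing meristem loops; AP1 stays low for ~12 days
and then rises steeply through the cooperative LFY term, with its half-rise
near day 12.5; and SOC1 is a much stronger LFY activator than AGL24
(β7 = 60 vs β6 = 6 nM/day) with similar binding constants (K11 = 90,
K10 = 70 nM), the asymmetry that makes *soc1* and *agl24* knockouts behave
differently. Under this set a *soc1* knockout suppresses AP1 below the
wild-type threshold for the whole horizon and reports the no-flowering
sentinel. Random ground truths are log-normal jitters (sd 0.25) of the
reference, rejection-sampled until the wild-type AP1 half-rise falls within
days 5–19.

What passing tests on synthetic data do and do not show: they demonstrate
that the estimation machinery recovers dynamics generated by the model class
itself under the stated noise; they cannot certify fit quality on real
tissue data, which carries structured (non-log-normal) variability,
model-misspecification error and day-to-day biology the generator does not
emulate (no diurnal sampling effects, no reference-gene instability, no
replicate correlation).

## Problem sizes and tolerances used by the bundled checks

Decoupled fits use 12 multistarts (8 for model selection) on the 401-point
quadrature grid; coupled refinements cap at 60 objective evaluations;
closed-form integrator checks run at rtol 1e−10 and assert at 1e−6/1e−8;
permutation calibration uses 400 null datasets of 10 pairs with 199
permutations each. These sizes were chosen so the whole verification runs
comfortably on a laptop while leaving each check's conclusion unchanged at
larger settings.
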