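# Methods

This note documents the models, statistics and numerical choices behind
`soilprime`, and what the synthetic-data generators do and do not emulate.

## Isotope partitioning of respiration

Headspace CO2 and 13CO2 mixing ratios (ppm) are converted to moles with
the ideal gas law `n = PV/(RT)` (defaults: 25 ml headspace, 101 kPa,
298 K, R = 8.314 J K⁻¹ mol⁻¹). The fraction of respired CO2-C derived
from an isotopically labeled substrate follows from two-pool mixing

    f = (A_C − A_T) / (A_C − A_L)

where `A_C` is the isotope composition of basal (no-substrate) CO2,
`A_T` of CO2 respired with labeled substrate, and `A_L` of the substrate
itself. The formula is stated in the literature in δ¹³C notation;
`soilprime` converts δ to atom fraction via the VPDB ratio (0.0111802)
and mixes in atom fraction, which is exact (δ mixing is only
approximate because δ is a nonlinear function of atom fraction).
Fractions are computed per day — the labile substrate depletes, so the
fraction drifts over an incubation — and applied to each day's efflux
before summation. Values nudged outside [0, 1] by replicate noise are
clamped with a warning rather than rejected.

The priming partition for each replicate is exact bookkeeping:

    primed = total(with straw) − substrate-derived − basal(no straw)

Negative primed values are legitimate results (negative priming), not
errors. The net soil-C effect of an addition combines replenishment
(added C left after microbial respiration) with primed native-C loss;
with positive priming defined as a loss, `net = replenishment − primed`.
A `sign_convention="gain"` switch flips the sign for bookkeeping systems
that record priming with the opposite sense. The mass of substrate C
added is an explicit input everywhere (nominally 10 mg C per g soil for
0.1 g straw in 5 g soil; the straw contains 40.10% C and 1.70% N, a C:N
ratio of about 24, with 75.1 atom% ¹³C in the labeled batch).

## qSIP active-decomposer detection

For every ASV and sample, the buoyant density is summarised as the
abundance-weighted mean over the 24 CsCl gradient fractions. The density
shift of an ASV is the difference between its weighted density in the
¹³C-straw sample and the paired ¹²C-straw sample, paired within
biological replicate (a `pooled` pairing against the mean of all ¹²C
samples is available). A percentile bootstrap (default 1000 resamples)
over the replicate shift vector yields a 90% confidence interval; the
ASV is called an active decomposer when the interval's lower bound is
above zero. Resampling is over replicates, not fractions, because the
shift is defined at replicate level. With only four replicates every
replicate-resampling interval (percentile, basic, BCa — all measured by
simulation) has a true one-sided error near 12%, not the nominal 5%;
this anticonservatism is a property of the tiny sample, not of the
interval type, and users should expect a corresponding share of false
positives among called decomposers. The sensitivity of the rule at the
default effect size (0.02 g/ml shift against 0.003 g/ml noise) is
essentially one.

Absolute abundances scale relative ASV abundance by the total 16S copy
number per gram of soil,

    A_total = (Σ_i a_i) · Ve · Vr / (Vd · M)

with per-fraction qPCR concentrations `a_i` (copies/µl), elution volume
`Ve`, resuspension volume `Vr`, loaded volume `Vd` and soil mass `M`
(defaults 100 µl, 35 µl, 5 µl, 0.25 g). An optional per-ASV 16S copy
number divides the abundances. The community active fraction is the
summed absolute abundance of active ASVs over that of all ASVs. ASVs
absent from either isotope treatment are excluded from calling rather
than scored zero.

## The microbial-explicit decomposition model

Nine pools per isotope channel: two particulate organic carbon pools
(`P_O` oxidisable, `P_H` hydrolysable), mineral-associated carbon `M`,
dissolved organic carbon `D`, active and dormant microbial biomass
(`B_A`, `B_D`), oxidative and hydrolytic enzymes (`E_O`, `E_H`) and
cumulative CO2. Fluxes (per hour, mg C/g soil):

* POC decomposition `F_j = VP_j·E_j·P_j/(KP_j+P_j)·fT·fW·fpH` with the
  hydrolytic enzyme acting on `P_H` and the oxidative on `P_O`; MOC
  decomposition `F_M = VM·E_O·M/(KM+M)·scalars`. A fraction `f_D` of
  POC decomposition goes to DOC, the rest to MOC; `F_M` goes to DOC.
* DOC uptake `U = (1/Yg(T))·(Vg+Vmt)·S·B_A·scalars` with substrate
  saturation `S = D/(K_D+D)`; growth C (`Vg·S·B_A·scalars`) enters
  `B_A`, maintenance (`Vmt·S·B_A·scalars`) and the yield overflow go to
  CO2. `Vmt = α·Vg/(1−α)` and `Yg(T) = max(Yg_min, Yg − k_Yg(T−Tref))`.
* Dormancy `ψ_A2D·(1−S)·B_A` and resuscitation `ψ_A2D·S·B_D` share one
  rate constant, gated oppositely by `S`; dormant maintenance is
  `β·Vmt·B_D`.
* Enzyme production `p_EP·B_A` (hydrolytic) and `fp_EM·p_EP·B_A`
  (oxidative) drawn from `B_A`; enzyme turnover `r_E·E_j` returns to
  DOC; mortality `k_B·B_A` splits `g_D` to DOC and the rest to `P_H`.
* Environmental scalars: `fT = Q10^((T−Tref)/10)`,
  `fW = min(1, (θ/θ_ref)^0.5)`, `fpH = exp(−((pH−pH_opt)/σ_pH)²/2)`.

Isotope tracing: nonlinear fluxes are computed on channel-summed pools
and split pro rata by the label fraction of each flux's source pool.
Because both the labeled mass and any "origin" tracer satisfy the same
linear transport equations given the combined trajectory, superposition
holds exactly: labeled + unlabeled reproduces a combined-carbon run to
machine precision, and a tracer twin with unlabeled background and
fully-labeled substrate yields the exact substrate-derived CO2. This is
what makes the closed-loop check of the priming partition exact.

Integration is classical RK4 with step halving whenever a step would
drive any pool below −10⁻⁹ (roundoff-scale negatives are accepted
unchanged so mass conservation stays exact; outflows from empty pools
are clipped inside the derivative). A numba-compiled kernel carries the
integration; the pure-Python implementation remains as the documented
reference and the test suite asserts the two produce bit-identical
trajectories. Default steps: 2 h for 7-day incubations, 6 h for
multi-year field runs (24 h in the scaled test configurations); mass
balance holds to better than 1e−8 relative over 7 simulated years at
these settings.

Defaults represent a tallgrass-prairie topsoil: ~21 mg C/g in organic
pools (4/6/10 P_O/P_H/M), 1 mg C/g microbial biomass with 35% active,
enzyme stocks ~10% of biomass, basal respiration a few hundred µg C/g
per week at 25 °C, and positive priming of order 100–200 µg C/g per
week after a 10 mg C/g straw pulse — the same order as field-derived
incubations report. Fixed constants (`VP`, `KP`, `VM`, `KM`, `k_B`,
`Tref = 20 °C`, `Yg_min = 0.2`) are class attributes and overridable.
`VM` was chosen so the mineral pool's equilibrium under steady litter
input sits near its initial stock; even so its equilibration time
constant is multi-decadal, so `spin_up()` integrates in 50-year chunks
until total pool carbon drifts by less than 0.1%/year (capped at
300 years) rather than stopping at a fixed horizon.

Warming legacy in the laboratory generator is emulated by a +3 °C
offset on the response-function temperature plus a 1.4× multiplier on
the initial active biomass and enzyme stocks of warmed-soil runs; the
in-situ warming signal proper is an emergent property the generator
only mimics.

## The first-order comparison model

Seven pools (foliage, root, metabolic and structural litter, fast/slow/
passive SOM) decompose at `k_i·C_i·ξ(T,θ)` with
`ξ = Q10^((T−Tref)/10)·θ^b`; a fixed CENTURY-lineage transfer matrix
routes decomposed C between pools and the column remainder is respired.
GPP-derived input enters the plant pools (60:40 foliage:root). The
model is linear in pool sizes, matches single-pool exponential decay
within 0.1% at a daily RK4 step, and exposes ten calibrated parameters
(seven turnover rates, Q10-type temperature sensitivity, moisture
exponent, reference temperature).

## Calibration, COFI uncertainty, and the model experiments

Fit statistics: `MARE = mean|sim−obs|/|obs|` for sparse variables with
comparable absolute values, `R² = 1 − SSE/SST` for densely observed
Rh, and Pearson `r` for series observed only up to an unknown positive
scale (functional-gene proxies of enzyme concentration, mapped into the
objective as `(1−r)/2`). The composite objective is the weighted sum
`J = Σ w_i J_i`, weights on the simplex; presets put 5/8 on cumulative
CO2 in the laboratory (enzymes and active fraction 1/8 each, all MARE)
and 5/9 on Rh in the field (MBC and active fraction by MARE, the two
enzyme-gene correlations by `(1−r)/2`, 1/9 each).

The optimizer is seeded differential evolution with every evaluation
archived, followed by an archived polish designed for the flat
compensation valley (notably α–Yg) that dominates the near-optimal
surface: simplex descents from several well-separated starts, then a
profile stage that identifies the valley's dominant parameter from the
sloppiest eigendirection of a finite-difference Hessian at the
incumbent, pins it on a grid spanning its bounds, solves the
better-conditioned subproblem at each pin by warm-started continuation
(in normalised coordinates with an explicit wide simplex), refines the
winning pin by golden section, and finishes with a full-space simplex
polish. Plain descent — Nelder-Mead or Powell — reliably stalls at an
arbitrary point of this valley or in a deceptive secondary basin;
profiling is the standard treatment for sloppy kinetic models. Model
failures during search receive a penalty objective and the search
continues.

Parameter uncertainty uses the critical objective function index

    J_cr = J_opt · (1 + p/(n−p) · F(α; p, n−p)),   α = 0.05

with `p` calibrated parameters and `n` observations (the laboratory
default is n = 48: 42 respiration points from the four incubation
cases plus 6 microbial points). Every archived vector with `J ≤ J_cr`
is feasible; per-parameter ranges are the min/max over the feasible
set and the CV is sample-sd/mean (a range-based CV is available behind
a flag). The threshold uses `max(J_opt, J_floor)` with an
observational-precision floor `J_floor = 10⁻³`: parameter vectors whose
predictions agree with the observations to better than roughly three
significant figures cannot be distinguished by the data, and without
the floor the multiplicative threshold degenerates as `J_opt → 0` (an
exact fit would claim zero parameter uncertainty, an artefact of the
noise-free limit rather than a statement about identifiability). Because a global search alone leaves the archive sparse below
`J_cr`, `fit()` spends a fraction of its budget on refinement: tracing
the `J_cr` crossing outward from the optimum along every parameter
axis; walking the compensation valley by pinning its dominant
(Hessian-identified) parameter at increasing offsets and re-optimising
the remaining sloppy parameters by continuation; and adaptive Gaussian
sampling whose step tunes itself to the feasible acceptance rate.
These stages iterate to a fixpoint — on an under-converged surface any
stage can still lower the optimum, which invalidates earlier feasible
points — stopping when the optimum is stable and the feasible set is
populated. All refinement evaluations use the true objective and enter
the archive, so reported ranges always reflect actual objective
values, never a sampler's assumption.

The five data-combination experiments calibrate (i) the first-order
model against Rh; the microbial model against (ii) Rh + enzyme genes,
(iii) + active fraction, (iv) Rh + genes with the laboratory COFI
ranges replacing the prior bounds of the five lab-calibrated
parameters, and (v) all streams with those priors. Mean parameter CV
per experiment, by seed, is the comparison metric. Parameter
sensitivity screening is Morris-type elementary effects (radial
one-at-a-time design, mean |effect| ranking). The complexity sweep
splits the observation record temporally (first 3/4 trains), ranks
parameters once by sensitivity, and for each k calibrates the top-k
with the rest at defaults, reporting train/test unexplained Rh
variance (1−R²) and mean COFI CV.

## PLS, VIP and partial R²

Single-response PLS via NIPALS on centred/scaled data, with
per-component unit-norm weight vectors `W_f` and explained response
sums of squares `SSY_f` from sequential deflation. The per-predictor
variance apportionment is

    partialR²_j = Σ_f (W_jf² · SSY_f) / SSY = R²Y · VIP_j² / p

which sums exactly to R²Y over predictors because Σ_j W_jf² = 1. Q²Y is
k-fold cross-validated (deterministic contiguous folds, default 7);
when the component count is not given it maximises Q²Y (capped at 5).
Permutation significance permutes the response, refits with the same
component count, and uses the add-one estimator
`p = (1 + #{stat_perm ≥ stat_obs})/(1 + n_perm)` for both R²Y and Q²Y.
Forward selection greedily adds the predictor that maximises Q²Y and
stops when the augmented model loses permutation significance (at
α = 0.05) for either R²Y or Q²Y; community composition enters as the
top PCoA axes (classical metric scaling, via scikit-bio) of the
Bray–Curtis dissimilarity.

The response-ratio test is the standard log-ratio z-test:
`RR = ln(mean_t/mean_c)` with delta-method standard error
`SE² = sd_t²/(n_t·mean_t²) + sd_c²/(n_c·mean_c²)`; one-sided
alternatives are supported. With group SDs estimated from n≈4–6
replicates the z-interval is mildly anticonservative; the null
rejection rate approaches the nominal α for larger groups.

## Synthetic data: what it emulates, what it does not

The generators reproduce the *design* of a warming × straw-amendment
study — 7-day dual-isotope incubations (4 replicates × warmed/control ×
no straw/¹²C/¹³C straw), 24-fraction density profiles, and multi-year
daily forcing with sparse microbial observations — from a known
parameter vector, with multiplicative lognormal noise everywhere (all
observed quantities are positive). Respiration noise is applied as a
shared factor to a replicate-day's total and ¹³C channel (a common
gas-handling error), which preserves the ¹³C ≤ total bound. qSIP
profiles are Gaussian bands (sd 0.008 g/ml, typical of CsCl gradients)
discretized on the fraction grid with a first-moment correction so that
the weighted-density estimator recovers zero-noise shifts exactly; the
labeled taxa's ¹³C-sample band centres shift by
N(density_shift_mean, density_noise_sd). Field forcing is sinusoidal
plus weather noise; gene abundances are enzyme concentrations times an
arbitrary positive scale, which is what motivates the correlation-based
enzyme objective.

Not emulated: sequencing reads and their error structure, compositional
artefacts of rarefaction, GC-dependent density offsets, fractionation,
spatial heterogeneity, nitrogen limitation, and realistic
autocorrelated weather. Passing tests therefore demonstrate that the
estimators and the calibration machinery recover known truth under the
stated noise model — not that they are robust to every artefact of real
amplicon or flux data.

## Problem sizes

The default test and acceptance configurations run at desk scale: 3000
objective evaluations per laboratory calibration (three seeds), one
synthetic field year at a 24-hour step with a 5-year spin-up and a
4000-evaluation budget for the model experiments, 1000 bootstrap
resamples for qSIP calls, and 100 random datasets for the PLS
identities. The generator defaults describe the full study design
(7 field years, 200 ASVs, 4 replicates); the smaller sizes used in the
test harness are stated at each call site.
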