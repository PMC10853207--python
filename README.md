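# soilprime

Tools for the computational chain behind soil-warming × priming
incubation studies: partitioning respired CO₂ into straw-derived and
native soil carbon with dual-isotope (¹³C) mixing, detecting active
bacterial decomposers by quantitative stable isotope probing (qSIP),
simulating soil carbon with a microbial-explicit enzyme model (and a
CENTURY-style first-order comparison model), calibrating either model
against multi-stream observations with formal parameter-uncertainty
quantification, and apportioning explained variance among drivers with
a PLS partial-R² statistic. A synthetic-data module generates every
input table from known ground truth, so the whole chain is testable
end to end.

Intended users: soil microbial ecologists and biogeochemical modellers
who run straw-amendment / SIP incubations or assimilate field flux and
microbial data into process models.

## The core models and statistics

**Isotope partitioning.** The substrate-derived fraction of respired
CO₂ follows two-pool mixing, `f = (A_C − A_T)/(A_C − A_L)`, with
A-values the isotope compositions (atom fraction ¹³C) of basal CO₂,
treatment CO₂ and the labeled straw. Primed C is
`total(with straw) − substrate-derived − basal`, per replicate.

**qSIP.** An ASV is an active decomposer when the lower bound of a 90%
bootstrap confidence interval on its mean replicate density shift
(¹³C-sample weighted density minus paired ¹²C-sample weighted density,
over 24 CsCl fractions) is above zero. Absolute abundances scale by
`A_total = Σa_i · Ve·Vr/(Vd·M)` copies per g soil.

**Microbial-explicit model.** Nine pools per isotope channel (two POC
pools, MOC, DOC, active/dormant biomass, two enzyme classes, CO₂) with
Michaelis–Menten enzyme kinetics, substrate-gated dormancy, a
temperature-dependent growth yield `Yg(T) = max(Yg_min, Yg − k_Yg ΔT)`,
and Q10/moisture/pH rate scalars. Dual isotope channels are traced
pro rata through every flux, so priming emerges mechanistically and can
be measured exactly against the model's own tracer.

**Calibration and COFI.** A seeded archiving optimizer minimises
`J = Σ w_i J_i` (MARE / 1−R² / (1−r)/2 components); the feasible
parameter set is every archived vector with
`J ≤ J_cr = max(J_opt, J_floor)·(1 + p/(n−p)·F(0.05; p, n−p))`,
yielding per-parameter uncertainty ranges and CVs.

**PLS partial R².** For a NIPALS PLS1 model with unit-norm weights
`W_jf` and per-component explained response sums of squares `SSY_f`,
`partialR²_j = Σ_f W_jf²·SSY_f / SSY = R²Y·VIP_j²/p`, which apportions
R²Y exactly among predictors.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```python
import soilprime as sp

cfg = sp.SynthConfig(seed=7)                      # known ground truth
series, truth = sp.make_lab_incubation(cfg)       # 7-day incubation table
priming = sp.partition_respiration(
    series, straw_atom13=cfg.lab_setup.straw_atom13)
print(priming.summary()[["treatment", "primed_mean", "primed_std"]])

ds, qtruth = sp.make_qsip_dataset(cfg)            # 24-fraction qSIP tables
calls, samples = sp.call_active_and_fraction(ds, n_boot=1000, seed=7)
print(f"{int(calls.is_active.sum())} of {cfg.n_asvs} ASVs called active; "
      f"mean active fraction "
      f"{samples[samples.isotope_label=='c13'].active_fraction.mean():.3f}")

model = sp.LabMendModel(truth["observables"])     # noise-free assimilation
result = model.fit(budget=800, seed=7)
print(result.summary().round(4))
```

prints

```
  treatment  primed_mean  primed_std
0   control   217.333722   10.469487
1    warmed   220.364473   19.333705
48 of 200 ASVs called active; mean active fraction 0.311
  parameter    best  feasible_min  feasible_max      cv
0      p_ep  0.0020        0.0020        0.0020  0.0007
1       v_g  0.0200        0.0200        0.0202  0.0023
2     alpha  0.1968        0.1457        0.2696  0.0995
3       k_d  0.2519        0.2489        0.2571  0.0061
4       y_g  0.4482        0.4226        0.4905  0.0257
```

The priming table says straw addition made the soil respire ~217 µg
native C per g beyond the no-straw basal rate in control soil and ~220
in warmed soil (positive priming). The qSIP caller flags all 20 truly
labeled ASVs plus 28 false positives — the bootstrap CI over four
replicates is anticonservative, a known small-sample property discussed
in `docs/methods.md`. The calibration summary shows each microbial
parameter's best-fit value with its COFI feasible range and CV; the
true values (0.002, 0.02, 0.2, 0.25, 0.45) all lie inside their ranges,
with the maintenance ratio α the least identifiable (widest range,
CV ≈ 0.1) because it trades off against the growth yield.

A command-line interface wraps the same library:

```sh
soilprime synth --seed 7 --outdir demo      # write input tables
soilprime priming demo/respiration_series.csv
soilprime run --seed 7 --outdir full_run    # full pipeline
```

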