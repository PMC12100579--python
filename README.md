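# thermacclim

Thermal-acclimation analysis of leaf photosynthesis for multi-site
gas-exchange campaigns: fit the Farquhar–von Caemmerer–Berry (FvCB) model to
A–Ci curves measured at several leaf temperatures, characterise the
temperature response of net photosynthesis and of the apparent photosynthetic
capacities, derive acclimation metrics, run stomatal/respiratory
counterfactuals, and relate photosynthesis at growth temperature to tree
growth. A synthetic campaign generator with known ground truth backs every
stage with recovery tests.

## Who this is for

Plant ecophysiologists analysing LI-COR-style A–Ci campaigns across
temperature or elevation gradients (e.g. common-garden thermosequence
experiments with montane and lowland tropical tree species), and anyone who
needs a tested, scriptable implementation of the standard analysis chain
rather than a pile of one-off scripts.

## The models

**FvCB photosynthesis.** Net CO2 assimilation is the minimum of the
Rubisco-limited and RuBP-regeneration-limited rates,

```
Ac = Vcmax (Ci − Γ*) / (Ci + Kc (1 + O/Ko)) − Rday
Aj = (Jmax/4) (Ci − Γ*) / (Ci + 2Γ*) − Rday
A  = min(Ac, Aj)
```

with Bernacchi (2001) temperature scaling of Γ*, Kc, Ko. Vcmax and Jmax are
*apparent* (Ci-based) values; mesophyll conductance is deliberately not
modelled. Each A–Ci curve is fit by the **bilinear method**: both branches
are linear in their parameters once kinetics are fixed, so every admissible
split of the Ci-sorted points into a low-Ci (Rubisco) and high-Ci (RuBP)
regime is solved exactly by least squares, and the split with the smallest
total SSE wins.

**Temperature responses.** Apparent Vcmax and Jmax across leaf temperatures
follow a peaked (modified) Arrhenius function in its optimum
parameterisation, with the deactivation energy fixed at Hd = 200 kJ mol⁻¹:

```
f(Tk) = kopt · Hd exp[Ea (Tk−Topt)/(Tk R Topt)] / (Hd − Ea (1 − exp[Hd (Tk−Topt)/(Tk R Topt)]))
```

Net photosynthesis at ambient CO2 versus leaf temperature is summarised by a
parabola `A(T) = Aopt − b (T − ToptA)²`, giving the thermal optimum ToptA,
its breadth `b`, the high-temperature compensation point
`Tmax = √(Aopt/b) + ToptA`, and `Agrowth`, the rate at the site's mean
daytime growth temperature (21.4, 24.3, 31.2 °C for the 14, 22, 26 °C MAT
sites). Acclimation is quantified as °C of optimum shift per °C of
between-site MAT difference.

**Counterfactuals.** ToptA is recomputed (i) at a common Ci of
287 µmol mol⁻¹ (Ci/Ca = 0.7 at 410 µmol mol⁻¹), removing stomatal CO2-supply
effects, and (ii) for gross photosynthesis (Rday not subtracted), removing
respiratory drag; Welch t-tests compare observed and counterfactual optima.

**Growth.** Relative growth rate per tree is
`RGR = (ln Dᵢ − ln D₀)/(tᵢ − t₀)` from quarterly diameter censuses, and a
one-sided regression asks whether Agrowth predicts RGR across species×site
means. Trait differences are tested by two-way ANOVA (site × provenance
group, type-II sums of squares for the unbalanced design) with Levene and
Shapiro–Wilk checks and Šidák-adjusted post hoc contrasts.

## Worked example

```python
import thermacclim as ta

cfg = ta.default_truth_config(seed=1)          # 13 species, 3 sites, 4 trees each
ds = ta.simulate_campaign(cfg)                 # gas exchange + growth + truth
bundle = ta.run_pipeline(ta.PipelineConfig(),
                         gasx=ds.gas_exchange, growth=ds.growth)
print(bundle["shift_table"])
print(bundle["rgr_regression"])
```

prints (seed 1):

```
    group site_from site_to  shift_per_degC
lowland22        14      22        0.065082
lowland22        22      26        0.928691
lowland26        14      22        0.196360
lowland26        22      26        0.091707
montane14        14      22        0.590419

RGR ~ Agrowth: slope=0.0091 r2=0.255 p(one-sided)=0.002227 n=30
```

The montane group's thermal optimum shifts by ≈0.6 °C per °C of warming
between the 14 °C and 22 °C sites — recovering the 0.6 °C/°C acclimation
built into the generator's truth — while lowland species barely shift when
cooled. Net photosynthesis at growth temperature explains ≈26 % of the
variance in relative growth rate here (the generator couples them at 30 %).

The same chain is scriptable from a shell:

```bash
thermacclim simulate --seed 1 --out scratch/sim
thermacclim fit-aci --in scratch/sim/gas_exchange.csv --out scratch/fits.csv
```

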