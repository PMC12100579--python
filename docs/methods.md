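# Methods

## Scope and units

The package analyses leaf gas-exchange campaigns in which each tree is
measured with one A–Ci curve per leaf-temperature setpoint (CO2 sequence
410, 50, 100, 150, 250, 410, 800, 1200, 1600, 2000 µmol mol⁻¹; leaf
temperatures 15–35 °C at cooler sites, 20–40 °C at the warmest, reflecting
the ±10 °C control range of field instruments around ambient). All interface
temperatures are °C; temperature arithmetic is done in kelvin internally.
Energies are J mol⁻¹ inside the kinetics and kJ mol⁻¹ in fitted-parameter
reporting, converted at the interface. Rates are µmol m⁻² s⁻¹, conductances
mol m⁻² s⁻¹, diameters mm, RGR mm mm⁻¹ yr⁻¹.

## FvCB evaluation (`fvcb`)

Two-limitation FvCB only; triose-phosphate limitation is not modelled.
Kinetic constants default to the Bernacchi (2001) in-vivo set
(Γ*₂₅ = 42.75 µmol mol⁻¹, Ea 37 830 J mol⁻¹; Kc₂₅ = 404.9 µmol mol⁻¹, Ea
79 430; Ko₂₅ = 278.4 mmol mol⁻¹, Ea 36 380; O = 210 mmol mol⁻¹), the
de-facto standard behind Ci-based ("apparent") curve fitting. The table is a
frozen dataclass, serialisable to a dict/YAML block, and fully overridable
for replication against other kinetic sets. Ties in min(Ac, Aj) are labelled
"rubisco". Gross rates are obtained by switching off the Rday subtraction,
which by construction differs from the net output by exactly Rday.

## Bilinear A–Ci fitting (`aci`)

With kinetics fixed, Ac is linear in (Vcmax, Rday) against
x_c = (Ci−Γ*)/(Ci+Km), and Aj is linear in Jmax against
x_j = (Ci−Γ*)/(Ci+2Γ*). For every split of the Ci-sorted observations
leaving ≥3 points per regime (never splitting tied Ci values, which keeps
the fit order-invariant), the low-Ci regime is regressed for
slope = Vcmax and intercept = −Rday; Rday is then held fixed and the high-Ci
regime regressed through the origin for Jmax/4. The split minimising total
SSE is selected; the reported transition is the Ci midpoint of the winning
split. Negative Rday estimates are clamped to zero (`rday_clamped`), and
splits at the admissible boundary are flagged (`boundary_transition`).
Parameters are reported at measurement temperature — no 25 °C normalisation
anywhere, because the temperature-response fits consume per-temperature
apparent rates directly.

Exactness: on noiseless forward-model curves whose true limitation pattern
is a clean Ci-partition (all-Rubisco below the crossover, all-RuBP above),
the method recovers (Vcmax, Jmax, Rday) to machine precision. At warm
temperatures the lowest CO2 setpoint can fall below Γ*(T) — a real leaf
there is below its compensation point and the minimum rule puts the point on
the RuBP branch — so those curves are fit approximately, exactly as with
field data. Tests assert exact inversion only where the clean-partition
condition holds and tolerate small bias elsewhere.

QC before fitting is deterministic and machine-readable: minimum point
count (default 6), non-degenerate A range (default ≥1 µmol m⁻² s⁻¹), ≥4
distinct Ci, at least one positive gs. These defaults are the package's
own; they are documented, overridable, and not claimed to replicate any
particular campaign's screening.

## Temperature responses (`thermal`)

The peaked Arrhenius function uses the optimum parameterisation (Medlyn
et al. 2002 form) with Hd fixed at 200 kJ mol⁻¹ to avoid
over-parameterisation; (kopt, Topt, Ea) are estimated by nonlinear least
squares with kopt profiled out analytically (it enters linearly) and a
deterministic multi-start grid (Topt ∈ {20,25,30,35,40} °C,
Ea ∈ {30,60,90} kJ mol⁻¹; the four best starts by initial RSS are polished;
ties resolve to the lowest Ea). Bounds: 0 < Topt < 60 °C, 0 < Ea < Hd.
Fitting is seed-free. Monotone-rising data converge with the optimum at or
beyond max(T) and are flagged `topt_extrapolated`; such fits are reported,
not suppressed, mirroring the common situation where apparent Vcmax has not
peaked within the measured range.

The parabola A(T) = Aopt − b(T−ToptA)² is solved in closed form (ordinary
quadratic least squares, re-parameterised to vertex form), which provably
attains the global SSE minimum; a property test confirms agreement with a
general nonlinear solver to 1e-8. Upward-opening fits set
`curvature_ok=False` and suppress Tmax/Agrowth for that tree.
Tmax = √(Aopt/b) + ToptA satisfies A(Tmax) = 0 identically.

Acclimation slopes divide Topt differences by differences in site mean
annual temperature (14/22/26 °C), not daytime growth temperature, matching
the convention of reporting shift per °C of MAT warming. Eq-2 fitting is
per tree by default (one parabola per tree from its 5–6 temperatures),
aggregated afterwards to species×site means for statistics; fitting a
single curve to group means is available by passing pooled points directly.

## Counterfactuals (`counterfactuals`)

Both counterfactuals re-evaluate the fitted FvCB parameters of each
measurement temperature — no Arrhenius interpolation between temperatures —
at a modified condition: a common Ci (default 0.7 × 410 = 287 µmol mol⁻¹)
for the stomatal counterfactual, and no Rday subtraction for the gross one.
The gross counterfactual defaults to each curve's observed Ci at its first
410 setpoint, with a common-Ci mode one flag away. The Rday used is the
bilinear-fitted value per temperature. Two exact nulls anchor the logic:
temperature-invariant Ci/Ca makes Topt287 ≡ ToptA, and temperature-invariant
Rday makes ToptGross ≡ ToptA (a constant shifts Aopt, not the vertex).
Welch unpaired t-tests compare observed and counterfactual optima; two
zero-variance groups with equal means return p = 1 by convention.

## Growth and statistics (`growth`)

RGR uses natural logarithms and the first-to-latest census (the log-ratio
convention; the census-by-census average is deliberately not used). The
RGR~Agrowth regression is ordinary least squares with a one-sided p for a
positive slope. The two-way ANOVA runs on species×site means with type-II
sums of squares — the montane group is absent from the hottest site, so the
design is unbalanced and type-I would be order-dependent; the site×group
interaction is included only when estimable, otherwise flagged. Post hoc
pairwise contrasts are Welch t-tests between site×group cells with Šidák
adjustment p' = 1 − (1−p)^m and a compact letter display (insert-and-absorb
algorithm) at α = 0.05. gs at growth temperature is read off the curve
measured nearest each site's daytime growth temperature (20/25/30 °C for
the 14/22/26 °C sites) at the first 410 setpoint; AgN is Agrowth divided by
area-based leaf nitrogen.

## Synthetic campaign (`simulate`)

The generator emulates the study design: 9 montane + 2 + 2 lowland species,
four trees per species×site, montane absent from the hottest site, the full
CO2 sequence, site-specific temperature sets, Gaussian noise of
sd 0.3 µmol m⁻² s⁻¹ on Anet only (typical instrument-level scatter), and
lognormal species/tree effects on capacities (cv 10 %/5 %) with additive
optimum jitter (sd 0.8/0.4 °C).

Truth structure. Per group×site, apparent Vcmax and Jmax follow peaked
Arrhenius responses. The Jmax:Vcmax balance was chosen so that ambient-CO2
photosynthesis sits at or near the Ac/Aj co-limitation point: the net
optimum then lives near the limitation crossover, and shifting both
capacity optima together moves it almost one-for-one, which is the
generator's acclimation mechanism. Because the Rubisco kinetics and the
Rday ramp do not acclimate, a capacity-optimum offset does not translate
exactly into a net-optimum shift; the offsets were therefore calibrated
once against the noiseless 0.01 °C-grid oracle so that the *realised*
ToptA shifts equal the intended ones — 0.6 °C/°C warming for montane
species, 1.2 °C/°C for the 22 °C-lowland group moved to the hottest site,
0.23 °C/°C cooling for the 26 °C-lowland group, zero elsewhere. The
`true_topt_oracle` function exposes the realised optimum for any
group×site, independent of noise settings, and is the reference for all
recovery tests.

Stomata are modelled as a Ci/Ca ratio per CO2 setpoint (0.7 at 410,
rising toward 0.95 at 50 µmol mol⁻¹ where assimilation approaches zero and
Ci approaches Ca, falling to 0.60 at 2000), optionally drifting with leaf
temperature; gs is emitted via Fick's law. This is the minimum structure
needed to exercise the common-Ci counterfactual — it is not a coupled
conductance model, so stomatal dynamics, VPD responses and patchiness are
outside what passing tests can certify. Day respiration is
Rday(T) = 1.0 + 0.04 (T−25) µmol m⁻² s⁻¹, floored at zero.

Growth: diameters start near 25 mm (lognormal, sd 0.15 in log space) and
grow exponentially over 13 quarterly censuses spanning 3 years with
rgr = α + β·Agrowth + ε (α = 0.02 yr⁻¹, β = 0.012 per µmol m⁻² s⁻¹). The
noise ε is drawn at the species×site level with its sd derived from the
realised spread of Agrowth so that the expected variance explained at the
species-mean level is 30 % (override `rgr_noise_sd` to decouple); a small
tree-level jitter is added on top. Everything is reproducible byte-for-byte
from (config, seed).

What the generator does not emulate: VPD and humidity covariates, leaf
energy balance, mesophyll conductance, TPU limitation, instrument drift and
match/leak artefacts, mortality other than the montane absence at the hot
site, and seasonal growth variation. Recovery results therefore demonstrate
correctness of the estimation chain, not robustness to every field
pathology.

## Pipeline and I/O (`io`, `cli`)

Long-format CSV is the canonical input (a documented column map adapts
instrument exports); the second pass through 410 µmol mol⁻¹ is tagged
`return_410` and excluded from ambient-A and gs extraction. The pipeline
persists every stage as tidy CSV (per-curve fits, per-tree traits,
species×site means, shifts, counterfactual tests, RGR, ANOVA tables) plus a
run log of per-stage counts, so every final number is recomputable from the
intermediates. All randomness lives in the generator's single seed; fitting
is deterministic by construction. A thin click CLI (`simulate`, `fit-aci`,
`fit-thermal`, `pipeline`, `report`) wraps the library for shell use; exit
codes are 0/1/2 for ok/user error/data error.

## Numerical choices and scaled-down test sizes

RSS convergence tolerances are 1e-12 (least-squares ftol/xtol/gtol);
parabola fitting is exact. The acceptance-style tests use problem sizes
chosen to exercise the claims while keeping the default suite quick on one
CPU: 500 curves for the enumeration-equivalence check, 500 replicates for
the noisy Arrhenius recovery, 1000 random parabolas for the Tmax identity,
20 seeds of a montane-only campaign (9 species × 4 trees × 2 sites) for the
end-to-end shift recovery, 1000 null simulations for the p-uniformity check
and 1e5 permutations for the ANOVA comparison. These sizes are the
package's own choices and are easy to scale up.

## Known limitations

* Apparent (Ci-based) parameters only; no gm, no Cc-based "true" values.
* The bilinear method inherits its classical failure modes: curves measured
  mostly in one regime return flagged or non-converged fits, and points
  below Γ* at warm temperatures bias the Rubisco regression slightly.
* The parabola is a local summary; on strongly kinked or asymmetric
  responses ToptA is a few tenths of a °C below the true argmax. Because the
  bias is shared across sites it largely cancels in shift estimates.
* Welch-based post hoc contrasts are a deliberate simplification of
  model-based (emmeans-style) contrasts; with 2–9 species per cell the
  difference is small but not zero.
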