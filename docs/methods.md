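# Methods

## Model structure and assumptions

The respiratory tract is represented by four absorbing segments — nasal
cavity (Nose), bronchi (BB), bronchioles (bb) and alveoli (AL) — each as a
pair of well-stirred compartments: an epithelial lining fluid (ELF) layer
and a mucosal tissue layer. The pharynx is not a compartment: anything
deposited there is swallowed instantly into the gastrointestinal depot.
Everything outside the respiratory tract is lumped into a single central
compartment of volume Vc with linear clearance CL acting on total plasma
concentration. Peripheral-exchange rate constants (k12, k21, k13, k31)
exist in the parameterisation and are fixed at zero: oral disposition is
adequately mono-exponential on the sampling horizon used.

Flux conventions, chosen where the anatomy and the reference outputs pin
them down:

- **ELF → tissue is one-way** (`PS_x · fu_ELF · C_ELF,x`). Mucociliary
  clearance competes with permeation only in the bb and BB segments
  (bb → BB → pharynx → swallowed), with first-order rate constants
  k_mcc,bb = 0.083 h⁻¹ and k_mcc,BB = 0.417 h⁻¹.
- **Tissue ↔ central is bidirectional**, driven by the free-concentration
  gradient `fu_tissue·C_tissue − fu_p·Cp` through the same PS. A one-way
  tissue → central flux would give the nasal tissue a terminal half-life
  of ~0.4 h (PS_Nose/V_Nose-tissue ≈ 1.6 h⁻¹); the reference simulations
  show nasal and plasma terminal phases parallel at ~13–15 h, which only
  the bidirectional form reproduces.
- **Elimination acts on total plasma concentration** (CL·Cp); the free
  fractions appear only in permeation fluxes, because CL was estimated
  against total concentrations.
- **Oral lag** is realised by scheduling the GI deposit at
  `dose time + tlag` (no transit chain). Drug swallowed from the airways
  enters the same depot without extra lag; at the reference pharyngeal
  fraction (~8×10⁻⁷) this is irrelevant.
- The GI depot absorbs first-order (ka) with fraction FA = 0.9 reaching
  the circulation; the remainder is booked to a cumulative unabsorbed
  sink. No first-pass metabolism is modelled, so FA doubles as oral
  bioavailability. "Nasal concentration" means amount in nasal mucosal
  tissue divided by its volume (2.829 mL); the ELF layer is a transit
  space, not the reported matrix.

## Parameters

| parameter | value | unit | provenance |
|---|---|---|---|
| FA | 0.9 | – | oral absorption fraction, literature |
| fu_ELF, fu_tissue | 1.0 | – | assumed (no specific binding known) |
| fu_p | 0.8 | – | plasma protein binding < 20% |
| k_mcc,bb / k_mcc,BB | 0.083 / 0.417 | 1/h | airway ciliary clearance, literature |
| V_ELF (Nose/BB/bb/AL) | 0.2459 / 2.1 / 2.1 / 20.8 | mL | literature |
| V_tissue (Nose) | 2.829 | mL | S_Nose·D_Nose = 0.0246 m² × 1.15×10⁻⁴ m |
| V_tissue (BB/bb/AL) | 38 / 38 / 381 | mL | literature |
| Peff | 5.1097×10⁻⁶ | cm/s | 2.228×10⁻⁶ × (26.145/11.4) |
| PS (Nose/BB=bb/AL) | 4.525 / 137.96 / 25753 | mL/h | Peff × S, S = 0.0246 / 0.75 / 140 m² |
| tlag, ka, Vc, CL (US) | 0.371 h, 1.036 h⁻¹, 194.35 L, 10.001 L/h | | oral-profile fit, American adults |
| tlag, ka, Vc, CL (CN) | 0.156 h, 1.064 h⁻¹, 190.82 L, 11.320 L/h | | oral-profile fit, Chinese adults |
| F1, F2 (F3–F5 = 0) | 0.547, 7.6375×10⁻⁷ | – | intranasal-profile fit; spray droplets ≥30 µm do not reach the lower airways |

Internal units are ng / mL / h (so concentrations come out in ng/mL
without scale factors); values quoted in L or L/h are converted ×1000 at
load. Peff is carried at full precision when computing PS — the tabulated
PS_AL (25.728 L/h) implies an unrounded intermediate. The nasal ELF
volume keeps the literature value 2.459×10⁻⁴ L rather than the direct
geometric product S_Nose·H_Nose = 2.46×10⁻⁵ L (the two are mutually
inconsistent at the stated H_Nose = 10⁻⁶ m; downstream reference results
were produced with the former, and `derive_nasal_volumes` exposes the
latter for anyone who wants the geometric convention).

## Numerical integration

The ODE system is linear and time-invariant between dose events, so the
default propagator advances the state with cached matrix exponentials of
the 12×12 rate matrix over each inter-checkpoint interval. This is exact
to machine precision, unconditionally stable despite the stiffness (rate
constants span 0.045–1240 h⁻¹), conserves mass identically, and is fast
enough for 500-subject multidose populations in about a second. A
stiff-ODE path (`method="lsoda"`, rtol 1e-8, atol 1e-6 ng, hard restart
at each dose event) is retained and agrees with the exponential
propagator to ~1e-8; the test suite cross-checks the two. Samples that
coincide with a dose time record the post-dose state; plasma and nasal
tissue concentrations are continuous across dose events, so troughs read
off the grid are true pre-dose troughs.

Default observation grid: {0, 0.08, 0.25, 0.5, 1, 2, 3, 4, 6, 8, 12} h
after every dose, plus {16, 24, 36, 48, 72} h after the final dose; the
labelled regimen is 0.06 mg BID on days 1–6 (doses at 0, 12, …, 132 h)
plus a single dose on day 7 (144 h), followed to 216 h.

## Fitting

Estimation is weighted least squares on mean profiles (no mixed-effects
modelling — the reference datasets are arithmetic means). Default
weighting is 1/ŷ² (proportional error), appropriate for concentrations
spanning two orders of magnitude; uniform and 1/ŷ are available.
Zero-valued observations are below-LLOQ censorings and are excluded: under
least squares they carry no usable information, and the source convention
(sub-LLOQ → 0 in means) would otherwise bias the tail fit downward.

The optimizer is Nelder–Mead over transformed parameters (logistic for
tlag onto [0, 2] h, log for ka/Vc/CL, and F1 = σ(x₁), F2 = σ(x₂)(1−F1)
to enforce F1+F2 ≤ 1), with five seeded jittered restarts. Two numerical
points matter:

- The lag search is additionally capped at the first quantifiable
  sampling time: a longer lag predicts zero there, which the data
  contradict, and the prediction-weighted objective is flat in the lag on
  that side — an optimizer trap, not a useful region.
- Each restart uses a wide initial simplex (0.5 per transformed
  coordinate) so the reflection step can cross flat patches.

Noise-free recovery is exact to ≲1e-6 relative for tlag, ka, Vc, CL and
F1; F2 is identifiable only because synthetic data are noise-free — at
its reference magnitude (~10⁻⁷ of the dose) it is practically
unidentifiable from real data, and the tests require only F2 < 10⁻³.
Sensitivity: freezing a −10% misspecified CL moves F1 by a few percent and
leaves F2 ≈ 0; an overestimated (+10%) CL makes the optimum recruit a
visible swallowed fraction (F2 ≈ 0.14) that partially compensates the
terminal-slope mismatch — a genuine optimum under proportional weighting,
not an optimizer artifact, and a caution against trusting F2 when the
systemic parameters are uncertain.

## Virtual populations

Inter-individual variability goes on CL and Vc only, as independent
lognormals with natural-scale CV = 0.38 and **arithmetic mean equal to
the typical value**: X_i = X_typ·exp(η − σ²/2), η ~ N(0, σ²),
σ² = ln(1+CV²). The mean-centred parameterisation is deliberate: every
reference population summary (mean Cmax, AUC, T1/2 for n=300) is an
arithmetic mean over subjects, and a median-centred lognormal
underpredicts all of them by the factor e^{σ²/2} ≈ 1.07 (7–10% short);
mean-centring reproduces them within ~2–5%. Consequence: the sample
median of a parameter sits at 0.935× the typical value. Absorption
(tlag, ka), deposition fractions and physiology are shared; CL–Vc
correlation and covariates are out of scope.

Evaluation runs use n = 300 subjects (single-dose comparisons) and
n = 500 (multidose regimen analyses). Seeds are explicit everywhere;
the default (20220707) is an arbitrary documented constant.

## NCA conventions

Linear trapezoidal AUC (keeping AUC additivity exact); Cmax/Tmax read off
the observation grid without interpolation; λz by unweighted log-linear
regression over the best adjusted-R² window among the last 3–6 points
after Tmax (ties favour fewer points); AUC0–∞ = AUClast + Clast/λz;
CL/F = dose/AUC0–∞ and V/F = (CL/F)/λz normalised by the administered
device dose, not the deposited fraction (this is what makes the nasal
CL/F ≈ 8.3–8.4 mL/h ≈ PS_Nose/F1 come out on the published scale).
Multidose accumulation compares the final dosing interval
([144, 156] h) with the first ([0, 12] h).

Population accumulation ratios are reported two ways: per-subject ratios
with dispersion, and ratio-of-means rows (`R_Cmax_pop`, `R_AUC_pop`) —
mean day-7 exposure over mean day-1 exposure — which is the convention of
the reference summaries (their accumulation entries carry no SD) and is
the quantity checked in acceptance. The mean-of-ratios runs ~4–5% higher
because the per-subject ratio is convex in the elimination rate.

Time to steady state: first day whose morning pre-dose trough reaches a
threshold fraction (default 0.95) of the final-day pre-dose trough,
computed on the typical-subject profile. At 0.95 the labelled regimen
reaches steady state on day 4 (systemic and nasal); at 0.90, day 3. The
population-*mean* trough curve approaches steady state more slowly (the
slowest-clearing subjects dominate late troughs) and can indicate day 5
under the same threshold — a property of averaging, not of the kinetics
of any subject.

## Synthetic observed data

The mean profiles used for estimation are regenerated, not downloaded:
the model's true profile on the clinical sampling grid, multiplied by
mean-one lognormal error (μ = −σ²/2, σ² = ln(1+sd²), so averaging
replicates is unbiased), optionally plus additive Gaussian error, then
censored to 0 below the LLOQ. Defaults: 10% proportional error, no
additive error, LLOQ 0.05 ng/mL (a plausible bioanalytical magnitude —
the true assay LLOQ is unpublished — flagged as a placeholder in output
metadata). At these defaults the 0.12 mg intranasal profile loses its
points beyond ~36–48 h to censoring, matching the reported pattern of
sub-LLOQ tail values. What passing recovery tests show is internal
consistency (the estimator recovers the generator's truth under the
assumed error model); they cannot validate the error model itself against
real assay behaviour (no between-subject noise in means, no time-varying
assay error, no quantisation).

## Known limitations

- The exact reference airway ODEs are not published in accessible form;
  the ELF↔tissue directionality chosen here reproduces the published
  steady-state, accumulation and terminal-phase behaviour, but the nasal
  **distribution-phase shape** is only loosely constrained: this model
  puts the single-dose nasal Cmax at ~8390 ng/mL at 0.25 h and
  AUC0–∞ ≈ 7520 h·ng/mL against reference values of ~7984 ng/mL at
  0.08 h and ≈ 7165 h·ng/mL (about +5%/+1.3% on Cmax/AUC once computed on
  a dense grid). Nasal-phase quantities should be read with ~10%
  headroom.
- No particle-size-resolved deposition physics: F1–F5 are inputs, with
  the lower-airway fractions fixed at zero for spray-sized droplets.
- No enterohepatic recirculation, first-pass metabolism, nonlinear
  binding, or covariate models; fits are to mean profiles only.
- BB/bb/AL geometry is constant literature data, not derived from
  anatomy.
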