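# Methods

## Scope and overall procedure

The package answers one question: for a hypofractionated liver SBRT course
(50 Gy in 5 fractions), how do predicted liver and duodenal toxicities
compare between photon (IMRT) and proton (IMPT) delivery, each with and
without daily online adaptation? The pipeline runs in four stages:

1. per-structure differential DVHs (planning dose plus one DVH per
   delivered fraction) are produced by the synthetic cohort generator or
   read from CSV;
2. each DVH is scored with six published LKB models (EQD conversion →
   EUD reduction → probit);
3. fraction doses are scaled to the prescription and scored individually,
   giving five fraction NTCPs per course whose mean/range summarize the
   treatment NTCP;
4. per-patient treatment NTCPs are compared between schemes with paired
   t-tests.

## Radiobiological core

**EQD conversion.** Every model's TD50 lives on a reference-fractionation
scale, so total physical dose D in each bin is converted with the
linear-quadratic model. The per-bin fraction dose is D / n_fractions: all
courses considered are equal-fraction, and no per-voxel fractionation
record exists at the DVH level. Three reference schemes are supported:

* fixed dose per fraction d_ref (Dawson 1.5 Gy; ALBI, Child–Pugh, Pan
  2 Gy): `EQD = D (D/n + α/β) / (d_ref + α/β)`;
* single 25 Gy fraction (Murphy): the same formula with d_ref = 25 Gy;
* isoeffective total dose in 25 fractions (Holyoake): the reference
  fraction dose is not fixed, so EQD is the positive root X of
  `X (X/25 + α/β) = D (D/n + α/β)`, i.e.
  `X = 12.5 (−α/β + sqrt((α/β)² + (4/25) D (D/n + α/β)))`. The exact
  quadratic isoeffect solution is this package's choice; the original
  model publication does not spell out the operational rule.

Zero dose maps to zero under every scheme, and conversion is the identity
whenever D/n equals the reference fraction dose (tested property).

**EUD.** `EUD = (Σ D_i^(1/n) V_i / V_tot)^n`. For near-maximum models
(n ≈ 0.12 → exponent ≈ 8.3) naive powers overflow for large doses, so the
sum is evaluated with max-dose factoring: all dose ratios are ≤ 1 and the
maximum dose multiplies the result at the end. EUD is bounded by the
minimum and maximum dose of nonzero-volume bins for every n > 0 and
reduces to the volume-weighted mean at n = 1 (tested against a direct
oracle at 1e−9 relative tolerance).

**Probit.** `NTCP = Φ((EUD − TD50)/(m·TD50))`, evaluated through the
error-function-based normal CDF (`scipy.special.ndtr`), not numeric
integration; a trapezoid-rule integral of the Gaussian density serves as
the independent oracle in tests (1e−6 agreement). At zero dose the
prediction is Φ(−1/m) > 0 — the models carry a baseline risk from the
disease itself (≈ 0.106 for Child–Pugh, ≈ 0.252 for ALBI).

**Proton RBE.** A constant multiplicative 1.1 on physical proton dose,
applied before any LQ conversion and configurable. Variable, LET-dependent
RBE is out of scope; a constant 1.1 likely understates proton NTCPs. The
equal treatment of RBE-weighted and physical dose in the 2 Gy/fx models is
a convention of this package (RBE first, then EQD).

## Fraction and treatment NTCP

Deformably accumulating daily doses onto one anatomy is unreliable when
structures are re-drawn every day, so each fraction's dose is scaled by
the number of fractions ("scaled to the prescription") and scored as if
the whole course had been delivered that way; the scaled course is treated
as N fractions of the observed fraction dose during EQD conversion. N
identical fractions therefore reproduce the planning NTCP exactly (tested
to machine precision). The treatment-NTCP point estimate is the arithmetic
mean of the fraction NTCPs — the mean and the (min, max) range are always
reported together, since neither alone is a headline statistic. Plan
metrics for scheme comparison are the volume-weighted mean dose, VxGy in
absolute cc, and the near-maximum dose D0.5cc (smallest dose with at most
0.5 cc at or above it, mirroring the 0.5 cc planning constraint; the tail
volume is a parameter).

## Synthetic cohort generator

**What it emulates.** Ten patients with the published GTV and healthy
liver volumes; duodenum volumes (45–90 cc) and GTV–duodenum proximities
(6–10 mm) are synthetic stand-ins drawn from a seeded stream, because the
real values are unpublished. Four schemes: IMRT with 5 mm (non-adaptive)
or 2 mm (adaptive) margins; IMPT with 3 % range uncertainty plus 3 mm or
1 mm setup terms, RBE 1.1.

**Dose model.** DVHs are binned (0.1 Gy default) from analytic
cumulative-volume curves:

* GTV: a narrow Gaussian at the prescription (σ = 0.3 Gy) with a ±0.3 %
  normalization jitter, so the GTV mean is within 1 % of 50 Gy;
* liver-GTV: an exponential low-dose spill `V(D) = A·V·exp(−D/λ)` capped
  at the prescription (the residual mass forms a hot shell abutting the
  target). The spill fraction A is set so the mean liver dose hits a
  target of 9 Gy × (0.5 for protons) × (1 + 0.01·margin_mm) × patient ×
  plan noise; falloff λ is 14 Gy for photons, 7 Gy for protons;
* duodenum: an exponential spill (40 % of the organ, 3 Gy falloff) plus a
  small hot tail (0.2–0.4 cc) at a penumbra dose
  `P·(floor + w·exp(−d/λ_mod))`, with effective distance d = proximity −
  0.2·margin. Photons: floor 0.45, λ 12 mm; protons: floor 0.20, λ 6 mm —
  protons deliver both less integral dose and a sharper penumbra.

Noise is lognormal: a patient-level factor (σ = 0.15) shared across
schemes (so comparisons are paired) and a plan-level factor (σ = 0.07)
independent per scheme, scaling the whole liver spill and the whole
duodenal dose level respectively. Plans are rejection-sampled (≤ 10
draws) until mean liver-GTV < 20 Gy, duodenum V35Gy(RBE) < 0.5 cc and the
GTV mean is within 1 % of prescription; an infeasible configuration raises
a diagnostic error rather than silently relaxing a constraint.

**Daily perturbation.** Each fraction draws a signed displacement
~N(0, 3 mm), shared across all schemes of a patient; protons add a signed
range-error draw (0.5 mm per % uncertainty) shared between the two proton
schemes. The displacement moves the OAR into or out of the dose spill,
modelled as a multiplicative dose factor exp(c·δ) on the OAR DVHs
(c = 0.01/mm for both liver and duodenum). Adaptation attenuates the
displacement to 25 % of its value (residual-margin re-planning). Because
exp is convex and the draws are shared, the *expected* OAR dose of a
non-adaptive course is ≥ its adaptive counterpart for the same anatomy
days, while individual days can go either way; with zero displacement
every fraction is exactly plan/N.

**Effect-size rationale.** The defaults encode the study conditions the
analysis is meant to exhibit: a strong proton-sparing effect (≈ 2× lower
mean liver dose, markedly lower duodenal penumbra dose) and a near-zero
adaptation effect (a few-percent margin term plus a second-order
convexity term, deliberately below the paired-noise floor at n = 10).
Under these defaults the comparison table flags photon-vs-proton for the
ALBI and all duodenal models and flags no adaptive-vs-non-adaptive cell —
the qualitative sign pattern, not any specific p-value, is the
reproduction target. Across 30 generator seeds the modality contrasts are
flagged in ≈ 97 % of the relevant cells and adaptation contrasts in ≈ 2 %
(consistent with a near-null effect at α = 0.05).

**What it does not emulate.** No image-space dose calculation, organ
motion biomechanics, plan optimization trade-offs, or systematic anatomy
drift (weight loss); per-fraction perturbations are i.i.d. Passing tests
show the pipeline is correct and well-calibrated on DVHs with this
statistical structure — they do not validate the dose model against real
patients.

## Statistics

Two-sided paired t-tests on per-patient treatment NTCPs, n−1 degrees of
freedom, α = 0.05, no multiplicity correction (a deliberate mirroring of
common practice in planning studies; with 24 cells per run, ≈ 1 false
positive is expected under the null — treat isolated marginal flags
accordingly). Degenerate conventions: all-zero differences → t = 0,
p = 1; constant non-zero difference → |t| = ∞, p = 0. The implementation
is hand-rolled to enforce these conventions and is cross-checked against
`scipy.stats.ttest_rel` and a closed-form hand computation in tests; null
p-values are verified approximately uniform (KS < 0.1 over 1000
label permutations).

## Numerical choices and degenerate inputs

* DVH bin width 0.1 Gy; halving it moves no NTCP by more than 1e−3
  (regression-tested).
* EUD in log/ratio space (no overflow up to 1/n ≈ 20); zero-dose bins
  contribute exactly zero.
* `near_max_dose` returns the hottest bin dose if even that bin exceeds
  the tail volume, and the minimum bin dose if the tail volume exceeds the
  organ volume.
* RNG streams are keyed by (seed, patient, stream, scheme) and hashed
  through SHA-256 before seeding, so nearby keys give fully decorrelated
  streams while paired draws (patient factors, anatomy days) remain
  shared by construction. Every run is a pure function of (config, seed).

## Known limitations

LQ-based EQD is uncertain at 10 Gy fractions; the constant RBE likely
biases proton NTCPs low; the LKB models were fitted to other cohorts and
fractionations; the synthetic generator's parameters are plausibility
choices, not fits to data. Conclusions drawn from the default cohort are
statements about the modelled conditions, not about any patient
population.
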