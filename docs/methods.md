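# Methods

## Model structure and assumptions

The simulator is a perfusion-limited whole-body PBPK model. Blood leaves a
well-mixed venous pool, passes through the lung in series, fills a
well-mixed arterial pool and perfuses thirteen systemic tissues in parallel
(adipose, muscle, liver, spleen, heart, brain, kidney, skin, reproductive
organs, red and yellow marrow, and a rest-of-body lump). The gut is a
zero-volume flow conduit whose arterial flow joins the portal vein
unexchanged; spleen and gut drain portally into the liver, whose tabulated
flow is its total (portal + hepatic-arterial) outflow.

Every tissue is flow-limited: the venous blood leaving tissue *t* is in
instantaneous equilibrium with the tissue at blood concentration
(Aₜ/Vₜ)·R_bp/K_p,t, so distribution is limited by perfusion, not membrane
permeability. This is appropriate for a small hydrophilic molecule like
aztreonam whose tissue uptake is dominated by paracellular and
transporter-mediated pathways, and is the assumption under which a
tissue:plasma ratio at steady state *is* the K_p.

Reported "plasma" is the venous-pool blood concentration divided by R_bp.
Doses enter the venous pool: a bolus as the initial condition (preserving
exact mass balance), an infusion as a zero-order rate over its stated
duration (the integrator is restarted at the discontinuity), and IM/SC
regimens as a first-order depot (default ka = 6 h⁻¹, F = 1, reflecting
the drug's rapid and essentially complete parenteral absorption).

### Flow closure

The tabulated physiologies close their flow balance exactly for human, dog
and monkey; rat and mouse close to within 0.2% (rat: cardiac output
0.7990 mL/s vs summed venous returns 0.7981 mL/s). The residual is carried
by a signed arterial→venous shunt so that inflow equals outflow at every
node without altering any printed per-tissue value. A physiology whose
imbalance exceeds 2% is rejected at load time.

### Elimination

Renal clearance is mechanistic: CL_renal = f_up × GFR, filtration of
unbound drug. Hepatic clearance absorbs the remainder of the calibrated
species total, with a fixed 10% of the hepatic route excreted into a bile
sink (linear, no transporter saturation, no enterohepatic recirculation).
The split is rebuilt deterministically from the total: renal at its
mechanistic value (capped at the total), remainder hepatic + biliary, so
the components always sum to the target exactly — the total is the quantity
the calibration controls, and the split only determines route attribution.

Elimination is organ-assigned and plasma-referenced. The removal rate is
CL × C_plasma with C_plasma the **arterial plasma concentration entering
the organ**, and the drug is removed from the organ's venous-return stream
rather than from the tissue mass balance. For a low-extraction drug,
inflowing and equilibrated outflowing plasma are nearly identical, and this
convention is the unique one (verified analytically on the 0→∞ integrals of
the network ODEs) under which three identities hold simultaneously:

1. AUC₀₋∞ = Dose / CL_total, exactly (machine precision in the tests);
2. steady-state infusion reproduces every input K_p as the tissue:plasma
   ratio, exactly;
3. moment-based NCA Vss (CL × MRT) agrees with the volume-weighted K_p sum
   to within ~1%.

Placing the elimination term inside the eliminating organ's mass balance
instead would break all three by the organ's extraction ratio (up to ~40%
for the rat liver at the calibrated split) — a material bias for a model
whose calibration target *is* the NCA clearance.

### Volume of distribution

Vss (plasma-referenced) = R_bp·(V_arterial + V_venous) + Σₜ K_p,t·Vₜ. The
blood pools contribute R_bp·V because the amount they hold at steady state
is C_plasma·R_bp·V. This synthesis is tested against a constant-infusion
steady-state oracle (amount in body ÷ plasma concentration) to 2%.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| log P | −1.141 | — | neutral-species lipophilicity, partition prediction |
| pKa | 4.09 (acid) | — | dominant ionisable group; Henderson–Hasselbalch speciation |
| f_up | 0.594 (h), 0.32568 (r), 0.47787 (m) | — | fraction unbound; drives renal CL and K_p translation |
| R_bp | 0.997 (h), 0.65 (r), 0.827 (m) | — | blood:plasma ratio; concentration-scale conversion |
| GFR | 7.5 (h), 0.0786 (r), 0.0168 (m), 3.678 (d), 0.624 (mk) | L/h | renal filtration |
| CL total | 6.56 (h), 0.216 (r), 0.016 (m), 5.570 (d), 0.775 (mk) | L/h | calibrated systemic clearance |
| biliary fraction | 0.10 | — | share of hepatic route excreted in bile |
| allometric exponent | 0.75 | — | CL ∝ W^b, midpoint of the conventional 0.6–0.8 band |
| ka (depot) | 6 | 1/h | IM/SC absorption rate |

Dog and monkey plasma binding was never measured for this compound; both
adopt the rat f_up and R_bp (overridable). GFR is not part of the compound
data and is embedded from standard physiology references; because the
calibration constrains the *total* clearance, GFR's absolute value only
moves the renal/hepatic attribution, not exposure. Hematocrit defaults
(0.41–0.46 by species) exist for composition-based partition work.

Physiology tables are stored in their source units (mL, mL/s) and converted
once to canonical units (L, L/h) by a guarded normalisation that refuses to
run twice. Canonical units throughout: h, mg, L, mg/L (≡ µg/mL).

Two tabulated physiology values are transcribed as printed even though they
look unusual: the human liver compartment (13.44 L — plausibly a composite
splanchnic volume) and the strongly species-divergent reproductive-organ
volumes. The liver volume inflates the human K_p-weighted Vss (≈ 42 L)
relative to a textbook liver; all internal identities remain consistent.

## Partition coefficients

The authoritative defaults are calibrated reference tables (rat and human);
kidney (K_p ≈ 2.4–3.0) and liver dominate, consistent with renal excretion
of the drug. Mouse, dog and monkey tables are built from the rat column via
the protein-binding translation rule
K_p,target = (f_up,t/f_up,s)·(R_bp,s/R_bp,t)·K_p,source — exactly
invertible, tested to machine precision — followed by the dog-specific +30%
muscle adjustment (dogs' higher muscle mass), guarded against double
application.

The de-novo pathway implements the Rodgers–Rowland single-parameter scheme
for acids/neutrals: partitioning into extra- and intracellular water with
Henderson–Hasselbalch ionisation (plasma pH 7.4, intracellular pH 7.0),
dissolution of the neutral species into neutral lipids and phospholipids,
and extracellular albumin binding scaled by tissue:plasma albumin ratios.
Tissue compositions are standard rat values from the method's literature;
yellow marrow reuses the adipose-like composition and rest-of-body a
whole-body average. The predicted aztreonam K_p values rank correctly
(adipose lowest, < 0.1) but the kidney/liver values of the reference tables
are transporter-calibrated and are not expected from passive composition
arithmetic — hence the reference tables remain the default.

## Non-compartmental analysis

Linear-up/log-down trapezoids by default (log segment only where both
bracketing concentrations are positive and declining); λz by log-linear
regression over terminal windows of ≥ 3 points (excluding Cmax), window
chosen by adjusted-R² maximisation with ties to the larger window;
AUC₀₋∞ = AUC₀₋ₜ + C_last/λz; MRT = AUMC/AUC − TI/2 for infusions;
Vss = CL × MRT. Extrapolated fractions above 20% are flagged. Values below
the LLOQ are zeroed before Cmax and dropped after it; concentrations below
10⁻⁹ × Cmax are treated as numerically zero so solver-tolerance tails of
dense simulated profiles cannot masquerade as a terminal phase.

For IV-bolus profiles whose first sample lies after t = 0, C0 is
back-extrapolated log-linearly from the first two declining points — the
standard bolus convention, and material here: the model's venous-pool
washout (τ ≈ 14 s in rat) places a large share of the true AUC before a
0.25 h first sample.

The synthetic-study recovery workflow uses the plain **linear** trapezoid,
the default convention of the NCA software used for the studies this design
emulates. On sparse bolus schedules the log-down rule under-integrates the
convex early decline (the log-linear chord lies below a multi-exponential
curve), inflating recovered CL by ~9 points in the rat design; the two
methods agree on dense grids. Supporting this choice, linear NCA of the
noiseless model profile at the 8 observation times reproduces the
reference analysis's predicted AUC₀₋ₜ (55.2 vs 55.40 µg·h/mL).

## Synthetic studies

The generator emulates a destructive-sampling small-animal study: the rat
default is 50 mg/kg IV bolus, samples at 0.25, 0.5, 1, 2, 4, 7, 10 and
24 h, three animals per time point, LLOQ 0.005 mg/L. Assay noise is
multiplicative lognormal with σ² = ln(1 + CV²), so the sample CV equals the
design CV exactly and the mean bias is exp(σ²/2) − 1 (both verified
empirically at n = 10⁴). Default CV = 0.15, of the order of the reported
parameter variability in comparable studies. Values below the LLOQ are
flagged BQL with the same convention the NCA applies, so generated studies
round-trip through the pipeline exactly.

What the generator does **not** emulate: inter-animal physiological
variability (no population PBPK), assay drift, or sampling-time error.
Passing recovery tests therefore demonstrate correctness of the analysis
chain under the stated noise model, not robustness to real biological
variability.

## Evaluation metrics

FE = predicted/observed per point; AFE = 10^(mean log₁₀ FE) (bias
direction); AAFE = 10^(mean |log₁₀ FE|) (magnitude; always ≥ 1 and ≥ both
AFE and 1/AFE). Scalar parameters use RPE = (pred − obs)/obs × 100% and
ARE = |RPE|, rounded to one decimal only at presentation. A concentration
fit is acceptable iff R² ≥ 0.8, every FE ∈ [0.3, 3] (bounds inclusive) and
AFE, AAFE < 2; parameters are reliable iff every ARE < 30%. Points with
FE outside [1/3, 3] are flagged as outliers and excluded only when
exclusion is explicitly enabled, with every exclusion logged. R² is the
coefficient of determination of the OLS regression of predicted on
observed; an identity-line variant is available behind a flag. The embedded
observed/predicted reference pairs include several error percentages that
were evidently computed from unrounded source values; the reproduce
workflow recomputes each pair and flags which printed values are exactly
recoverable.

## Sensitivity analysis

Five parameters are scanned as multiplicative perturbations: R_bp, f_up,
log D, CL_hep (with its tied biliary fraction) and CL_renal. Each grid
point re-simulates the model; the headline statistic is the normalised
coefficient ∂lnAUC₀₋∞/∂ln p at baseline by central difference (±5%).
Default grid 0.1×–10×, log-spaced, 21 points. f_up propagates into
CL_renal = f_up × GFR (clamped at f_up ≤ 1) and, behind a switch, into the
K_p set via the protein-binding translation; because AUC = Dose/CL, the
switch moves distribution (Vss, tissue peaks), not exposure. With the
fixed reference K_p tables the log D coefficient is structurally zero —
the model's statement that this drug's exposure does not depend on
lipophilicity — and the clearance coefficients satisfy
∂lnAUC/∂lnCL_renal + ∂lnAUC/∂lnCL_hep = −1 exactly, each equal to
−CL_component/CL_total. Grid points that violate a physiological validation
(e.g. a clearance multiplier exceeding the organ's deliverable blood flow,
CL > R_bp·Q) are recorded as failures, not fatal.

## Numerics

LSODA (stiff-capable) with rtol 10⁻⁸ and atol 10⁻¹⁰ mg; infusions
integrate piecewise across the rate discontinuity; the AUC is carried as a
quadrature state in the solver rather than post-hoc trapezoids. States more
negative than the tolerance floor abort with a diagnostic; smaller
negatives are clipped. The mass-balance audit —
max over time of |body + eliminated − administered|/dose — is attached to
every result and must stay below 10⁻³ (observed: ~10⁻¹²–10⁻¹⁴). Simulation
grids in the shipped scenarios (0.005–0.01 h over 24–48 h) resolve the
bolus front while keeping a full species run under a second.

## Known limitations

- No permeability-limited tissues, transporter kinetics, or oral
  absorption; biliary output is a sink.
- Mouse/dog/monkey K_p sets inherit rat calibration through a
  protein-binding rule; no primate- or canine-specific tissue data enter.
- NCA Vss from depot (IM/SC) data includes the mean absorption time and
  overestimates the distributional Vss, as in any model-free analysis.
- The sensitivity scan is local (one-at-a-time); no global (Sobol/Morris)
  indices.
- Mean-profile NCA only: no sparse-sampling variance estimators for the
  destructive design.
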