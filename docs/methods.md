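# Methods

## The model

The package implements a kinetic ODE model of the EGFR–PYK2–c-Met
signalling network of a basal-like TNBC cell.  Thirteen state variables
are integrated: the EGFR pool in three inter-convertible states
(unmodified, phosphorylated, ubiquitinated — receptor synthesis and
degradation are not modelled, so the EGFR total is conserved), PYK2 and
STAT3 with their active phospho-forms, c-Met and phospho-c-Met, ERK and
phospho-ERK, and explicit PYK2 and c-Met mRNAs.  STAT3 and ERK totals are
conserved; PYK2 and c-Met pools are open (translation from their mRNAs,
first-order decay, Cbl-mediated c-Met degradation).  Cbl and PTP
activation by phospho-EGFR are fast relative to every other process and
are carried as quasi-steady-state algebraic expressions rather than state
variables; this keeps exactly 13 dynamical states while retaining both
negative feedback loops.

Kinetic forms follow the standard conventions: Michaelis–Menten for
catalysed (de)phosphorylation and (de)ubiquitination steps, Hill kinetics
(exponent 2) for STAT3-driven transcription of PYK2 and c-Met, and mass
action for synthesis and decay.  The lumped ERK-activation step stands in
for the whole Ras–Raf–MEK cascade and is driven by phospho-EGFR,
phospho-c-Met and phospho-PYK2.  Seventy named kinetic parameters close
the system; each of the four positive feedback loops (F1: PYK2 shields
EGFR from Cbl-mediated ubiquitination; F2: STAT3→PYK2 transcription;
F3: STAT3→c-Met transcription; F4: c-Met→PYK2 activation) is mediated by
a dimensionless coupling weight `w_f1..w_f4` counted among the seventy,
so that inhibiting a loop by a fraction f is exactly multiplication of
its weight by (1 − f).

Drug action is non-competitive: each inhibitor divides its target's
activation rate law by `1 + [I]/Ki` (Gefitinib→EGFR via Ki1, PF396→PYK2
via Ki3b, EMD→c-Met via KiEMD, Stattic→STAT3 via KiStattic).  Units:
abundances in arbitrary immunoblot-calibrated units, time in hours, drug
doses in µM, ligands in ng/ml.

### Reference parameterisation

The supplementary fitted values of the original study are not available
to this implementation, so the package ships its own hand-calibrated
reference set, tuned once to reproduce the trained qualitative
behaviours: a low basal state that ignites under EGF (100 ng/ml); a
biphasic total-c-Met response (fast Cbl-mediated loss, then
transcription-driven overshoot above basal within 24 h); transient pERK
suppression under 1 µM Gefitinib with a late bounce-back that the
Gefitinib+PF396 combination abolishes; switch-like (H > 1) Gefitinib
dose-response curves; reduced signalling under PYK2 knockdown and under
direct c-Met inhibition; and the six-pair synergy structure (EGFR+PYK2
co-inhibition most synergistic, c-Met+STAT3 least).  Two parameters are
anchored quantitatively: the PYK2 mRNA turnover pair (Vs5, kdeg6) is set
so that the balanced reverse-function inversion at a 30-fold transcript
increase lands on the published adjusted pair (52, 280); the translation
rate ktl7 absorbs the resulting change of mRNA scale so protein-level
dynamics are untouched (mRNA units are arbitrary).

The mechanism behind the drug-combination structure in this calibration:
Gefitinib's steady-state effect is partially absorbed by feedback
compensation — losing phospho-EGFR de-activates Cbl, the c-Met pool
accumulates, and c-Met-driven PYK2/ERK signalling recovers (the
bounce-back).  PF396 (and, less completely, EMD) disables this
compensation, which is what makes the Gefitinib pairs super-multiplicative
at matched IC25 doses.

## Numerical choices

- Integration: LSODA (stiff-capable), rtol 1e-8, atol 1e-10.  Stimuli and
  treatments with onset times are handled by segment-wise integration
  restarted exactly at each discontinuity.
- Steady states: chunked long-horizon integration (50 h chunks, up to
  500 h) followed by a Newton polish; accepted only when the sup-norm of
  the right-hand side is below 1e-8.  Sustained oscillations are reported
  as errors, never silently averaged (the one exception: reverse-function
  grid cells in extreme corners tabulate the flagged limit-cycle mean).
- Dose responses are evaluated by the experimental protocol — the drug is
  applied to the EGF-stimulated steady state and the system relaxed — so
  in bistable regimes the dynamically reached branch is reported.  A
  "continuation" fast path polishes from the warm start and accepts the
  root only if it is linearly stable and close to the start; otherwise
  the trajectory is integrated.  Some treated conditions cross a genuine
  fold, where the response is discontinuous in dose; IC_x bisection
  tolerates hormetic bumps below 10% of the untreated level and reports
  unreachable targets explicitly.
- Hill fits: bounded trust-region least squares, initialised from the
  curve extremes, the half-range dose and H = 1; tolerances 1e-14, so
  noiseless model-class data are recovered to ~1e-6.
- The genetic algorithm searches log10 space: tournament selection
  (size 3), BLX-style blend crossover (rate 0.8), per-gene Gaussian
  mutation (rate 1/n_genes) with a geometrically annealed width
  (0.25 → 0.05 log10 units), elitism 2.  Simulation failures score a
  large finite sentinel (1e12).  Deterministic under a fixed seed.
- Constraint penalties enter the objective as weight·margin² with weight
  1e3; the three shipped constraints encode the biphasic c-Met response,
  sustained late ERK activation under EGF, and reduced late pSTAT3/pERK
  after PYK2 knockdown.

## Implicit reverse functions and patient models

The reverse-function table records, on a log-spaced (synthesis, decay)
scale grid, the pre-stimulus steady-state mRNA fold change of the
personalised model relative to the base model (each grid cell relaxed
from the base basal state, the same protocol used for patient models).
Because the steady-state transcript level depends on the two rates only
through their ratio, iso-fold contours are straight lines in log space
and the log-nearest point to the fitted pair lies on the balanced
anti-diagonal; the inversion solves a 1-D root along that direction,
refined against the generating model directly (coarse-grid interpolation
misplaces the crossing by a few percent, the refined inversion reproduces
the worked 30-fold example to better than 1%).  Synthesis-only and
degradation-only adjustment rules are exposed as alternatives.

A patient model scales the conserved-pool totals (EGFR, STAT3, ERK, Cbl)
directly by their expression fold changes and realises the PYK2/c-Met
transcript folds through the reverse functions.  Because a patient's
other fold changes shift the transcriptional operating point, the
adjusted pairs are refined per patient by a damped secant iteration along
the balanced axis until the achieved steady-state fold matches the
request within 2%.  Patients whose parameter combination has no stable
basal state (rare oscillatory corners) are reported and excluded by the
pipeline, as are non-responders (patients for whom a single agent cannot
reach the analysis-level IC_x on their own model).

## Synthetic data: what it emulates, and what a green test shows

The time-course generator reproduces the wet-lab training design
(EGF stimulation series of phospho/total readouts over 24 h, mRNA series
over 8 h, PYK2 knockdown and c-Met inhibition series) from the reference
model and corrupts it with multiplicative log-normal noise, σ = 0.15 by
default — the positivity-preserving choice matching immunoblot
quantification variability.  The cohort generator draws six node
expression values per sample (log-normal, σ = 0.2 about median 1 — the
spread of within-subtype normalised expression) with subtype labels in a
discovery-cohort-shaped composition, and can plant a ground-truth
condition: a 2-fold PYK2 upregulation in a labelled half of the cohort,
with c-Met co-shifted by √2 (the two transcripts share the STAT3-driven
transcriptional program in the modelled network, so a PYK2-program
upregulation co-regulates them).  The generator parameters were fixed
once, before use in tests, such that the planted condition is recoverable
by the pipeline — they are fixtures with known ground truth, not claims
about any real cohort.  A green stratification test therefore establishes
that the pipeline recovers a planted, mechanistically coupled biomarker
at realistic noise; it does not establish effect sizes in real patients,
nor does the generator model missing data, batch effects or
protein/transcript discordance.

## Known limitations and deviations

- The synergy ranking is computed as the mean log2 of the available
  CI/BI/CDI scores across both readouts.  In this calibration the ranking
  places Gefitinib+PF396 first, the three Gefitinib pairs in descending
  order, and EMD+Stattic last; PF396+Stattic however ranks 4th of 6
  rather than in the bottom two.  The cause is structural: with
  per-readout IC_x-calibrated doses on a network whose readouts share one
  collapse-capable feedback system, Bliss-type indices inflate the
  apparent synergy of pairs containing the drug that directly divides the
  scored readout (Stattic on pSTAT3), because after a combination-induced
  collapse the direct division deepens the residual readout.  The
  corresponding acceptance test asserts the stricter expectation and is
  left failing rather than weakened.
- Under 20% F4 inhibition the Hill coefficient of the PF396→pSTAT3 curve
  falls (the asserted loss of switch-ness); the Gefitinib→pSTAT3
  coefficient instead rises slightly in this calibration.
- The PF396 dose-response curves contain a genuine fold (first-order)
  discontinuity; IC50s bisected onto the fold are quantised by its
  position, so curve comparisons across perturbations use the median
  response displacement instead.
- The network has an ultra-slow near-neutral relaxation mode
  (receptor-pool redistribution), so finite-horizon integration approaches
  the polished fixed point only to ~1e-4 in that direction.
- Whether PYK2 attenuates EGFR ubiquitination or promotes deubiquitination
  is not distinguishable from the emulated data; the attenuation variant
  is the default, the alternative is available via
  `reference_definition(pyk2_mode="promote_deub")`.
- SBML i/o is a self-contained Level 3 writer/reader (content MathML for
  all rate laws; structural metadata that SBML core cannot represent
  travels in a JSON annotation).  Round trips are exact, but documents
  from other tools are not guaranteed to import.
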