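# Methods

## Scope and data flow

`parpscreen` covers the desk-side analysis of a structure-based screening
campaign against the PARP-1 catalytic domain. Computationally expensive
physics — docking, MD, MM/GBSA energy evaluation, decoy generation — is out
of scope by design; those engines' numeric outputs (per-residue energy
tables, scored libraries, B-factors/RMSF tables, snapshot energy streams)
are the package's inputs, read from plain CSV/PDB. The bundled reference
data are the published 33-complex group-energy panel (15 rows with
experimental affinities) and the published MM/GBSA term summary for the four
confirmed screening hits; both are stored as decimal strings at their
printed 2-decimal precision, so comparisons against them are free of
float-literal drift.

## The affinity model

The core statistic is an ordinary-least-squares fit of

ΔG = c1·E_ele + c2·E_nonele + c3·E_other + c0

on complexes with experimental affinities. Choices:

- **IC50 → ΔG.** ΔG = −RT·ln(1/IC50) with R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹
  and T = 298.15 K by default. Replicate IC50s are averaged arithmetically
  in concentration space, and only when they agree within a 10-fold spread
  (the "same order of magnitude" gate); otherwise the record is rejected
  with a reason.
- **Estimator.** OLS with intercept, no weighting or regularization — with
  n = 15 labeled complexes anything richer is unjustified. At least five
  labeled rows (four parameters + 1) are required. Rank-deficiency is
  diagnosed before fitting so the error names the degenerate column.
- **Diagnostics.** R² = 1 − SSres/SStot on the fitting rows; coefficient
  standard errors are carried on the results object. The standalone
  `r_squared` helper is uncapped (it may be negative for arbitrary
  predictions).
- **Refit vs published coefficients.** Refitting on the bundled panel
  (whose energies are printed rounded to 2 decimals) gives
  (0.069, 0.095, 0.434, −3.969) with R² = 0.842. The published calibration
  (0.067, 0.104, 0.457, −3.615) achieves R² = 0.840 on the same rows: the
  least-squares surface is nearly flat along these directions (SE on the
  E_other coefficient is 0.12, on the intercept 1.14), so a calibration fit
  on unrounded energies is expected to differ from the rounded-input refit
  by amounts within one standard error, exactly as observed. Tests
  comparing predictions against tabulated values therefore use the printed
  2-decimal tolerance, while refit coefficients should be judged against
  their standard errors.

## Residue grouping

The partition into electrostatic / non-electrostatic / other is either
**explicit** (the shipped PARP-1 scheme lists the eight electrostatic pocket
residues) or **rule-based**: a residue is electrostatic iff its type is
charged (ASP/GLU/LYS/ARG — histidine is treated as uncharged, consistent
with His862 belonging to the non-electrostatic group) *and* the magnitude of
its mean contribution across the panel reaches a threshold, 0.25 kcal/mol by
default with a closed boundary. The mean (not the maximum) over the panel is
the salience statistic, reflecting distribution-level perturbation; the
numeric threshold is a package choice — no published value exists — and is
therefore configurable. Group sums use compensated summation and conserve
the table total to machine precision; unlabeled residues fall into OTHER
with a warning rather than silently vanishing.

## Screening metrics

AUC is computed by the Mann–Whitney rank formulation with midranks for ties,
which is exactly the trapezoidal area under the full step ROC curve; the
curve points come from scikit-learn. Scores follow the docking convention
(lower = better; a flag flips it). The enrichment factor takes the top
⌈fraction·n⌉ compounds with ties at the cut broken by stable input order.
Pose recovery judges the *best-scoring* candidate pose — not the closest
one — by heavy-atom RMSD without superposition (redocked poses share the
receptor frame), with success strictly below the 2 Å threshold.

## The funnel

Stage order is fixed: Lipinski prefilter (MW ≤ 500, logP ≤ 5, HBD ≤ 5,
HBA ≤ 10, closed boundaries, configurable violation allowance) → ranked
retention stages (default fractions 0.10/0.10/0.20, matching the published
protocol; each keeps ⌈fraction·n⌉ by stable sort) → truncation to the best
2000 → rescoring by the linear model keeping the best 500 → k-means in
descriptor space (k = 20 by default, the number of purchased picks) with the
member nearest each centroid as representative. Every drop is recorded with
a reason; the whole run is deterministic given library order and seed.
Scorers are pluggable callables (batch → scores), standing in for the
docking stages.

## Flexibility profiles

"Normalized B-factor" is implemented as the per-chain z-score of per-residue
backbone (N, CA, C, O) B-factor means, using the **population** (n) standard
deviation — fixed here since no published definition exists. Z-scoring is
idempotent and invariant under positive affine transforms of the raw values,
which is what makes profiles comparable across structures refined at
different overall B-factor scales, and puts RMSF profiles (normalized
identically) on the same axis. Ensemble averaging aligns residues by number
and averages normalized values over the profiles containing each residue;
the result is deliberately *not* re-normalized. The shipped helix annotation
for the PARP-1 helical domain (αA–αF, ART) is a placeholder with approximate
intervals and is marked non-authoritative in its docstring; users should
curate it against their structures. Degenerate inputs (constant B-factors,
< 3 residues, negative RMSF) raise typed errors rather than producing NaNs.

## MM/GBSA aggregation

Per-term means and SDs use the sample (n−1) convention over snapshots. The
enthalpy ΔH is summed per snapshot first, then averaged — by linearity its
mean equals the sum of term means, an identity asserted on every call (the
SDs differ, since terms are correlated within a snapshot). Differences
between compounds propagate SDs as √(SD_a² + SD_b²) under an independence
assumption; this reproduces the published difference column (e.g.
√(2.84² + 3.68²) = 4.65). Entropy is not modelled. Per-residue
decompositions are ranked ascending (most favourable first) and
cross-tabulated across compounds with explicit absences.

## Synthetic data

Generators are pure functions of their arguments with a seeded
`numpy.random.Generator`; defaults mirror the study design:

- **Energy panels** (default n = 33, noise SD 0.5 kcal/mol): group-sum
  targets drawn uniformly on the reference panel's feature ranges
  (E_ele ∈ [−56, −2], E_nonele ∈ [−55, −21], E_other ∈ [−3, 4]) and split
  across a realistic residue roster; panel features are then *computed*
  from the emitted per-residue tables, so table/feature consistency is
  exact by construction. Affinities are the linear model plus Gaussian
  noise. At n = 1000 and noise 0.5 the three slope coefficients recover to
  ±0.01; the intercept estimator has sampling SD ≈ 0.07 under these
  conditions (its variance carries the μᵀΣ⁻¹μ term of the large feature
  means), so equally tight intercept recovery requires much larger n.
- **Active/decoy scores** (default 40 vs 1990, the published design):
  decoys N(0,1), actives N(−d,1), giving expected AUC Φ(d/√2).
- **Compound libraries**: drug-likeness properties with a controllable
  Lipinski failure rate; descriptors from k Gaussian blobs spaced along the
  first axis so that well-separated blobs are exactly recoverable.
- **Flexibility ensembles**: backbone-only structures whose B-factors are
  baseline + planted per-segment offsets (in noise-SD units) + noise,
  rounded to PDB precision so they round-trip exactly through the writer.
- **Snapshot streams** (default 200 snapshots): independent Gaussians per
  term. Real MM/GBSA terms are correlated within a snapshot, so the
  generated ΔH SD exceeds what correlated terms would give — tests
  therefore check term means, not ΔH SD, against generator parameters.

What passing these tests shows — and does not. The synthetic generators
validate the estimators and bookkeeping under their own assumptions
(linearity, Gaussian noise, independent terms, spherical descriptor blobs).
They say nothing about how well a linear three-group model describes any
particular docking engine's energies; that judgement rests on the reference
panel refit (R² ≈ 0.84) and on the user's own data.

## Problem sizes

The bundled analyses are small (33 complexes, 15 labeled). The statistical
self-checks use 2×10⁵ scored compounds for the closed-form AUC comparison,
1000-compound libraries for funnel arithmetic, 10-structure ensembles for
planted-effect recovery, and n = 1000 panels for coefficient recovery —
sizes chosen so every property is measured well inside its Monte-Carlo
error while the whole suite runs in seconds.
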