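# Methods

This note records the models, parameter choices and numerical conventions
behind `impurisk`, and what the simulation-backed tests do and do not show
about real data.

## Peptide model and masses

Peptides are ordered lists of canonical residues, each optionally carrying
a modification from a controlled vocabulary (acetyl-K +42.037 Da,
deamidated-N/Q +0.985 Da, oxidized-M +15.999 Da, D-isomer ±0). Average
(not monoisotopic) residue masses are used throughout: molar doses of
multi-kDa peptides are computed from bulk material, for which the average
mass is the relevant quantity, and the case-study's printed doses
(5.8/5.7 µM at 20 µg/mL) are consistent with average masses. The mass of a
chain is Σ residue masses + 18.015 (water), −0.985 per C-terminal amide,
−2.016 per disulfide bridge, plus modification deltas. Reported µM values
are rounded to one decimal, half away from zero (5.83 → 5.8, 5.66 → 5.7);
Python's banker's rounding would get 5.75 → 5.7 wrong for this convention.
Positions are 1-based, matching impurity nomenclature ("DES-THR21" deletes
threonine 21). Disulfide pairs are re-indexed across indels and dropped
when a bridged cysteine is deleted or substituted.

Scanning requires canonical residues, so modified peptides are first
*naturalized*: each modified residue maps to an ordered list of natural
analogs (cartesian expansion, capped at 64 combinations). Deamidation
needs no table — its product is a canonical residue (N→D, Q→E). The
default acetyl-lysine analog is glutamine (neutral, polar, comparable
side-chain length); this is a heuristic default, overridable by a TSV
table, and results downstream of it inherit its uncertainty.

## Epitope scanning and calibration

Each allele is a 9×20 position weight matrix; a frame's raw score is the
sum of its nine position weights. Calibration scores a random-peptide
background (default 1,200 peptides of length 18, i.e. 12,000 frames) and
stores the per-allele mean and SD, so Z = (raw − mean)/SD. Thresholds are
the normal-tail quantiles matching the "top 5% / top 10%" definitions:
z_hit = 1.64, z_elevated = 1.28, both closed (ties count as hits). A
frame's raw score is a sum of nine independent draws, so its background
distribution is close to normal and the held-out hit rate lands in the
4–6% band the tests require.

The aggregate score subtracts the background expectation of the hit-cell
Z mass per assessment (estimated during calibration) and scales per 1,000
assessments, so 0 is the random-peptide expectation and the epitope-dense
cut of the quadrant plot. The score sums Z over *hit* cells only — summing
over all elevated cells is a defensible alternative, but hits-only keeps
the score interpretable as "significant epitope content" and makes the
hit/EpiBar/score triple internally consistent.

The shipped default matrices are synthetic (seeded standard-normal
weights). They exercise every procedure — calibration, hit calling,
EpiBars, cross-conservation — but make no claim about real allele
specificity; real analyses should supply measured matrices via the TSV
interface. For the same reason no published per-peptide score value is a
reproduction target; the tests check procedure properties (calibration
rate, brute-force equivalence, planted-structure recovery) instead.

## Cross-conservation and quadrants

The TCR/MHC face split is fixed at positions 2,3,5,7,8 vs 1,4,6,9 of a
bound 9-mer for every allele; allele-specific anchor maps exist but are
not modelled. A proteome match must share the TCR face exactly *and* be a
hit (Z ≥ 1.64) for the same allele under the same matrices — that is the
operational meaning of "same HLA restriction" here. The homology score is
the unweighted mean match depth over hit cells (0 for peptides with no
hits); scores strictly above 2.0 flag elevated tolerance potential. The
proteome index maps TCR-face patterns to 9-mer occurrences, so duplicated
proteins contribute once per occurrence by construction. Quadrant cuts
default to 0 (epitope density) and 2.0 (homology); points on a cut are
assigned to the lower-risk side, a deliberate tie-break so borderline
peptides are not over-flagged.

## New epitopes and assay selection

An impurity hit cell is *new* when no API hit for the same allele has the
same 9-mer sequence — identity by sequence, not frame index, so an indel
that shifts an unchanged epitope creates nothing. New cells whose HLA
anchors match some API hit for that allele are "altered-TCR-face";
the rest are "new-HLA-binding". Free-form impurities are aligned to the
API by global alignment (match +1, mismatch −1, gap −2, leftmost gap on
ties); edit-specified impurities use the exact mapping implied by the
edit. Assay peptides default to 15-mers centering the binding frame,
clipped (and flagged) at termini; cysteines in the window become serines,
recorded in the design provenance, to prevent disulfide-linked
aggregation in the binding assay.

The monotonicity of the new-cell count in the hit threshold is checked
empirically over random matrix/peptide draws, not asserted as a theorem:
lowering z_hit enlarges both sides' hit sets, and enlarging the API's set
can in principle retire impurity cells, so the property is a tendency of
the statistic under the tested conditions.

## Binding curves

The 4PL model y = bottom + (top − bottom)/(1 + 10^(hill·(log₁₀IC50 − x)))
is fitted to all 21 points (7 concentrations × 3 replicates, not
per-concentration means) by bounded least squares, with soft bounds
bottom ∈ [−10, 20], top ∈ [60, 110], hill ∈ [0.05, 5], and log₁₀IC50
within 3 decades of the tested range. Dose dependence — required for any
binder call — is a one-sided Spearman trend test of mean inhibition
against concentration (p < 0.05) plus the fitted IC50 lying within 10× of
the tested range; fit failure is reported as a non-binder with a
diagnostic rather than an exception. Affinity bins have closed upper
bounds ("100 nM or less" is very-high). Under the simulation conditions
the tests prescribe (true IC50 log-uniform over 10²–10⁵ nM, 10%
multiplicative CV), the median |log₁₀(fitted/true)| over 200 seeded
curves is ≤ 0.07; accuracy degrades for inflections at the edge of the
tested range, which the non-binder range gate deliberately screens.

## FluoroSpot analytics

Spot counts normalise as SFC/10⁶ = count × 10⁶/cells-per-well (default
10⁵ cells). Positivity requires all three of: SI ≥ 2 (closed), mean
SFC/10⁶ > 50 (strict), and a two-sided two-sample equal-variance
Student's t-test against medium with p < 0.05 — sidedness and pooling are
the classical reading of "Student's t-test". The SI denominator is
floored at one spot (flagged) so zero-background wells yield a defined,
conservative index. Donor QC requires positive KLH, CEFT and PHA and
negative HSA calls. Response-rate percentages round half away from zero
(7/16 → 44%, 10/16 → 63%). Condition comparisons use exact Mann–Whitney
and Wilcoxon distributions for n ≤ 12 without ties, normal approximation
with tie correction otherwise; all-zero paired differences are reported
as p = 1 with a degeneracy flag. HLA coverage is the sum of table
frequencies over allele families carried by at least one donor — it
reproduces no published coverage constant, whose underlying frequency
table is not available.

## Synthetic data: what it emulates, what it does not

Backgrounds are i.i.d. uniform-frequency peptides (a human-like frequency
profile is configurable). Proteomes are random proteins with planted
9-mer copies at non-overlapping slots; a "mutate face" option breaks one
TCR- or MHC-face position per copy so face-specific matching is testable.
Binding curves add multiplicative lognormal noise (mean-one, given CV) to
the 4PL signal above its floor. FluoroSpot counts are negative binomial —
over-dispersed relative to Poisson, as ELISpot replicates are — with
dispersion (size) 40, i.e. replicate CV ≈ 25% at a 25-spot response,
typical of FluoroSpot triplicates; responders multiply the background
mean (default 5 spots) by the effect size (default 5×). Under these
conditions the positivity rule detects ≥ 90% of planted responders at
three replicates with a null false-positive rate well under 5%, and a
planted 7/16 responder fraction is recovered within binomial error.

None of the simulators reproduce real biology: matrices are not real
allele preferences, the proteome has no homolog structure, donors have no
HLA-linked response correlation, and formulation/excipient effects on
in vitro responses are out of scope. Passing tests therefore validate the
*procedures* (calibration, counting, fitting, calling) and their operating
characteristics, not predictions for any particular drug product.

## Problem sizes and determinism

Default analysis sizes — 12,000 calibration frames, 11,000 held-out
frames, 60×120-residue proteomes, 200 recovery curves, 2,000 null
donor-conditions, 30 recovery cohorts — were chosen so each property is
measured with useful precision while the whole suite runs in well under a
minute per module. Every stochastic step takes an explicit seed;
generators are deterministic per seed, and the pipeline report records
the seed and every threshold used.

## Known limitations

- Proprietary scoring coefficients are unavailable; synthetic defaults
  mean absolute score values are not comparable across matrix sets.
- Only HLA DR class II is modelled; DQ/DP and class I are out of scope,
  as are peptide-processing (cleavage) models and register-shift
  ("twisted groove") effects.
- The acetyl-lysine analog mapping is heuristic; edits touching both
  faces are labelled "both" without weighting.
- Whether published cohort t-tests used raw counts or SFC-normalised
  values is unstated; with equal cells per well the two are equivalent,
  which is what this implementation assumes.
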