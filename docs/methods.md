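# Methods

## The synthetic study

The generator (`prmnet.simulate`) emulates a targeted PRM experiment on
sarkosyl-insoluble brain extracts so the full analysis chain can be
exercised and benchmarked against known ground truth.

**Cohort.** 44 cases in four groups (12 CTL, 8 AsymAD, 12 AD, 12 PD).
Ages and postmortem intervals are truncated-normal draws with the
group-wise means/SDs of the emulated cohort (e.g. age 76.0 ± 10.5 years
in CTL, 82.5 ± 9.7 in AsymAD; PMI 7.3 ± 3.9 h in CTL, 17.5 ± 9.6 h in
AsymAD); sexes follow the group male fractions (0.50/0.625/0.667/0.75);
CERAD (0–3), Braak (0–6) and ABC (0–3) scores are clipped rounded normal
draws around the group means (CERAD 0.2/2.8/3.0/0.2; Braak
1.6/3.0/5.9/2.2), and PD cases carry a binary neocortical Lewy-body
indicator at rate 0.5. Cases are randomly permuted over the injection
sequence; six pooled-standard injections occupy evenly spaced positions
among the 50 runs. The even spacing is an assumption — the emulated
design only states that pooled standards were interleaved.

**Targets.** 870 peptides over 390 roll-up entities: 385 RBPs, MAPT
(35 peptides), APP (9 peptides, of which 3 map to the amyloid-beta
region and roll up to a separate `Abeta` entity) and two spare slots.
Peptide sequences are synthetic tryptic-like strings; precursor m/z is
computed monoisotopically with fixed carbamidomethyl-Cys (+57.0215 Da).

**Abundance model.** Proteins live on the log2 scale:

    y_ps = base_p + sigma_bio * (sqrt(c) * f_m(s) + sqrt(1-c) * e_ps)
           + shift(m, group_s) + covariate terms

with per-module standard-normal factors `f_m`, within-module correlation
`c = 0.7`, biological SD `sigma_bio = 0.6` log2 units, and per-protein
baselines ~ N(17, 1.5). 29 modules are planted with sizes
round(60·rank^−0.8) clipped to [5, 60] (≈330 assigned proteins; the rest
are background with independent noise). The default effect table plants
an AsymAD/AD-increased module (which also hosts MAPT and Abeta, +0.8 and
+1.2 log2 units), an AD-increased module (+0.8), an AD-decreased module
(−0.8) and a PD-decreased module (−0.8) — the qualitative pattern of
stage-specific snRNP insolubility gains and translation-machinery losses.
Covariate slopes (age 0.01 log2/yr, sex 0.10, PMI 0.01 log2/h) are small
but nonzero so residualization is testable.

**Measurement layer.** Observed transition areas are
`2^y × peptide share × fragment share × drift(j) × lognormal noise`,
where each peptide's ionization share within its entity and its 3–6
fragment shares are fixed gamma/Dirichlet draws, drift is the
multiplicative per-injection scalar `1.417 − 0.0167·j` (shared by all
peptides of an injection, matching a correction that is a single
per-injection scalar), and the lognormal noise has unit mean and CV
`noise_cv = 0.15` by default — a realistic technical CV for targeted
PRM. The reference mix (6 peptide sets × 5 levels, exact tenfold series
from 0.0001× to 1×) is spiked at a constant nominal amount and sees the
same drift and noise.

**Missingness.** Missing values are drawn completely at random per
entity × sample at rate 0.0073 and zero out *all* of that entity's
peptides in that injection, so the protein-level zero fraction matches
the configured rate (0.73% of the 17,160 matrix cells in expectation).
Peptide-level MCAR at the same rate would make protein-level zeros
vanishingly rare, contradicting the matrix-level bookkeeping the
pipeline is checked against; entity-level masking is the reading that
makes the arithmetic consistent.

**What the generator does not emulate.** Chromatographic peak shape and
interference, retention-time drift, peptide-specific (non-shared)
drift, informative missingness (low-abundance dropout), PTM site
structure, and correlated biological covariates beyond the planted
age/sex/PMI slopes. Passing tests therefore demonstrate correctness of
the *procedures* under the stated model, not robustness to every
artifact of real LC-MS data.

**Determinism.** Every stochastic component draws from
`default_rng(SeedSequence([seed, stream]))` with a fixed stream id per
purpose, so identical configurations give byte-identical outputs and
sub-products (cohort, targets, truth) are stable when other components
change.

## Drift correction

Correction factors use the observed per-injection mean ratios Ī_Rj, not
the fitted line; the OLS fit (slope, intercept, R²) is a diagnostic
only. Consequently correction cancels *any* positive multiplicative
per-injection drift exactly at zero noise (up to one global scalar, the
run-mean drift level), not just linear drift. Calibration uses the
0.01× dilution level; the four reference peptides with the highest
per-peptide R² of area on injection index are selected, mirroring the
"most linear" selection rule. CVs are reported as 100·SD/mean with the
n−1 denominator (conventional for QC; the choice is not dictated by the
emulated protocol). Pooled-standard injections receive correction
factors like any sample but are excluded from group statistics.

Note one subtlety: because each peptide's intensity ratio is normalized
by its own run-wide mean, the mean ratio at injection j equals
`d(j) / mean_j d(j)` rather than the raw drift line, so a refit of
generator output recovers the planted slope only up to that scale
factor (≈0.9% here). The acceptance check for the printed line
therefore fits a ratio series lying on the line itself.

## Preprocessing

The stage order is fixed and enforced: correction → roll-up → half-min
imputation → log2 → residualization; out-of-order calls raise. Half-min
imputation is row-wise at the level being analyzed; all-zero rows cannot
define a half-minimum and are dropped with a logged warning, never
silently. Residualization fits ordinary least squares per protein on
(intercept, age, sex as 0/1, PMI) and returns residual + grand mean so
group contrasts keep their location; constant covariates are dropped
with a warning. Residuals are exactly orthogonal to the retained
centered covariates.

Because PMI and age differ between groups, regressing them out removes
part of the between-group variance even under a null: omnibus tests on
residualized data are mildly conservative. This is an inherent property
of the regress-then-test order, which the pipeline keeps; the
calibration tests evaluate the test statistics on unresidualized null
data.

## Differential statistics

Equal-variance Student t (not Welch), two-tailed, disease vs control on
the residualized log2 matrix; the fold-change flag threshold is linear
±1.5-fold, i.e. |log2 FC| > log2 1.5. p-values are floored at 1e-300 and
never adjusted for multiple testing in the default path (a deliberate
property of the small-cohort design this mirrors); Benjamini–Hochberg is
available to callers via `statsmodels` if wanted but is not wired into
the default outputs. Kruskal–Wallis and one-way ANOVA provide omnibus
p-values with star bins at 0.05/0.01/0.001; entities constant within
every group are degenerate and reported at p = 1 with a warning.

## Network construction

bicor uses the conventional 9×MAD tuning constant, per-vector Pearson
fallback when MAD = 0, and NaN for constant vectors. Signed adjacency is
((1+ρ)/2)^β; the default β = 23 with the mean-denominator TOM. Soft
powers are chosen as the lowest candidate whose binned log-log
connectivity fit reaches R² 0.80, else the first power whose R² gain
drops below 0.01 (plateau rule).

The dynamic hybrid tree cut is re-implemented in simplified form, and
this is the package's main algorithmic design choice. At β = 23 the TOM
dissimilarities of weakly-correlated module pairs are compressed into a
thin band near 1, so any rule based on absolute dendrogram heights is
fragile. The cut therefore works on merge *order*:

1. average-linkage dendrogram on 1−TOM;
2. global cut at the height maximizing the number of branches of at
   least the effective minimum size, where deepSplit maps to that
   minimum (`min_module_size × (1 + (4 − deepSplit))`: 5 at deepSplit 4,
   25 at 0). Candidate cuts are evaluated only between *distinct* merge
   heights (a fully tied dissimilarity yields one module) and the lowest
   height attaining the maximum is taken;
3. per-branch refinement: each branch is re-cut by the same rule and
   split only where sub-branch eigenproteins share less than half their
   variance (|r| < √0.5, grouped by single linkage) — genuinely distinct
   modules that merged below the global cut (e.g. two disease-shifted
   modules correlated through their shared group pattern) are separated,
   while transient clumps of one module are not;
4. PAM stage: unassigned proteins join the nearest module by average
   dissimilarity, restricted to their own dendrogram branch when
   `pam_respects_dendro`, and capped by both the cut height and the
   module's internal spread (largest member-to-rest average), a
   core-scatter-style guard against absorbing unrelated proteins.

Merging then proceeds on eigenprotein correlation > 1 − 0.07 with
recomputation after every merge; members with own-module kME < 0.30 move
to the unassigned bin; a member is reassigned where its kME is higher
and the Fisher-z test on the kME difference is significant at p < 0.05
(a simplified stand-in for the reference reassignment test). Modules are
labelled M1..Mk by decreasing size, M0 unassigned. Eigenproteins are
first right singular vectors of the member-standardized submatrix, unit
norm, sign fixed positive against the module-mean profile (ties toward a
positive first coordinate), so the whole stage is deterministic.

Bit-compatibility with the reference implementation is explicitly not
promised; recovery of planted structure is the correctness criterion.
Under the default conditions (29 modules, within-module correlation 0.7,
390 × 44) the stage returns 29 modules at the default seed and 27–29
across seeds, with mean adjusted Rand index ≈ 0.93 against the planted
labels; the residual discrepancy is background proteins whose chance
correlation with a module factor at n = 44 exceeds the kME threshold.

For a correlated pair of module members the eigenprotein variance
explained is (1 + |r|)/2 (Gram eigenvalues 1 ± |r|); a perfectly
anticorrelated pair is rank one with variance explained 1.

Module–trait correlations use bicor with the two-tailed Student p for a
correlation coefficient (a permutation scheme would also be defensible;
the Student p is the simpler documented choice); diagnoses are binarized
one-vs-rest. The pathology ranking reports bicor of every protein
against the amyloid-beta and tau profiles across samples.

## Enrichment

Two-tailed Fisher exact p on the 2×2 overlap table against a supplied
background universe; the signed Z equivalent is the standard-normal
quantile of p/2, positive when the observed overlap exceeds its
expectation. Only over-represented pairs with Z > 1.96 *and* overlap ≥ 3
symbols are flagged — the 3-symbol rule is applied to the overlap, the
reading under which a matched-symbol minimum makes sense. Annotation
input is a plain two-column (term, gene) TSV or GMT; no ontology-graph
propagation. The macro-cluster count is a parameter (default 6), not
inferred. With a degenerate universe (background = module ∪ term) the
overlap can never exceed expectation, so nothing is flagged.

## Pipeline

Seven stages (simulate, quantify, normalize, rollup, diff, network,
enrich) run in fixed order over a run directory. Each stage records
input and output SHA-256 checksums, parameters and wall time in
`manifest.json`; a rerun skips stages whose inputs, parameters and
outputs are unchanged, and a downstream stage refuses to read an
intermediate whose checksum no longer matches what its producer wrote
(naming the file). All tabular outputs are RFC-4180 CSV with UTF-8 and
'.' decimals. Execution is single-threaded; outputs are deterministic
functions of config + seed.

## Problem sizes

The test suite and the acceptance script run the full 390 × 44 design
(the study scale); the module-recovery check repeats it over 20 seeds.
Structural and orchestration tests use a reduced 24-protein / 15-case
configuration, which exercises every code path at a fraction of the
cost. Brute-force oracles (bicor, TOM, OLS, eigenprotein, Fisher
enumeration) run on instances of at most 20–30 elements where exhaustive
computation is exact and fast.

## Known limitations

- The tree cut is a behavioral, not literal, port of the reference
  dynamic hybrid algorithm; deepSplit values other than the default 4
  map onto a coarser effective branch-size rule rather than the
  reference's four-parameter sensitivity schedule.
- The kME reassignment test treats the two correlations as independent
  Fisher-z draws, ignoring their dependence through the shared member
  profile.
- Under-representation Z signs are emitted but never flagged
  significant, and no across-term multiple-testing control is applied.
- The generator's lognormal noise and MCAR missingness are simpler than
  real PRM error structure; see the generator section for the full list
  of unmodelled features.
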