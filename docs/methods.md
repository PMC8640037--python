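# Methods

This note records the models the package implements, the conventions and
numerical choices behind them, what the synthetic cohorts do and do not
emulate, and the design decisions taken where the underlying procedure
left room.

## Editing events and QC

An editing call is one genomic substitution observed in one sample as
reference/alternative read depths; its level is alt/(ref+alt).  Event-level
QC applies four filters in a fixed order: (1) total depth ≥ 20 per call,
(2) alternative depth ≥ 5 per call, (3) site frequency ≥ 10%, (4) site not
at a known genomic-variant position.  Audit counts are attributed to the
first failing filter, so input = passing + Σ removed holds exactly at both
the call level (filters 1–2) and the site level (filters 3–4); a
brute-force per-call re-check is part of the test suite.

Two readings of filter (3) exist in the field: the proportion of subjects
carrying a passing call ("prevalence") or the per-call allele fraction.
We default to prevalence — frequency and level are distinct axes of an
atlas (events are plotted level-versus-frequency), and "frequent in ≥ 10%
of subjects" is the phrase the prevalence reading matches — and expose
`frequency_mode="level"` as a switch.  A subject carries an event if at
least one of their samples in the dataset has a passing call; the
frequency denominator is the number of distinct subjects in the table
(overridable).

Canonical A-to-I status is decided from the genome-reported pair alone
(A>G or T>C), independent of transcript annotation, so both orientations
tally as canonical without requiring strand-resolved gene models.

### Annotation

Positions are annotated against strand-aware transcript models with
1-based fully closed coordinates throughout.  When transcripts disagree,
the most transcript-internal category wins: exonic (CDS) > 5′UTR > 3′UTR >
intronic > ncRNA > upstream > downstream > intergenic.  Upstream and
downstream are the 1-kb windows 5′ of the transcription start and 3′ of
the transcript end, strand-aware.  The closest gene is the nearest model
span (distance 0 inside), ties broken by lexicographic gene ID so outputs
are deterministic.  Reported status is set membership against a catalogue
of previously published editing positions.

## Re-coding prediction and the edited-peptide database

For a CDS position, the edited base is substituted on the coding strand
(a genomic T>C on a minus-strand transcript is A>G in transcript space),
the affected codon translated with the standard code, and the edit is
re-coding iff the amino acid changes.  All 2^k − 1 non-empty combinations
of a transcript's re-coding edits become edited proteoforms; a guard
refuses k > 16 (65,535 forms) since realistic per-transcript k is small.
The initiator methionine is retained; translation truncates at the first
stop, and an edit creating a premature stop truncates the proteoform with
a warning (canonical A>G chemistry cannot create a stop, but the guard
also covers arbitrary substitutions and model defects).

Digestion is fully tryptic under the Keil rule — cleave C-terminal to K or
R except before P, the convention of the common search engines — with up
to 2 missed cleavages and a minimum length of 6 residues, emitted N→C then
by missed-cleavage count.  The database keeps peptides that (a) cover at
least one edited residue and (b) are absent from the digest of the
unedited proteome under identical parameters, deduplicated by sequence
with all source proteoforms retained.  Correctness is pinned to an
independent brute-force enumerator over all substrings (every start/end at
a valid cleavage boundary), run on random proteins up to 50 residues.
Genetic variation is deliberately excluded from the database: admitting
variant peptides alongside edited ones would inflate false discovery in
downstream matching.  Observed-peptide matching is exact string equality;
per-site concordance reports "confirmed" versus "RNA-only".

## TAMPOR batch correction

The abundance matrix is peptides × samples, positive with missing entries,
each sample labelled with its TMT batch and a GIS (pooled global internal
standard) flag.  Before correction, peptides with ≥ 50% missing values are
culled — except editing-specific peptides, which are sparse by nature and
are the object of study.

Each iteration applies, per entry,

    abundance / median_GIS(batch)  ×  grand_median / median_case(centred batch)

where the first denominator is the row's median over the batch's GIS
channels, the second median runs over the batch's case samples of the
median-centred abundances, and the grand median is the row's median of the
batch medians.  The matrix is then log2-transformed, each sample column is
centred on its median log2 ratio, anti-logged, and rows are rescaled to
the row-wise geometric means extracted before the first iteration (so row
geometric means are an exact invariant of the algorithm).  Iteration stops
when the maximum entry-wise relative change drops below `tol` (default
1e-8, `max_iter` 250); non-convergence is flagged on the results object
and warned, never silent.  An `all-samples` mode replaces both restricted
medians with whole-batch medians for matrices without usable GIS channels.

Medians and geometric means are computed over present entries only; a row
whose GIS channels are all missing in some batch propagates missingness
for that batch's entries rather than guessing.  On a noise-free two-batch
matrix with a planted factor, batch medians equalise to machine precision
in two iterations and the recovered factor (median raw/corrected ratio
over GIS entries, which carry no sample effects) is exact.

Sample outliers are flagged by network connectivity — the per-sample sum
of pairwise Pearson correlations of log2 abundances over shared-present
peptides — at |z| > 3, with one re-iteration after removing the first
pass's flags; zero connectivity variance flags nothing.  Edited/non-edited
ratios divide within-sample relative abundances of an edited peptide by
its unedited counterpart; because peptide-specific ionisation efficiencies
do not cancel across different peptides, these ratios compare samples
within a pair only.

## Association framework

All GLMs are Gaussian with identity link (the underlying procedure's "glm"
is unspecified; levels are proportions that sit well inside (0,1) here,
and a `logit-level` option applies an empirical-logit transform first).
Direction follows the analysis: editing level is the **response** for
diagnosis models (beta = level change per diagnosis step, diagnosis
ordinal 0/1/2, MAYO-like datasets 0/2 only), and the **exposure** for
pathology/cognition and cis-effect models.  Covariate sets are configured
per dataset (e.g. sex, age, PMI, RIN, batch, study for a ROSMAP-like
dataset; race replacing study for MSBB-like; tissue source for MAYO-like).
Rows with missing covariates are listwise-deleted with the count reported;
constant-level sites are skipped and listed.

When sites share a complete design matrix the per-site fits are computed
with a single vectorised least-squares pass — algebraically identical to
the one-site-at-a-time GLM, which the tests verify against statsmodels.

Regional contrasts fit, per site, a linear mixed model with a subject
random intercept on subjects sampled in both regions; singular or constant
fits are flagged and excluded from the multiplicity count.

Stage II pools per-dataset (beta, se) by inverse-variance fixed effects;
sites present in fewer than two datasets are carried forward flagged, not
silently pooled.  The Stage-I dataset is included in the Stage-II pool, as
in the original two-stage design, without overlap correction — a known
statistical caveat of that design that mildly anti-conservatively reuses
the Stage-I samples.  Cochran's Q is reported but never used to filter
(fixed effects only).  λ divides the median association χ²₁ by 0.4549
(the χ²₁ median).  Bonferroni thresholds always use the realized number of
tested events, which is why different analyses carry different
denominators.  Sex-stratified analysis is a rerun within strata, with no
interaction term.

Cis-effect fits regress (pre-normalised, log-scale) expression on binary
editing status with covariates, and classify each fit by sign(beta) × tier
(non p > 0.05, nominal, genome-wide), summarised per genomic-region
annotation.  The PCA of top events standardises columns to mean 0 / SD 1
(ddof = 1), decomposes by SVD, and fixes signs so each component's
largest-magnitude loading is positive.

## Synthetic cohorts

The generator emulates the structure of a multi-dataset brain cohort: four
datasets of 600 subjects by default, each sampled in two regions, with one
MAYO-like dataset lacking MCI subjects.  Each transcript occupies its own
toy chromosome with 1.5-kb flanks, a 60-nt 5′UTR, a CDS split 90 + 150 nt
by a 200-nt intron, and an 80-nt 3′UTR; strands alternate.  Editing sites
sit at coding-strand adenosines; 30% are placed in CDS by default
(candidate re-coding events), the rest in UTRs, introns and flanks.  Five
percent of sites are marked as known genomic variants (QC contamination)
and half as previously reported; the two subsets are disjoint by
construction, and planted-effect sites avoid the variant subset so they
survive QC.

Per subject × site, the true level is the site's base level (uniform on
0.05–0.60; 0.10–0.50 for planted sites so shifts never clip) plus a
subject-level Gaussian wobble of SD 0.02, plus the planted regional delta
(0.30 in the second region) or diagnosis slope (0.05 per step) at the
planted sites.  Total depths are negative-binomial (dispersion 10) around
a mean of 500, giving a realistic low-depth tail that fails QC naturally,
and alternative counts are binomial at the true level.  At these sizes the
sampling standard error of the recovered diagnosis slope is ≈ 0.0015, so
the recovery checks (|bias| < 0.005 for the disease slope averaged over
the ten planted sites, < 0.02 for the regional delta) are comfortably
powered without being vacuous.  The peptide generator produces
baseline × batch factor × sample factor × log-normal noise with two GIS
channels and eight case samples per batch, default batch factors (1, 2),
noise SD 0.05 and 20% missingness.

What the generator does **not** emulate: alignment artifacts and
hyper-editing clusters, Alu context, linkage between nearby sites,
cell-type-composition confounding, depth–level correlation, genuine
covariate effects on editing, and TMT isotope impurity or ratio
compression.  Passing recovery tests therefore demonstrates estimator
correctness under the declared sampling model, not robustness to every
failure mode of real data.

All randomness flows from integer-seeded NumPy generators with fixed
stream offsets per stage, so a fixed seed reproduces outputs byte for
byte; the pipeline manifest records seed, row counts and SHA-256 checksums
of every artifact.

## Problem sizes in the checks

The null-calibration study uses 5,000 sites across four datasets of 300
subjects; parameter recovery uses the default design (600 subjects, 60
sites, depth 500, one-to-four datasets); TAMPOR checks use 50–200 peptides
over two batches; the digestion oracle uses 200 random proteins of up to
50 residues — sizes at which every property is sharply testable while the
whole suite runs in well under a minute.

## Known limitations

- The Gaussian identity link can in principle predict levels outside
  [0, 1]; the logit option exists but is not the default, to keep betas in
  interpretable level units.
- Connectivity outlier removal re-iterates exactly once; a fully
  iterative-to-convergence variant would differ on pathological inputs.
- The combinatorial proteoform guard refuses rather than samples; for
  k > 16 re-coding sites on one transcript, the caller must split or
  filter the sites.
- Exact peptide matching treats I/L as distinct, which physical mass
  spectra cannot; concordance counts are therefore optimistic about
  distinguishability.
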