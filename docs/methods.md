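# Methods

## Data model and preprocessing

Inputs are a protein-group × run matrix of label-free intensities (zeros
are treated as "not quantified"), a design table assigning each LC-MS run
a background (bait-tagged or wild-type control), stimulation time,
biological replicate and technical replicate, and optionally a reference
list of known physical interactions. Protein groups are mapped to one
display symbol each (first gene name, else first accession; merged by
summing when several groups share a symbol). Ubiquitin precursors
(UBA52, RPS27A, UBB, UBC) collapse to a single UB entry by default, since
peptide evidence for ubiquitin cannot be attributed to a precursor gene;
the alias map is configurable. Reference symbols are matched
case-insensitively because human and mouse symbol casing differs.

Preprocessing operates on log₁₀ intensities (the base is a convention;
any fixed base gives identical decisions downstream) in four steps:

1. *Spike-in normalization* (optional): each run divided by its total
   spike-in standard intensity, factors rescaled to grand mean 1. Off by
   default because synthetic data carry no spike-ins.
2. *Global mean normalization*: per-run additive offsets anchored on the
   proteins quantified in every run, equalizing each run's anchor-set
   mean to the grand mean. Mean anchoring removes between-run shifts up
   to one global constant, which no downstream statistic sees (all are
   contrasts).
3. *Imputation*: per-protein means and SDs of log control intensities are
   summarized into μ₀ = 5th percentile of the means (linear-interpolation
   percentile) and σ₀ = mean of the SDs; every missing cell is drawn
   independently from N(μ₀, σ₀). Draws are assigned in canonical
   (protein, run) order, making the result invariant to row/column
   permutations of the input; observed values are never overwritten. If
   control coverage is degenerate the model falls back to the global 5th
   percentile with a warning.
4. *Per-condition normalization*: within each stimulation time, every
   run's mean log intensity (over all proteins) is shifted to the
   condition mean, removing residual per-run loading differences between
   the bait and control groups being compared.

Imputation is deliberately placed between global and per-condition
normalization: the background model needs globally comparable runs, and
the per-condition step needs complete columns.

## Interactor detection

For protein p at time t, with bait-run values x and control-run values y
(log₁₀, after preprocessing): enrichment r = 10^(x̄ − ȳ) and P from the
one-way ANOVA F-test with (1, n₁+n₂−2) degrees of freedom (identical to
the two-group equal-variance t-test). Degenerate groups (zero pooled
within-group variance) give P = 1 when the means agree and a machine-tiny
P when they differ. A protein is selected at t when P < P* and r > r*.

The selection is stabilized by a bootstrap: in each of 200 iterations the
run values of every (protein, time, group) cell set are resampled with
replacement (imputed values are resampled along with observed ones, they
are ordinary values once drawn), and the selection rule re-applied.
P(Detection) at t is the fraction of iterations in which the protein was
selected; ⟨r(t)⟩ and ⟨P(t)⟩ are bootstrap means (⟨r(t)⟩ averages the
per-iteration geometric-mean ratios). A protein is a specific interactor
if P(Detection) ≥ 0.9 at some time; a fraction exactly at the threshold
counts ("at least 90%"). The bait itself always passes and is flagged but
excluded from the interactor list. Defaults: P* = 0.001 for
triplicate-technical designs, 0.005 for duplicate designs, r* = 2,
200 iterations, threshold 0.9.

The raw ANOVA p-value is used by default; a per-time Benjamini–Hochberg
adjustment within each bootstrap iteration is available as
`p_adjust="bh"` for users who prefer FDR-adjusted volcano plots. Both
modes are recorded in the audit trail.

## Recruitment profiles and the co-recruitment network

Bait-background runs are first scaled so the bait's intensity is constant
across runs (log-offset per run); each interactor's series in each
biological replicate is then divided by its maximum-over-time of
technical-replicate means, giving profiles in [0, 1].

Pairing convention: the Pearson correlation between two interactors is
computed over the concatenation of *per-technical-run* normalized points
across all (bio replicate, time) strata — 45 points for a 3 bio × 3 tech
× 5 time design. Keeping technical runs as observations preserves the
full evidence about co-variation; averaging them first (available as
`points="tech-mean"`, 15 points) discards within-stratum information and
with only 13 residual degrees of freedom cannot produce p-values small
enough for moderately strong correlations (r ≈ 0.75) to survive the
Bonferroni bar, which would contradict the edge strengths the method is
designed to detect. Imputed cells are masked out of the profiles: an
imputed value is a background draw carrying no recruitment information,
so pairs are correlated over the points actually quantified for both
proteins (minimum 3).

For each pair, R_ij and P_ij are the means of the Pearson coefficient and
its two-sided p-value (t-distribution, n−2 df) over 1,000 bootstrap
resamples of the paired points; zero-variance resamples are skipped and
counted. One random substream is spawned per pair in sorted-protein
order, so the matrix is deterministic and invariant to input ordering.
Averaging p-values over resamples is conservative: the mean is dominated
by the weakest resamples, suppressing correlations that depend on a few
influential points.

The network keeps edges with P_ij < α/(N(N−1)/2) for N interactors
(bait excluded), default α = 5×10⁻⁵; edges with R > 0.8 form the
high-confidence subnetwork. K-means (squared Euclidean, best of 10
initializations) on the rows of R partitions interactors into kinetic
modules; k is a user choice, with a silhouette-score helper
(`suggest_k`) since the correlation structure, not any fixed constant,
should determine it.

## Benchmarking

Precision is |predicted ∩ reference| / |predicted| over unordered symbol
pairs after alias mapping. The random baseline is 2K/(N(N−1)) where K is
the number of reference edges with both endpoints among the N network
nodes. First-neighbor validation reports the fraction of an anchor's
distance-1 neighbors that lie in a target set; the matching random
expectation uses all N network nodes as candidates (the convention that
matches the 15/98 style of arithmetic, even though one could argue for
N−1). Distance-stratified validation bins nodes by unweighted
shortest-path distance from the anchor, with unreachable nodes at ∞.
Probabilities are reported raw and at 2 decimals, percentages and folds
at 1 decimal.

## Synthetic data generator

The generator emulates one bait experiment with matched wild-type
controls: 5 conditions (0, 30, 120, 300, 600 s), configurable biological
and technical replicates (presets: 3×3 "CBL-like", 3×2 "CBLB-like"),
200 contaminants and 40 planted preys by default.

* Every protein has a log₁₀ baseline drawn from N(7.0, 0.6); contaminants
  show that baseline in both backgrounds, so the enrichment test must
  reject them.
* A planted prey in a bait run at time t has expectation
  baseline + log₁₀(fold × profile(t)), fold = 8 by default, profiles
  taken from named presets (early-peak, late-peak, sustained, biphasic,
  constitutive) with max = 1. The four default module shapes are chosen
  mutually near-orthogonal (max pairwise |r| = 0.40) so that module
  membership and correlation structure coincide; a constitutive (flat)
  module would carry no kinetic information and its pairs would be
  unrecoverable by co-recruitment analysis *by construction*, so it is
  not a default.
* Co-recruitment is planted as a recruitment fluctuation shared by all
  members of a module within each (biological replicate, time) stratum
  (SD 0.25 log₁₀). This is what physical complex stoichiometry implies —
  members are captured in proportion to the amount of complex in that
  particular pulldown — and it is the signal the correlation stage is
  meant to detect; without any shared fluctuation, "modules" would exist
  only as equal mean shapes and the attainable pair correlation would be
  bounded by technical noise alone.
* Measurement noise totals 0.15 SD log₁₀ per cell, decomposed into a
  run-level component shared by all proteins of a run (loading/sampling
  variation — exactly what the normalization stages remove) and an
  independent protein-level residual of 0.08 (≈ 20% CV, a typical
  label-free technical replicate figure).
* The bait is present only in bait runs at a high constant level
  (10^9.5). Cells below the detection floor (10^5.5) are censored, plus a
  2% missing-completely-at-random rate; both yield the left-censored
  missingness pattern the imputation model assumes. The MCAR rate is kept
  low enough that a realistic always-detected anchor set survives 90
  runs.
* A reference-interaction list is derived from the planted within-module
  pairs by independent Bernoulli thinning at a configurable recall.

What the generator does *not* emulate: peptide-level evidence and
match-between-runs artifacts, per-protein variance heterogeneity (one
residual SD for all proteins), correlated contaminant structure (e.g.
carry-over), and non-physical sources of co-recruitment such as shared
subcellular compartments. Passing the recovery tests therefore shows the
pipeline is correct and well calibrated under these idealized conditions,
not that real data will reach the same sensitivity or edge recall.

## Determinism and numerics

A single master seed derives per-stage child seeds (imputation, detection
bootstrap, correlation bootstrap, K-means) through a seed sequence, so
full runs are bit-identical and stages reproducible in isolation; every
offset, threshold and seed actually applied is written to the run
manifest. P-values are clipped to [tiny, 1]; |r| = 1 pairs get the
machine-tiny p-value; percentile estimation uses linear interpolation.
Degenerate inputs (no interactors, empty reference, isolated nodes,
all-missing series) return empty-but-valid results rather than errors
wherever a downstream consumer can proceed.

## Problem sizes

Unit tests run on reduced designs (8 planted preys, 30 contaminants);
the parameter-recovery evaluation uses the full default conditions (40
preys, 200 contaminants, both replicate designs) over five generator
seeds, chosen so the complete suite and the acceptance script each finish
in well under a minute on one CPU.
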