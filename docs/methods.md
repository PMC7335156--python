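# Methods

## Measurement model and methylcytosine calling

Bisulphite sequencing converts unmethylated cytosines to uracil (read
as T) while methylated cytosines stay C.  We model the methylated read
count at a reference cytosine with coverage N and true level m as
Binomial(N, m + (1 − m)·ε): non-conversion inflates apparent
methylation, while truly methylated bases are assumed to be read
correctly.  The error rate ε is estimated per sample by pooling every
cytosine of the chloroplast chromosome — which carries no cytosine
methylation in plants — across contexts and strands:
ε = Σ n_meth / Σ N.  Pooling gives one error measure per sample; the
estimate is a maximum-likelihood binomial proportion whose standard
error √(ε(1−ε)/ΣN) is ~7·10⁻⁵ at the default simulated depth.

A site is called a methylcytosine when its coverage is at least
`min_depth` (default 5) and the exact upper-tail probability
P(X ≥ n_meth | X ~ Bin(N, ε)) is at most `alpha` (default 10⁻⁴).  The
tail is evaluated through the regularised incomplete beta function
(scipy's binomial survival function), never a normal approximation:
at depth 5 the threshold sits ~10 orders of magnitude into the tail
(0.006⁵ ≈ 8·10⁻¹²) where the approximation is useless.  No
multiple-testing correction is applied at the site level; the fixed
alpha is the published criterion for this analysis family.  The
percentage of methylcytosines per context uses sequencing-callable
sites (coverage ≥ min_depth) as denominator — the uncovered genome is
unknowable from the data; the choice is explicit and configurable.

## Sequence context

Context is classified from the reference 3-mer on the cytosine's
strand: CG if the next base is G, CHG if the next is H (≠ G) and the
one after is G, else CHH.  N counts as H (it cannot be called G), and
bases missing past the 3′ chromosome end are treated as H, so a
terminal cytosine is CHH unless its remaining neighbour is a G.  This
makes classification a deterministic total function; it affects a
handful of sites per chromosome end.

## DMR detection

Windows of 100 bp slide by 50 bp.  Window starts run 0, 50, 100, …
while a full step remains; a final start is added if needed so the
windows exactly cover the chromosome.  Within a window and context,
a cytosine contributes only when its coverage, pooled over replicates,
is ≥ 5 in both groups — the symmetric, stricter reading of the depth
rule, exposed as `min_depth`.  Windows need ≥ 3 contributing cytosines
(`min_cytosines`).

The group test is a binomial GLM with logit link whose only predictor
is the group indicator, compared to the intercept-only model by
likelihood ratio.  Because replicates are i.i.d. binomial observations
within a group, the group-wise MLEs pool the replicate counts and the
LR statistic reduces exactly to the 2×2 G-test on
[[M_A, N_A−M_A], [M_B, N_B−M_B]] — for any number of replicates, not
only one observation per group.  We therefore evaluate the closed form
(vectorised over all windows) and keep statsmodels' GLM as an
independent oracle in the tests.  Degenerate windows (both groups all-
or un-methylated) give p = 1; windows with zero coverage in a group
are excluded.  The model has no overdispersion term; replicate
variability beyond binomial is out of scope for v1 (a beta-binomial
switch would slot into the same interface).

q-values use a π₀-adjusted step-up rule: q₍ᵢ₎ = π̂₀·n·p₍ᵢ₎/i, made
monotone from the largest p down.  π̂₀ is the Storey-type estimate
#{p > λ}/(n(1−λ)) averaged over λ ∈ {0.4, …, 0.8} and clipped to
(0, 1].  The published analysis names a sliding-linear-model q-value;
its exact parameters are not recoverable, so we use this standard
π₀-adjusted family, whose π₀ = 1 member is bitwise Benjamini–Hochberg
(`pi0` is config-exposed).

Windows pass with |Δlevel| ≥ 25 points and q ≤ 0.01.  Passing bins of
one chromosome, context and direction merge when the gap to the
previous bin is ≤ 50 bp (overlaps always merge); hyper and hypo bins
never merge, so hyper- and hypo-DMRs are disjoint sets.  A DMR's
`mean_diff` is the coverage-weighted mean of member-bin differences
and `min_q` the smallest member q.  The difference sign is
condition B − condition A (B the later stage, or the focal cultivar),
so "hyper" means higher methylation in B.

## Annotation and TE status

Gene regions are the strand-aware body plus 2-kb flanks from the
transcription start and termination sites, clipped at chromosome
bounds; unstranded TEs orient like plus-strand features.  A DMR
overlapping several regions (≥ 1 bp, half-open intervals) is counted
in each — a boundary-spanning DMR belongs to both body and flank.
DMR-associated status is computed per comparison and per context.

TEs are methylated when they carry ≥ 1 called mC per 100 bp of body
and non-methylated when they carry none.  Densities strictly between 0
and 1 per 100 bp are undefined under that rule; we label them an
explicit "intermediate" class and exclude them from contrasts rather
than silently assign them (a config flag folds them into
non-methylated for a permissive reading).  TE-frequency contrasts
between gene sets use the two-sided Mann–Whitney rank-sum test —
set-vs-set comparisons are unpaired, so a signed-rank test would be
invalid; the paired Wilcoxon signed-rank form is used for
region-vs-region contrasts within one gene set, where pairing by gene
is natural.  Both are available.

## Metagene profiles and deciles

Body and each flank split into 10 near-equal bins (boundaries by
floor; sizes differ by ≤ 1 bp); the 30-bin axis is 5′→3′, so minus-
strand features reverse.  Bin level is 100·Σn_meth/ΣN pooled over all
contributing cytosines of the context across the stratum's features —
the "normalise to the cytosines present in the bin" reading; a
per-feature-mean mode exists for comparison.  All covered sites
contribute their observed proportion by default (restricting to called
mCs would bias low-methylation regions upward); a called-only mode
supports mC-style summaries.  Features with bodies shorter than the
bin count are skipped.

Expression deciles sort genes by FPKM with ties broken by gene id
(deterministic), split into 10 near-equal groups; decile 1 is
non-expressed, decile 10 highest.

## Small RNA

A read is assigned by its middle base, start + ⌊(length−1)/2⌋ —
left-of-centre for even lengths; any fixed convention preserves the
contrasts.  Reads deduplicate on (chrom, start, end, strand),
mirroring the unique-read collapse of small-RNA preprocessing.
Density is reads per 100 bp per bin, pooled across features.  The
TE-set contrast opposes middle-base counts in each set's bodies to the
remaining body bp in a 2×2 Fisher exact test — one defensible reading
of an unstated published procedure; a per-TE rank-test mode is also
provided.

## Synthetic data

The generator inverts the measurement model.  A uniform-random ACGT
assembly carries non-overlapping genes and TEs (a configurable
fraction of TEs intragenic) plus a featureless chloroplast.  Each
cytosine draws a methylated/unmethylated status (per-context,
per-stratum site fraction) and, if methylated, a stratum level;
defaults (CG 0.92 / CHG 0.85 / CHH 0.40 levels; 0.55 / 0.40 / 0.08 mC
site fractions) follow the ranges typical of seed methylomes.  The
distinction between "fraction of sites methylated" and "level at
methylated sites" mirrors the two standard summaries of plant WGBS.

Three design points matter for validity of the downstream checks:

- Per-site truth is drawn once per genome from a seed stream
  independent of stage, group and replicate.  Samples from one
  landscape therefore share the same truth and differ only by Poisson
  coverage and binomial counting noise — otherwise a "null"
  two-group comparison would carry real site-level differences and
  calibration would be meaningless.
- Stage-dependent CHH gain in TE bodies (+0.05 per stage by default)
  and planted DMRs (intervals whose cytosines take level_A in group A
  and level_B in group B, never overlapping each other) are
  deterministic modifications of that shared truth.
- The per-gene gene-body CG site fraction is Beta-distributed around
  the landscape default (concentration 10), giving genes genuinely
  different body methylation; expression couples to the realised body
  CG level through a Gaussian copula of configurable strength.
  Without that between-gene variance there would be nothing for
  expression to couple to.

Coverage is Poisson(depth_mean); zero-coverage sites are emitted with
0/0 counts so depth filters are exercised.  FPKM is log-normal;
planted DEGs get |log2FC| ≥ 1 with q ≤ 0.05 and everything else stays
sub-threshold, so DE truth is exact.  Small-RNA reads fall at per-bp
middle-base rate λ_bg genome-wide and λ_hyper inside designated
hypermethylated TE bodies, 24-nt with probability 0.8.  The generator
emits truth tables (planted DMRs, per-gene levels, DEG labels, hyper-TE
ids, and optionally per-site levels) sufficient to score every stage.

What the generator does not emulate: read-level artefacts (PCR
duplicates, M-bias, strand bias), overdispersion between replicates,
non-uniform genome composition, and correlated methylation along the
chromosome.  Passing tests therefore demonstrate correctness of the
statistics and plumbing under the stated model, not robustness to
real-data artefacts.

## Reference validation studies

`seedmeth.validation` packages the recovery studies run by the test
suite and the acceptance script, with problem sizes chosen to give
stable estimates in seconds to a few minutes on one CPU:

- conversion-error recovery on a 250-kb chloroplast (~1.25·10⁵ covered
  cytosines): estimate within 3 binomial SEs of ε = 0.006;
- null calibration on a 600-kb genome (≈1.2·10⁴ testable CG windows,
  2 replicates per group at 20×): ≤ 2% of windows pass all filters;
- recovery of 40 planted 300-bp CG DMRs (levels 0.2 vs 0.7, 20×):
  ≥ 90% sensitivity, ≤ 10% false calls;
- metagene recovery of a piecewise landscape (body CG 0.90, flanks
  0.60, all CG sites methylated so bins are pure; TE-body CHH gaining
  +0.05 per stage): every planted bin within 3 binomial SEs, stage
  means strictly increasing.  TE CHH flank bins are excluded from the
  3-SE claim because their mixture stratum adds landscape-realisation
  variance beyond the binomial yardstick;
- decile coupling with 600 genes: pooled body CG means ordered
  2 < 6 < 10 at coupling 0.5; at coupling 0 the 3-SE bands (SEM over
  genes, the right yardstick when between-gene variance dominates)
  of deciles 2 and 10 overlap;
- small-RNA contrast over 50 simulations (~2000 reads each): density
  ratio 5 rejects at p < 0.01 in ≥ 95%, ratio 1 in ≤ 5%.

## Numerical and degenerate-input choices

Exact binomial tails via the incomplete beta; G-test terms with zero
cells contribute 0 (xlogy); empty windows, empty contexts, empty gene
sets and zero-coverage groups yield explicitly missing results rather
than errors; ties in decile assignment break by gene id; merging sorts
stably, so output order is deterministic.  All TSV output uses a fixed
float format, and all randomness flows from one integer seed through
named numpy SeedSequence streams, so a rerun with the same config is
byte-identical.

## Known limitations

Binomial-only replicate model (no overdispersion correction, as in the
published criteria); window-level rather than site-level DMRs; the
π₀ estimator is one member of the family the published q-value method
belongs to; TE classes resolve only to {LTR, LINE, DNA, other}; GO
enrichment, QTL mapping and read alignment are out of scope — process
and QTL gene lists enter the candidate screen as plain ID lists.
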