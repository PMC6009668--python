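# Methods

This note documents the models and procedures implemented in `divtx`,
the parameter defaults and why they were chosen, what the synthetic
data generator does and does not emulate, and the package's known
limitations.

## CAGE tag clustering

Tag clusters (TCs) are called on CTSS data pooled over all eight
libraries. Same-strand positions within `merge_dist` (default 20 bp)
are single-linkage merged; each pre-cluster is trimmed from both edges
while the edge's pooled count is strictly below
`trim_fraction × summit count` (default 0.1, ties retained so the
boundary is deterministic); multimodal profiles are split at the
leftmost minimum of every valley whose depth is strictly below
`valley_fraction × min(flanking local-summit counts)` (default 0.1).
After a split, children are stripped only of zero-count edge
positions, which guarantees that child counts partition the trimmed
parent's count exactly — re-applying fractional trimming to children
would break that conservation. The procedure is idempotent: re-running
a TC on its own CTSS subset returns it unchanged.

Expression per TC per library is the CTSS count sum over `[start, end)`
on the TC strand, converted to tags-per-million using the genome-wide
library tag total as the denominator. TC annotation uses a
250-bp summit-to-TSS window (nearest TSS wins, coordinate tie-break),
a 500-bp antisense-upstream window for PROMPTs, and `distal`
otherwise.

## Background noise

The noise model is empirical: `n_windows` (default 10,000)
strand-specific 200-bp windows are placed uniformly outside an
exclusion set (DHSs ± 500 bp and annotated TSSs ± 500 bp — loci where
real initiation is plausible). The per-library threshold is the 0.999
empirical quantile of the per-window count sums, taken with the upper
("higher") convention so the threshold is an attained count value.
Window width matches the DHS quantification window so count and TPM
thresholds are comparable like-for-like. Expression must *strictly
exceed* the threshold in ≥ 2 of 4 replicates of a condition; a DHS is
"transcribed" when any strand passes in either condition. With other
replicate counts the rule scales proportionally
(`ceil(min_replicates/4 × n)`).

## DHS windows and scores

The divergent window pair (two abutting 200-bp windows; minus strand
upstream, plus strand downstream) is anchored at the position within
± 100 bp of the DHS center that maximizes pooled-knockdown divergent
coverage, with ties resolved toward the center and then the smaller
coordinate. A DHS is flagged convergent when the best convergent
arrangement strictly beats the best divergent one — at the study
conditions this stays a small minority (≈ 2–3% of synthetic DHSs, and
the generator plants none deliberately).

Exosome sensitivity is `max(0, 1 − control/KD)` on replicate-mean TPM,
undefined (NaN, excluded downstream) when KD expression is zero. The
clipping keeps the score in [0, 1] when control exceeds KD by sampling
noise. Directionality is `(major − minor)/(major + minor)` on
knockdown TPM with the major strand fixed per DHS from pooled KD data
(tie → plus strand). Summits are pooled-KD argmax positions per strand
(tie → most upstream relative to the strand).

## Classification

Features per DHS × replicate: log₂(KD TPM + 1) for both strand roles,
per-replicate major and minor sensitivity, and directionality, each
column-standardized. **Feature sensitivities are regularized**:
`1 − (control + a)/(KD + a)` with `a = 1 TPM`, clipped to [0, 1]. The
raw ratio is noise-dominated on near-silent strands — a control window
with zero counts reads as sensitivity 1 regardless of the strand's true
stability — and this made genuinely unidirectional stable promoters
indistinguishable from PROMPT-bearing ones. The pseudocount shrinks
ill-determined ratios toward 0 while leaving well-expressed strands
essentially unchanged. The reported (non-feature) sensitivity scores
are *not* regularized.

Step 1 clusters all rows with k-means (k = 6, k-means++ init, fixed
seed, 10 restarts). Step 2 summarizes each DHS by its 6-dim
composition vector (fraction of its four rows per step-1 group) and
clusters those vectors again (same k and seed policy). The final class
is the modal step-1 group (ties resolved by the consensus centroid's
largest component); the modal count is the replicate agreement, and
DHSs with agreement < 2 are removed. This composition-vector consensus
is this package's concrete realization of comparing group allocation
across replicates; on well-separated data removal is rare (0 of 600 on
the default synthetic dataset).

Semantic labels are assigned from per-cluster medians: stable iff
median major sensitivity < 0.5; among stable clusters, bidirectional
iff median directionality < 0.4, then PROMPT-associated iff ≥ 50% of
members have a minor strand above noise *and* median minor sensitivity
> 0.5; among unstable clusters, weak-unidirectional iff directionality
> 0.7, and the remaining two split by median major expression. The
mapping must be a bijection onto the six labels or labelling fails
with the offending medians — cutoffs are configuration, validated by
that bijection requirement. The middle unstable class is named
`intermediate_bidirectional_unstable`; the printed label
"Intermediate bidirectional stable" is kept as an alias
(`PRINTED_LABEL_ALIASES`).

## Sequence elements

Motifs are position probability matrices scored by log₂ odds against
the background composition. Match p-values are exact: per-position
log-odds are discretized at 0.01 bits and convolved over positions
under the background, giving P(score ≥ s) without simulation; the DP
matches brute-force enumeration over all 4^L words to 1e-6 on the
shared discretization. Scans run on strand-oriented ± 50 bp windows
around major/minor CAGE summits, keep the max-score position per
motif, and call significance at p < 0.001.

The bundled core-promoter models (TATA, Inr, DPE, MTE, E-box/Ohler5,
Ohler1, DRE, Ohler6, Trl) are **consensus-derived toy matrices** —
synthetic stand-ins built from IUPAC consensus strings, not the
published matrices; real analyses should supply matrices in MEME
minimal format (`read_meme`). Two consequences worth knowing: a
perfect DPE consensus match (RGWYVT) has p ≈ 0.006 and can never pass
the 0.001 threshold, and the Inr consensus sits at p ≈ 5e-4, close to
it. Core-promoter composition clustering z-scales the max-score matrix
(windows without a significant hit contribute the motif's minimum
attainable score; all-constant columns are dropped with a record),
then cuts a Ward-linkage tree at k = 10; class enrichments are log₂
ratios with one-sided Fisher tests.

Downstream processing profiles count, per growing window `[0, w)` from
the summit, significant splice-donor PWM hits (a canonical 9-nt donor
model with invariant GT — the choice of donor model is configuration)
or exact degenerate AWTAAA hexamer matches, as sites per bp averaged
over elements, minus the same statistic at random TSS-unlikely
positions.

## Enhancer potential and chromatin marks

STARR-seq enhancer potential is the log₂ fold change of signal over
input at the signal summit (leftmost argmax) within a 401-bp window
centered on the DHS midpoint, with a pseudocount of 1 in both
numerator and denominator; ≥ 1.5 calls the site active. Quantitative
signal/response associations use percentile-truncated (1st–99th)
equal-width binning for display and Spearman rank correlation on the
untruncated pairs for inference. Binary ChIP-mark presence is any
overlap within ± 100 bp of the major CAGE summit; footprint profiles
average presence in 50-bp distance bins up to 5 kb, mask bins that
touch a different DHS, and draw their background band from 10 uniform
relocations of the mark intervals.

## Chromatin architecture

DHS windows (major summit ± 200 bp) are allocated to a TAD on ≥ 200 bp
overlap (larger overlap wins; ties to the upstream TAD, flagged);
boundary proximity uses a 1-kb cutoff. All DHS pairs within 1 Mb of
center distance are enumerated. Same-TAD co-occurrence per focal class
is a binomial GLM, `same_tad ~ partner_class + log10(distance)`, with
sum-to-zero (deviation) coding so each partner coefficient is the
change in log-odds relative to encountering an average/random partner;
distance enters as log₁₀ because pair distances span three orders of
magnitude within 1 Mb. Only TADs with ≥ 3 transcribed DHSs count as
eligible same-TAD context. Complete separation is flagged and reported
as non-estimable rather than fitted. TAD composition clustering uses
log₂(count + 1) class-count vectors for TADs with ≥ 3 elements and
k-means (k = 7, fixed seed). Interaction-target models are the same
GLM form with the response being whether the target of a significant
interaction carries hkCP (or dCP) potential versus no potential at
all.

## Synthetic data

The generator emulates the full study design at desk scale:

- **Classes and expression.** 100 DHSs per class (600 total) on two
  chromosomes. Class parameter defaults (mean KD TPM major/minor;
  sensitivity major/minor): unidirectional stable 50/0.2, 0.1/0.8;
  with-PROMPT 50/2, 0.1/0.8; bidirectional stable 40/25, 0.1/0.15;
  weak bidirectional unstable 2/1.5, 0.8/0.85; intermediate 6/2,
  0.7/0.8; weak unidirectional unstable 3/0.1, 0.8/0.8.
- **Counts.** Library depth ≈ 10⁷ tags (10 tags per TPM unit), a
  deliberately reduced stand-in for deeply sequenced CAGE libraries
  chosen so low-TPM classes still yield countable tags. KD counts per
  replicate are negative binomial with size 100 (replicates
  concordant, ≈ 10% extra-Poisson noise); control counts use mean
  `KD × (1 − sensitivity)`. Tags pile around planted summits
  (± 25 bp from the anchor, opposite strands) with a geometric ± 10 bp
  profile (decay 0.6). Sixty "filler" gene promoters with lognormal
  weights absorb the library mass not carried by planted DHSs so that
  planted counts convert to the configured TPM values; Poisson
  background tags fall uniformly at 0.005 tags/bp/library.
- **Annotation.** Stable classes get mRNA gene TSSs at their major
  summits (both strands for the bidirectional class); half of the
  unidirectional stable DHSs get an upstream antisense gene TSS
  400–900 bp away (head-to-head pairs); unstable classes are
  gene-distal.
- **Sequence.** Core-promoter consensi are written into the random
  genome at class-specific offsets and rates (Ohler1/DRE/Inr on stable
  majors, Trl on unstable strands and PROMPT minors); splice-donor
  sites are planted 20–150 bp downstream of stable strands, AWTAAA
  hexamers downstream of unstable strands and stable minors.
- **STARR.** hkCP log₂ fold change is `0.25 + 0.55·log₂(1 + TPM_major)`
  plus N(0, 0.5) noise — increasing in expression; dCP fold change is
  normal around 2.2 for the two bidirectional-unstable classes, 0.8
  for weak unidirectional unstable and 0.3 for stable classes. Tracks
  are emitted as bedGraph with a flat input of 31 so the planted fold
  change is recovered through the pseudocount.
- **TADs.** TADs hold 3–6 DHSs; each TAD draws a stable/unstable
  archetype and members follow it with probability 0.8 (coupling 0
  makes classes independent of TADs — the null used for GLM
  calibration). Stable classes occupy boundary-proximal slots, and
  ≈ 15% of TAD gaps host a preferentially stable between-TAD DHS.
  Significant interactions wire stable members to their TAD's
  strongest-hkCP partner.

What the generator does **not** emulate: mapping artifacts and
mappability gaps, promoter shape diversity (all planted TCs are sharp),
sequencing-depth differences between libraries, overlapping or nested
DHSs, chimeric/antisense artifacts, and any coupling between motif
content and expression strength. Passing recovery tests therefore
demonstrates the pipeline's correctness under the planted model, not
performance on real libraries.

## Numerical choices and degenerate inputs

Ties are resolved deterministically everywhere (documented per
operation: leftmost, most upstream, nearest center, upstream TAD,
plus strand). Quantiles use the "higher" convention. Undefined scores
propagate as NaN and are mean-imputed only inside the clustering
feature matrix. k-means uses 10 k-means++ restarts with a fixed seed;
determinism under a fixed seed is tested. GLM separation, empty
interaction sets, constant score columns and constant correlation
inputs are flagged or reported as NaN rather than raising mid-run.

## Problem sizes

The default test and acceptance configuration uses 600 DHSs, 8
libraries at ≈ 10⁷ tags each, a ≈ 2.7-Mb genome, and 20 + 10 simulated
TAD architectures of 300 DHSs — sizes chosen so a full run completes
in well under a minute and the whole suite in about one minute on a
single CPU.

## Known limitations

- The bundled motif matrices are toy consensus expansions (above);
  positional profiles and core-promoter clusters on real data require
  the published PWMs.
- The two-step clustering realization (composition-vector consensus)
  and the GLM formula (deviation coding + log₁₀ distance) are this
  package's concrete design choices for procedures whose published
  descriptions leave room for interpretation; both are validated
  against planted truth rather than against the original
  implementation.
- TC-calling parameters (merge distance, trim and valley fractions)
  and the noise-estimator settings are configuration with stated
  defaults, not values fixed by an external standard.
- Convergent-transcription detection compares only the two extreme
  window arrangements; mixed or offset convergent geometries are not
  modelled.
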