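# Methods

## Data model

The unit of analysis is a *case pair*: the HER2-positive and HER2-negative
components of one tumor, profiled separately on a common probe grid. Probe
tables carry 1-based inclusive coordinates (array convention), gene
annotations are BED (0-based half-open), and all internal interval arithmetic
is 0-based half-open with conversion at the I/O boundary only. Missing log2
values are carried as flagged NaNs: they are excluded from every statistic and
re-attached to the enclosing segment for the smoothed vector, never imputed.
Chromosomes sort in natural order (chr1..chr22, chrX, chrY, then unknown names
lexicographically) so outputs are deterministic.

## Segmentation

Binary segmentation with a permutation test, searched over linear
(non-wrap-around) arcs of the chromosome-ordered values. The arc statistic is
the classic two-sample form

    T(i,j) = (mean(x[i:j]) − mean(complement)) / (σ̂ · sqrt(1/k + 1/(n−k)))

with σ̂ the sample SD of the current recursion window (no trimming). The
implementation uses the algebraically equivalent centered-cumulative-sum form
`T(i,j) = (g[j] − g[i]) · sqrt(n/(k(n−k))) / σ̂` with
`g[t] = c[t] − t·total/n`, which makes the permutation null (the maximum of
|T| over arcs, re-evaluated on uniformly shuffled windows) cheap to vectorize.
Ties in |T| break to the smallest `(i, j)`; mirror arcs (an arc and its
complement) are exactly tied and induce the same split, so the choice does not
affect the partition.

A split is accepted when `p = (1 + #{perm max |T| ≥ |T_obs|}) / (1 + nperm)`
is at most `cbs_alpha`. During recursion the permutation loop stops early once
the p-value provably exceeds alpha — the accept/reject decision is unchanged;
only the reported magnitude of clearly non-significant p-values is
conservative. Recursion proceeds on the up to three runs induced by the arc;
flanking runs shorter than `cbs_min_width` are absorbed into the arc run so
that no segment narrower than the minimum width is created.

After recursion, a merge pass repeatedly joins the adjacent pair of segments
with the smallest mean difference while that difference is below
`merge_sd_units` (default 1.5) times the **residual** SD — the SD of the
values around their fitted segment means. The whole-window SD would include
the genuine segment structure and at realistic noise would exceed the gain
amplitude itself, merging real events; the residual SD is zero for noiseless
input, so exact recovery of clean signals is preserved. This was a genuinely
open design point and is a deliberate choice of this package.

Defaults: `cbs_alpha = 0.01`, `cbs_nperm = 1000`, `cbs_min_width = 2`. The
heavier simulation-based tests and the acceptance script run with
`cbs_nperm = 250`; the smallest attainable p-value, 1/251 ≈ 0.004, is still
well below alpha, so split decisions are identical in distribution and the
saving is purely computational.

## State calling

Per-probe categorical states from the smoothed values with strict
inequalities: amplification above `amp_threshold` (+0.45), gain above
`gain_threshold` (+0.12), loss below `loss_threshold` (−0.12), neutral
otherwise; a value exactly at a cutoff takes the less extreme state.
These are conventional BAC-array cutoffs and are first-class configuration —
platform-specific recalibration is expected. Amplification is a refinement of
gain: dichotomizations use "gained-or-amplified" = encoding ≥ 1, "lost" =
encoding = −1, "amplified" = encoding = 2. No ploidy centering is applied
before thresholding.

## Differential frequencies and restricted amplifications

For each probe, the two component groups are compared with the exact
two-tailed Fisher test (point-probability rule — the sum of hypergeometric
point probabilities not exceeding the observed table's) on the 2×2 of group ×
event presence, counting only samples observed at that probe. q-values are
Benjamini–Hochberg across probes; both raw p and q are reported since it is a
genuine modelling choice whether per-probe tests of this kind are
multiplicity-corrected.

Component-restricted amplifications are maximal probe runs amplified in one
component and *strictly non-amplified* (gain allowed) in the partner — the
contrast is presence/absence of amplification, not of gain. Gene assignment
uses any overlap of at least one base, appropriate at 50 kb probe resolution
where reciprocal-overlap rules would be spuriously strict. Recurrence counts
distinct cases per gene.

## Clustering

Euclidean distances on the numeric state encodings with pairwise deletion of
probes missing in either profile, rescaled by `sqrt(grid/observed)` so that
distances remain unbiased under missing-at-random probes. Linkage is Ward's
criterion in its squared-distance (Ward.D2-style) form via the Lance–Williams
update, with heights reported as the square root of the merge cost; ties merge
at the pair whose clusters contain the smallest leaf indices, making the tree
fully deterministic. The linkage is implemented in-package because the
deterministic tie-break is part of the contract; it reproduces the standard
library implementation exactly on tie-free input. Only samples are clustered
(no probe clustering or pre-filtering). The *pair-sibling fraction* — the
fraction of cases whose two components merge as two singletons — is the
summary statistic of within-case clonal relatedness.

## Driver prioritization

"Copy-number regulated and overexpressed when amplified" is operationalized
as a one-sided rank-sum test (normal approximation with tie correction) of
expression in amplified versus non-amplified reference-cohort samples,
alternative amplified-greater; a Kruskal–Wallis variant across all four states
is available behind a flag. Groups smaller than 3 make a gene *untestable*
rather than raising. Mutual exclusivity with a reference amplification is the
hypergeometric lower tail P(co-amplified ≤ observed) with a Haldane-corrected
odds ratio as effect size; preferential amplification in reference
HER2-negative tumors is the same statistic read from the other margin, so one
test covers both clauses. Candidates must pass the regulation filter
(BH q ≤ `fdr_q`, default 0.05, positive direction) and are ordered by
recurrence (descending), exclusivity p, regulation q, then gene name — a
deterministic total order.

## Cancer-cell fractions

With purity α, local tumor copy number `q_t` (integer ≥ 1; normal copy number
fixed at 2 — autosomes only), multiplicity m and allele fraction f:

    E[f] = CCF · m · α / (α·q_t + 2(1−α))
    m̂   = round(f · (α·q_t + 2(1−α)) / α)   (half-way ties round down, clamp to [1, q_t])
    CCF  = f · (α·q_t + 2(1−α)) / (α·m̂)     (clamped to [0,1], raw value retained)

Uncertainty is an exact binomial (Clopper–Pearson) interval on f mapped
through the monotone adjustment. A mutation is *clonal* when the interval
reaches 1 or the point estimate exceeds `clonal_ccf_cut` (0.9). This is a
deliberately single-solution model: purity and local copy number are inputs,
and no multi-modal purity/ploidy search is attempted.

Sharing across components: a variant is a *candidate* at VAF > 0.15 in at
least one component (the exome candidate rule), *present* at VAF ≥ 0.02 with
depth ≥ 50, SHARED when present in both, RESTRICTED when a candidate in one
and below the presence cutoff at adequate depth in the other, UNDETERMINED
otherwise. The depth guard means a genuinely restricted mutation whose
carrier VAF falls below the candidate cutoff (low CCF and/or low purity) is
reported UNDETERMINED, not RESTRICTED — the classification never claims more
than the read counts support.

## Synthetic cohorts

The generator emulates the study design rather than any particular platform
artifact:

* 12 case pairs on a 22-chromosome grid of 250 probes × 50 kb per chromosome;
  per-probe log2 = truncal level + component-restricted level + N(0, noise_sd).
* 6 truncal events per case (loss/gain/amp at −0.6/+0.3/+1.0, drawn 0.4/0.4/0.2),
  lengths 8–50 probes; the shared fraction (default 0.7) sets how many extra
  component-restricted amplicons (lengths 8–30) are added.
* events never overlap, keep ≥ 5 probes apart and ≥ 2 probes from chromosome
  ends, so every planted breakpoint is well-posed at probe resolution and each
  probe's truth state follows from a single event;
* one differential amplicon (15 probes, chr17 by default) is planted in every
  positive and no negative component — the *HER2*-amplicon analog;
* expression cohorts: state per gene per sample (amplification probability
  configurable), expression = N(0,1) + β·dosage with dosage(loss..amp) =
  (−1,0,1,2); an optional multiplier scales co-amplification of a named gene
  pair (0 forbids it);
* mutation sets: truncal mutations have CCF 1 in both components and
  multiplicity uniform in [1, q_t]; restricted mutations have CCF ~ U(0.1, 1)
  in one component, 0 in the other, and multiplicity 1. Subclonal point
  mutations are given multiplicity 1 because a rounding-based multiplicity
  estimate cannot distinguish CCF 0.5 at m = 2 from CCF 1 at m = 1 — and
  because subclonal point mutations typically postdate the copy-number state
  of their locus. Read counts are Binomial(depth, expected VAF).

The noise SD default (0.15) is a simulation choice, not a platform
measurement. What the generator does **not** model: array waves and GC bias,
subclonal copy-number mixtures within one microdissected component,
sequencing error beyond binomial sampling, and allele-specific copy number.
Tests passing on these cohorts therefore demonstrate correctness of the
algorithms under the stated generative model, not robustness to real-array
artifacts.

## Problem sizes used by the test suite and acceptance script

Simulation-heavy checks run at sizes chosen to keep a full run comfortable on
one CPU while preserving the statistical structure: the 20-seed differential
and clustering properties use 12 case pairs × 10 chromosomes × 250 probes at
noise 0.1 with `cbs_nperm = 250`; breakpoint recovery uses 4 chromosomes ×
120 probes over 20 (tests) or 10 (script) replicates; CCF recovery uses
~1,000 carrier mutations across purities {0.3, 0.5, 0.8}, depths 100–4,000
and local copy numbers 1–4; prioritization uses 5 regulated genes (β = 1.5)
among 200 over 100-sample cohorts and 20 seeds.

## Known limitations

* The segmentation searches linear arcs only; the circular wrap-around arc is
  not considered (equivalent partitions on linearly ordered genomic data).
* Events shorter than `cbs_min_width`, or ending within a couple of probes of
  a chromosome end, are not reliably separable from their flanks; measured
  per-breakpoint recovery of amplification-level events at noise 0.1 is ~99%,
  not 100%, for exactly this reason.
* Absolute integer copy number, purity and ploidy are never inferred; the
  clonality model consumes them as inputs.
* The prioritization operates on a reference cohort table; it does not
  re-derive published gene lists, which depend on specific external datasets
  and annotation builds.
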