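# Methods

This note documents the statistical model behind `tumorhet`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical decisions that matter for reproducing its
output.

## Variant retention and TMB

A somatic variant is retained when all of the following hold: variant
allele frequency (VAF) ≥ `af_min` (default 0.05), read depth ≥ `depth_min`
(default 10×), evidence from ≥ `min_callers` callers (default 2), and, for
every caller named in `required_flags` that appears in the record's
evidence, the matching high-confidence flag (defaults: MuTect "KEEP",
Strelka "PASS"). Flags are enforced only for callers present in a record's
evidence because no flag convention is defined for every caller (VarScan2
has none here). Rejections are reported with the first failing criterion in
the fixed order *af → depth → callers → flag*, which makes filter audits
deterministic.

Effect classes: a variant within 2 bp of a splice site is *splicing*
regardless of its annotation string; otherwise the MAF-style
`Variant_Classification` vocabulary maps missense/nonsense/frameshift/
in-frame-indel/translation-start-stop/splice classes to *nonsilent*,
synonymous classes to *silent*, and anything unrecognized to *other* with a
warning (never an exception — cohort tables routinely contain UTR/intron
rows).

TMB = (nonsilent + splicing count) / `exome_size_mb`, in mutations per
megabase. `exome_size_mb` has **no default**: the sequenced footprint
depends on the capture design and silently assuming one would fabricate the
denominator. Classes follow the childhood-cancer convention: *hypermutator*
strictly above 10 muts/Mb, *pediatric high* for 2–10 muts/Mb with both
boundaries inclusive (a literal reading of "between 2 and 10"), *low*
below 2.

## CNV burden and gene calls

All coordinates are 1-based and inclusive; BED input is converted at the
I/O boundary. A segment is altered when its total copy number differs from
`neutral_copy_number` (default 2; configurable for sex chromosomes or
ploidy-relative definitions). Burden = altered bp / `genome_size_bp`, the
latter defaulting to the GRCh37 autosomal total (2,881,033,286 bp) as a
named constant, never hard-coded in a formula. Segments must be
non-overlapping per sample and chromosome; violations raise with the
offending pair.

Gene calls use the union of same-direction altered segments: a gene is
*amplified* when ≥ `min_overlap` (default 0.8) of its length is covered by
segments with copy number ≥ `amp_threshold` (default 3), *deleted*
analogously with ≤ `del_threshold` (default 1). The amp/del thresholds are
configuration, not biology: upstream CNV callers differ in how they
discretize states. If both directions reach the threshold (possible only
with pathological inputs) the larger coverage wins and exact ties fall back
to *none* with a warning. Burden and overlap are validated in the test
suite against a per-basepair brute-force scan on random instances, and both
are invariant under splitting a segment into same-copy-number pieces.

## The ITH pipeline

**CP mapping.** For purity φ, tumor copy number C_t (default 2) and
multiplicity m (default 1), E[VAF] = φ·CP·m / (φ·C_t + 2(1−φ)). The
maximum-likelihood CP given an observed VAF is the inverse, clipped to
[0, 1]. The heterozygous-diploid default (C_t = 2, m = 1) is the simplest
model consistent with the CP concept; both are parameters for sensitivity
analyses.

**Clustering.** The fidelity path ingests the loci table of an external
Dirichlet-process clonal-inference tool (mutation_id, cluster_id,
cellular_prevalence, VAF) and uses its assignments as-is. The built-in
alternative is an explicit stand-in, not a reimplementation of the Bayesian
model: a one-dimensional binomial mixture over (alt_count, depth) fitted by
EM for k = 1..`k_max` (default 6), each k from a fixed multi-start schedule
(VAF quantiles plus three seeded uniform starts), component count selected
by BIC with 2k−1 free parameters and ties resolved toward smaller k, and
loci hard-assigned by maximum responsibility. Mixture weights use the full
responsibility-average M-step; success probabilities are kept in
[1e−6, 1−1e−6] to avoid log(0). Cluster mean CPs are averages of the
per-mutation CP values, so ingested and built-in paths feed the same
downstream computation.

**Stage-1 merging** (singleton denoising): average-linkage hierarchical
clustering of cluster centroids in the 2-D space (mean CP, mean VAF), both
on the [0, 1] scale so the cut height `merge_cutoff` (default 0.05) is
commensurate with CP/VAF units; the dendrogram is cut at that height and
co-grouped clusters are pooled. 1-D (CP-only) centroids are available via
`stage1_features="cp"`. The stage applies to all clusters by default —
removing singleton noise is its expected consequence, not a restriction —
but `stage1_scope="singletons_only"` restricts it so that only
single-mutation clusters are absorbed (each into its nearest co-grouped
non-singleton).

**Stage-2 merging** (statistical refinement): for every unordered cluster
pair, two-sided rank-sum tests compare the member CP multisets and the
member VAF multisets; a pair is mergeable iff *both* p-values strictly
exceed `wilcoxon_alpha` (default 0.05). The rank-sum (Mann–Whitney) form is
forced by the data: clusters contain different mutations, so no pairing
exists for a signed-rank test. Merging is best-pair-first — the pair with
the largest min(p_CP, p_VAF) merges, with ties broken by larger p-sum, then
smaller centroid distance, then lexicographic labels — then means are
recomputed and the scan repeats until no pair qualifies. This fixed order
makes the procedure deterministic and idempotent (a second pass performs
zero merges, which the tests assert on random inputs). Every merge is
logged with its stage, member labels, and distance or p-values.

**Shannon ITH.** Mean CPs of the final clusters are normalized to
proportions pᵢ and H' = −Σ pᵢ ln pᵢ in natural-log units (nats), so a
monoclonal sample scores exactly 0 and k balanced subclones score ln k.
Zero-CP clusters are dropped with a warning before normalization (ln 0 is
undefined; dropping preserves the formula's domain), and a sample whose
clusters are all zero-CP is an error. Samples without a known tumor purity
are excluded from the pipeline with an explicit report, since CP is
uninterpretable without purity.

## Rank-sum testing

Small groups (min size ≤ 10) get the exact permutation distribution of the
midrank sum over all C(N, n₁) subset assignments, computed by dynamic
programming over the doubled-midrank multiset (doubling makes midranks
integers; the DP is exact in float64 at these sizes). The two-sided p-value
is twice the smaller tail with the observed point included, capped at 1 —
identical samples give p = 1 and the extreme 8-vs-8 separation gives
2/12870 ≈ 1.55e−4. The test suite checks this path against a full
`itertools` enumeration oracle to 1e−12, ties included. Larger groups use
the normal approximation with midrank tie correction and 0.5 continuity
correction, cross-checked against an independent implementation. Cohort
comparisons report raw p-values by default, matching the practice of
reporting unadjusted two-tailed Wilcoxon tests per contrast; a
Benjamini–Hochberg column is available behind a flag. Group medians use the
midpoint convention for even sizes.

## Synthetic data: what it emulates, and what it does not

`simulate_subclonal_tumor` draws, per mutation of subclone j, a depth from
a Poisson with the configured mean (floored at one read — a point-mass
shift, not a renormalized truncation; at the default 500× the difference is
immaterial) and an alt count from Binomial(depth, E[VAF]) with E[VAF] from
the CP mapping. The emitted loci table mirrors the external tool's output
dialect, with the CP column filled by the inverse mapping of the *observed*
VAF — i.e., per-mutation ML estimates, noisy around the truth exactly as
the downstream merging assumes. Defaults (depth 500, ≥ 30–40 mutations per
subclone, purity ≥ 0.6, CP separation ≥ 0.15, up to 6 subclones) describe
a well-powered WXS experiment; the recovery guarantees quoted by the tests
hold under those conditions and degrade gracefully below them.

`simulate_segments` tiles one synthetic chromosome with n altered segments
interleaved with neutral gaps so the altered spans sum exactly to
round(fraction × genome). `simulate_variant_table` emits records that pass
every retention filter by construction, with an option to spike a known
number of rows that each violate exactly one criterion (depth < 10,
VAF < 5%, single caller) — giving the filter tests exact expected counts.

`simulate_cohort` draws per-sample metric values i.i.d. from named
group-wise distributions. The default disease-status cohort uses Beta
distributions rescaled to [0, ln 6] — the Shannon range for up to six
subclones — with group sizes 17/9/13 (primary/recurrent/metastasis),
a realistic disease-status composition for an Ewing-sarcoma cohort, and shape
parameters Beta(2,6) / Beta(6,3) / Beta(5,3) placing recurrent and
metastatic tumors clearly higher in ITH; this is the structural contrast
(progressed disease is more heterogeneous) the end-to-end tests probe.

None of the generators simulate reads, alignment artifacts, caller error
profiles, mutational signatures, FFPE damage, or purity/ploidy estimation
error. Passing tests therefore demonstrate the *statistical machinery* —
filters, burden arithmetic, clustering, merging, scoring, testing — under a
clean generative model, not robustness to upstream calling artifacts in
real tumors.

## Problem sizes and runtime

The test suite and the acceptance script run at desk scale, chosen so the
full suite completes in a couple of minutes on one CPU: 100 replicate
tumors per subclone count k ∈ {1..4} for parameter recovery, 1,000 random
instances for the exact-test oracle comparison, 500 instances for the CNV
brute-force comparison, 1,000 replicate cohorts for type-I/power
calibration (n = 200 and n = 20 per group), and 200 replicate cohorts for
the end-to-end contrast. All randomness flows from explicit seeds;
same-seed runs are byte-identical.

## Known limitations

- The built-in clustering assumes one shared copy-number/multiplicity
  context per sample; subclonal copy-number changes bias CP for the loci
  they cover.
- The Shannon index summarizes subclonal diversity only: it carries no
  information about phylogeny, and rare subclones below the depth-driven
  detection limit are invisible to it.
- Stage-1 merging operates on centroids; two broadly overlapping clusters
  with distant means will not merge at stage 1 (stage 2 exists for exactly
  that case).
- The exact rank-sum path is O(n₁ · N · Σ ranks) per pair; it is
  intentionally capped at min group size 10, beyond which the corrected
  normal approximation is accurate.
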