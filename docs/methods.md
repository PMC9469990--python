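# Methods

This note documents the models and procedures the package implements,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic cohorts do and do not demonstrate.

## Coordinate conventions

All internal coordinates are 0-based half-open (the BED convention);
VCF (1-based) and GTF (1-based closed) positions are converted at the
I/O boundary (`pos_internal = pos_vcf − 1`). Touching intervals do not
overlap, but book-ended intervals merge, matching `bedtools merge`.
One internal convention eliminates the usual off-by-one bug class when
BED, VCF, GTF and segment tables meet in overlap logic.

## Tumor-only SNV/indel consensus filtering

The central difficulty of tumor-only calling is that private germline
variants are indistinguishable from somatic mutations by allele fraction
alone. The filter therefore subtracts *positions* seen in any external
evidence of germline origin, deliberately more aggressive than matched
tumor–normal practice:

1. **Flag rescue (primary caller).** Calls whose FILTER is exactly
   `germline` at positions withdrawn from the germline reference are
   reset to passing. The "only" clause matters: a record flagged
   `germline;weak_evidence` stays removed.
2. **Flag rescue (secondary caller).** Same rule for `alleleBias`,
   which otherwise deletes low-AF somatic calls.
3. **Panel of normals.** The union of variant positions across all
   normal call sets, membership tested position-only; applied to the
   secondary caller.
4. **Non-PASS removal** on both call sets. Order matters: rescues must
   precede this step (a regression test asserts the non-commutativity).
5. **Consensus intersection.** Sites called by both callers survive;
   the output carries the primary caller's allele representation, since
   downstream annotation follows that call set.
6. **Germline resources.** Positions present in any of the configured
   resource sets are removed. Resources are applied sequentially and
   audited per resource; the result equals removing their union.
7. **Support thresholds.** Keep iff AF ≥ 0.05 and DP ≥ 10 and alt
   reads ≥ 3 — the logical complement of strict-inequality removal
   conditions, so the boundary values are kept. Records lacking the
   support fields (after attempting AF = alt/DP reconstruction) are
   removed rather than passed unexamined.
8. **Regenotyping screen.** Any read/genotype support at the site in
   any normal sample removes the variant. The regenotyping engine is
   abstracted behind an evidence-table contract (boolean support per
   site per normal); a missing entry for a queried site raises rather
   than silently keeping the variant.

Position identity is `(chrom, pos)` — never the allele — because
different callers represent the same event with different alternate
alleles. For indels the same tools may also shift the start coordinate,
so indel matching against resources uses reference-footprint overlap
instead of exact position.

Every step appends `(label, n_in, n_removed, n_rescued)` to an audit
chain validated for conservation (`n_in` of step k+1 equals `n_out` of
step k).

## Structural-variant filtering

1. **Panel-of-normals screen.** Tumor and normal SV call sets are
   merged by single-linkage clustering: two SVs are mergeable iff they
   share type and chromosome pair and both breakpoints lie within
   d = min(1000 bp, shorter SV length); breakends and insertions use the
   flat 1000 bp cap, as no meaningful length exists. Clustering is
   order-independent (inputs are coordinate-sorted first). A tumor SV
   survives only if its cluster contains no normal-sample member.
2. **Quality filters.** Keep iff FILTER empty, not IMPRECISE, and
   paired-read or split-read support ≥ 15.
3. **Centromere flagging.** SVs spanning (or, for BNDs, with a
   breakpoint inside) a putative centromeric window are flagged but
   retained; an `--exclude-centromeric` switch removes them, since the
   original analysis does not state whether flagged variants were
   dropped before counting.
4. **Regenotyping screen**, per SV id, same contract as for SNVs.
5. **Orphan-breakend removal.** A surviving BND whose mate was filtered
   upstream is dropped, so the output is always mate-closed (asserted
   on every run). A mate id never present in the input at all is
   treated as a malformed call set and raises.

The published procedure labels its steps 1, 3, 4, 5 with no step 2; the
variant-id extraction sentence is treated here as the implicit step 2.
Inversion records are accepted in either the INV or the BND encoding.

## Copy-number classification

Segments are classified from the log2 tumor/normal copy ratio with
inclusive thresholds: ≥ 0.4 → one-copy gain, ≤ −0.9 → two-copy loss,
otherwise neutral. The source text attaches both parentheticals to
"losses", an evident slip; the parenthetical meanings are implemented.
No one-copy-loss cutoff is published, so the (−0.9, 0.4) band is
neutral by default with a configurable shallow-loss threshold.
Gene annotation targets the gene body (CDS-only as an option); covered
fractions are pooled over same-class segments of a sample so that
splitting a segment changes nothing, and recurrence counts each sample
once per (gene, class).

## Genome summaries

**Sex** is the ratio of mean chromosome-X depth to the unweighted mean
of per-autosome mean depths: 0.3–0.7 male, 0.8–1.2 female (endpoints
inclusive; the published "between" is ambiguous and inclusivity is the
documented choice here), anything else indeterminate. The unweighted
mean is configurable but default because per-chromosome means are
already length-aggregated.

**Burden** is mutations divided by the summed sizes (in Mb) of the same
contig allow-list used in filtering; X is included by default.

**Kataegis** is detected on the sorted, deduplicated per-chromosome
position series: a window of ≥ 6 consecutive mutations qualifies when
its mean inter-mutation spacing (pos_last − pos_first)/(k − 1) is
≤ 1000 bp; overlapping qualifying windows are unioned and each maximal
union reported as the interval from first to last mutation. The
original analysis identified kataegis visually from rainfall plots; the
numeric ≥ 6 / ≤ 1 kb rule is this package's parameterization of the
literature convention, and both knobs are exposed.

## Mutational-signature refitting

Catalogs count single-base substitutions into the 96 COSMIC-ordered
channels (pyrimidine-centered; purine-reference calls are
reverse-complemented). Signatures are adjusted for the target genome's
mutational opportunities by s′ₖⱼ ∝ sₖⱼ·oⱼ with per-row renormalization
(invariant under rescaling of o).

Exposures maximize the multinomial likelihood of the catalog given the
mixture Σₖ eₖ s′ₖ, solved by EM (log-likelihood provably non-decreasing;
convergence when the improvement drops below 1e-8, iteration cap
10,000). Uncertainty comes from multinomial bootstrap resampling of the
catalog at its observed total (default 200 replicates; percentile
intervals widened, if needed, to contain the point estimate). This
ML-EM + bootstrap scheme replaces a Bayesian MCMC fit: the downstream
selection rule consumes only a point estimate and an interval lower
bound, and the frequentist surrogate is fast, dependency-light and
directly testable. Selection keeps signatures whose interval lower
bound exceeds 0.025 in at least one sample and refits on the retained
set only.

## Breed/ancestry calling

Per-SNP two-population differentiation uses the Hudson estimator

    num = (p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1)
    den = p₁(1−p₂) + p₂(1−p₁)

(negative values possible in finite samples; NaN and excluded when both
populations are monomorphic for the same allele; multi-SNP aggregation
is ratio-of-averages). Marker selection first drops SNPs with ≥ 10%
missingness, then computes per-breed FST — one-vs-rest by default — and
keeps SNPs exceeding 0.15 in at least one comparison. The published
"across all comparisons" phrasing is ambiguous between all-pairwise and
one-vs-rest and between any/all quantifiers; requiring *all* pairwise
comparisons to exceed 0.15 selects almost nothing, so the informative
default is one-vs-rest/any, with `scheme` and `mode` switches exposing
the alternatives.

LD pruning works in fixed 50 kb position windows: while any retained
pair within a window has genotype r² > 0.5, the member of the
highest-r² pair with the higher missingness (ties: higher index) is
removed — a deterministic rule.

Supervised ancestry maximizes ∏ⱼ Binomial(gⱼ; 2, Σₖ qₖ fₖⱼ) over the
ancestry simplex q at *fixed* panel frequencies fₖⱼ (clamped to
[1e-6, 1−1e-6]), by EM with convergence at log-likelihood improvement
< 1e-7; missing genotypes are skipped. With fully labeled references,
supervised ADMIXTURE-style analysis reduces to exactly this per-sample
Q estimation, and the objective is concave in q, so the EM fixed point
is the global maximum and no random restarts are needed (a seed
argument is accepted for interface stability). The consensus call
reports the top breed if its fraction is ≥ 0.5 (inclusive), else
"mixed/village" — the expected signature for dogs without modern breed
ancestry.

## Cross-study concordance

External call sets are harmonized to chrom/pos/ref/alt (or intervals
for SVs/CNVs), restricted to merged CDS intervals, and stripped of
low-impact annotations (unannotated records are kept and tallied).
Gene recurrence counts a sample once per gene per study; confirmation
fractions (e.g. WES calls confirmed by WGS) are position-only by
default with an allele-exact mode, since the original matching
granularity is unstated. Translocations compare at gene level only —
breakpoint coordinates are generally unreported in the literature.

## Synthetic cohorts: what they emulate and what they do not

The generator plants every record with a known class and expected fate.
Defaults mirror the study design the pipeline was built for: 23 normal
genomes feed the panels, and each of 2 tumors carries 250 planted small
variants across ten classes (eligible somatic, rescued somatic,
low-support somatic, caller-private, panel-of-normals germline,
resource-only germline, flagged artifacts per caller, and regenotyping
leaks). Support values sit on discrete grids straddling every
threshold (AF 0.049/0.05, DP 9/10, alt 2/3; PR/SR 14/15; log2 ratios
−1.2/−0.9/−0.3/0/0.4/0.9; X-ratios 0.5/1.0/0.75), so boundary behaviour
is exercised on every run. About 30% of eligible somatic SNVs carry a
different alternate allele in the second caller, and a fraction of
resource germline variants are indels with shifted start positions, to
exercise position-only and footprint matching. Planted SVs keep ≥ 2.5 kb
apart so proximity clusters can never chain unrelated plants. The toy
genome is four chromosomes totalling 850 kb of i.i.d. random sequence;
breed panels use Balding–Nichols drift (FST 0.15) from uniform ancestral
frequencies over 2,000 markers with 12 reference dogs per breed — small
enough to generate in seconds, large enough for supervised calling to be
informative. All randomness flows from one integer seed through a single
`numpy` generator; identical seed and configuration give byte-identical
bundles.

Because germline and artifact classes are planted disjointly (e.g.
panel-of-normals germline sites are kept out of the resource files so
each removal step has its own unambiguous targets), perfect truth
recovery on these fixtures demonstrates that the *decision logic* is
exactly right — not that real data would be filtered perfectly. Real
call sets have overlapping evidence classes, coverage-dependent AF
noise, alignment artifacts, and germline variation absent from every
resource (the village-dog problem), none of which the generator
emulates. Read-level simulation is out of scope.

## Problem sizes and numerical choices

Test and acceptance runs use the desk-scale defaults above: 2 tumors ×
250 planted variants, ~39 SVs per tumor, signature experiments with 3–4
signatures at 20,000 mutations per sample (20–100 replicates, 20–60
bootstrap resamples), ancestry recovery at 5,000 markers, and
1,000-record oracle comparisons. EM tolerances are 1e-8 (signatures,
log-likelihood scale) and 1e-7 (ancestry); the signature EM caps at
10,000 iterations and raises on non-convergence rather than returning a
stale estimate.

## Known limitations

- The regenotyping screens consume boolean evidence tables; read-level
  regenotyping (Graphtyper-style) is intentionally out of scope.
- The SV merge is O(n²) single-linkage, suitable for per-sample call
  sets up to a few tens of thousands of records, not for population
  merging.
- Supervised ancestry assumes reference panel frequencies are known
  without error; with small panels (12 dogs/breed) frequency noise
  biases Q estimates, visible in the synthetic cohort demo.
- The kataegis rule is a fixed-threshold convention, not a background-
  rate model; regions are descriptive.
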