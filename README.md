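# tumoronly

Whole-genome somatic characterization of tumor samples **without a
matched germline normal** — the situation for most established cancer
cell lines, where the donor's constitutional DNA was never banked.
Without a matched normal, somatic calls are heavily contaminated with
private germline variation and caller artifacts; this package
implements a stringent consensus-filtering strategy built around
unmatched-normal panels and external germline resources, developed for
canine osteosarcoma cell-line genomes and applicable to any tumor-only
WGS dataset.

It is aimed at researchers characterizing cell lines or archival tumors
where tumor-only calling is unavoidable, and provides:

- **SNV/indel consensus filtering** — an eight-step procedure combining
  a Mutect2-style and a Platypus-style call set: flag rescues at sites
  withdrawn from the germline reference, a position-only panel-of-normals
  screen, non-PASS removal, two-caller consensus intersection, germline
  resource subtraction, support thresholds (AF ≥ 0.05, DP ≥ 10, ≥ 3
  alt reads), and a regenotyping screen that removes any site with read
  support in any normal. Matching is *position-only* throughout (the
  alternate allele is deliberately ignored), with footprint-overlap
  matching for indels. Every step is audited (in/removed/rescued).
- **Structural-variant filtering** — Jasmine-style proximity merging
  against normal panels (nonlinear distance d = min(1000 bp, SV length)),
  support/precision filters (PASS, not IMPRECISE, PR ≥ 15 or SR ≥ 15),
  centromere flagging, a regenotyping screen, and removal of orphaned
  breakends so the surviving BND set is always mate-closed.
- **Copy-number classification** — log2 copy-ratio segments called as
  one-copy gain (≥ 0.4) or two-copy loss (≤ −0.9), with gene-overlap
  annotation and cohort recurrence fractions.
- **Genome summaries** — sex from the X/autosome coverage ratio
  (0.3–0.7 male, 0.8–1.2 female), mutational burden (mutations/Mb), and
  kataegis detection on inter-mutation distance series.
- **Mutational-signature refitting** — SBS96 catalogs (COSMIC channel
  order), opportunity adjustment s′ₖⱼ ∝ sₖⱼ·oⱼ, maximum-likelihood
  exposure refitting under the multinomial model counts ~
  Multinomial(n, Σₖ eₖ s′ₖ) via EM, bootstrap interval bounds, and the
  select-and-refit rule (keep signatures whose interval lower bound
  exceeds 0.025 in any sample, then refit).
- **Breed/ancestry calling** — per-SNP Hudson FST,
  FST &gt; 0.15 marker selection, 50 kb/r² &gt; 0.5 LD pruning, and
  supervised ancestry fractions q maximizing
  ∏ⱼ Binomial(gⱼ; 2, Σₖ qₖ fₖⱼ) over the simplex by EM, with a
  consensus breed call ("mixed/village" when no breed dominates).
- **Cross-study concordance** — CDS restriction, low-impact exclusion,
  gene-recurrence fractions per study, and WES-vs-WGS confirmation
  fractions.
- **A synthetic cohort generator** — complete desk-scale file bundles
  (two-dialect tumor VCFs, 23 normal VCFs, germline resources,
  Manta-style SV VCFs with mate-paired breakends, segment/coverage
  tables, toy reference and GTF, genotype panels, signature catalogs)
  with a planted-truth ledger for every record, so the whole pipeline is
  testable end-to-end with known answers.

## Worked example

Generate a small cohort and run the SNV filter:

```bash
tumoronly simulate --out cohort --seed 7 --n-tumors 1 --n-normals 5
# wrote 250 planted variants, 39 SVs -> cohort/manifest.json

tumoronly snv-filter \
  --mutect2 cohort/tumors/tumor_1/mutect2.vcf \
  --platypus cohort/tumors/tumor_1/platypus.vcf \
  --pon-dir cohort/normals \
  --germline-resources cohort/resources/germline_reference.vcf,cohort/resources/broad_snps.vcf,cohort/resources/axelsson_snps.vcf \
  --removed-sites cohort/resources/removed_sites.vcf \
  --evidence cohort/tumors/tumor_1/snv_evidence.tsv \
  --out filtered.vcf --audit-out audit.tsv
# 70 passing variants -> filtered.vcf
```

The audit table shows what each step did:

```
step                                    n_in  n_removed  n_rescued  n_out
step1_rescue_germline                    240          0         20    240
step4_drop_non_pass                      240         15          0    225
step5_consensus                          225         80          0    145
step6_germline[germline_reference.vcf]   145         10          0    135
step6_germline[broad_snps.vcf]           135         10          0    125
step6_germline[axelsson_snps.vcf]        125         10          0    115
step7_support                            115         30          0     85
step8_regenotype                          85         15          0     70
```

20 flagged-but-rescuable calls were restored in step 1; artifact-flagged
records fell at step 4; single-caller and panel-of-normals sites fell at
the consensus step; germline-resource sites, weakly supported calls and
sites with normal read support were removed in steps 6–8. The 70
survivors are exactly the planted somatic variants that meet the support
thresholds — the generator's truth ledger confirms precision = recall = 1.0.

The other stages work the same way (`tumoronly sv-filter`,
`cnv-annotate`, `summarize`, `signatures`, `ancestry`, `merge-bed`); all
take files in standard formats (VCF, BED, GTF, seg/TSV tables).

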