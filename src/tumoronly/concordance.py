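"""Cross-study harmonization and concordance statistics.

External variant tables (from published WES/WGS studies) are harmonized
to chrom/pos/ref/alt records with optional impact class and gene
assignment, restricted to coding sequence, stripped of low-impact
annotations, and compared by gene recurrence and per-sample confirmation
fractions (e.g. the fraction of WES calls confirmed by WGS).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import pandas as pd

from .genes import GeneSet
from .intervals import GenomicInterval
from .variants import SiteKey


@dataclass(frozen=True)
class HarmonizedVariant:
    """One normalized record from one study/sample."""

    study: str
    sample: str
    chrom: str
    pos: int  # 1-based; for interval variants, the start
    ref: str = ""
    alt: str = ""
    end: int | None = None  # 1-based inclusive end for interval variants
    gene: str | None = None
    impact: str | None = None  # e.g. HIGH/MODERATE/LOW/MODIFIER

    @property
    def site(self) -> SiteKey:
        return SiteKey(self.chrom, self.pos)

    @property
    def is_interval(self) -> bool:
        return self.end is not None

    def interval(self) -> GenomicInterval:
        end = self.end if self.end is not None else self.pos
        return GenomicInterval(self.chrom, self.pos - 1, max(end, self.pos))


@dataclass
class HarmonizedCallset:
    study: str
    sample: str
    records: list[HarmonizedVariant]


def restrict_to_cds(
    records: Sequence[HarmonizedVariant], gene_set: GeneSet
) -> list[HarmonizedVariant]:
    """Keep point variants inside a CDS and interval variants that
    intersect one. Idempotent."""
    return [r for r in records if gene_set.in_cds(r.interval())]


def exclude_low_impact(
    records: Sequence[HarmonizedVariant],
) -> tuple[list[HarmonizedVariant], int]:
    """Drop records annotated low-impact; unannotated records are kept
    and their count returned as a warning tally."""
    kept = [r for r in records if (r.impact or "").upper() != "LOW"]
    n_unannotated = sum(1 for r in kept if not r.impact)
    return kept, n_unannotated


def assign_genes(
    records: Sequence[HarmonizedVariant], gene_set: GeneSet
) -> list[HarmonizedVariant]:
    """Fill the gene field from annotation overlap where missing (first
    overlapping gene by sorted id)."""
    out = []
    for r in records:
        if r.gene is None:
            hits = gene_set.genes_overlapping(r.interval())
            gene = sorted(g.gene_id for g in hits)[0] if hits else None
            r = replace(r, gene=gene)
        out.append(r)
    return out


def gene_recurrence_across_studies(
    callsets: Sequence[HarmonizedCallset],
) -> pd.DataFrame:
    """Per-gene fraction of samples affected within each study.

    A sample counts once per gene regardless of how many records hit it.
    Returns a tidy frame: gene, study, n_samples, n_affected, fraction.
    """
    samples_per_study: dict[str, set[str]] = {}
    affected: dict[tuple[str, str], set[str]] = {}  # (gene, study) -> samples
    for cs in callsets:
        samples_per_study.setdefault(cs.study, set()).add(cs.sample)
        for r in cs.records:
            if r.gene:
                affected.setdefault((r.gene, cs.study), set()).add(cs.sample)
    rows = []
    for (gene, study), samples in sorted(affected.items()):
        n = len(samples_per_study[study])
        rows.append(
            {
                "gene": gene,
                "study": study,
                "n_samples": n,
                "n_affected": len(samples),
                "fraction": len(samples) / n,
            }
        )
    return pd.DataFrame(rows, columns=["gene", "study", "n_samples", "n_affected", "fraction"])


def pooled_recurrence(recurrence: pd.DataFrame, studies: Sequence[str]) -> pd.DataFrame:
    """Pool several studies into one 'prior literature' fraction by
    summing affected and total samples per gene."""
    sub = recurrence[recurrence["study"].isin(studies)]
    totals = sub.groupby("study")["n_samples"].first().sum()
    pooled = sub.groupby("gene", as_index=False)["n_affected"].sum()
    pooled["n_samples"] = totals
    pooled["fraction"] = pooled["n_affected"] / totals
    return pooled


@dataclass
class ConcordanceResult:
    n_total: int
    n_confirmed: int
    confirmed: list[HarmonizedVariant]
    unconfirmed: list[HarmonizedVariant]

    @property
    def fraction(self) -> float | None:
        """Confirmed fraction; None when set_a was empty (undefined)."""
        if self.n_total == 0:
            return None
        return self.n_confirmed / self.n_total


def callset_concordance(
    set_a: Sequence[HarmonizedVariant],
    set_b: Sequence[HarmonizedVariant],
    allele_exact: bool = False,
) -> ConcordanceResult:
    """Fraction of ``set_a`` confirmed in ``set_b``.

    Confirmation is position-only by default; ``allele_exact`` requires
    chrom/pos/ref/alt identity.
    """
    if allele_exact:
        keys_b = {(r.chrom, r.pos, r.ref, r.alt) for r in set_b}
        hit = lambda r: (r.chrom, r.pos, r.ref, r.alt) in keys_b  # noqa: E731
    else:
        keys_b = {r.site for r in set_b}
        hit = lambda r: r.site in keys_b  # noqa: E731
    confirmed = [r for r in set_a if hit(r)]
    unconfirmed = [r for r in set_a if not hit(r)]
    return ConcordanceResult(len(set_a), len(confirmed), confirmed, unconfirmed)
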