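"""Eight-step tumor-only consensus filter for SNVs and small indels.

Without a matched germline sample, somatic calls from a tumor-only
caller are heavily contaminated with germline variation and caller
artifacts.  The procedure implemented here combines two callers run in
tumor-only mode (a Mutect2-style primary and a Platypus-style secondary)
and strips putative germline variation using external resources:

1. Rescue Mutect2 calls flagged only ``germline`` at positions withdrawn
   from the germline reference.
2. Rescue Platypus calls flagged only ``alleleBias`` at those positions
   (allele-bias filtering would otherwise delete low-AF somatic calls).
3. Remove Platypus calls at any position present in a panel of normals
   built from unmatched germline samples.
4. Drop all non-passing records from both call sets.
5. Keep only sites called by both callers (consensus intersection).
6. Remove sites present in any germline resource.
7. Apply support thresholds: keep iff AF >= 0.05, DP >= 10 and >= 3
   alt-supporting reads.
8. Remove sites with read support in any regenotyped normal sample.

Matching is position-only throughout: alternate alleles are *not*
required to agree, because different callers represent the same event
with different allele strings (particularly for indels, where the
start/end may also shift — indel matching therefore uses reference
footprint overlap rather than exact position).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .intervals import IntervalIndex
from .variants import SiteKey, VariantRecord, site_set

DEFAULT_MIN_AF = 0.05
DEFAULT_MIN_DP = 10
DEFAULT_MIN_ALT = 3


# --- audit trail -------------------------------------------------------------

@dataclass
class AuditStep:
    label: str
    n_in: int
    n_removed: int
    n_rescued: int = 0

    @property
    def n_out(self) -> int:
        return self.n_in - self.n_removed


@dataclass
class FilterAudit:
    """Ordered per-step record counts; consecutive steps must chain."""

    steps: list[AuditStep] = field(default_factory=list)

    def record(self, label: str, n_in: int, n_removed: int, n_rescued: int = 0) -> None:
        self.steps.append(AuditStep(label, n_in, n_removed, n_rescued))

    def validate_chain(self) -> None:
        for prev, nxt in zip(self.steps, self.steps[1:]):
            if nxt.n_in != prev.n_out:
                raise AssertionError(
                    f"audit chain broken between {prev.label!r} ({prev.n_out} out) "
                    f"and {nxt.label!r} ({nxt.n_in} in)"
                )

    def to_rows(self) -> list[tuple[str, int, int, int, int]]:
        return [(s.label, s.n_in, s.n_removed, s.n_rescued, s.n_out) for s in self.steps]


# --- panel of normals & evidence --------------------------------------------

@dataclass
class PanelOfNormalSites:
    """Position-only site set observed across unmatched normal samples."""

    sites: frozenset[SiteKey]
    provenance: tuple[str, ...] = ()

    def __contains__(self, key: SiteKey) -> bool:
        return key in self.sites

    def __len__(self) -> int:
        return len(self.sites)


class NormalEvidenceTable:
    """Boolean per-normal read support at queried sites (regenotyping).

    The decision rule downstream is "any support in any normal removes the
    variant"; the provider only has to answer yes/no per (site, sample).
    Querying a site the table does not cover is an error — silently
    keeping an unscreened variant would defeat the screen.
    """

    def __init__(self, support: Mapping[SiteKey, Mapping[str, bool]]) -> None:
        self._support = {SiteKey(*k): dict(v) for k, v in support.items()}

    @classmethod
    def from_tsv(cls, path: str) -> "NormalEvidenceTable":
        """Columns: chrom, pos (1-based), sample, support (0/1)."""
        table: dict[SiteKey, dict[str, bool]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                chrom, pos, sample, sup = line.split("\t")[:4]
                table.setdefault(SiteKey(chrom, int(pos)), {})[sample] = bool(int(sup))
        return cls(table)

    def covers(self, key: SiteKey) -> bool:
        return key in self._support

    def any_support(self, key: SiteKey) -> bool:
        if key not in self._support:
            raise KeyError(f"no regenotyping evidence for site {key}")
        return any(self._support[key].values())


def build_site_pon(
    normal_callsets: Sequence[Sequence[VariantRecord]],
    labels: Sequence[str] | None = None,
) -> PanelOfNormalSites:
    """Union of variant positions over all normal call sets.

    Membership is position-only and deduplicated; an empty input is an
    error because a zero-normal panel filters nothing.
    """
    if not normal_callsets:
        raise ValueError("panel of normals requires at least one normal call set")
    sites: set[SiteKey] = set()
    for callset in normal_callsets:
        sites |= site_set(callset)
    prov = tuple(labels) if labels is not None else tuple(
        f"normal_{i}" for i in range(len(normal_callsets))
    )
    return PanelOfNormalSites(frozenset(sites), prov)


# --- individual filter steps -------------------------------------------------

def rescue_flag(
    records: Sequence[VariantRecord],
    removed_sites: set[SiteKey],
    flag_name: str,
    audit: FilterAudit | None = None,
    label: str | None = None,
) -> list[VariantRecord]:
    """Reset the filter to passing for records whose *only* flag is
    ``flag_name`` and whose position was withdrawn from the germline
    resource.  Everything else is untouched."""
    target = frozenset({flag_name})
    out: list[VariantRecord] = []
    n_rescued = 0
    for r in records:
        if r.filter_flags == target and r.site in removed_sites:
            out.append(r.with_filters(()))
            n_rescued += 1
        else:
            out.append(r)
    if audit is not None:
        audit.record(label or f"rescue[{flag_name}]", len(records), 0, n_rescued)
    return out


def _footprint_index(resource: Iterable[VariantRecord]) -> IntervalIndex:
    idx = IntervalIndex()
    for r in resource:
        idx.add(r.footprint())
    return idx


def remove_sites(
    records: Sequence[VariantRecord],
    sites: set[SiteKey],
    audit: FilterAudit | None = None,
    label: str = "remove_sites",
    indel_footprints: IntervalIndex | None = None,
) -> list[VariantRecord]:
    """Drop records at listed positions, alleles ignored.

    SNVs match by exact chrom+pos.  Indels additionally match when their
    reference footprint intersects a resource variant's footprint
    (callers shift indel start/end between representations).
    """
    kept: list[VariantRecord] = []
    n_removed = 0
    for r in records:
        hit = r.site in sites
        if not hit and not r.is_snv and indel_footprints is not None:
            hit = indel_footprints.any_overlap(r.footprint())
        if hit:
            n_removed += 1
        else:
            kept.append(r)
    if audit is not None:
        audit.record(label, len(records), n_removed)
    return kept


def drop_non_pass(
    records: Sequence[VariantRecord],
    audit: FilterAudit | None = None,
    label: str = "drop_non_pass",
) -> list[VariantRecord]:
    """Keep only records whose filter set is empty."""
    kept = [r for r in records if r.passing]
    if audit is not None:
        audit.record(label, len(records), len(records) - len(kept))
    return kept


def consensus_intersect(
    callset_a: Sequence[VariantRecord],
    callset_b: Sequence[VariantRecord],
    audit: FilterAudit | None = None,
    label: str = "consensus",
) -> list[VariantRecord]:
    """Records of the primary caller at positions also called by the
    secondary caller.  Allele representation follows the primary caller;
    matching is position-only."""
    samples_a = {r.sample for r in callset_a if r.sample}
    samples_b = {r.sample for r in callset_b if r.sample}
    if samples_a and samples_b and samples_a != samples_b:
        raise ValueError(
            f"consensus requires matching samples, got {samples_a} vs {samples_b}"
        )
    b_sites = site_set(callset_b)
    kept = [r for r in callset_a if r.site in b_sites]
    if audit is not None:
        audit.record(label, len(callset_a), len(callset_a) - len(kept))
    return kept


def apply_support_thresholds(
    records: Sequence[VariantRecord],
    min_af: float = DEFAULT_MIN_AF,
    min_dp: int = DEFAULT_MIN_DP,
    min_alt: int = DEFAULT_MIN_ALT,
    audit: FilterAudit | None = None,
    label: str = "support_thresholds",
) -> list[VariantRecord]:
    """Keep iff AF >= min_af AND DP >= min_dp AND alt reads >= min_alt.

    The boundary is kept (removal conditions are strict inequalities).
    Records lacking the support fields are removed.
    """
    kept: list[VariantRecord] = []
    for r in records:
        if r.unsupported:
            continue
        if r.af >= min_af and r.sample_dp >= min_dp and r.sample_alt_depth >= min_alt:
            kept.append(r)
    if audit is not None:
        audit.record(label, len(records), len(records) - len(kept))
    return kept


def regenotype_screen(
    records: Sequence[VariantRecord],
    evidence: NormalEvidenceTable,
    audit: FilterAudit | None = None,
    label: str = "regenotype_screen",
) -> list[VariantRecord]:
    """Remove a record iff any normal sample shows support at its site."""
    kept = [r for r in records if not evidence.any_support(r.site)]
    if audit is not None:
        audit.record(label, len(records), len(records) - len(kept))
    return kept


# --- full pipeline -----------------------------------------------------------

@dataclass
class SnvPipelineConfig:
    """Inputs for one tumor sample.

    ``germline_resources`` maps resource label -> list of resource records;
    they are applied (and audited) per resource, equivalent to removing
    their union.  ``contig_allowlist`` drops unanchored/mitochondrial
    contigs before any step.
    """

    mutect2_records: Sequence[VariantRecord]
    platypus_records: Sequence[VariantRecord]
    normal_callsets: Sequence[Sequence[VariantRecord]]
    germline_resources: Mapping[str, Sequence[VariantRecord]]
    removed_sites: set[SiteKey]
    evidence: NormalEvidenceTable
    min_af: float = DEFAULT_MIN_AF
    min_dp: int = DEFAULT_MIN_DP
    min_alt: int = DEFAULT_MIN_ALT
    contig_allowlist: frozenset[str] | None = None


@dataclass
class SnvPipelineResult:
    final_records: list[VariantRecord]
    audit: FilterAudit


def run_snv_pipeline(config: SnvPipelineConfig) -> SnvPipelineResult:
    """Execute steps 1-8 in order and return the surviving calls + audit.

    The audit chain follows the primary (Mutect2-dialect) call set from
    the consensus step onward; the Platypus-side steps (2-4) are audited
    under their own labels.
    """
    audit = FilterAudit()

    def allow(records: Sequence[VariantRecord]) -> list[VariantRecord]:
        if config.contig_allowlist is None:
            return list(records)
        return [r for r in records if r.chrom in config.contig_allowlist]

    m2 = allow(config.mutect2_records)
    plat = allow(config.platypus_records)

    # Steps 1-2: rescues
    m2 = rescue_flag(m2, config.removed_sites, "germline", audit, "step1_rescue_germline")
    plat = rescue_flag(plat, config.removed_sites, "alleleBias", None)

    # Step 3: Platypus panel of normals
    pon = build_site_pon([allow(cs) for cs in config.normal_callsets])
    plat = remove_sites(plat, set(pon.sites), None)

    # Step 4: non-PASS removal on both call sets
    m2 = drop_non_pass(m2, audit, "step4_drop_non_pass")
    plat = drop_non_pass(plat, None)

    # Step 5: consensus
    m2 = consensus_intersect(m2, plat, audit, "step5_consensus")

    # Step 6: germline resources (audited per resource; equals the union)
    for name, resource in config.germline_resources.items():
        m2 = remove_sites(
            m2,
            site_set(resource),
            audit,
            f"step6_germline[{name}]",
            indel_footprints=_footprint_index(r for r in resource if not r.is_snv),
        )

    # Step 7: support thresholds
    m2 = apply_support_thresholds(
        m2, config.min_af, config.min_dp, config.min_alt, audit, "step7_support"
    )

    # Step 8: regenotyping screen
    m2 = regenotype_screen(m2, config.evidence, audit, "step8_regenotype")

    audit.validate_chain()
    return SnvPipelineResult(m2, audit)
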