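"""Structural-variant filtering for unmatched tumor samples.

Manta-style SV calls (DEL/INS/INV/DUP plus mate-paired BND records for
translocations) are screened in five steps: a panel-of-normals screen
via breakpoint-proximity merging (Jasmine-style nonlinear distance),
support/precision filters (PASS, not IMPRECISE, PR or SR >= 15),
centromere flagging, a regenotyping screen against normal samples, and
removal of orphaned breakends whose mate was filtered earlier.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

from .intervals import GenomicInterval, IntervalIndex
from .snv_filter import FilterAudit

DEFAULT_MAX_DIST = 1000
DEFAULT_MIN_SUPPORT = 15

SV_TYPES = ("DEL", "INS", "INV", "DUP", "BND")


@dataclass(frozen=True)
class StructuralVariant:
    """One SV call; BND records come in mate pairs linked by ``mate_id``."""

    sv_id: str
    sv_type: str
    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    length: int | None = None
    pr_support: int = 0
    sr_support: int = 0
    imprecise: bool = False
    filter_flags: frozenset[str] = frozenset()
    mate_id: str | None = None
    centromeric_flag: bool = False
    sample: str = ""

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.sv_type!r}")
        if self.sv_type != "BND":
            if self.chrom1 != self.chrom2:
                raise ValueError("non-BND SV must have both ends on one chromosome")
            if self.pos1 > self.pos2:
                raise ValueError("non-BND SV requires pos1 <= pos2")
        if self.pr_support < 0 or self.sr_support < 0:
            raise ValueError("PR/SR support must be non-negative")

    @property
    def passing(self) -> bool:
        return not self.filter_flags

    @property
    def breakpoints(self) -> tuple[tuple[str, int], tuple[str, int]]:
        return ((self.chrom1, self.pos1), (self.chrom2, self.pos2))

    def spanned(self) -> GenomicInterval | None:
        """Interval covered by a non-BND SV (None for breakends)."""
        if self.sv_type == "BND":
            return None
        return GenomicInterval(self.chrom1, self.pos1 - 1, max(self.pos2, self.pos1 + 1))


@dataclass
class SvCluster:
    representative: StructuralVariant
    member_ids: list[str]
    member_samples: list[str]


def _merge_distance(a: StructuralVariant, b: StructuralVariant, max_dist: int) -> int:
    """Jasmine-style nonlinear distance: capped by the shorter SV length
    for length-bearing types; plain ``max_dist`` for BND and INS."""
    if a.sv_type in ("BND", "INS"):
        return max_dist
    lengths = [x for x in (a.length, b.length) if x is not None]
    if not lengths:
        return max_dist
    return min(max_dist, min(abs(x) for x in lengths))


def _mergeable(a: StructuralVariant, b: StructuralVariant, max_dist: int) -> bool:
    if a.sv_type != b.sv_type:
        return False
    d = _merge_distance(a, b, max_dist)
    (ac1, ap1), (ac2, ap2) = a.breakpoints
    (bc1, bp1), (bc2, bp2) = b.breakpoints
    direct = (
        ac1 == bc1 and ac2 == bc2
        and abs(ap1 - bp1) <= d and abs(ap2 - bp2) <= d
    )
    # BND mates may list ends in either order
    swapped = (
        a.sv_type == "BND"
        and ac1 == bc2 and ac2 == bc1
        and abs(ap1 - bp2) <= d and abs(ap2 - bp1) <= d
    )
    return direct or swapped


def merge_svs(
    callsets: Sequence[Sequence[StructuralVariant]],
    max_dist: int = DEFAULT_MAX_DIST,
) -> list[SvCluster]:
    """Single-linkage clustering over the pairwise mergeable relation.

    Deterministic regardless of input order: variants are sorted by
    coordinates before clustering and the representative is the sorted
    first member.
    """
    svs = sorted(
        (sv for cs in callsets for sv in cs),
        key=lambda s: (s.chrom1, s.pos1, s.chrom2, s.pos2, s.sv_type, s.sample, s.sv_id),
    )
    n = len(svs)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    for i in range(n):
        for j in range(i + 1, n):
            if _mergeable(svs[i], svs[j], max_dist):
                union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    clusters = []
    for root in sorted(groups):
        members = groups[root]
        clusters.append(
            SvCluster(
                representative=svs[members[0]],
                member_ids=[svs[i].sv_id for i in members],
                member_samples=[svs[i].sample for i in members],
            )
        )
    return clusters


def pon_screen(
    cell_line_svs: Sequence[StructuralVariant],
    normal_callsets: Sequence[Sequence[StructuralVariant]],
    max_dist: int = DEFAULT_MAX_DIST,
    normal_samples: frozenset[str] | None = None,
    audit: FilterAudit | None = None,
) -> list[StructuralVariant]:
    """Keep a tumor SV iff its merge cluster contains no normal member."""
    if normal_samples is None:
        normal_samples = frozenset(
            sv.sample for cs in normal_callsets for sv in cs
        )
    clusters = merge_svs([list(cell_line_svs), *normal_callsets], max_dist)
    contaminated: set[str] = set()
    tumor_ids = {sv.sv_id for sv in cell_line_svs}
    for cl in clusters:
        if any(s in normal_samples for s in cl.member_samples):
            contaminated |= set(cl.member_ids) & tumor_ids
    kept = [sv for sv in cell_line_svs if sv.sv_id not in contaminated]
    if audit is not None:
        audit.record("sv_pon_screen", len(cell_line_svs), len(cell_line_svs) - len(kept))
    return kept


def apply_sv_quality_filters(
    svs: Sequence[StructuralVariant],
    min_support: int = DEFAULT_MIN_SUPPORT,
    audit: FilterAudit | None = None,
) -> list[StructuralVariant]:
    """Keep iff PASS, precise, and PR or SR support >= min_support."""
    kept = [
        sv
        for sv in svs
        if sv.passing
        and not sv.imprecise
        and (sv.pr_support >= min_support or sv.sr_support >= min_support)
    ]
    if audit is not None:
        audit.record("sv_quality", len(svs), len(svs) - len(kept))
    return kept


def flag_centromeric(
    svs: Sequence[StructuralVariant],
    centromere_windows: Sequence[GenomicInterval],
) -> list[StructuralVariant]:
    """Flag (not remove) SVs touching putative centromeric windows.

    A non-BND SV is flagged when its spanned interval overlaps a window;
    a BND when either breakpoint base falls in one.
    """
    index = IntervalIndex(centromere_windows)
    out: list[StructuralVariant] = []
    for sv in svs:
        if sv.sv_type == "BND":
            hit = any(
                index.any_overlap(GenomicInterval(c, p - 1, p))
                for c, p in sv.breakpoints
            )
        else:
            hit = index.any_overlap(sv.spanned())
        out.append(replace(sv, centromeric_flag=hit) if hit != sv.centromeric_flag else sv)
    return out


class SvEvidenceTable:
    """Boolean per-normal regenotyping support, keyed by sv_id."""

    def __init__(self, support: Mapping[str, Mapping[str, bool]]) -> None:
        self._support = {k: dict(v) for k, v in support.items()}

    @classmethod
    def from_tsv(cls, path: str) -> "SvEvidenceTable":
        """Columns: sv_id, sample, support (0/1)."""
        table: dict[str, dict[str, bool]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                sv_id, sample, sup = line.split("\t")[:3]
                table.setdefault(sv_id, {})[sample] = bool(int(sup))
        return cls(table)

    def any_support(self, sv_id: str) -> bool:
        if sv_id not in self._support:
            raise KeyError(f"no regenotyping evidence for SV {sv_id!r}")
        return any(self._support[sv_id].values())


def regenotype_screen_sv(
    svs: Sequence[StructuralVariant],
    evidence: SvEvidenceTable,
    audit: FilterAudit | None = None,
) -> list[StructuralVariant]:
    """Remove an SV iff any normal sample shows support for it."""
    kept = [sv for sv in svs if not evidence.any_support(sv.sv_id)]
    if audit is not None:
        audit.record("sv_regenotype", len(svs), len(svs) - len(kept))
    return kept


def drop_orphan_breakends(
    svs: Sequence[StructuralVariant],
    original_ids: frozenset[str] | None = None,
    audit: FilterAudit | None = None,
) -> list[StructuralVariant]:
    """Remove BND records whose mate is no longer in the set.

    A BND whose mate_id never existed in the *original* input indicates a
    malformed call set and raises; a mate merely filtered out upstream
    causes the survivor to be dropped here, leaving a mate-closed set.
    """
    present = {sv.sv_id for sv in svs}
    if original_ids is None:
        original_ids = frozenset(present)
    kept: list[StructuralVariant] = []
    for sv in svs:
        if sv.sv_type != "BND":
            kept.append(sv)
            continue
        if sv.mate_id is None or sv.mate_id not in original_ids:
            raise ValueError(f"BND {sv.sv_id!r} has mate {sv.mate_id!r} absent from input")
        if sv.mate_id in present:
            kept.append(sv)
    if audit is not None:
        audit.record("sv_orphan_bnd", len(svs), len(svs) - len(kept))
    return kept


@dataclass
class SvPipelineResult:
    final_svs: list[StructuralVariant]
    audit: FilterAudit


def run_sv_pipeline(
    tumor_svs: Sequence[StructuralVariant],
    normal_callsets: Sequence[Sequence[StructuralVariant]],
    centromere_windows: Sequence[GenomicInterval],
    evidence: SvEvidenceTable,
    max_dist: int = DEFAULT_MAX_DIST,
    min_support: int = DEFAULT_MIN_SUPPORT,
    exclude_centromeric: bool = False,
) -> SvPipelineResult:
    """Run the five SV filtering steps in order.

    Centromere-overlapping SVs are flagged and retained by default
    (``exclude_centromeric=True`` removes them before the final output).
    """
    audit = FilterAudit()
    original_ids = frozenset(sv.sv_id for sv in tumor_svs)
    svs = pon_screen(tumor_svs, normal_callsets, max_dist, audit=audit)
    svs = apply_sv_quality_filters(svs, min_support, audit=audit)
    svs = flag_centromeric(svs, centromere_windows)
    audit.record("sv_centromere_flag", len(svs), 0)
    svs = regenotype_screen_sv(svs, evidence, audit=audit)
    svs = drop_orphan_breakends(svs, original_ids, audit=audit)
    if exclude_centromeric:
        n_in = len(svs)
        svs = [sv for sv in svs if not sv.centromeric_flag]
        audit.record("sv_centromere_exclude", n_in, n_in - len(svs))
        svs = drop_orphan_breakends(svs, original_ids, audit=audit)
    audit.validate_chain()
    return SvPipelineResult(svs, audit)


# --- Manta-style VCF reading -------------------------------------------------

def read_sv_vcf(path: str, sample: str = "") -> list[StructuralVariant]:
    """Read a Manta-style SV VCF (INFO SVTYPE/END/SVLEN/IMPRECISE/MATEID,
    FORMAT PR/SR as ref,alt pairs)."""
    import pysam

    out: list[StructuralVariant] = []
    with pysam.VariantFile(path) as vcf:
        sample_names = list(vcf.header.samples)
        sname = sample or (sample_names[0] if sample_names else "")
        for rec in vcf:
            info = rec.info
            sv_type = info.get("SVTYPE")
            if sv_type is None:
                continue
            mate = info.get("MATEID")
            if isinstance(mate, tuple):
                mate = mate[0]
            # pysam surfaces END via rec.stop (0-based exclusive, numerically
            # equal to the 1-based inclusive END)
            chrom2, pos2 = rec.chrom, (rec.stop if rec.stop > rec.pos else rec.pos)
            if sv_type == "BND" and rec.alts:
                # parse mate locus out of the breakend ALT, e.g. A[chr2:123[
                alt = rec.alts[0]
                core = alt.strip("ACGTNacgtn").strip("[]")
                if ":" in core:
                    chrom2, p = core.rsplit(":", 1)
                    pos2 = int(p)
            length = info.get("SVLEN")
            if isinstance(length, tuple):
                length = length[0]
            def _alt_count(value) -> int:
                # Manta writes ref,alt pairs; take the alt-supporting count
                if value is None:
                    return 0
                if isinstance(value, str):
                    value = value.split(",")
                vals = [v for v in (value if isinstance(value, (tuple, list)) else (value,))
                        if v is not None]
                return int(vals[-1]) if vals else 0

            pr = sr = 0
            if sample_names:
                fmt = rec.samples[sample_names[0]]
                if "PR" in fmt:
                    pr = _alt_count(fmt["PR"])
                if "SR" in fmt:
                    sr = _alt_count(fmt["SR"])
            flags = frozenset(f for f in rec.filter.keys() if f != "PASS")
            out.append(
                StructuralVariant(
                    sv_id=rec.id or f"{rec.chrom}:{rec.pos}:{sv_type}",
                    sv_type=sv_type,
                    chrom1=rec.chrom,
                    pos1=rec.pos,
                    chrom2=chrom2,
                    pos2=int(pos2),
                    length=int(length) if length is not None else None,
                    pr_support=pr,
                    sr_support=sr,
                    imprecise=bool(info.get("IMPRECISE", False)),
                    filter_flags=flags,
                    mate_id=mate,
                    sample=sname,
                )
            )
    return out
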