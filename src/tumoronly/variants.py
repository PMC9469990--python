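"""Variant records, site keys, and VCF input/output.

Reading goes through :mod:`pysam`; each caller "dialect" declares which
FORMAT/INFO keys carry the allele fraction (AF), read depth (DP) and
alt-supporting read count, since Mutect2-style and Platypus-style VCFs
encode these differently.  Multiallelic rows are split into one record
per alternate allele on ingest.

Site identity throughout the tumor-only pipeline is *position only*
(chromosome + position, never the allele): unmatched-normal filtering
deliberately treats two calls at the same site with different alternate
alleles as the same event, because callers frequently represent the same
underlying variant with different allele strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Sequence

import pysam

from .intervals import GenomicInterval


class SiteKey(NamedTuple):
    """Position-only variant identity (chrom + 1-based position)."""

    chrom: str
    pos: int


@dataclass(frozen=True)
class VariantRecord:
    """One SNV/indel call for one alternate allele.

    ``pos`` is the 1-based VCF position. ``filter_flags`` is the FILTER
    field tokenized into a set; PASS and "." are both represented as the
    empty set (a record *passes* iff the set is empty).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    filter_flags: frozenset[str] = frozenset()
    info_flags: frozenset[str] = frozenset()
    sample_af: float | None = None
    sample_dp: int | None = None
    sample_alt_depth: int | None = None
    caller: str = ""
    sample: str = ""

    def __post_init__(self) -> None:
        if not self.alt:
            raise ValueError("alt allele must be non-empty")
        if self.sample_af is not None and not (0.0 <= self.sample_af <= 1.0):
            raise ValueError(f"AF out of [0,1]: {self.sample_af}")
        if (
            self.sample_dp is not None
            and self.sample_alt_depth is not None
            and not (0 <= self.sample_alt_depth <= self.sample_dp)
        ):
            raise ValueError("require 0 <= alt_depth <= DP")

    @property
    def site(self) -> SiteKey:
        return SiteKey(self.chrom, self.pos)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def passing(self) -> bool:
        return not self.filter_flags

    @property
    def af(self) -> float | None:
        """Allele fraction; recomputed as alt_depth/DP when AF is absent."""
        if self.sample_af is not None:
            return self.sample_af
        if self.sample_dp and self.sample_alt_depth is not None:
            return self.sample_alt_depth / self.sample_dp
        return None

    @property
    def unsupported(self) -> bool:
        """True when neither AF nor the depths needed to derive it exist.

        Unsupported records fail the support-threshold filter by design.
        """
        return self.af is None or self.sample_dp is None or self.sample_alt_depth is None

    def footprint(self) -> GenomicInterval:
        """Reference bases the call spans, internal 0-based half-open."""
        return GenomicInterval(self.chrom, self.pos - 1, self.pos - 1 + len(self.ref))

    def with_filters(self, flags: Iterable[str]) -> "VariantRecord":
        return replace(self, filter_flags=frozenset(flags))


# --- caller dialects ---------------------------------------------------------

@dataclass(frozen=True)
class CallerDialect:
    """Field mapping for one caller's VCF flavour.

    ``af_key``/``dp_key`` name per-sample FORMAT keys; ``ad_key`` names the
    allelic-depth FORMAT key (ref followed by alts) and ``alt_key`` an
    alternative per-alt alt-read-count key (Platypus ``NV``).  ``nr_key``
    is a Platypus-style per-alt total-depth key used when ``dp_key`` is
    absent.
    """

    name: str
    af_key: str | None = None
    dp_key: str | None = None
    ad_key: str | None = None
    alt_key: str | None = None
    nr_key: str | None = None


DIALECTS: dict[str, CallerDialect] = {
    # Mutect2: FORMAT AF (per alt), DP, AD (ref,alt1,...)
    "mutect2": CallerDialect("mutect2", af_key="AF", dp_key="DP", ad_key="AD"),
    # Platypus: FORMAT NR (per-alt total reads), NV (per-alt variant reads)
    "platypus": CallerDialect("platypus", alt_key="NV", nr_key="NR"),
    # Generic: best effort from AF/DP/AD
    "generic": CallerDialect("generic", af_key="AF", dp_key="DP", ad_key="AD"),
}


def _as_tuple(value) -> tuple:
    if value is None:
        return ()
    if isinstance(value, (tuple, list)):
        return tuple(value)
    return (value,)


def _parse_record(
    rec: pysam.VariantRecord, dialect: CallerDialect, sample_name: str
) -> list[VariantRecord]:
    flags = frozenset(f for f in rec.filter.keys() if f != "PASS")
    info_flags = frozenset(
        k for k, v in rec.info.items() if isinstance(v, bool) and v
    )
    sample = rec.samples[sample_name] if sample_name in rec.samples else None

    def fmt(key):
        if sample is None or key is None or key not in sample:
            return None
        return sample[key]

    afs = _as_tuple(fmt(dialect.af_key))
    ads = _as_tuple(fmt(dialect.ad_key))
    alts_counts = _as_tuple(fmt(dialect.alt_key))
    nrs = _as_tuple(fmt(dialect.nr_key))
    dp = fmt(dialect.dp_key)

    out: list[VariantRecord] = []
    alts = rec.alts or ()
    for i, alt in enumerate(alts):
        if alt is None or alt in {".", "*"}:
            continue
        alt_depth = None
        if i + 1 < len(ads) and ads[i + 1] is not None:
            alt_depth = int(ads[i + 1])
        elif i < len(alts_counts) and alts_counts[i] is not None:
            alt_depth = int(alts_counts[i])
        depth = None
        if dp is not None:
            depth = int(dp)
        elif i < len(nrs) and nrs[i] is not None:
            depth = int(nrs[i])
        af = None
        if i < len(afs) and afs[i] is not None:
            af = min(1.0, max(0.0, float(afs[i])))
        if alt_depth is not None and depth is not None:
            alt_depth = min(alt_depth, depth)
        out.append(
            VariantRecord(
                chrom=rec.chrom,
                pos=rec.pos,
                ref=rec.ref,
                alt=alt,
                filter_flags=flags,
                info_flags=info_flags,
                sample_af=af,
                sample_dp=depth,
                sample_alt_depth=alt_depth,
                caller=dialect.name,
                sample=sample_name,
            )
        )
    return out


def read_vcf(path: str, caller_dialect: str = "generic") -> list[VariantRecord]:
    """Read a VCF into per-alt :class:`VariantRecord` objects.

    Raises ``KeyError`` for an unknown dialect and ``ValueError`` (naming
    the failing record ordinal) for malformed rows.
    """
    if caller_dialect not in DIALECTS:
        raise KeyError(
            f"unknown caller dialect {caller_dialect!r}; "
            f"known: {sorted(DIALECTS)}"
        )
    dialect = DIALECTS[caller_dialect]
    records: list[VariantRecord] = []
    with pysam.VariantFile(path) as vcf:
        samples = list(vcf.header.samples)
        sample_name = samples[0] if samples else ""
        for ordinal, rec in enumerate(vcf, 1):
            try:
                records.extend(_parse_record(rec, dialect, sample_name))
            except Exception as exc:  # noqa: BLE001 - re-raise with location
                raise ValueError(
                    f"{path}: malformed VCF record #{ordinal} "
                    f"({rec.chrom}:{rec.pos}): {exc}"
                ) from exc
    return records


def write_vcf(
    records: Sequence[VariantRecord],
    path: str,
    sample_name: str = "SAMPLE",
    extra_filters: Iterable[str] = (),
) -> None:
    """Write records as a minimal VCF 4.2 file (Mutect2-style FORMAT).

    Filter tokens are preserved verbatim; records with an empty flag set
    are written as PASS.  Output re-reads cleanly through :func:`read_vcf`.
    """
    filters: set[str] = set(extra_filters)
    contigs: list[str] = []
    for r in records:
        filters |= r.filter_flags
        if r.chrom not in contigs:
            contigs.append(r.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        for f in sorted(filters):
            fh.write(f'##FILTER=<ID={f},Description="{f}">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths">\n'
        )
        fh.write(
            '##FORMAT=<ID=AF,Number=A,Type=Float,'
            'Description="Allele fraction">\n'
        )
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{sample_name}\n"
        )
        for r in sorted(records, key=lambda x: (x.chrom, x.pos, x.alt)):
            filt = ";".join(sorted(r.filter_flags)) if r.filter_flags else "PASS"
            dp = r.sample_dp if r.sample_dp is not None else "."
            ad_alt = r.sample_alt_depth
            if ad_alt is not None and r.sample_dp is not None:
                ad = f"{r.sample_dp - ad_alt},{ad_alt}"
            elif ad_alt is not None:
                ad = f".,{ad_alt}"
            else:
                ad = ".,."
            af = f"{r.sample_af:.6g}" if r.sample_af is not None else "."
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\t{filt}\t.\t"
                f"GT:AD:AF:DP\t0/1:{ad}:{af}:{dp}\n"
            )


def site_set(records: Iterable[VariantRecord]) -> set[SiteKey]:
    return {r.site for r in records}
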