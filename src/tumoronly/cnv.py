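"""Copy-ratio segment classification and gene-level CNV annotation.

Segments carry a log2 tumor/normal copy ratio from an upstream
segmentation.  Classification uses fixed thresholds: ratio >= 0.4 is a
one-copy gain, ratio <= -0.9 a two-copy loss; the band in between is
neutral by default, with an optional configurable shallow-loss cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .genes import GeneSet
from .intervals import GenomicInterval, total_bases

GAIN_THRESH = 0.4
DEEP_LOSS_THRESH = -0.9

GAIN = "gain"
NEUTRAL = "neutral"
LOSS_ONE = "loss_one_copy"
LOSS_TWO = "loss_two_copy"


def classify_segment(
    log2_ratio: float,
    gain_thresh: float = GAIN_THRESH,
    deep_loss_thresh: float = DEEP_LOSS_THRESH,
    shallow_loss_thresh: float | None = None,
) -> str:
    """Call class for one log2 copy ratio (thresholds inclusive)."""
    if not math.isfinite(log2_ratio):
        raise ValueError(f"non-finite log2 ratio: {log2_ratio}")
    if not gain_thresh > 0 > deep_loss_thresh:
        raise ValueError("require gain_thresh > 0 > deep_loss_thresh")
    if log2_ratio >= gain_thresh:
        return GAIN
    if log2_ratio <= deep_loss_thresh:
        return LOSS_TWO
    if shallow_loss_thresh is not None and log2_ratio <= shallow_loss_thresh:
        return LOSS_ONE
    return NEUTRAL


@dataclass(frozen=True)
class CopyRatioSegment:
    interval: GenomicInterval
    log2_ratio: float
    call: str
    sample: str = ""

    @classmethod
    def from_ratio(
        cls,
        interval: GenomicInterval,
        log2_ratio: float,
        sample: str = "",
        **thresholds,
    ) -> "CopyRatioSegment":
        return cls(interval, log2_ratio, classify_segment(log2_ratio, **thresholds), sample)


def read_seg_table(path: str, sample: str = "", **thresholds) -> list[CopyRatioSegment]:
    """Read a GATK ModelSegments-style TSV (contig, start, end, log2 ratio).

    Start/end are 1-based inclusive on disk, converted to the internal
    half-open convention.
    """
    df = pd.read_csv(path, sep="\t", comment="@")
    cols = {c.lower(): c for c in df.columns}

    def col(*names):
        for n in names:
            if n in cols:
                return cols[n]
        raise ValueError(f"segment table {path} lacks a column among {names}")

    out = []
    for _, row in df.iterrows():
        iv = GenomicInterval(
            str(row[col("contig", "chrom", "chromosome")]),
            int(row[col("start")]) - 1,
            int(row[col("end", "stop")]),
        )
        out.append(
            CopyRatioSegment.from_ratio(
                iv,
                float(row[col("mean_log2_copy_ratio", "log2_copy_ratio", "log2", "seg.mean")]),
                sample=sample,
                **thresholds,
            )
        )
    return out


@dataclass(frozen=True)
class GeneCnvCall:
    gene_id: str
    sample: str
    call: str
    overlap_fraction: float

    def __post_init__(self) -> None:
        if not (0.0 < self.overlap_fraction <= 1.0):
            raise ValueError("overlap fraction must lie in (0, 1]")


def annotate_genes(
    segments: Sequence[CopyRatioSegment],
    gene_set: GeneSet,
    exonic_only: bool = False,
) -> list[GeneCnvCall]:
    """Gene-level calls for every non-neutral segment overlapping a gene.

    The overlap target is the gene body by default (``exonic_only``
    restricts to merged CDS).  If several same-class segments of one
    sample hit a gene their covered fractions are pooled, so splitting a
    segment in two changes nothing.
    """
    # (gene, sample, call) -> list of covered sub-intervals
    covered: dict[tuple[str, str, str], list[GenomicInterval]] = {}
    targets: dict[str, list[GenomicInterval]] = {}
    for seg in segments:
        if seg.call == NEUTRAL:
            continue
        for gene in gene_set.genes_overlapping(seg.interval):
            ivs = gene.merged_cds() if exonic_only else [gene.body]
            targets[gene.gene_id] = ivs
            pieces = []
            for iv in ivs:
                s = max(iv.start, seg.interval.start)
                e = min(iv.end, seg.interval.end)
                if s < e:
                    pieces.append(GenomicInterval(iv.chrom, s, e))
            if pieces:
                covered.setdefault((gene.gene_id, seg.sample, seg.call), []).extend(pieces)
    calls = []
    for (gid, sample, call), pieces in sorted(covered.items()):
        denom = total_bases(targets[gid])
        frac = total_bases(pieces) / denom if denom else 0.0
        calls.append(GeneCnvCall(gid, sample, call, min(1.0, frac)))
    return calls


def recurrence(gene_calls: Iterable[GeneCnvCall], n_samples: int) -> pd.DataFrame:
    """Per-gene, per-class fraction of samples altered.

    A sample counts once per (gene, class) however many segments support
    the call.  Returns a tidy frame: gene_id, call, n_samples_altered,
    fraction.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    seen: dict[tuple[str, str], set[str]] = {}
    for c in gene_calls:
        seen.setdefault((c.gene_id, c.call), set()).add(c.sample)
    rows = [
        {
            "gene_id": gid,
            "call": call,
            "n_samples_altered": len(samples),
            "fraction": len(samples) / n_samples,
        }
        for (gid, call), samples in sorted(seen.items())
    ]
    return pd.DataFrame(rows, columns=["gene_id", "call", "n_samples_altered", "fraction"])
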