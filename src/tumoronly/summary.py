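"""Per-sample genome summaries: sex from coverage, mutational burden,
rainfall series and kataegis detection.

Sex is inferred from the ratio of mean X-chromosome depth to the mean of
per-autosome mean depths: ratios in [0.3, 0.7] call male (one X), ratios
in [0.8, 1.2] call female (two X); anything else is indeterminate.

Kataegis (localized hypermutation) is detected on the inter-mutation
distance series: a region is a maximal stretch of >= ``min_run``
consecutive mutations whose mean inter-mutation spacing is <= the
``max_mean_dist`` cutoff.  The numeric rule parameterizes what rainfall
plots show visually.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .intervals import GenomicInterval
from .variants import VariantRecord

MALE_BIN = (0.3, 0.7)
FEMALE_BIN = (0.8, 1.2)


@dataclass
class CoverageSummary:
    """Per-chromosome mean read depth and the designated X chromosome."""

    depths: Mapping[str, float]
    x_chrom: str = "chrX"

    def autosomes(self) -> list[str]:
        return [c for c in self.depths if c != self.x_chrom]


@dataclass
class SexCall:
    label: str  # "male" | "female" | "indeterminate"
    ratio: float


def infer_sex(coverage: CoverageSummary) -> SexCall:
    """X/autosome depth-ratio sex call with inclusive bin endpoints.

    The autosome reference value is the unweighted mean of per-autosome
    mean depths.
    """
    autosomes = coverage.autosomes()
    if not autosomes or coverage.x_chrom not in coverage.depths:
        raise ValueError("need X and at least one autosome in the coverage table")
    auto_mean = sum(coverage.depths[c] for c in autosomes) / len(autosomes)
    if auto_mean <= 0:
        raise ValueError("zero autosomal depth")
    ratio = coverage.depths[coverage.x_chrom] / auto_mean
    if MALE_BIN[0] <= ratio <= MALE_BIN[1]:
        label = "male"
    elif FEMALE_BIN[0] <= ratio <= FEMALE_BIN[1]:
        label = "female"
    else:
        label = "indeterminate"
    return SexCall(label, ratio)


def read_coverage_tsv(path: str, x_chrom: str = "chrX") -> CoverageSummary:
    """Two-column TSV: chrom, mean depth."""
    depths: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, depth = line.split("\t")[:2]
            depths[chrom] = float(depth)
    return CoverageSummary(depths, x_chrom)


def mutational_burden(
    n_mutations: int, chromosome_sizes: Mapping[str, int]
) -> float:
    """Mutations per megabase over the summed chromosome sizes (bp)."""
    if not chromosome_sizes:
        raise ValueError("empty chromosome size table")
    if n_mutations < 0:
        raise ValueError("negative mutation count")
    total_mb = sum(chromosome_sizes.values()) / 1e6
    return n_mutations / total_mb


@dataclass
class RainfallSeries:
    """Sorted deduplicated mutation positions and successive distances."""

    positions: dict[str, list[int]] = field(default_factory=dict)
    distances: dict[str, list[int]] = field(default_factory=dict)


def rainfall(records: Iterable[VariantRecord]) -> RainfallSeries:
    by_chrom: dict[str, set[int]] = {}
    for r in records:
        by_chrom.setdefault(r.chrom, set()).add(r.pos)
    series = RainfallSeries()
    for chrom in sorted(by_chrom):
        pos = sorted(by_chrom[chrom])
        series.positions[chrom] = pos
        series.distances[chrom] = [b - a for a, b in zip(pos, pos[1:])]
    return series


def detect_kataegis(
    series: RainfallSeries,
    min_run: int = 6,
    max_mean_dist: float = 1000.0,
) -> list[GenomicInterval]:
    """Maximal dense mutation runs as genomic intervals.

    A window of mutations i..j (j-i+1 >= min_run) qualifies when its mean
    spacing (pos[j]-pos[i])/(j-i) is <= max_mean_dist; overlapping
    qualifying windows are unioned, and each maximal union is reported as
    the interval from its first to its last mutation (half-open).
    """
    regions: list[GenomicInterval] = []
    for chrom, pos in series.positions.items():
        n = len(pos)
        if n < min_run:
            continue
        qualifying: list[tuple[int, int]] = []
        for i in range(n):
            for j in range(i + min_run - 1, n):
                if (pos[j] - pos[i]) / (j - i) <= max_mean_dist:
                    qualifying.append((i, j))
        if not qualifying:
            continue
        qualifying.sort()
        cur_i, cur_j = qualifying[0]
        merged: list[tuple[int, int]] = []
        for i, j in qualifying[1:]:
            if i <= cur_j:  # index ranges share a mutation -> same region
                cur_j = max(cur_j, j)
            else:
                merged.append((cur_i, cur_j))
                cur_i, cur_j = i, j
        merged.append((cur_i, cur_j))
        for i, j in merged:
            regions.append(GenomicInterval(chrom, pos[i] - 1, pos[j]))
    return regions
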