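"""Synthetic cohort generator with planted truth.

Emits a complete desk-scale file bundle exercising every pipeline stage
— two-caller tumor VCFs, normal panels, germline resources, Manta-style
SV VCFs with mate-paired breakends, copy-ratio segment tables, coverage
tables, a toy reference and gene annotation, regenotyping evidence
tables, breed genotype panels and signature catalogs — together with a
:class:`CohortTruth` ledger recording the planted class and expected
fate of every record.

Default sizes mirror the study design this pipeline was built for:
23 unmatched normal genomes feed the panels, each tumor carries 250
planted small variants whose allele fractions, depths and alt-read
counts sit on grids straddling the filtering thresholds (AF 0.05, DP 10,
3 alt reads), SV support straddles the 15-read cutoff, and segment
ratios straddle the 0.4 / -0.9 copy-number thresholds, so boundary
behaviour is always exercised.  All randomness flows from a single
integer seed through one ``numpy`` generator.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .intervals import GenomicInterval
from .signatures import CHANNELS, MutationCatalog, SignatureCatalog
from .variants import SiteKey

BASES = np.array(list("ACGT"))

# planted small-variant classes and the pipeline step expected to act
VARIANT_CLASSES = {
    "somatic_eligible": "survive",
    "rescued_somatic": "survive",
    "somatic_lowsupport": "step7_support",
    "somatic_private_m2": "step5_consensus",
    "somatic_private_plat": "absent_from_primary",
    "germline_pon": "step5_consensus",  # removed from Platypus at step 3
    "germline_resource": "step6_germline",
    "artifact_m2": "step4_drop_non_pass",
    "artifact_plat": "step5_consensus",
    "evidence_leak": "step8_regenotype",
}


@dataclass
class CohortConfig:
    n_tumors: int = 2
    n_normals: int = 23
    # per-tumor planted small-variant class counts (sum = 250)
    n_somatic_eligible: int = 50
    n_rescued_somatic: int = 20
    n_somatic_lowsupport: int = 30
    n_somatic_private_m2: int = 10
    n_somatic_private_plat: int = 10
    n_germline_pon: int = 60
    n_germline_resource: int = 30
    n_artifact_m2: int = 15
    n_artifact_plat: int = 10
    n_evidence_leak: int = 15
    discordant_alt_fraction: float = 0.3  # same-position/different-allele callers
    indel_fraction: float = 0.2  # within the resource-germline class
    n_normal_private_sites: int = 20  # extra PON-only sites per normal
    # SV classes per tumor
    n_sv_somatic_pass: int = 8
    n_sv_bnd_pairs_pass: int = 3
    n_sv_lowsupport: int = 4
    n_sv_imprecise: int = 3
    n_sv_nonpass: int = 3
    n_sv_germline: int = 6
    n_sv_bnd_orphan_pairs: int = 2
    n_sv_evidence_leak: int = 3
    n_sv_centromeric: int = 2
    # genome
    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: {
            "chr1": 300_000,
            "chr2": 250_000,
            "chr3": 200_000,
            "chrX": 100_000,
        }
    )
    x_chrom: str = "chrX"
    autosome_depth: float = 40.0
    sex_ratios: tuple[float, ...] = (0.5, 1.0, 0.75)  # cycled over tumors
    seg_ratios: tuple[float, ...] = (-1.2, -0.9, -0.3, 0.0, 0.4, 0.9)
    # signatures
    n_signatures: int = 3
    exposure_truth: tuple[float, ...] = (0.6, 0.3, 0.1)
    n_catalog_mutations: int = 20_000
    # breed panel
    n_breeds: int = 4
    n_refs_per_breed: int = 12
    n_markers: int = 2000
    drift_fst: float = 0.15
    genotype_missingness: float = 0.02
    admixture_truth: tuple[float, ...] = (0.7, 0.3)

    def variant_counts(self) -> dict[str, int]:
        return {
            "somatic_eligible": self.n_somatic_eligible,
            "rescued_somatic": self.n_rescued_somatic,
            "somatic_lowsupport": self.n_somatic_lowsupport,
            "somatic_private_m2": self.n_somatic_private_m2,
            "somatic_private_plat": self.n_somatic_private_plat,
            "germline_pon": self.n_germline_pon,
            "germline_resource": self.n_germline_resource,
            "artifact_m2": self.n_artifact_m2,
            "artifact_plat": self.n_artifact_plat,
            "evidence_leak": self.n_evidence_leak,
        }

    def validate(self) -> None:
        if not (0 <= self.discordant_alt_fraction <= 1):
            raise ValueError("discordant_alt_fraction must be in [0,1]")
        if abs(sum(self.exposure_truth) - 1.0) > 1e-9:
            raise ValueError("exposure_truth must sum to 1")
        if abs(sum(self.admixture_truth) - 1.0) > 1e-9:
            raise ValueError("admixture_truth must sum to 1")
        if len(self.admixture_truth) > self.n_breeds:
            raise ValueError("admixture_truth has more components than breeds")


@dataclass
class PlantedVariant:
    tumor: str
    var_class: str
    chrom: str
    pos: int
    ref: str
    alt: str
    alt_platypus: str | None  # differs for discordant-allele plants
    af: float
    dp: int
    alt_depth: int
    expected_fate: str


@dataclass
class PlantedSv:
    tumor: str
    sv_class: str
    sv_id: str
    sv_type: str
    expected_survives: bool


@dataclass
class CohortTruth:
    variants: list[PlantedVariant] = field(default_factory=list)
    germline_sites_per_normal: dict[str, list[list]] = field(default_factory=dict)
    svs: list[PlantedSv] = field(default_factory=list)
    segment_calls: dict[str, list[dict]] = field(default_factory=dict)
    sex: dict[str, str] = field(default_factory=dict)
    sex_ratio: dict[str, float] = field(default_factory=dict)
    exposures: dict[str, list[float]] = field(default_factory=dict)
    signature_labels: list[str] = field(default_factory=list)
    admixture_q: dict[str, dict[str, float]] = field(default_factory=dict)

    def expected_survivor_sites(self, tumor: str) -> set[SiteKey]:
        return {
            SiteKey(v.chrom, v.pos)
            for v in self.variants
            if v.tumor == tumor and v.expected_fate == "survive"
        }

    def planted_count(self, tumor: str) -> int:
        return sum(1 for v in self.variants if v.tumor == tumor)


# --- low-level helpers -------------------------------------------------------

def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, size=length))


def _other_base(rng: np.random.Generator, ref: str, forbid: str | None = None) -> str:
    choices = [b for b in "ACGT" if b != ref and b != forbid]
    return str(rng.choice(choices))


def synthetic_signatures(
    k: int, seed: int | None = None, rng: np.random.Generator | None = None,
    concentration: float = 0.15,
) -> SignatureCatalog:
    """K random sparse signature profiles over the 96 channels.

    Low Dirichlet concentration yields peaked, well-separated profiles
    resembling real substitution signatures.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    probs = rng.dirichlet(np.full(96, concentration), size=k)
    return SignatureCatalog(probs, [f"SBSsim{i + 1}" for i in range(k)])


def simulate_signature_catalog(
    exposures: Sequence[float],
    signatures: SignatureCatalog,
    n_mutations: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    sample: str = "sample",
) -> MutationCatalog:
    """Multinomial catalog draw from a known signature mixture."""
    if rng is None:
        rng = np.random.default_rng(seed)
    e = np.asarray(exposures, dtype=float)
    if abs(e.sum() - 1.0) > 1e-9 or (e < 0).any():
        raise ValueError("exposures must lie on the simplex")
    p = e @ signatures.probs
    counts = rng.multinomial(n_mutations, p / p.sum())
    return MutationCatalog(counts[:, None], [sample])


def simulate_admixed_genotypes(
    panel_freqs: np.ndarray,
    q: Sequence[float],
    n_markers: int | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    missingness: float = 0.0,
) -> np.ndarray:
    """Dosages ~ Binomial(2, sum_k q_k f_k) per marker, with optional
    missing entries coded -1."""
    if rng is None:
        rng = np.random.default_rng(seed)
    q = np.asarray(q, dtype=float)
    if abs(q.sum() - 1.0) > 1e-9 or (q < 0).any():
        raise ValueError("q must lie on the simplex")
    f = q @ np.asarray(panel_freqs, dtype=float)
    if n_markers is not None:
        f = f[:n_markers]
    g = rng.binomial(2, f).astype(np.int16)
    if missingness > 0:
        g[rng.random(g.shape) < missingness] = -1
    return g


# --- bundle writer -----------------------------------------------------------

class _VcfWriter:
    """Minimal deterministic VCF text emitter for the generator."""

    @staticmethod
    def header(contigs: Sequence[str], filters: Sequence[str], fmt_lines: Sequence[str],
               info_lines: Sequence[str], sample: str) -> str:
        lines = ["##fileformat=VCFv4.2"]
        lines += [f"##contig=<ID={c}>" for c in contigs]
        lines += [f'##FILTER=<ID={f},Description="{f}">' for f in sorted(filters)]
        lines += list(info_lines) + list(fmt_lines)
        cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT"
        lines.append(f"{cols}\t{sample}" if sample else cols[: cols.rfind("\t")])
        return "\n".join(lines) + "\n"


MUTECT2_FORMAT = [
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
    '##FORMAT=<ID=AF,Number=A,Type=Float,Description="Allele fraction">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
]
PLATYPUS_FORMAT = [
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=NR,Number=A,Type=Integer,Description="Reads covering">',
    '##FORMAT=<ID=NV,Number=A,Type=Integer,Description="Reads supporting variant">',
]
MANTA_HEADER_EXTRAS = [
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
    '##INFO=<ID=END,Number=1,Type=Integer,Description="End position">',
    '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">',
    '##INFO=<ID=IMPRECISE,Number=0,Type=Flag,Description="Imprecise">',
    '##INFO=<ID=MATEID,Number=1,Type=String,Description="Mate breakend id">',
]
MANTA_FORMAT = [
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=PR,Number=.,Type=Integer,Description="Paired reads ref,alt">',
    '##FORMAT=<ID=SR,Number=.,Type=Integer,Description="Split reads ref,alt">',
]


@dataclass
class CohortBundle:
    """Paths of every emitted file plus the truth ledger."""

    out_dir: str
    config: CohortConfig
    truth: CohortTruth
    files: dict[str, object] = field(default_factory=dict)

    def path(self, key: str):
        return self.files[key]


def simulate_cohort(
    config: CohortConfig | None = None,
    seed: int = 0,
    out_dir: str | None = None,
) -> CohortBundle:
    """Generate the full fixture bundle under ``out_dir``.

    Same config + same seed produces byte-identical output.
    """
    if config is None:
        config = CohortConfig()
    config.validate()
    if out_dir is None:
        raise ValueError("out_dir is required")
    rng = np.random.default_rng(seed)
    os.makedirs(out_dir, exist_ok=True)
    for sub in ("tumors", "normals", "sv_normals", "resources", "breeds",
                "signatures"):
        os.makedirs(os.path.join(out_dir, sub), exist_ok=True)

    truth = CohortTruth()
    files: dict[str, object] = {}
    contigs = list(config.chrom_lengths)
    autosomes = [c for c in contigs if c != config.x_chrom]

    # reference genome
    reference = {c: _random_sequence(rng, n) for c, n in config.chrom_lengths.items()}
    ref_path = os.path.join(out_dir, "reference.fa")
    with open(ref_path, "w") as fh:
        for c in contigs:
            fh.write(f">{c}\n")
            seq = reference[c]
            for i in range(0, len(seq), 70):
                fh.write(seq[i: i + 70] + "\n")
    files["reference"] = ref_path

    sizes_path = os.path.join(out_dir, "chrom_sizes.tsv")
    with open(sizes_path, "w") as fh:
        for c in contigs:
            fh.write(f"{c}\t{config.chrom_lengths[c]}\n")
    files["chrom_sizes"] = sizes_path

    # position pool: unique positions per chromosome, margin from edges
    def draw_positions(n: int) -> list[tuple[str, int]]:
        out = []
        while len(out) < n:
            c = autosomes[int(rng.integers(len(autosomes)))]
            pos = int(rng.integers(10, config.chrom_lengths[c] - 10))
            if (c, pos) not in used_positions:
                used_positions.add((c, pos))
                out.append((c, pos))
        return out

    used_positions: set[tuple[str, int]] = set()
    normals = [f"normal_{i:02d}" for i in range(config.n_normals)]
    tumors = [f"tumor_{i + 1}" for i in range(config.n_tumors)]

    # support grids straddling the thresholds
    passing_grid = [(0.05, 10, 3), (0.10, 30, 5), (0.25, 60, 15), (0.5, 40, 20)]
    failing_grid = [(0.049, 50, 10), (0.04, 60, 12), (0.5, 9, 4), (0.3, 8, 3),
                    (0.2, 50, 2), (0.04, 9, 2)]

    removed_sites_all: list[tuple[str, int, str, str]] = []
    resource_records: dict[str, list[tuple[str, int, str, str]]] = {
        "germline_reference": [], "broad_snps": [], "axelsson_snps": []
    }
    resource_names = list(resource_records)
    pon_sites_per_normal: dict[str, list[tuple[str, int, str, str]]] = {
        n: [] for n in normals
    }

    tumor_m2: dict[str, list[dict]] = {t: [] for t in tumors}
    tumor_plat: dict[str, list[dict]] = {t: [] for t in tumors}
    snv_evidence: dict[str, list[tuple[str, int, str, int]]] = {t: [] for t in tumors}

    def support(passing: bool) -> tuple[float, int, int]:
        grid = passing_grid if passing else failing_grid
        af, dp, alt = grid[int(rng.integers(len(grid)))]
        return af, dp, alt

    for tumor in tumors:
        counts = config.variant_counts()
        for var_class, n in counts.items():
            for _ in range(n):
                chrom, pos = draw_positions(1)[0]
                ref = reference[chrom][pos - 1]
                alt = _other_base(rng, ref)
                is_indel = False
                if var_class == "germline_resource" and rng.random() < config.indel_fraction:
                    is_indel = True
                    del_len = int(rng.integers(3, 8))
                    ref = reference[chrom][pos - 1: pos - 1 + del_len]
                    alt = ref[0]
                passing = var_class not in ("somatic_lowsupport",)
                af, dp, alt_depth = support(passing)
                alt_plat = alt
                if (
                    var_class == "somatic_eligible"
                    and not is_indel
                    and rng.random() < config.discordant_alt_fraction
                ):
                    alt_plat = _other_base(rng, ref, forbid=alt)

                m2_filters: list[str] = []
                plat_filters: list[str] = []
                in_m2 = var_class != "somatic_private_plat"
                in_plat = var_class not in ("somatic_private_m2", "artifact_m2")
                if var_class == "rescued_somatic":
                    m2_filters, plat_filters = ["germline"], ["alleleBias"]
                elif var_class == "artifact_m2":
                    m2_filters = [str(rng.choice(["weak_evidence", "strand_bias"]))]
                elif var_class == "artifact_plat":
                    plat_filters = ["alleleBias"]

                if var_class == "germline_pon":
                    n_carriers = min(int(rng.integers(1, 6)), config.n_normals)
                    carriers = rng.choice(
                        config.n_normals, size=n_carriers, replace=False
                    )
                    for ci in sorted(carriers):
                        pon_sites_per_normal[normals[ci]].append((chrom, pos, ref, alt))
                if var_class == "germline_resource":
                    res = resource_names[int(rng.integers(len(resource_names)))]
                    r_pos, r_ref, r_alt = pos, ref, alt
                    if is_indel:
                        # caller-shifted indel: same event, offset start
                        r_pos = pos + 2
                        r_ref = reference[chrom][r_pos - 1: r_pos - 1 + len(ref)]
                        r_alt = r_ref[0]
                    elif rng.random() < 0.5:
                        r_alt = _other_base(rng, ref, forbid=alt)  # allele mismatch
                    resource_records[res].append((chrom, r_pos, r_ref, r_alt))
                if var_class == "rescued_somatic":
                    removed_sites_all.append((chrom, pos, ref, alt))

                ev = 1 if var_class == "evidence_leak" else 0
                ev_sample = normals[int(rng.integers(config.n_normals))]
                snv_evidence[tumor].append((chrom, pos, ev_sample, ev))

                if in_m2:
                    tumor_m2[tumor].append(
                        dict(chrom=chrom, pos=pos, ref=ref, alt=alt,
                             filters=m2_filters, af=af, dp=dp, alt_depth=alt_depth)
                    )
                if in_plat:
                    tumor_plat[tumor].append(
                        dict(chrom=chrom, pos=pos, ref=ref, alt=alt_plat,
                             filters=plat_filters, af=af, dp=dp, alt_depth=alt_depth)
                    )
                truth.variants.append(
                    PlantedVariant(
                        tumor, var_class, chrom, pos, ref, alt,
                        alt_plat if alt_plat != alt else None,
                        af, dp, alt_depth, VARIANT_CLASSES[var_class],
                    )
                )

    # normal-private PON sites (never in tumors)
    for normal in normals:
        for _ in range(config.n_normal_private_sites):
            chrom, pos = draw_positions(1)[0]
            ref = reference[chrom][pos - 1]
            pon_sites_per_normal[normal].append((chrom, pos, ref, _other_base(rng, ref)))
        truth.germline_sites_per_normal[normal] = [
            list(x[:2]) for x in pon_sites_per_normal[normal]
        ]

    # --- write SNV VCFs ---
    def write_mutect2(path: str, rows: list[dict], sample: str) -> None:
        filters = {f for r in rows for f in r["filters"]}
        with open(path, "w") as fh:
            fh.write(_VcfWriter.header(contigs, filters, MUTECT2_FORMAT, [], sample))
            for r in sorted(rows, key=lambda r: (r["chrom"], r["pos"], r["alt"])):
                filt = ";".join(sorted(r["filters"])) or "PASS"
                ad = f"{r['dp'] - r['alt_depth']},{r['alt_depth']}"
                fh.write(
                    f"{r['chrom']}\t{r['pos']}\t.\t{r['ref']}\t{r['alt']}\t.\t{filt}\t.\t"
                    f"GT:AD:AF:DP\t0/1:{ad}:{r['af']:.4f}:{r['dp']}\n"
                )

    def write_platypus(path: str, rows: list[dict], sample: str) -> None:
        filters = {f for r in rows for f in r["filters"]}
        with open(path, "w") as fh:
            fh.write(_VcfWriter.header(contigs, filters, PLATYPUS_FORMAT, [], sample))
            for r in sorted(rows, key=lambda r: (r["chrom"], r["pos"], r["alt"])):
                filt = ";".join(sorted(r["filters"])) or "PASS"
                fh.write(
                    f"{r['chrom']}\t{r['pos']}\t.\t{r['ref']}\t{r['alt']}\t.\t{filt}\t.\t"
                    f"GT:NR:NV\t0/1:{r['dp']}:{r['alt_depth']}\n"
                )

    for tumor in tumors:
        tdir = os.path.join(out_dir, "tumors", tumor)
        os.makedirs(tdir, exist_ok=True)
        m2_path = os.path.join(tdir, "mutect2.vcf")
        plat_path = os.path.join(tdir, "platypus.vcf")
        write_mutect2(m2_path, tumor_m2[tumor], tumor)
        write_platypus(plat_path, tumor_plat[tumor], tumor)
        files[f"{tumor}/mutect2"] = m2_path
        files[f"{tumor}/platypus"] = plat_path
        ev_path = os.path.join(tdir, "snv_evidence.tsv")
        with open(ev_path, "w") as fh:
            for chrom, pos, sample, sup in sorted(snv_evidence[tumor]):
                fh.write(f"{chrom}\t{pos}\t{sample}\t{sup}\n")
        files[f"{tumor}/snv_evidence"] = ev_path

    normal_paths = []
    for normal in normals:
        rows = [
            dict(chrom=c, pos=p, ref=ref, alt=alt, filters=[],
                 af=0.5, dp=30, alt_depth=15)
            for c, p, ref, alt in pon_sites_per_normal[normal]
        ]
        path = os.path.join(out_dir, "normals", f"{normal}.platypus.vcf")
        write_platypus(path, rows, normal)
        normal_paths.append(path)
    files["normal_vcfs"] = normal_paths

    for res, recs in resource_records.items():
        path = os.path.join(out_dir, "resources", f"{res}.vcf")
        rows = [dict(chrom=c, pos=p, ref=r, alt=a, filters=[], af=0.5, dp=30,
                     alt_depth=15) for c, p, r, a in recs]
        write_mutect2(path, rows, "RESOURCE")
        files[f"resource/{res}"] = path
    removed_path = os.path.join(out_dir, "resources", "removed_sites.vcf")
    write_mutect2(
        removed_path,
        [dict(chrom=c, pos=p, ref=r, alt=a, filters=[], af=0.5, dp=30, alt_depth=15)
         for c, p, r, a in removed_sites_all],
        "REMOVED",
    )
    files["removed_sites"] = removed_path

    # --- centromeres ---
    centromeres = []
    for c in autosomes:
        mid = config.chrom_lengths[c] // 2
        centromeres.append(GenomicInterval(c, mid - 2500, mid + 2500))
    cen_path = os.path.join(out_dir, "centromeres.bed")
    with open(cen_path, "w") as fh:
        for iv in centromeres:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
    files["centromeres"] = cen_path

    # --- SVs ---
    sv_evidence_rows: dict[str, list[tuple[str, str, int]]] = {t: [] for t in tumors}
    for tumor in tumors:
        sv_rows: list[dict] = []
        germline_sv_per_normal: dict[str, list[dict]] = {n: [] for n in normals}
        counter = 0

        def new_id() -> str:
            nonlocal counter
            counter += 1
            return f"{tumor}_sv{counter:03d}"

        sv_spans: dict[str, list[tuple[int, int]]] = {c: [] for c in autosomes}
        # keep planted SVs far enough apart that merge clusters can never
        # chain two unrelated plants together (max_dist 1000 + normal
        # jitter 200, doubled for safety)
        sv_gap = 2500

        def place_sv(avoid_centromere: bool = True) -> tuple[str, int, int]:
            while True:
                c = autosomes[int(rng.integers(len(autosomes)))]
                length = int(rng.integers(500, 5000))
                start = int(rng.integers(1000, config.chrom_lengths[c] - length - 1000))
                iv = GenomicInterval(c, start - 1, start + length)
                in_cen = any(iv.overlaps(w) for w in centromeres)
                if in_cen != (not avoid_centromere):
                    continue
                lo, hi = start - sv_gap, start + length + sv_gap
                if any(s < hi and lo < e for s, e in sv_spans[c]):
                    continue
                sv_spans[c].append((lo, hi))
                return c, start, length

        def add(sv_class: str, sv_type: str, pr: int, sr: int, imprecise: bool,
                filters: list[str], survives: bool, evidence: int = 0,
                in_centromere: bool = False) -> dict:
            c, start, length = place_sv(avoid_centromere=not in_centromere)
            row = dict(
                sv_id=new_id(), sv_type=sv_type, chrom=c, pos=start,
                end=start + length if sv_type != "INS" else start,
                svlen=(-length if sv_type == "DEL" else length),
                pr=pr, sr=sr, imprecise=imprecise, filters=filters, mate=None,
            )
            sv_rows.append(row)
            truth.svs.append(PlantedSv(tumor, sv_class, row["sv_id"], sv_type, survives))
            ev_sample = normals[int(rng.integers(config.n_normals))]
            sv_evidence_rows[tumor].append((row["sv_id"], ev_sample, evidence))
            return row

        def add_bnd_pair(sv_class: str, pr1: int, sr1: int, pr2: int, sr2: int,
                         survives: tuple[bool, bool]) -> None:
            c1, p1, _ = place_sv()
            c2, p2, _ = place_sv()
            id1, id2 = new_id(), new_id()
            for sid, mid, c, p, oc, op, pr, sr, surv in (
                (id1, id2, c1, p1, c2, p2, pr1, sr1, survives[0]),
                (id2, id1, c2, p2, c1, p1, pr2, sr2, survives[1]),
            ):
                sv_rows.append(dict(
                    sv_id=sid, sv_type="BND", chrom=c, pos=p, end=None,
                    svlen=None, pr=pr, sr=sr, imprecise=False, filters=[],
                    mate=mid, mate_locus=(oc, op),
                ))
                truth.svs.append(PlantedSv(tumor, sv_class, sid, "BND", surv))
                ev_sample = normals[int(rng.integers(config.n_normals))]
                sv_evidence_rows[tumor].append((sid, ev_sample, 0))

        types = ["DEL", "DUP", "INV", "INS"]
        for _ in range(config.n_sv_somatic_pass):
            t = types[int(rng.integers(len(types)))]
            add("somatic_pass", t, int(rng.integers(15, 60)), int(rng.integers(0, 60)),
                False, [], True)
        for _ in range(config.n_sv_bnd_pairs_pass):
            add_bnd_pair("bnd_pass", int(rng.integers(15, 60)), 0,
                         int(rng.integers(15, 60)), 0, (True, True))
        for _ in range(config.n_sv_lowsupport):
            add("sv_lowsupport", types[int(rng.integers(len(types)))], 14, 14,
                False, [], False)
        for _ in range(config.n_sv_imprecise):
            add("sv_imprecise", types[int(rng.integers(len(types)))],
                int(rng.integers(15, 60)), 0, True, [], False)
        for _ in range(config.n_sv_nonpass):
            add("sv_nonpass", types[int(rng.integers(len(types)))],
                int(rng.integers(15, 60)), 0, False, ["MinQUAL"], False)
        for _ in range(config.n_sv_germline):
            row = add("sv_germline", types[int(rng.integers(3))],
                      int(rng.integers(15, 60)), 0, False, [], False)
            n_carriers = min(int(rng.integers(1, 4)), config.n_normals)
            carriers = rng.choice(config.n_normals, size=n_carriers, replace=False)
            for ci in sorted(carriers):
                shift = int(rng.integers(-200, 200))
                germline_sv_per_normal[normals[ci]].append(
                    dict(row, sv_id=f"{normals[ci]}_{row['sv_id']}",
                         pos=row["pos"] + shift,
                         end=(row["end"] + shift) if row["end"] else None)
                )
        for _ in range(config.n_sv_bnd_orphan_pairs):
            add_bnd_pair("bnd_orphan", int(rng.integers(15, 60)), 0, 5, 5,
                         (False, False))
        for _ in range(config.n_sv_evidence_leak):
            row = add("sv_evidence_leak", types[int(rng.integers(len(types)))],
                      int(rng.integers(15, 60)), 0, False, [], False, evidence=1)
            sv_evidence_rows[tumor][-1] = (row["sv_id"],
                                           sv_evidence_rows[tumor][-1][1], 1)
        for _ in range(config.n_sv_centromeric):
            add("sv_centromeric", "DEL", int(rng.integers(15, 60)), 0, False, [],
                True, in_centromere=True)

        def write_sv_vcf(path: str, rows: list[dict], sample: str) -> None:
            filters = {f for r in rows for f in r["filters"]}
            with open(path, "w") as fh:
                fh.write(_VcfWriter.header(contigs, filters, MANTA_FORMAT,
                                           MANTA_HEADER_EXTRAS, sample))
                for r in sorted(rows, key=lambda r: (r["chrom"], r["pos"], r["sv_id"])):
                    filt = ";".join(sorted(r["filters"])) or "PASS"
                    ref = reference[r["chrom"]][r["pos"] - 1]
                    info = [f"SVTYPE={r['sv_type']}"]
                    if r["sv_type"] == "BND":
                        oc, op = r["mate_locus"]
                        alt = f"{ref}[{oc}:{op}["
                        info.append(f"MATEID={r['mate']}")
                    else:
                        alt = f"<{r['sv_type']}>"
                        info.append(f"END={r['end']}")
                        if r["svlen"] is not None:
                            info.append(f"SVLEN={r['svlen']}")
                    if r["imprecise"]:
                        info.append("IMPRECISE")
                    pr = f"0,{r['pr']}"
                    sr = f"0,{r['sr']}"
                    fh.write(
                        f"{r['chrom']}\t{r['pos']}\t{r['sv_id']}\t{ref}\t{alt}\t.\t"
                        f"{filt}\t{';'.join(info)}\tGT:PR:SR\t0/1:{pr}:{sr}\n"
                    )

        tdir = os.path.join(out_dir, "tumors", tumor)
        sv_path = os.path.join(tdir, "sv.vcf")
        write_sv_vcf(sv_path, sv_rows, tumor)
        files[f"{tumor}/sv"] = sv_path
        ev_path = os.path.join(tdir, "sv_evidence.tsv")
        with open(ev_path, "w") as fh:
            for sv_id, sample, sup in sorted(sv_evidence_rows[tumor]):
                fh.write(f"{sv_id}\t{sample}\t{sup}\n")
        files[f"{tumor}/sv_evidence"] = ev_path
        normal_sv_paths = []
        for normal in normals:
            path = os.path.join(out_dir, "sv_normals", f"{normal}.{tumor}.sv.vcf")
            write_sv_vcf(path, germline_sv_per_normal[normal], normal)
            normal_sv_paths.append(path)
        files[f"{tumor}/normal_svs"] = normal_sv_paths

    # --- segments, coverage, GTF ---
    from .cnv import classify_segment

    gtf_path = os.path.join(out_dir, "genes.gtf")
    gene_rows = []
    gid = 0
    for c in autosomes:
        for frac in (0.15, 0.6):
            gid += 1
            start = int(config.chrom_lengths[c] * frac)
            end = start + 3000
            gene_rows.append((c, start + 1, end, f"GENE{gid:02d}"))
    with open(gtf_path, "w") as fh:
        for c, s, e, g in gene_rows:
            attrs = f'gene_id "{g}";'
            fh.write(f"{c}\ttoy\tgene\t{s}\t{e}\t.\t+\t.\t{attrs}\n")
            fh.write(f"{c}\ttoy\tCDS\t{s}\t{s + 900}\t.\t+\t0\t{attrs}\n")
            fh.write(f"{c}\ttoy\tCDS\t{e - 900}\t{e}\t.\t+\t0\t{attrs}\n")
    files["gtf"] = gtf_path

    for ti, tumor in enumerate(tumors):
        tdir = os.path.join(out_dir, "tumors", tumor)
        seg_path = os.path.join(tdir, "segments.seg")
        seg_truth = []
        with open(seg_path, "w") as fh:
            fh.write("CONTIG\tSTART\tEND\tMEAN_LOG2_COPY_RATIO\n")
            ratios = list(config.seg_ratios)
            for c in autosomes:
                L = config.chrom_lengths[c]
                n_seg = len(ratios)
                bounds = np.linspace(1, L, n_seg + 1).astype(int)
                order = rng.permutation(n_seg)
                for k in range(n_seg):
                    ratio = ratios[order[k]]
                    s, e = int(bounds[k]), int(bounds[k + 1] - 1)
                    fh.write(f"{c}\t{s}\t{e}\t{ratio:.4f}\n")
                    seg_truth.append(
                        {"chrom": c, "start": s, "end": e, "log2": ratio,
                         "call": classify_segment(ratio)}
                    )
        truth.segment_calls[tumor] = seg_truth
        files[f"{tumor}/segments"] = seg_path

        ratio = config.sex_ratios[ti % len(config.sex_ratios)]
        cov_path = os.path.join(tdir, "coverage.tsv")
        with open(cov_path, "w") as fh:
            depths = {}
            for c in autosomes:
                d = config.autosome_depth * (1 + 0.02 * rng.standard_normal())
                depths[c] = d
            auto_mean = sum(depths.values()) / len(depths)
            depths[config.x_chrom] = ratio * auto_mean
            for c in contigs:
                fh.write(f"{c}\t{depths[c]:.6f}\n")
        files[f"{tumor}/coverage"] = cov_path
        if 0.3 <= ratio <= 0.7:
            truth.sex[tumor] = "male"
        elif 0.8 <= ratio <= 1.2:
            truth.sex[tumor] = "female"
        else:
            truth.sex[tumor] = "indeterminate"
        truth.sex_ratio[tumor] = ratio

    # --- signatures ---
    sigs = synthetic_signatures(config.n_signatures, rng=rng)
    truth.signature_labels = list(sigs.labels)
    sig_path = os.path.join(out_dir, "signatures", "signatures.tsv")
    with open(sig_path, "w") as fh:
        fh.write("Type\t" + "\t".join(sigs.labels) + "\n")
        for j, ch in enumerate(CHANNELS):
            fh.write(ch + "\t" + "\t".join(f"{sigs.probs[k, j]:.8e}"
                                           for k in range(len(sigs.labels))) + "\n")
    files["signatures"] = sig_path
    opp = rng.uniform(0.5, 2.0, size=96)
    opp_path = os.path.join(out_dir, "signatures", "opportunities.tsv")
    with open(opp_path, "w") as fh:
        for ch, w in zip(CHANNELS, opp):
            fh.write(f"{ch}\t{w:.8f}\n")
    files["opportunities"] = opp_path
    cat_path = os.path.join(out_dir, "signatures", "catalog.tsv")
    columns = {}
    for tumor in tumors:
        cat = simulate_signature_catalog(
            config.exposure_truth, sigs, config.n_catalog_mutations,
            rng=rng, sample=tumor,
        )
        columns[tumor] = cat.counts[:, 0]
        truth.exposures[tumor] = list(config.exposure_truth)
    with open(cat_path, "w") as fh:
        fh.write("Type\t" + "\t".join(tumors) + "\n")
        for j, ch in enumerate(CHANNELS):
            fh.write(ch + "\t" + "\t".join(str(int(columns[t][j]))
                                           for t in tumors) + "\n")
    files["catalog"] = cat_path

    # --- breed panel ---
    ancestral = rng.uniform(0.05, 0.95, size=config.n_markers)
    F = config.drift_fst
    a, b = ancestral * (1 - F) / F, (1 - ancestral) * (1 - F) / F
    breed_freqs = np.vstack(
        [rng.beta(a, b) for _ in range(config.n_breeds)]
    )
    breeds = [f"Breed{chr(ord('A') + i)}" for i in range(config.n_breeds)]
    marker_pos = np.sort(rng.choice(
        np.arange(1000, 10_000_000), size=config.n_markers, replace=False))
    geno_rows, sample_ids, labels = [], [], {}
    for bi, breed in enumerate(breeds):
        for ri in range(config.n_refs_per_breed):
            sid = f"{breed}_ref{ri:02d}"
            sample_ids.append(sid)
            labels[sid] = breed
            g = rng.binomial(2, breed_freqs[bi]).astype(np.int16)
            g[rng.random(config.n_markers) < config.genotype_missingness] = -1
            geno_rows.append(g)
    # query samples: one per tumor; first pure breed A, second admixed
    q_truths = []
    for ti, tumor in enumerate(tumors):
        if ti == 0:
            q = np.zeros(config.n_breeds)
            q[0] = 1.0
        else:
            q = np.zeros(config.n_breeds)
            for k, w in enumerate(config.admixture_truth):
                q[k] = w
        q_truths.append(q)
        sample_ids.append(tumor)
        g = simulate_admixed_genotypes(
            breed_freqs, q, rng=rng, missingness=config.genotype_missingness
        )
        geno_rows.append(g)
        truth.admixture_q[tumor] = {b: float(q[k]) for k, b in enumerate(breeds)}
    geno_path = os.path.join(out_dir, "breeds", "genotypes.tsv")
    with open(geno_path, "w") as fh:
        fh.write("sample\t" + "\t".join(f"chr1:{p}" for p in marker_pos) + "\n")
        for sid, g in zip(sample_ids, geno_rows):
            fh.write(sid + "\t" + "\t".join(str(int(x)) for x in g) + "\n")
    files["genotypes"] = geno_path
    labels_path = os.path.join(out_dir, "breeds", "labels.tsv")
    with open(labels_path, "w") as fh:
        for sid, breed in labels.items():
            fh.write(f"{sid}\t{breed}\n")
    files["labels"] = labels_path
    files["breed_freqs"] = breed_freqs
    files["marker_positions"] = marker_pos

    # --- manifest ---
    manifest = {
        "seed": seed,
        "n_tumors": config.n_tumors,
        "n_normals": config.n_normals,
        "planted_variants": len(truth.variants),
        "planted_svs": len(truth.svs),
        "files": {k: v for k, v in files.items()
                  if isinstance(v, (str, list)) and k not in ("breed_freqs",)},
    }
    man_path = os.path.join(out_dir, "manifest.json")
    with open(man_path, "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    files["manifest"] = man_path

    return CohortBundle(out_dir, config, truth, files)


def read_genotype_tsv(path: str, labels_path: str | None = None):
    """Read the generator's genotype table into a GenotypeMatrix."""
    from .ancestry import GenotypeMatrix

    with open(path) as fh:
        header = fh.readline().strip().split("\t")[1:]
        sample_ids, rows = [], []
        for line in fh:
            fields = line.strip().split("\t")
            sample_ids.append(fields[0])
            rows.append([int(x) for x in fields[1:]])
    chroms = np.array([m.split(":")[0] for m in header])
    positions = np.array([int(m.split(":")[1]) for m in header])
    labels = {}
    if labels_path:
        with open(labels_path) as fh:
            for line in fh:
                sid, breed = line.strip().split("\t")
                labels[sid] = breed
    return GenotypeMatrix(np.array(rows, dtype=np.int16), positions, chroms,
                          sample_ids, labels)
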