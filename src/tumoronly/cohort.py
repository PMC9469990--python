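"""Convenience runners wiring a generated cohort bundle into the pipelines.

These load the emitted files back through the package's own readers and
execute the SNV and SV filtering stages exactly as a user would from the
command line, so end-to-end truth-recovery checks exercise the full
file-to-result path.
"""

from __future__ import annotations

from .simulate import CohortBundle
from .snv_filter import (
    NormalEvidenceTable,
    SnvPipelineConfig,
    SnvPipelineResult,
    run_snv_pipeline,
)
from .sv import SvEvidenceTable, SvPipelineResult, read_sv_vcf, run_sv_pipeline
from .intervals import read_bed
from .variants import read_vcf, site_set


def run_snv_for_tumor(bundle: CohortBundle, tumor: str) -> SnvPipelineResult:
    m2 = read_vcf(bundle.path(f"{tumor}/mutect2"), "mutect2")
    plat = read_vcf(bundle.path(f"{tumor}/platypus"), "platypus")
    normals = [read_vcf(p, "platypus") for p in bundle.path("normal_vcfs")]
    resources = {
        key.split("/", 1)[1]: read_vcf(bundle.path(key), "generic")
        for key in bundle.files
        if key.startswith("resource/")
    }
    removed = site_set(read_vcf(bundle.path("removed_sites"), "generic"))
    evidence = NormalEvidenceTable.from_tsv(bundle.path(f"{tumor}/snv_evidence"))
    config = SnvPipelineConfig(
        mutect2_records=m2,
        platypus_records=plat,
        normal_callsets=normals,
        germline_resources=resources,
        removed_sites=removed,
        evidence=evidence,
        contig_allowlist=frozenset(bundle.config.chrom_lengths),
    )
    return run_snv_pipeline(config)


def run_sv_for_tumor(
    bundle: CohortBundle, tumor: str, exclude_centromeric: bool = False
) -> SvPipelineResult:
    svs = read_sv_vcf(bundle.path(f"{tumor}/sv"))
    normals = [read_sv_vcf(p) for p in bundle.path(f"{tumor}/normal_svs")]
    centromeres = read_bed(bundle.path("centromeres"))
    evidence = SvEvidenceTable.from_tsv(bundle.path(f"{tumor}/sv_evidence"))
    return run_sv_pipeline(
        svs, normals, centromeres, evidence, exclude_centromeric=exclude_centromeric
    )
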