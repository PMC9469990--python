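"""Gene models from GTF/GFF3 annotations (gene bodies and CDS intervals)."""

from __future__ import annotations

from dataclasses import dataclass, field

import gffutils

from .intervals import GenomicInterval, IntervalIndex, merge_intervals


@dataclass
class GeneModel:
    """One gene: its body interval and (possibly unmerged) CDS intervals.

    Queries behave as if CDS intervals were merged; ``merged_cds`` caches
    that view.
    """

    gene_id: str
    body: GenomicInterval
    cds: list[GenomicInterval] = field(default_factory=list)

    def merged_cds(self) -> list[GenomicInterval]:
        return merge_intervals(self.cds) if self.cds else []

    def cds_length(self) -> int:
        return sum(len(iv) for iv in self.merged_cds())


@dataclass
class GeneSet:
    """All genes of an annotation plus overlap indexes."""

    genes: dict[str, GeneModel]

    def __post_init__(self) -> None:
        self._body_index = IntervalIndex()
        self._body_lookup: dict[GenomicInterval, list[str]] = {}
        self._cds_index = IntervalIndex()
        for g in self.genes.values():
            self._body_index.add(g.body)
            self._body_lookup.setdefault(g.body, []).append(g.gene_id)
            for iv in g.merged_cds():
                self._cds_index.add(iv)

    def genes_overlapping(self, query: GenomicInterval) -> list[GeneModel]:
        hits: list[GeneModel] = []
        seen: set[str] = set()
        for body in self._body_index.overlapping(query):
            for gid in self._body_lookup[body]:
                if gid not in seen:
                    seen.add(gid)
                    hits.append(self.genes[gid])
        return hits

    def in_cds(self, query: GenomicInterval) -> bool:
        return self._cds_index.any_overlap(query)

    def all_cds(self) -> list[GenomicInterval]:
        return merge_intervals(
            [iv for g in self.genes.values() for iv in g.merged_cds()]
        )


def read_gtf(path: str) -> GeneSet:
    """Load gene and CDS features from a GTF/GFF3 file.

    GTF coordinates are 1-based closed; they are converted to the internal
    0-based half-open convention here.  Genes lacking an explicit ``gene``
    feature get a body spanning their CDS extent.
    """
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    bodies: dict[str, GenomicInterval] = {}
    cds: dict[str, list[GenomicInterval]] = {}
    for feat in db.all_features():
        gid = feat.attributes.get("gene_id", [feat.id])[0]
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end)
        if feat.featuretype == "gene":
            bodies[gid] = iv
        elif feat.featuretype == "CDS":
            cds.setdefault(gid, []).append(iv)
    genes: dict[str, GeneModel] = {}
    for gid in set(bodies) | set(cds):
        ivs = cds.get(gid, [])
        body = bodies.get(gid)
        if body is None:
            body = GenomicInterval(
                ivs[0].chrom, min(v.start for v in ivs), max(v.end for v in ivs)
            )
        genes[gid] = GeneModel(gid, body, ivs)
    return GeneSet(genes)
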