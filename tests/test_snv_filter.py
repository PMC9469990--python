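"""The eight-step tumor-only SNV/indel consensus filter."""

import numpy as np
import pytest

from tumoronly.snv_filter import (
    FilterAudit,
    NormalEvidenceTable,
    apply_support_thresholds,
    build_site_pon,
    consensus_intersect,
    drop_non_pass,
    regenotype_screen,
    remove_sites,
    rescue_flag,
)
from tumoronly.variants import SiteKey, VariantRecord, site_set


def rec(pos, alt="T", flags=(), af=0.3, dp=40, alt_depth=12, chrom="chr1",
        ref="A", sample="t1"):
    return VariantRecord(chrom, pos, ref, alt, frozenset(flags),
                         sample_af=af, sample_dp=dp, sample_alt_depth=alt_depth,
                         sample=sample)


class TestRescue:
    def test_germline_only_flag_at_removed_site_becomes_passing(self):
        r = rec(100, flags=("germline",))
        (out,) = rescue_flag([r], {SiteKey("chr1", 100)}, "germline")
        assert out.passing

    def test_extra_flag_blocks_rescue(self):
        r = rec(100, flags=("germline", "weak_evidence"))
        (out,) = rescue_flag([r], {SiteKey("chr1", 100)}, "germline")
        assert out.filter_flags == {"germline", "weak_evidence"}

    def test_non_removed_site_is_untouched(self):
        r = rec(100, flags=("germline",))
        (out,) = rescue_flag([r], {SiteKey("chr1", 999)}, "germline")
        assert out.filter_flags == {"germline"}


class TestPanelOfNormals:
    def test_shared_site_appears_once(self):
        pon = build_site_pon([[rec(100, sample="n1")], [rec(100, sample="n2")]])
        assert len(pon) == 1

    def test_different_alleles_at_one_position_collapse(self):
        pon = build_site_pon([[rec(100, alt="T")], [rec(100, alt="G")]])
        assert len(pon) == 1
        assert SiteKey("chr1", 100) in pon

    def test_empty_panel_is_an_error(self):
        with pytest.raises(ValueError):
            build_site_pon([])


class TestRemoveSites:
    def test_allele_mismatch_still_removes(self):
        out = remove_sites([rec(100, alt="G")], {SiteKey("chr1", 100)})
        assert out == []

    def test_absent_site_is_kept(self):
        out = remove_sites([rec(100)], {SiteKey("chr1", 999)})
        assert len(out) == 1

    def test_removal_is_idempotent(self):
        records = [rec(p) for p in (100, 200, 300)]
        sites = {SiteKey("chr1", 200)}
        once = remove_sites(records, sites)
        assert remove_sites(once, sites) == once

    def test_shifted_indel_removed_by_footprint_overlap(self):
        from tumoronly.intervals import IntervalIndex
        tumor_indel = rec(100, ref="ACGTAC", alt="A")
        resource_indel = VariantRecord("chr1", 103, "TACGT", "T")
        idx = IntervalIndex([resource_indel.footprint()])
        out = remove_sites([tumor_indel], set(), indel_footprints=idx)
        assert out == []


class TestNonPassAndConsensus:
    def test_only_empty_filter_sets_survive(self):
        out = drop_non_pass([rec(1), rec(2, flags=("alleleBias",))])
        assert [r.pos for r in out] == [1]

    def test_rescued_record_survives_non_pass_removal(self):
        r = rec(100, flags=("germline",))
        rescued = rescue_flag([r], {SiteKey("chr1", 100)}, "germline")
        assert len(drop_non_pass(rescued)) == 1

    def test_consensus_keeps_position_matches_regardless_of_allele(self):
        a = [rec(100, alt="T")]
        b = [rec(100, alt="G")]
        out = consensus_intersect(a, b)
        assert len(out) == 1 and out[0].alt == "T"  # primary caller's allele

    def test_private_variant_dropped(self):
        assert consensus_intersect([rec(100)], [rec(200)]) == []

    def test_sample_mismatch_is_an_error(self):
        with pytest.raises(ValueError):
            consensus_intersect([rec(1, sample="t1")], [rec(1, sample="t2")])

    def test_consensus_equals_set_intersection_on_random_input(self):
        rng = np.random.default_rng(5)
        a = [rec(int(p)) for p in rng.choice(2000, 400, replace=False)]
        b = [rec(int(p)) for p in rng.choice(2000, 400, replace=False)]
        out = consensus_intersect(a, b)
        assert site_set(out) == site_set(a) & site_set(b)


class TestSupportThresholds:
    @pytest.mark.parametrize(
        "af,dp,alt,kept",
        [
            (0.05, 10, 3, True),   # boundary inclusive on the keep side
            (0.04, 50, 2, False),
            (0.049, 50, 10, False),
            (0.5, 9, 4, False),
            (0.5, 10, 2, False),
            (0.2, 30, 3, True),
        ],
    )
    def test_threshold_boundaries(self, af, dp, alt, kept):
        out = apply_support_thresholds([rec(1, af=af, dp=dp, alt_depth=alt)])
        assert bool(out) is kept

    def test_unsupported_record_is_removed(self):
        r = VariantRecord("chr1", 1, "A", "T")
        assert apply_support_thresholds([r]) == []

    def test_af_derived_from_depths_when_field_missing(self):
        r = VariantRecord("chr1", 1, "A", "T", sample_dp=100, sample_alt_depth=10)
        assert len(apply_support_thresholds([r])) == 1


class TestRegenotypeScreen:
    def test_support_in_one_normal_removes(self):
        ev = NormalEvidenceTable({SiteKey("chr1", 1): {"n1": True, "n2": False}})
        assert regenotype_screen([rec(1)], ev) == []

    def test_no_support_keeps(self):
        ev = NormalEvidenceTable({SiteKey("chr1", 1): {"n1": False}})
        assert len(regenotype_screen([rec(1)], ev)) == 1

    def test_missing_evidence_is_an_error_never_a_keep(self):
        ev = NormalEvidenceTable({})
        with pytest.raises(KeyError):
            regenotype_screen([rec(1)], ev)


class TestAuditAndOrdering:
    def test_audit_chain_conserves_counts(self):
        audit = FilterAudit()
        records = [rec(p) for p in range(1, 21)] + [
            rec(p, flags=("x",)) for p in range(21, 31)
        ]
        out = drop_non_pass(records, audit, "a")
        out = remove_sites(out, {SiteKey("chr1", 1)}, audit, "b")
        apply_support_thresholds(out, audit=audit, label="c")
        audit.validate_chain()
        for step in audit.steps:
            assert step.n_in == step.n_removed + step.n_out

    def test_germline_and_support_steps_commute(self):
        records = [rec(p, af=0.04 if p % 2 else 0.3) for p in range(1, 40)]
        sites = {SiteKey("chr1", p) for p in range(1, 40, 5)}
        ab = apply_support_thresholds(remove_sites(records, sites))
        ba = remove_sites(apply_support_thresholds(records), sites)
        assert ab == ba

    def test_rescue_must_precede_non_pass_removal(self):
        # rescue-then-drop keeps the record; drop-then-rescue loses it
        r = rec(100, flags=("germline",))
        removed = {SiteKey("chr1", 100)}
        keep_order = drop_non_pass(rescue_flag([r], removed, "germline"))
        wrong_order = rescue_flag(drop_non_pass([r]), removed, "germline")
        assert len(keep_order) == 1
        assert wrong_order == []

    def test_resource_allele_permutation_never_changes_output(self):
        records = [rec(p) for p in range(1, 30)]
        resource_t = [rec(p, alt="T") for p in range(1, 30, 3)]
        resource_g = [rec(p, alt="G") for p in range(1, 30, 3)]
        assert remove_sites(records, site_set(resource_t)) == remove_sites(
            records, site_set(resource_g)
        )
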