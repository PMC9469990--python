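"""SBS96 catalogs, opportunity adjustment, and exposure refitting."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from tumoronly.signatures import (
    CHANNELS,
    MutationCatalog,
    SignatureCatalog,
    adjust_for_opportunities,
    build_catalog,
    channel_of,
    fit_exposures,
    select_and_refit,
)
from tumoronly.simulate import simulate_signature_catalog, synthetic_signatures
from tumoronly.variants import VariantRecord


class TestChannels:
    def test_96_unique_channels_in_substitution_major_order(self):
        assert len(CHANNELS) == 96
        assert len(set(CHANNELS)) == 96
        assert CHANNELS[0] == "A[C>A]A"
        assert CHANNELS[-1] == "T[T>G]T"

    def test_pyrimidine_context_maps_directly(self):
        assert channel_of("C", "T", "A", "G") == "A[C>T]G"

    def test_purine_reference_reverse_complements(self):
        # G>A at 5'-CGT-3' is C>T at A_G on the opposite strand
        assert channel_of("G", "A", "C", "T") == "A[C>T]G"

    def test_non_acgt_context_is_rejected(self):
        assert channel_of("C", "T", "N", "G") is None


class TestBuildCatalog:
    def test_counts_and_skips_conserve_input(self):
        ref = {"chr1": "ACGTACGTAC"}
        snvs = [
            VariantRecord("chr1", 2, "C", "T"),   # context A C G
            VariantRecord("chr1", 3, "G", "A"),   # purine: collapses
            VariantRecord("chr1", 1, "A", "T"),   # contig edge -> skipped
            VariantRecord("chr1", 5, "ACG", "A"),  # indel -> skipped
        ]
        cat = build_catalog({"s": snvs}, ref)
        assert cat.counts.sum() == 2
        assert cat.n_skipped["s"] == 2
        # both SNVs are the same event on opposite strands -> one channel
        assert cat.counts[CHANNELS.index("A[C>T]G"), 0] == 2

    def test_strand_collapse_merges_complementary_mutations(self):
        ref = {"chr1": "TACGT"}
        # C>T at pos 3 (context ACG); G>A at pos 4 = C>T at CGT revcomp -> A[C>T]G? no
        snvs = [VariantRecord("chr1", 3, "C", "T")]
        cat = build_catalog({"s": snvs}, ref)
        assert cat.counts[CHANNELS.index("A[C>T]G"), 0] == 1


class TestOpportunities:
    def test_uniform_opportunities_change_nothing(self):
        sigs = synthetic_signatures(3, seed=1)
        adj = adjust_for_opportunities(sigs, np.ones(96))
        np.testing.assert_allclose(adj.probs, sigs.probs)

    def test_zero_opportunity_zeroes_the_channel(self):
        sigs = synthetic_signatures(2, seed=2)
        opp = np.ones(96)
        opp[10] = 0.0
        adj = adjust_for_opportunities(sigs, opp)
        assert (adj.probs[:, 10] == 0).all()

    def test_scale_invariance(self):
        sigs = synthetic_signatures(2, seed=3)
        opp = np.random.default_rng(0).uniform(0.5, 2.0, 96)
        a = adjust_for_opportunities(sigs, opp)
        b = adjust_for_opportunities(sigs, 2.0 * opp)
        np.testing.assert_allclose(a.probs, b.probs)

    def test_round_trip_through_inverse_opportunities(self):
        sigs = synthetic_signatures(3, seed=4)
        opp = np.random.default_rng(1).uniform(0.2, 5.0, 96)
        back = adjust_for_opportunities(adjust_for_opportunities(sigs, opp), 1.0 / opp)
        np.testing.assert_allclose(back.probs, sigs.probs, atol=1e-10)


class TestFitExposures:
    def test_single_signature_catalog_recovers_exposure_one(self):
        sigs = synthetic_signatures(3, seed=5)
        cat = simulate_signature_catalog([1.0, 0.0, 0.0], sigs, 5000, seed=6)
        est = fit_exposures(cat, sigs, n_boot=30, seed=7)
        assert est.exposures.iloc[0, 0] > 0.98

    def test_orthogonal_mixture_recovered_within_tolerance(self):
        # disjoint-support signatures: exact identifiability
        probs = np.zeros((2, 96))
        probs[0, :48] = 1 / 48
        probs[1, 48:] = 1 / 48
        sigs = SignatureCatalog(probs, ["a", "b"])
        cat = simulate_signature_catalog([0.6, 0.4], sigs, 10_000, seed=8)
        est = fit_exposures(cat, sigs, n_boot=30, seed=9)
        assert abs(est.exposures.iloc[0, 0] - 0.6) <= 0.02
        assert abs(est.exposures.iloc[0, 1] - 0.4) <= 0.02

    def test_exposures_form_a_simplex_with_ordered_intervals(self):
        sigs = synthetic_signatures(4, seed=10)
        cat = simulate_signature_catalog([0.4, 0.3, 0.2, 0.1], sigs, 8000, seed=11)
        est = fit_exposures(cat, sigs, n_boot=40, seed=12)
        assert est.exposures.iloc[0].sum() == pytest.approx(1.0)
        assert (est.lower.values <= est.exposures.values + 1e-12).all()
        assert (est.exposures.values <= est.upper.values + 1e-12).all()

    def test_em_matches_direct_numerical_maximizer(self):
        rng = np.random.default_rng(14)
        sigs = synthetic_signatures(3, rng=rng, concentration=0.5)
        cat = simulate_signature_catalog([0.5, 0.3, 0.2], sigs, 3000, rng=rng)
        est = fit_exposures(cat, sigs, n_boot=2, seed=15)
        counts = cat.counts[:, 0].astype(float)

        def neg_ll(x):
            e = np.abs(x) / np.abs(x).sum()
            p = np.maximum(e @ sigs.probs, 1e-300)
            return -(counts @ np.log(p))

        best = min(
            (minimize(neg_ll, x0, method="Nelder-Mead",
                      options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
             for x0 in ([1, 1, 1], [3, 1, 1], [1, 3, 1])),
            key=lambda r: r.fun,
        )
        e_direct = np.abs(best.x) / np.abs(best.x).sum()
        np.testing.assert_allclose(est.exposures.iloc[0].to_numpy(), e_direct, atol=1e-4)

    def test_zero_mutation_sample_is_an_error(self):
        sigs = synthetic_signatures(2, seed=16)
        cat = MutationCatalog(np.zeros((96, 1), dtype=int), ["empty"])
        with pytest.raises(ValueError):
            fit_exposures(cat, sigs, n_boot=2, seed=17)


class TestSelectAndRefit:
    def test_true_zero_signature_dropped_and_actives_retained(self):
        rng = np.random.default_rng(18)
        sigs = synthetic_signatures(4, rng=rng)
        cat = simulate_signature_catalog([0.5, 0.5, 0.0, 0.0], sigs, 20_000, rng=rng)
        est = fit_exposures(cat, sigs, n_boot=60, rng=rng)
        refit, retained = select_and_refit(est, cat, sigs, n_boot=60, rng=rng)
        assert set(retained) == {"SBSsim1", "SBSsim2"}
        assert refit.exposures.iloc[0].sum() == pytest.approx(1.0)

    def test_high_exposure_in_a_single_sample_suffices(self):
        rng = np.random.default_rng(19)
        sigs = synthetic_signatures(3, rng=rng)
        cat1 = simulate_signature_catalog([1.0, 0.0, 0.0], sigs, 10_000, rng=rng,
                                          sample="s1")
        cat2 = simulate_signature_catalog([0.5, 0.0, 0.5], sigs, 10_000, rng=rng,
                                          sample="s2")
        counts = np.hstack([cat1.counts, cat2.counts])
        cat = MutationCatalog(counts, ["s1", "s2"])
        est = fit_exposures(cat, sigs, n_boot=60, rng=rng)
        _, retained = select_and_refit(est, cat, sigs, n_boot=60, rng=rng)
        assert "SBSsim3" in retained  # active only in s2
        assert "SBSsim2" not in retained

    def test_empty_retained_set_is_an_error(self):
        sigs = synthetic_signatures(2, seed=20)
        cat = simulate_signature_catalog([0.5, 0.5], sigs, 1000, seed=21)
        est = fit_exposures(cat, sigs, n_boot=10, seed=22)
        with pytest.raises(ValueError):
            select_and_refit(est, cat, sigs, floor=1.1, n_boot=10, seed=23)
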