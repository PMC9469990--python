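"""Hudson FST, marker selection, LD pruning, and supervised ancestry."""

import numpy as np
import pandas as pd
import pytest

from tumoronly.ancestry import (
    MISSING,
    AlleleFrequencyPanel,
    GenotypeMatrix,
    _pairwise_r2,
    consensus_breed,
    hudson_fst,
    ld_prune,
    select_markers,
    supervised_ancestry,
)
from tumoronly.simulate import simulate_admixed_genotypes


def drifted_panel(rng, k=2, m=2000, fst=0.15):
    anc = rng.uniform(0.05, 0.95, m)
    a, b = anc * (1 - fst) / fst, (1 - anc) * (1 - fst) / fst
    return np.vstack([rng.beta(a, b) for _ in range(k)])


class TestHudsonFst:
    def test_fixed_difference_is_exactly_one(self):
        assert hudson_fst(1.0, 50, 0.0, 50) == pytest.approx(1.0)

    def test_identical_frequencies_near_zero(self):
        assert hudson_fst(0.5, 10_000, 0.5, 10_000) <= 0.0

    def test_hand_computed_example(self):
        # p1=0.8, p2=0.2, n1=n2=10:
        # num = 0.36 - 0.16/9 - 0.16/9 = 0.324444..., den = 0.68
        est = hudson_fst(0.8, 10, 0.2, 10)
        assert est == pytest.approx(0.3244444444 / 0.68, abs=1e-9)
        assert est == pytest.approx(0.4771, abs=1e-4)

    def test_monotone_in_frequency_difference(self):
        base = 0.5
        values = [hudson_fst(base + d, 100, base - d, 100) for d in
                  (0.05, 0.15, 0.25, 0.35, 0.45)]
        assert values == sorted(values)

    def test_same_allele_monomorphic_is_nan(self):
        assert np.isnan(hudson_fst(0.0, 10, 0.0, 10))

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            hudson_fst(0.5, 1, 0.5, 10)

    def test_agrees_with_heterozygosity_formulation(self):
        """Oracle: the equivalent 1 - Hw/Hb form, where Hw is the mean
        bias-corrected within-population heterozygosity and Hb the
        between-population heterozygosity."""
        rng = np.random.default_rng(0)
        p1 = rng.uniform(0.01, 0.99, 200)
        p2 = rng.uniform(0.01, 0.99, 200)
        n1, n2 = 24, 36
        hw = (2 * p1 * (1 - p1) * n1 / (n1 - 1) + 2 * p2 * (1 - p2) * n2 / (n2 - 1)) / 2
        hb = p1 * (1 - p2) + p2 * (1 - p1)
        np.testing.assert_allclose(hudson_fst(p1, n1, p2, n2), 1 - hw / hb, atol=1e-12)


def matrix(dosages, labels=None, positions=None, chrom="chr1"):
    d = np.asarray(dosages, dtype=np.int16)
    n, m = d.shape
    return GenotypeMatrix(
        d,
        np.asarray(positions if positions is not None else np.arange(m) * 100),
        np.array([chrom] * m),
        [f"s{i}" for i in range(n)],
        labels or {},
    )


class TestSelectMarkers:
    def test_high_missingness_snp_excluded(self):
        rng = np.random.default_rng(1)
        d = rng.binomial(2, 0.5, size=(40, 5)).astype(np.int16)
        d[:20, 0] = 2  # breed-informative SNP 0 ...
        d[20:, 0] = 0
        d[:5, 0] = MISSING  # ... but 12.5% missing
        labels = {f"s{i}": ("A" if i < 20 else "B") for i in range(40)}
        sel = select_markers(matrix(d, labels), max_missing=0.10)
        assert 0 not in sel

    def test_fixed_difference_marker_selected(self):
        d = np.zeros((40, 3), dtype=np.int16)
        d[:20, 1] = 2  # SNP 1 fixed-different between breeds
        labels = {f"s{i}": ("A" if i < 20 else "B") for i in range(40)}
        sel = select_markers(matrix(d, labels))
        assert list(sel) == [1]

    def test_single_breed_is_an_error(self):
        d = np.zeros((10, 3), dtype=np.int16)
        labels = {f"s{i}": "A" for i in range(10)}
        with pytest.raises(ValueError):
            select_markers(matrix(d, labels))

    def test_selection_matches_naive_recount(self):
        rng = np.random.default_rng(2)
        freqs = drifted_panel(rng, k=3, m=200, fst=0.2)
        rows, labels = [], {}
        for bi, breed in enumerate("ABC"):
            for ri in range(15):
                sid = f"s{len(rows)}"
                labels[sid] = breed
                rows.append(rng.binomial(2, freqs[bi]).astype(np.int16))
        g = matrix(np.vstack(rows), labels)
        sel = set(select_markers(g, fst_thresh=0.15))
        # naive one-vs-rest recount
        d = g.dosages
        breeds = np.array([labels[s] for s in g.sample_ids])
        expected = set()
        for j in range(g.n_snps):
            col = d[:, j]
            for breed in "ABC":
                a = col[breeds == breed]
                b = col[breeds != breed]
                p1, p2 = a.mean() / 2, b.mean() / 2
                f = hudson_fst(p1, len(a), p2, len(b))
                if not np.isnan(f) and f > 0.15:
                    expected.add(j)
                    break
        assert sel == expected


class TestLdPrune:
    def test_duplicated_snp_loses_one_copy(self):
        rng = np.random.default_rng(3)
        col = rng.binomial(2, 0.5, 60).astype(np.int16)
        d = np.stack([col, col], axis=1)
        kept = ld_prune(matrix(d, positions=[100, 200]))
        assert len(kept) == 1

    def test_pair_below_threshold_both_kept(self):
        rng = np.random.default_rng(4)
        a = rng.binomial(2, 0.5, 500).astype(np.int16)
        b = rng.binomial(2, 0.5, 500).astype(np.int16)
        assert _pairwise_r2(a, b) < 0.5
        kept = ld_prune(matrix(np.stack([a, b], axis=1), positions=[100, 200]))
        assert len(kept) == 2

    def test_snps_in_different_windows_never_compared(self):
        col = np.tile(np.array([0, 1, 2], dtype=np.int16), 20)
        d = np.stack([col, col], axis=1)
        kept = ld_prune(matrix(d, positions=[100, 60_000]), window_bp=50_000)
        assert len(kept) == 2

    def test_no_retained_within_window_pair_exceeds_threshold(self):
        rng = np.random.default_rng(5)
        m = 40
        base = rng.binomial(2, 0.5, size=(80, m)).astype(np.int16)
        # make some columns near-copies of neighbours
        for j in range(1, m, 3):
            base[:, j] = base[:, j - 1]
            flip = rng.random(80) < 0.05
            base[flip, j] = rng.binomial(2, 0.5, flip.sum())
        g = matrix(base, positions=rng.choice(200_000, m, replace=False))
        kept = ld_prune(g, window_bp=50_000, r2_thresh=0.5)
        for ai in range(len(kept)):
            for bi in range(ai + 1, len(kept)):
                a, b = kept[ai], kept[bi]
                same_window = (
                    g.positions[a] // 50_000 == g.positions[b] // 50_000
                )
                if same_window:
                    assert _pairwise_r2(g.dosages[:, a], g.dosages[:, b]) <= 0.5


class TestSupervisedAncestry:
    def test_pure_breed_query_recovers_dominant_fraction(self):
        rng = np.random.default_rng(6)
        freqs = drifted_panel(rng, k=3, m=5000)
        g = simulate_admixed_genotypes(freqs, [1.0, 0.0, 0.0], rng=rng)
        panel = AlleleFrequencyPanel(freqs, ["A", "B", "C"], np.array([50] * 3))
        res = supervised_ancestry(g, panel)
        assert res.q.iloc[0, 0] >= 0.95

    def test_two_way_admixture_recovered_within_tolerance(self):
        rng = np.random.default_rng(7)
        freqs = drifted_panel(rng, k=2, m=5000)
        g = simulate_admixed_genotypes(freqs, [0.7, 0.3], rng=rng)
        panel = AlleleFrequencyPanel(freqs, ["A", "B"], np.array([50, 50]))
        res = supervised_ancestry(g, panel)
        assert abs(res.q.iloc[0, 0] - 0.7) <= 0.03

    def test_em_matches_grid_search_oracle_on_k2_toys(self):
        rng = np.random.default_rng(8)
        for trial in range(3):
            freqs = drifted_panel(rng, k=2, m=600)
            q_true = rng.uniform(0.2, 0.8)
            g = simulate_admixed_genotypes(freqs, [q_true, 1 - q_true], rng=rng)
            panel = AlleleFrequencyPanel(freqs, ["A", "B"], np.array([50, 50]))
            res = supervised_ancestry(g, panel)
            f = np.clip(freqs, 1e-6, 1 - 1e-6)

            def ll(q):
                p = np.clip(q * f[0] + (1 - q) * f[1], 1e-12, 1 - 1e-12)
                return float(g @ np.log(p) + (2 - g) @ np.log(1 - p))

            grid = np.arange(0.0, 1.0001, 0.001)
            best = grid[int(np.argmax([ll(q) for q in grid]))]
            assert abs(res.q.iloc[0, 0] - best) <= 1e-3

    def test_missing_genotypes_are_skipped(self):
        rng = np.random.default_rng(9)
        freqs = drifted_panel(rng, k=2, m=3000)
        g = simulate_admixed_genotypes(freqs, [0.8, 0.2], rng=rng, missingness=0.3)
        panel = AlleleFrequencyPanel(freqs, ["A", "B"], np.array([50, 50]))
        res = supervised_ancestry(g, panel)
        assert abs(res.q.iloc[0, 0] - 0.8) <= 0.05

    def test_all_missing_sample_is_an_error(self):
        rng = np.random.default_rng(10)
        freqs = drifted_panel(rng, k=2, m=50)
        panel = AlleleFrequencyPanel(freqs, ["A", "B"], np.array([50, 50]))
        with pytest.raises(ValueError):
            supervised_ancestry(np.full(50, MISSING), panel)

    def test_q_is_a_simplex(self):
        rng = np.random.default_rng(11)
        freqs = drifted_panel(rng, k=4, m=1000)
        g = simulate_admixed_genotypes(freqs, [0.25] * 4, rng=rng)
        panel = AlleleFrequencyPanel(freqs, list("ABCD"), np.array([50] * 4))
        res = supervised_ancestry(g, panel)
        q = res.q.iloc[0].to_numpy()
        assert (q >= 0).all()
        assert q.sum() == pytest.approx(1.0)


class TestConsensusBreed:
    def test_dominant_breed_called(self):
        q = pd.Series({"A": 0.9, "B": 0.06, "C": 0.04})
        assert consensus_breed(q) == "A"

    def test_spread_fractions_called_mixed_village(self):
        q = pd.Series({f"B{i}": v for i, v in enumerate([0.12] * 5 + [0.08] * 5)})
        assert consensus_breed(q) == "mixed/village"

    def test_threshold_boundary_inclusive(self):
        q = pd.Series({"A": 0.5, "B": 0.5})
        assert consensus_breed(q) == "A"

    def test_admixed_missingness_parameter_respected(self):
        rng = np.random.default_rng(12)
        freqs = drifted_panel(rng, k=2, m=4000)
        g = simulate_admixed_genotypes(freqs, [0.5, 0.5], rng=rng, missingness=0.12)
        frac = (g == MISSING).mean()
        assert abs(frac - 0.12) < 0.02
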