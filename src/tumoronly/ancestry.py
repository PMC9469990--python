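"""Breed/ancestry calling from genotype dosages.

Marker selection uses the Hudson two-population FST estimator per SNP
(one-vs-rest per breed by default), keeping SNPs with FST above a
threshold in at least one comparison, followed by windowed LD pruning
(r^2 within fixed-width windows of base positions).  Supervised global
ancestry is then estimated per query sample by maximizing the binomial
likelihood of its dosages given fixed breed allele frequencies, over the
ancestry-proportion simplex, via EM — the quantity estimated is the Q
vector of supervised ADMIXTURE-style analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = -1  # dosage code for a missing genotype


@dataclass
class GenotypeMatrix:
    """Samples x biallelic SNPs dosage matrix (0/1/2, MISSING = -1)."""

    dosages: np.ndarray  # int array, samples x SNPs
    positions: np.ndarray  # bp positions, one chromosome namespace per chrom array
    chroms: np.ndarray  # chromosome label per SNP
    sample_ids: list[str]
    labels: dict[str, str] = field(default_factory=dict)  # sample -> breed (refs only)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int16)
        valid = np.isin(self.dosages, (0, 1, 2, MISSING))
        if not valid.all():
            raise ValueError("dosages must be 0, 1, 2 or missing (-1)")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def missingness(self) -> np.ndarray:
        """Per-SNP fraction of missing genotypes."""
        return (self.dosages == MISSING).mean(axis=0)

    def reference_samples(self) -> list[int]:
        return [i for i, s in enumerate(self.sample_ids) if s in self.labels]

    def query_samples(self) -> list[int]:
        return [i for i, s in enumerate(self.sample_ids) if s not in self.labels]


@dataclass
class AlleleFrequencyPanel:
    """Breeds x SNPs allele frequencies with per-breed sample counts."""

    freqs: np.ndarray  # breeds x SNPs in [0,1]
    breeds: list[str]
    n_per_breed: np.ndarray

    @classmethod
    def from_genotypes(
        cls, genotypes: GenotypeMatrix, min_panel_size: int = 1
    ) -> "AlleleFrequencyPanel":
        breeds = sorted(set(genotypes.labels.values()))
        rows, kept, counts = [], [], []
        for breed in breeds:
            idx = [
                i
                for i, s in enumerate(genotypes.sample_ids)
                if genotypes.labels.get(s) == breed
            ]
            if len(idx) < min_panel_size:
                continue
            g = genotypes.dosages[idx]
            obs = g != MISSING
            with np.errstate(invalid="ignore"):
                f = np.where(obs.sum(axis=0) > 0,
                             np.where(g == MISSING, 0, g).sum(axis=0) / (2 * np.maximum(obs.sum(axis=0), 1)),
                             0.5)
            rows.append(f)
            kept.append(breed)
            counts.append(len(idx))
        return cls(np.vstack(rows), kept, np.asarray(counts))


# --- Hudson FST --------------------------------------------------------------

def hudson_fst(
    p1: np.ndarray | float,
    n1: np.ndarray | int,
    p2: np.ndarray | float,
    n2: np.ndarray | int,
) -> np.ndarray | float:
    """Per-SNP Hudson FST estimate between two populations.

    numerator   = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    denominator = p1(1-p2) + p2(1-p1)

    May be negative in finite samples; NaN where the denominator is zero
    (both populations monomorphic for the same allele) — such SNPs are
    excluded from any aggregation.  Multi-SNP aggregation should be the
    ratio of averaged numerators to averaged denominators.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if (n1 < 2).any() or (n2 < 2).any():
        raise ValueError("Hudson FST requires sample sizes >= 2")
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return fst if fst.shape else float(fst)


def hudson_fst_aggregate(num_sum: float, den_sum: float) -> float:
    """Ratio-of-averages multi-SNP FST."""
    if den_sum <= 0:
        raise ValueError("aggregate denominator must be positive")
    return num_sum / den_sum


def select_markers(
    genotypes: GenotypeMatrix,
    fst_thresh: float = 0.15,
    max_missing: float = 0.10,
    scheme: str = "ovr",
    mode: str = "any",
) -> np.ndarray:
    """Indices of ancestry-informative SNPs.

    SNPs with missingness >= ``max_missing`` are dropped first.  FST is
    computed per breed either one-vs-rest (``scheme='ovr'``) or for all
    breed pairs (``'pairwise'``); a SNP is selected when its FST exceeds
    ``fst_thresh`` in at least one comparison (``mode='any'``) or in all
    of them (``'all'``; NaN comparisons are ignored).
    """
    breeds = sorted(set(genotypes.labels.values()))
    if len(breeds) < 2:
        raise ValueError("marker selection requires >= 2 labeled breeds")
    ref_idx = genotypes.reference_samples()
    g = genotypes.dosages[ref_idx]
    breed_of = np.array([genotypes.labels[genotypes.sample_ids[i]] for i in ref_idx])
    low_missing = genotypes.missingness() < max_missing

    def freqs_counts(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        sub = g[mask]
        obs = sub != MISSING
        n = obs.sum(axis=0)
        alt = np.where(sub == MISSING, 0, sub).sum(axis=0)
        with np.errstate(invalid="ignore"):
            f = np.where(n > 0, alt / (2 * np.maximum(n, 1)), np.nan)
        return f, n

    comparisons: list[np.ndarray] = []
    if scheme == "ovr":
        pairs = [(b, None) for b in breeds]
    elif scheme == "pairwise":
        pairs = [(a, b) for i, a in enumerate(breeds) for b in breeds[i + 1:]]
    else:
        raise ValueError(f"unknown FST scheme {scheme!r}")
    for a, b in pairs:
        mask_a = breed_of == a
        mask_b = (breed_of != a) if b is None else (breed_of == b)
        fa, na = freqs_counts(mask_a)
        fb, nb = freqs_counts(mask_b)
        ok = (na >= 2) & (nb >= 2)
        fst = np.full(genotypes.n_snps, np.nan)
        fst[ok] = hudson_fst(fa[ok], na[ok], fb[ok], nb[ok])
        comparisons.append(fst)
    stack = np.vstack(comparisons)
    exceeds = stack > fst_thresh
    if mode == "any":
        hit = np.nan_to_num(exceeds, nan=False).any(axis=0)
    elif mode == "all":
        hit = np.where(np.isnan(stack), True, exceeds).all(axis=0) & ~np.isnan(stack).all(axis=0)
    else:
        raise ValueError(f"unknown FST mode {mode!r}")
    return np.where(low_missing & hit)[0]


# --- LD pruning --------------------------------------------------------------

def _pairwise_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared genotype correlation over jointly observed samples."""
    obs = (a != MISSING) & (b != MISSING)
    if obs.sum() < 2:
        return 0.0
    x, y = a[obs].astype(float), b[obs].astype(float)
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def ld_prune(
    genotypes: GenotypeMatrix,
    window_bp: int = 50_000,
    r2_thresh: float = 0.5,
    snp_indices: np.ndarray | None = None,
) -> np.ndarray:
    """Deterministic windowed LD pruning; returns retained SNP indices.

    Within each ``window_bp`` tile of each chromosome, while any retained
    pair has r^2 > ``r2_thresh``, the member of the worst pair with the
    higher missingness (ties: higher index) is removed.
    """
    if snp_indices is None:
        snp_indices = np.arange(genotypes.n_snps)
    missing = genotypes.missingness()
    retained: list[int] = []
    order = sorted(
        snp_indices, key=lambda i: (str(genotypes.chroms[i]), int(genotypes.positions[i]), int(i))
    )
    # group into fixed windows
    from itertools import groupby

    def window_key(i: int):
        return (str(genotypes.chroms[i]), int(genotypes.positions[i]) // window_bp)

    for _, group in groupby(order, key=window_key):
        idx = list(group)
        alive = set(idx)
        while True:
            worst = None
            for ii, a in enumerate(idx):
                if a not in alive:
                    continue
                for b in idx[ii + 1:]:
                    if b not in alive:
                        continue
                    r2 = _pairwise_r2(genotypes.dosages[:, a], genotypes.dosages[:, b])
                    if r2 > r2_thresh and (worst is None or r2 > worst[0]):
                        worst = (r2, a, b)
            if worst is None:
                break
            _, a, b = worst
            if (missing[a], a) >= (missing[b], b):
                alive.discard(a)
            else:
                alive.discard(b)
        retained.extend(sorted(alive))
    return np.asarray(sorted(retained), dtype=int)


# --- supervised ancestry -----------------------------------------------------

@dataclass
class AncestryResult:
    """Per-query simplex over breeds plus a consensus label."""

    q: pd.DataFrame  # query samples x breeds
    log_likelihood: pd.Series


def supervised_ancestry(
    query_genotypes: np.ndarray,
    panel: AlleleFrequencyPanel,
    seed: int | None = None,
    tol: float = 1e-7,
    max_iter: int = 5000,
    sample_ids: Sequence[str] | None = None,
) -> AncestryResult:
    """Per-sample ancestry fractions by EM at fixed panel frequencies.

    Maximizes prod_j Binomial(g_j; 2, sum_k q_k f_kj) over the simplex q
    for each query row; missing genotypes are skipped.  Panel
    frequencies are clamped away from {0,1} for numerical stability.
    The likelihood is concave in q, so the EM fixed point is the global
    maximum; the ``seed`` argument fixes the (uniform) initialization
    convention and is accepted for interface stability.
    """
    del seed  # deterministic: uniform initialization, concave objective
    g_all = np.atleast_2d(np.asarray(query_genotypes))
    K = len(panel.breeds)
    f = np.clip(panel.freqs.astype(float), 1e-6, 1 - 1e-6)  # K x M
    rows = []
    lls = []
    for g in g_all:
        obs = g != MISSING
        if not obs.any():
            raise ValueError("query sample has no observed genotypes")
        go = g[obs].astype(float)
        fo = f[:, obs]  # K x m
        q = np.full(K, 1.0 / K)
        prev_ll = -np.inf
        for _ in range(max_iter):
            p = q @ fo  # expected alt frequency per marker
            p = np.clip(p, 1e-12, 1 - 1e-12)
            ll = float(go @ np.log(p) + (2 - go) @ np.log(1 - p))
            # E-step responsibilities folded into the M-step update
            alt_share = (q[:, None] * fo) / p[None, :]
            ref_share = (q[:, None] * (1 - fo)) / (1 - p)[None, :]
            q_new = (alt_share * go[None, :] + ref_share * (2 - go)[None, :]).sum(axis=1)
            q = q_new / q_new.sum()
            if ll - prev_ll < tol and np.isfinite(prev_ll):
                break
            prev_ll = ll
        rows.append(q)
        lls.append(ll)
    ids = list(sample_ids) if sample_ids is not None else [
        f"query_{i}" for i in range(len(rows))
    ]
    return AncestryResult(
        q=pd.DataFrame(np.vstack(rows), index=ids, columns=panel.breeds),
        log_likelihood=pd.Series(lls, index=ids),
    )


def consensus_breed(
    q: np.ndarray | pd.Series,
    breeds: Sequence[str] | None = None,
    dominance_thresh: float = 0.5,
) -> str:
    """Top breed if its fraction is >= the dominance threshold
    (inclusive), else "mixed/village" — the signature of village-dog
    ancestry is many small fractions with no dominant breed."""
    if isinstance(q, pd.Series):
        breeds = list(q.index)
        q = q.to_numpy()
    q = np.asarray(q, dtype=float)
    if breeds is None:
        raise ValueError("breed labels required")
    top = int(np.argmax(q))
    if q[top] >= dominance_thresh:
        return breeds[top]
    return "mixed/village"
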