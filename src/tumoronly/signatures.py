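"""SBS96 mutation catalogs and signature exposure refitting.

Catalogs count single-base substitutions over the 96 canonical channels
(6 pyrimidine-centered substitution classes x 16 flanking contexts, in
the COSMIC file order).  Exposures of a fixed signature catalog are
refit per sample under the multinomial model

    counts ~ Multinomial(n, sum_k e_k s'_k)

where s'_k are the signatures after adjustment for the target genome's
mutational opportunities (per-channel trinucleotide abundance).  The
point estimate is the maximum-likelihood solution found by EM;
uncertainty intervals are bootstrap percentile intervals from resampled
catalogs, a frequentist surrogate for a Bayesian highest-posterior-
density interval that serves the same purpose in the selection rule:
signatures whose interval lower bound exceeds 0.025 in at least one
sample are retained and the fit is rerun on the retained set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

PYRIMIDINES = ("C", "T")
BASES = ("A", "C", "G", "T")
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def sbs96_channels() -> list[str]:
    """The 96 channel labels in COSMIC order (substitution-major,
    then 5' flank, then 3' flank, alphabetical)."""
    return [
        f"{five}[{sub}]{three}"
        for sub in SUBSTITUTIONS
        for five in BASES
        for three in BASES
    ]


CHANNELS = sbs96_channels()
CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS)}


def channel_of(ref: str, alt: str, context5: str, context3: str) -> str | None:
    """Channel label for one SNV; purine refs are reverse-complemented
    into the pyrimidine frame. Returns None for non-ACGT input."""
    ref, alt = ref.upper(), alt.upper()
    context5, context3 = context5.upper(), context3.upper()
    for b in (ref, alt, context5, context3):
        if b not in BASES:
            return None
    if ref == alt:
        return None
    if ref not in PYRIMIDINES:
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
        context5, context3 = COMPLEMENT[context3], COMPLEMENT[context5]
    return f"{context5}[{ref}>{alt}]{context3}"


@dataclass
class MutationCatalog:
    """Per-sample SBS96 counts (channels x samples)."""

    counts: np.ndarray  # shape (96, n_samples), non-negative ints
    samples: list[str]
    n_skipped: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape[0] != 96:
            raise ValueError("catalog must have 96 channel rows")
        if (self.counts < 0).any():
            raise ValueError("catalog counts must be non-negative")

    def total(self, sample: str) -> int:
        return int(self.counts[:, self.samples.index(sample)].sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=CHANNELS, columns=self.samples)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MutationCatalog":
        if list(df.index) != CHANNELS:
            raise ValueError("catalog rows must be the 96 SBS channels in COSMIC order")
        return cls(df.to_numpy(), list(df.columns))


def build_catalog(
    snvs_by_sample: Mapping[str, Sequence],
    reference: Mapping[str, str],
) -> MutationCatalog:
    """Count SNVs into SBS96 channels using +/-1 bp reference context.

    ``reference`` maps chromosome name to sequence (a ``pyfaidx.Fasta``
    works).  Records at contig edges or with non-ACGT context are skipped
    and tallied per sample.
    """
    samples = list(snvs_by_sample)
    counts = np.zeros((96, len(samples)), dtype=int)
    skipped: dict[str, int] = {}
    for si, sample in enumerate(samples):
        n_skip = 0
        for r in snvs_by_sample[sample]:
            if not (len(r.ref) == 1 and len(r.alt) == 1):
                n_skip += 1
                continue
            seq = reference.get(r.chrom) if hasattr(reference, "get") else reference[r.chrom]
            if seq is None:
                n_skip += 1
                continue
            i = r.pos - 1  # 0-based position of the ref base
            if i - 1 < 0 or i + 1 >= len(seq):
                n_skip += 1
                continue
            ch = channel_of(r.ref, r.alt, str(seq[i - 1]), str(seq[i + 1]))
            if ch is None:
                n_skip += 1
                continue
            counts[CHANNEL_INDEX[ch], si] += 1
        skipped[sample] = n_skip
    return MutationCatalog(counts, samples, skipped)


@dataclass
class SignatureCatalog:
    """K signatures x 96 channel probabilities, rows summing to 1."""

    probs: np.ndarray  # shape (K, 96)
    labels: list[str]

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 96:
            raise ValueError("signature matrix must be K x 96")
        if (self.probs < 0).any():
            raise ValueError("signature probabilities must be non-negative")
        sums = self.probs.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-8):
            raise ValueError("each signature row must sum to 1 (tol 1e-8)")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SignatureCatalog":
        """COSMIC layout: channel rows ("Type" index), signature columns."""
        df = df.reindex(CHANNELS)
        if df.isna().any().any():
            raise ValueError("signature table does not cover the 96 SBS channels")
        return cls(df.to_numpy().T, list(df.columns))

    def subset(self, labels: Sequence[str]) -> "SignatureCatalog":
        idx = [self.labels.index(l) for l in labels]
        return SignatureCatalog(self.probs[idx], list(labels))


def adjust_for_opportunities(
    signatures: SignatureCatalog, opportunities: np.ndarray
) -> SignatureCatalog:
    """Reweight each signature by per-channel opportunity and renormalize.

    Invariant under rescaling of the opportunity vector.
    """
    opp = np.asarray(opportunities, dtype=float)
    if opp.shape != (96,):
        raise ValueError("opportunities must be a 96-vector")
    if (opp < 0).any() or not opp.any():
        raise ValueError("opportunities must be non-negative and not all zero")
    adjusted = signatures.probs * opp[None, :]
    sums = adjusted.sum(axis=1, keepdims=True)
    if (sums == 0).any():
        bad = [signatures.labels[i] for i in np.where(sums[:, 0] == 0)[0]]
        raise ValueError(f"opportunity adjustment zeroed signatures: {bad}")
    return SignatureCatalog(adjusted / sums, list(signatures.labels))


@dataclass
class ExposureEstimate:
    """Per-sample exposure simplex with bootstrap interval bounds."""

    exposures: pd.DataFrame  # samples x signatures, rows sum to 1
    lower: pd.DataFrame
    upper: pd.DataFrame
    log_likelihood: pd.Series
    n_mutations: pd.Series
    interval_mass: float = 0.95


def _em_fit(
    counts: np.ndarray,
    sig: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 10000,
) -> tuple[np.ndarray, float]:
    """Maximize the multinomial log-likelihood over the exposure simplex.

    Standard mixture EM: responsibilities of each signature for each
    channel, then exposure update by expected counts.  The log-likelihood
    is non-decreasing; convergence is declared when its improvement drops
    below ``tol``.
    """
    K = sig.shape[0]
    n = counts.sum()
    if n == 0:
        raise ValueError("cannot fit exposures for a sample with zero mutations")
    e = np.full(K, 1.0 / K)
    nonzero = counts > 0
    c = counts[nonzero].astype(float)
    s = sig[:, nonzero]  # K x m
    prev_ll = -np.inf
    for _ in range(max_iter):
        p = e @ s  # mixture channel probabilities
        p = np.maximum(p, 1e-300)
        ll = float(c @ np.log(p))
        e = (e[:, None] * s / p[None, :] * c[None, :]).sum(axis=1) / n
        e = np.maximum(e, 0.0)
        e /= e.sum()
        if ll - prev_ll < tol and np.isfinite(prev_ll):
            return e, ll
        prev_ll = ll
    raise RuntimeError(
        f"EM did not converge within {max_iter} iterations (last ll={prev_ll:.6f})"
    )


def fit_exposures(
    catalog: MutationCatalog,
    signatures: SignatureCatalog,
    n_boot: int = 200,
    interval_mass: float = 0.95,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> ExposureEstimate:
    """ML exposures per sample plus bootstrap percentile intervals.

    Bootstrap replicates resample each sample's catalog multinomially at
    its observed total; the interval covers the central ``interval_mass``
    of refit exposures and is widened, if necessary, to contain the point
    estimate.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    sig = signatures.probs
    K, S = sig.shape[0], len(catalog.samples)
    point = np.zeros((S, K))
    lower = np.zeros((S, K))
    upper = np.zeros((S, K))
    lls = np.zeros(S)
    totals = catalog.counts.sum(axis=0)
    alpha = (1.0 - interval_mass) / 2.0
    for si in range(S):
        counts = catalog.counts[:, si]
        e, ll = _em_fit(counts, sig)
        point[si], lls[si] = e, ll
        n = int(totals[si])
        boots = np.zeros((n_boot, K))
        p_emp = counts / n
        for b in range(n_boot):
            resampled = rng.multinomial(n, p_emp)
            boots[b], _ = _em_fit(resampled, sig)
        lower[si] = np.minimum(np.quantile(boots, alpha, axis=0), e)
        upper[si] = np.maximum(np.quantile(boots, 1 - alpha, axis=0), e)
    labels = signatures.labels
    return ExposureEstimate(
        exposures=pd.DataFrame(point, index=catalog.samples, columns=labels),
        lower=pd.DataFrame(lower, index=catalog.samples, columns=labels),
        upper=pd.DataFrame(upper, index=catalog.samples, columns=labels),
        log_likelihood=pd.Series(lls, index=catalog.samples),
        n_mutations=pd.Series(totals, index=catalog.samples),
        interval_mass=interval_mass,
    )


def select_and_refit(
    estimates: ExposureEstimate,
    catalog: MutationCatalog,
    signatures: SignatureCatalog,
    floor: float = 0.025,
    n_boot: int = 200,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[ExposureEstimate, list[str]]:
    """Keep signatures whose interval lower bound exceeds ``floor`` in at
    least one sample, then refit on the retained set only."""
    retained = [
        label
        for label in signatures.labels
        if (estimates.lower[label] > floor).any()
    ]
    if not retained:
        raise ValueError(f"no signature has interval lower bound > {floor} in any sample")
    refit = fit_exposures(
        catalog,
        signatures.subset(retained),
        n_boot=n_boot,
        interval_mass=estimates.interval_mass,
        seed=seed,
        rng=rng,
    )
    return refit, retained


def read_signature_tsv(path: str) -> SignatureCatalog:
    """Read a COSMIC-layout signature TSV (Type column + signature columns)."""
    df = pd.read_csv(path, sep="\t")
    type_col = df.columns[0]
    df = df.set_index(type_col)
    return SignatureCatalog.from_frame(df)


def read_opportunities_tsv(path: str) -> np.ndarray:
    """Read a 96-channel opportunity vector (channel, weight) TSV."""
    df = pd.read_csv(path, sep="\t", header=None, names=["channel", "weight"])
    series = df.set_index("channel")["weight"].reindex(CHANNELS)
    if series.isna().any():
        raise ValueError("opportunity table does not cover the 96 SBS channels")
    return series.to_numpy(dtype=float)
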