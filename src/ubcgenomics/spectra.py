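"""96-channel trinucleotide mutation spectra and NMF signature extraction.

A somatic substitution is assigned to one of 96 channels: six
pyrimidine-represented substitutions (C>A, C>G, C>T, T>A, T>C, T>G) times
the 16 combinations of the bases immediately 5' and 3' of the mutated
site.  Substitutions at purine reference bases are mapped to the
reverse-complement pyrimidine representation.  Channel order follows the
conventional COSMIC ordering (substitution blocks, flanking context
lexicographic within each block) so reference catalogs load without
permutation.

De novo signatures are extracted by nonnegative matrix factorization of
the 96 x S count matrix with Brunet-style multiplicative updates
minimizing the generalized Kullback-Leibler divergence, restarted from
random initializations; rank is selected by balancing restart stability
(mean silhouette of clustered signature vectors, cosine distance) against
reconstruction error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

from .types import BASES, Genome, SnvCatalog

SUBSTITUTIONS = (("C", "A"), ("C", "G"), ("C", "T"), ("T", "A"), ("T", "C"), ("T", "G"))
N_CHANNELS = 96

_CODE = {b: i for i, b in enumerate(BASES)}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_SUB_INDEX = {pair: i for i, pair in enumerate(SUBSTITUTIONS)}

#: channel labels in fixed order, e.g. ``A[C>A]A``
CHANNEL_LABELS = tuple(
    f"{five}[{ref}>{alt}]{three}"
    for (ref, alt) in SUBSTITUTIONS
    for five in BASES
    for three in BASES
)


class NoContextError(ValueError):
    """The trinucleotide context of a mutation is unavailable."""


def channel_index(ref: str, alt: str, five: str, three: str) -> int:
    """Channel of a substitution given its plus-strand trinucleotide context."""
    if ref in "AG":  # purine reference: fold onto the pyrimidine strand
        ref, alt = _COMP[ref], _COMP[alt]
        five, three = _COMP[three], _COMP[five]
    sub = _SUB_INDEX[(ref, alt)]
    return sub * 16 + _CODE[five] * 4 + _CODE[three]


def snv_channel(snv, genome: Genome) -> int:
    """Map one SNV to its 96-channel index using the reference sequence.

    Raises :class:`NoContextError` for mutations at position 1 or the
    chromosome end, where no flanking base exists.
    """
    codes = genome.codes(snv.chrom)
    if snv.pos <= 1 or snv.pos >= len(codes):
        raise NoContextError(f"no trinucleotide context at {snv.chrom}:{snv.pos}")
    tri = genome.seq(snv.chrom, snv.pos - 2, snv.pos + 1)
    if tri[1] != snv.ref:
        raise ValueError(
            f"reference mismatch at {snv.chrom}:{snv.pos}: genome {tri[1]}, record {snv.ref}"
        )
    return channel_index(snv.ref, snv.alt, tri[0], tri[2])


@dataclass
class MutationSpectrum:
    """96 x S matrix of mutation counts with the fixed channel order."""

    counts: pd.DataFrame  # index = CHANNEL_LABELS, columns = samples
    n_skipped: int = 0

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def matrix(self) -> np.ndarray:
        return self.counts.to_numpy(dtype=float)


def build_spectrum(catalog: SnvCatalog, genome: Genome, samples=None) -> MutationSpectrum:
    """Count every SNV of the catalog into its trinucleotide channel.

    Mutations lacking a flanking base (first/last position of a
    chromosome) are skipped and tallied in ``n_skipped``.
    """
    if samples is None:
        samples = catalog.samples
    sample_index = {s: j for j, s in enumerate(samples)}
    mat = np.zeros((N_CHANNELS, len(samples)), dtype=np.int64)
    skipped = 0
    df = catalog.df
    for chrom, sub in df.groupby("chrom", sort=False):
        codes = genome.codes(str(chrom))
        pos0 = sub["pos"].to_numpy(np.int64) - 1
        interior = (pos0 >= 1) & (pos0 <= len(codes) - 2)
        skipped += int((~interior).sum())
        sub = sub[interior]
        pos0 = pos0[interior]
        if not len(sub):
            continue
        five = codes[pos0 - 1].astype(np.int64)
        center = codes[pos0].astype(np.int64)
        three = codes[pos0 + 1].astype(np.int64)
        ref = sub["ref"].map(_CODE).to_numpy(np.int64)
        alt = sub["alt"].map(_CODE).to_numpy(np.int64)
        if (center != ref).any():
            i = int(np.argmax(center != ref))
            raise ValueError(
                f"reference mismatch at {chrom}:{int(pos0[i]) + 1}: "
                f"genome {BASES[center[i]]}, record {BASES[ref[i]]}"
            )
        purine = (ref == 0) | (ref == 2)  # A or G
        r = np.where(purine, 3 - ref, ref)
        a = np.where(purine, 3 - alt, alt)
        f = np.where(purine, 3 - three, five)
        t = np.where(purine, 3 - five, three)
        sub_idx = np.select(
            [
                (r == 1) & (a == 0), (r == 1) & (a == 2), (r == 1) & (a == 3),
                (r == 3) & (a == 0), (r == 3) & (a == 1), (r == 3) & (a == 2),
            ],
            [0, 1, 2, 3, 4, 5],
        )
        channels = sub_idx * 16 + f * 4 + t
        cols = sub["sample_id"].map(sample_index).to_numpy(np.int64)
        np.add.at(mat, (channels, cols), 1)
    counts = pd.DataFrame(mat, index=list(CHANNEL_LABELS), columns=list(samples))
    return MutationSpectrum(counts=counts, n_skipped=skipped)


# ---------------------------------------------------------------------------
# NMF
# ---------------------------------------------------------------------------

_EPS = 1e-12


@dataclass
class SignatureSet:
    """Result of one NMF factorization of a mutation spectrum."""

    W: pd.DataFrame  # 96 x K, columns sum to 1
    H: pd.DataFrame  # K x S exposures
    k: int
    reconstruction_error: float  # generalized KL divergence
    stability: float | None = None
    divergence_trace: np.ndarray | None = None  # best restart, per iteration

    @property
    def signatures(self) -> np.ndarray:
        return self.W.to_numpy()

    @property
    def exposures(self) -> np.ndarray:
        return self.H.to_numpy()


def generalized_kl(V: np.ndarray, WH: np.ndarray) -> float:
    """D(V || WH) = sum V log(V/WH) - V + WH, with 0 log 0 = 0."""
    WH = np.maximum(WH, _EPS)
    mask = V > 0
    term = np.zeros_like(WH)
    term[mask] = V[mask] * np.log(V[mask] / WH[mask]) - V[mask]
    return float((term + WH).sum())


def _mu_kl(V, W, H, max_iter, tol):
    """Multiplicative updates for generalized KL; returns trace of divergence."""
    ones = np.ones_like(V)
    trace = []
    prev = np.inf
    for _ in range(max_iter):
        WH = W @ H + _EPS
        H *= (W.T @ (V / WH)) / (W.T @ ones + _EPS)
        WH = W @ H + _EPS
        W *= ((V / WH) @ H.T) / (ones @ H.T + _EPS)
        d = generalized_kl(V, W @ H)
        trace.append(d)
        if prev - d <= tol * max(d, 1.0):
            break
        prev = d
    return W, H, np.asarray(trace)


def _mu_frobenius(V, W, H, max_iter, tol):
    trace = []
    prev = np.inf
    for _ in range(max_iter):
        H *= (W.T @ V) / (W.T @ W @ H + _EPS)
        W *= (V @ H.T) / (W @ H @ H.T + _EPS)
        d = float(((V - W @ H) ** 2).sum())
        trace.append(d)
        if prev - d <= tol * max(d, 1.0):
            break
        prev = d
    return W, H, np.asarray(trace)


def nmf_decompose(
    spectrum: MutationSpectrum,
    k: int,
    n_restarts: int = 10,
    max_iter: int = 1000,
    tol: float = 1e-6,
    seed: int | None = None,
    objective: str = "kl",
) -> SignatureSet:
    """Factorize a spectrum into ``k`` signatures, best of ``n_restarts``.

    Each restart initializes W, H from i.i.d. uniform noise and iterates
    multiplicative updates until the relative decrease of the objective
    falls below ``tol`` or ``max_iter`` iterations are reached.  The
    restart with the lowest final divergence is kept; its W columns are
    normalized to sum to one, with compensating row scaling of H.
    """
    V = spectrum.matrix
    if V.sum() == 0:
        raise ValueError("all-zero spectrum cannot be factorized")
    n, s = V.shape
    if k < 1 or k > min(n, s):
        raise ValueError(f"rank k={k} infeasible for a {n}x{s} spectrum")
    update = _mu_kl if objective == "kl" else _mu_frobenius
    rng = np.random.default_rng(seed)
    best = None
    scale = np.sqrt(V.mean() / k)
    for _ in range(n_restarts):
        W0 = rng.uniform(_EPS, 1.0, size=(n, k)) * scale
        H0 = rng.uniform(_EPS, 1.0, size=(k, s)) * scale
        W, H, trace = update(V, W0, H0, max_iter, tol)
        if best is None or trace[-1] < best[2][-1]:
            best = (W, H, trace)
    W, H, trace = best
    colsum = W.sum(axis=0)
    colsum[colsum == 0] = 1.0
    W = W / colsum
    H = H * colsum[:, None]
    sig_names = [f"S{i + 1}" for i in range(k)]
    return SignatureSet(
        W=pd.DataFrame(W, index=list(CHANNEL_LABELS), columns=sig_names),
        H=pd.DataFrame(H, index=sig_names, columns=spectrum.samples),
        k=k,
        reconstruction_error=float(trace[-1]),
        divergence_trace=trace,
    )


def _stability(all_W: np.ndarray, k: int, seed: int) -> float:
    """Silhouette-based stability of restart signatures clustered into k groups.

    The statistic is the *minimum over clusters* of the mean cosine
    silhouette within the cluster: the overall mean is dominated by the
    k-1 reproducible signatures and hides a single unstable component,
    whereas the weakest cluster is exactly what overshooting the rank
    degrades.
    """
    X = all_W.T  # one row per signature vector
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    Xn = X / np.maximum(norms, _EPS)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(Xn)
    if len(set(labels)) < 2:
        return 0.0
    sil = silhouette_samples(X, labels, metric="cosine")
    return float(min(sil[labels == c].mean() for c in set(labels)))


def _bootstrap_spectrum(V: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Multinomial resample of each sample's mutation counts."""
    out = np.zeros_like(V)
    for s in range(V.shape[1]):
        n = int(V[:, s].sum())
        if n == 0:
            continue
        p = V[:, s] / n
        out[:, s] = rng.multinomial(n, p)
    return out


def select_rank(
    spectrum: MutationSpectrum,
    k_range=range(2, 16),
    n_restarts: int = 8,
    max_iter: int = 1000,
    tol: float = 1e-6,
    seed: int | None = None,
    stability_floor: float = 0.8,
    bootstrap: bool = True,
) -> tuple[int, pd.DataFrame]:
    """Run NMF across ranks; return (chosen k, table of stability/error).

    For each rank every restart factorizes a multinomial bootstrap
    resample of the spectrum (restarts on the identical matrix reconverge
    even above the true rank, so resampling is what exposes unstable
    components); the pooled signature vectors are clustered into k groups
    and stability is the mean cosine silhouette of that clustering.
    Reconstruction error is the best generalized KL divergence against
    the *original* spectrum.  The chosen rank is the largest one whose
    stability reaches ``stability_floor`` (the stability/error "optimal
    balance" made explicit); the full table is returned so callers can
    override.
    """
    V = spectrum.matrix
    n, s = V.shape
    rng = np.random.default_rng(seed)
    rows = []
    for k in k_range:
        if k < 1 or k > min(n, s):
            warnings.warn(f"rank {k} infeasible for a {n}x{s} spectrum; dropped", stacklevel=2)
            continue
        sub_seed = int(rng.integers(0, 2**31 - 1))
        sub_rng = np.random.default_rng(sub_seed)
        Ws, best_err = [], np.inf
        scale = np.sqrt(V.mean() / k)
        for _ in range(n_restarts):
            Vr = _bootstrap_spectrum(V, sub_rng) if bootstrap else V
            W0 = sub_rng.uniform(_EPS, 1.0, size=(n, k)) * scale
            H0 = sub_rng.uniform(_EPS, 1.0, size=(k, s)) * scale
            W, H, trace = _mu_kl(Vr, W0, H0, max_iter, tol)
            colsum = np.maximum(W.sum(axis=0), _EPS)
            Ws.append(W / colsum)
            best_err = min(best_err, generalized_kl(V, W @ H))
        stab = 1.0 if k == 1 else _stability(np.hstack(Ws), k, sub_seed)
        rows.append({"k": k, "stability": stab, "reconstruction_error": best_err})
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("no feasible rank in k_range")
    ok = table[table["stability"] >= stability_floor]
    chosen = int(ok["k"].max()) if len(ok) else int(table.loc[table["stability"].idxmax(), "k"])
    return chosen, table


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(u, v) / (nu * nv))


def match_to_reference(W: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    """Best cosine match of each extracted signature against a reference catalog.

    ``reference`` has channel labels as index and one column per reference
    signature.  Ties are broken by the first reference column.
    """
    ref = reference.reindex(list(CHANNEL_LABELS))
    if ref.isna().any().any():
        raise ValueError("reference catalog is missing channels")
    rows = []
    for sig in W.columns:
        sims = [cosine_similarity(W[sig].to_numpy(), ref[c].to_numpy()) for c in ref.columns]
        best = int(np.argmax(sims))  # argmax takes the first maximum: tie -> first reference
        rows.append({"signature": sig, "best_reference": ref.columns[best],
                     "cosine_similarity": sims[best]})
    return pd.DataFrame(rows)
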