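"""Mutational-signature extraction, comparison and refitting.

De novo extraction factorises a matrix of 96-channel spectra into
non-negative signatures and per-sample exposures by NMF under the
generalised Kullback-Leibler objective (multiplicative updates, best of
several random restarts).  The number of signatures is chosen from the
cophenetic correlation coefficient of a consensus clustering over restarts.
Known signature sets are fitted to individual spectra by non-negative least
squares, with an iterative elimination of components contributing 5% or
less of the fitted spectrum — small contributions of broad, flat signatures
are rarely distinguishable from noise, so only components retaining a >5%
share after refitting are reported as detected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.optimize import nnls
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import NMF

from .spectra import CHANNELS, SpectraError, TripletSpectrum

logger = logging.getLogger(__name__)


class SignatureError(ValueError):
    pass


@dataclass
class SignatureMatrix:
    """Non-negative 96 x k matrix of signature definitions (columns sum to 1)."""

    matrix: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 96:
            raise SignatureError(f"signature matrix must be 96 x k, got {self.matrix.shape}")
        if self.matrix.shape[1] != len(self.names):
            raise SignatureError("number of names does not match number of signatures")
        if (self.matrix < 0).any():
            raise SignatureError("signatures must be non-negative")
        sums = self.matrix.sum(axis=0)
        if (sums <= 0).any():
            raise SignatureError("each signature must have positive total")
        self.matrix = self.matrix / sums

    @property
    def k(self) -> int:
        return self.matrix.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(CHANNELS), columns=self.names)

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "channel"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SignatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.index) != list(CHANNELS):
            raise SignatureError(f"{path}: rows do not match the fixed 96-channel order")
        return cls(df.to_numpy(), [str(c) for c in df.columns])


@dataclass
class ExposureVector:
    """Per-sample signature contributions (counts de novo, fractions on refit)."""

    values: np.ndarray
    names: list[str]
    residual_cosine: float = float("nan")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < -1e-12).any():
            raise SignatureError("exposures must be non-negative")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise SignatureError("cosine similarity is undefined for a zero vector")
    return float(np.dot(a, b) / (na * nb))


def _generalized_kl(x: np.ndarray, y: np.ndarray) -> float:
    mask = x > 0
    div = float(np.sum(x[mask] * np.log(x[mask] / np.maximum(y[mask], 1e-300))))
    return div - float(x.sum()) + float(y.sum())


def _spectra_matrix(spectra: Sequence[TripletSpectrum]) -> tuple[np.ndarray, list[str]]:
    x = np.vstack([s.counts for s in spectra])
    labels = [s.label or f"sample_{i}" for i, s in enumerate(spectra)]
    if (x.sum(axis=1) <= 0).any():
        raise SignatureError("all-zero spectrum in input")
    return x, labels


@dataclass
class NMFResult:
    signatures: SignatureMatrix
    exposures: pd.DataFrame  # samples x k, mutation-count units
    reconstruction_cosine: pd.Series
    kl_divergence: float
    k: int
    seed: int


def _fit_one(x: np.ndarray, k: int, random_state: int) -> tuple[np.ndarray, np.ndarray, float]:
    model = NMF(
        n_components=k,
        init="random",
        solver="mu",
        beta_loss="kullback-leibler",
        max_iter=200,
        tol=1e-6,
        random_state=random_state,
    )
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        # the 200-iteration cap is a deliberate budget; restarts compensate
        warnings.simplefilter("ignore", ConvergenceWarning)
        w = model.fit_transform(x)
    h = model.components_
    return w, h, _generalized_kl(x, w @ h)


def nmf_decompose(
    spectra: Sequence[TripletSpectrum],
    k: int,
    n_runs: int = 30,
    seed: int = 0,
) -> NMFResult:
    """Factorise spectra into k signatures by KL-NMF, best of ``n_runs`` restarts.

    Signature columns are normalised to sum 1, with exposures rescaled so the
    reconstruction is unchanged; fully reproducible for a fixed seed.
    """
    x, labels = _spectra_matrix(spectra)
    if k < 1:
        raise SignatureError("k must be >= 1")
    if k > len(spectra):
        raise SignatureError(f"k={k} exceeds the number of samples ({len(spectra)})")
    rng = np.random.default_rng(seed)
    run_seeds = rng.integers(0, 2**31 - 1, size=n_runs)
    best: tuple[np.ndarray, np.ndarray, float] | None = None
    for rs in run_seeds:
        w, h, kl = _fit_one(x, k, int(rs))
        if best is None or kl < best[2]:
            best = (w, h, kl)
    assert best is not None
    w, h, kl = best
    scale = h.sum(axis=1)  # per-signature total over channels
    scale[scale == 0] = 1.0
    sig = SignatureMatrix((h / scale[:, None]).T, [f"S{i + 1}" for i in range(k)])
    exposures = pd.DataFrame(w * scale[None, :], index=labels, columns=sig.names)
    recon = w @ h
    cosines = pd.Series(
        [cosine_similarity(x[i], recon[i]) for i in range(len(labels))], index=labels
    )
    return NMFResult(
        signatures=sig,
        exposures=exposures,
        reconstruction_cosine=cosines,
        kl_divergence=kl,
        k=k,
        seed=seed,
    )


@dataclass
class RankSelection:
    chosen_k: int
    #: restart-stability (mean silhouette of the run-signature clustering) per rank
    stability: dict[int, float]
    #: cophenetic correlation of the run-signature dendrogram per rank
    cophenetic: dict[int, float]
    stable: bool


def _rank_stability(run_signatures: np.ndarray, k: int) -> tuple[float, float]:
    """Stability of a candidate rank from the signatures of all restarts.

    The pooled run-signatures (n_runs * k rows) are clustered by average
    linkage at cosine distance and cut into k clusters.  Returns the mean
    silhouette width of that clustering (the stability statistic: ~1 when
    every restart reproduces the same k signatures, dropping sharply once k
    exceeds the reproducible rank) and the cophenetic correlation of the
    dendrogram against the pairwise distances (reported for inspection).
    """
    from scipy.cluster.hierarchy import fcluster
    from sklearn.metrics import silhouette_score

    d = np.clip(pdist(run_signatures, metric="cosine"), 0.0, None)
    if k == 1 or not d.size:
        # single cluster: stability is the tightness of the replicate signatures
        mean_d = float(d.mean()) if d.size else 0.0
        return max(0.0, 1.0 - mean_d), 1.0
    if np.allclose(d, 0.0):
        logger.info("degenerate run-signature set (all identical); stability 1")
        return 1.0, 1.0
    z = linkage(d, method="average")
    c, _ = cophenet(z, d)
    coph = 1.0 if np.isnan(c) else float(c)
    labels = fcluster(z, t=k, criterion="maxclust")
    if len(set(labels)) < 2:
        return 1.0, coph
    sil = float(silhouette_score(squareform(d), labels, metric="precomputed"))
    return sil, coph


def select_rank(
    spectra: Sequence[TripletSpectrum],
    k_range: Sequence[int],
    n_runs: int = 30,
    seed: int = 0,
    delta: float = 0.05,
    stability_floor: float = 0.9,
) -> RankSelection:
    """Choose the number of signatures from restart stability.

    For each candidate k, the signatures of ``n_runs`` NMF restarts are
    pooled and clustered (average linkage, cosine distance, cut at k); the
    mean silhouette of that clustering measures how reproducibly the k
    signatures are recovered across restarts.  The chosen rank is the
    largest k before the first drop of more than ``delta`` in the stability
    curve (ties towards smaller k); when no such drop occurs, the k with the
    highest stability is chosen.  The cophenetic correlation of each rank's
    run-signature dendrogram is reported alongside.  ``stable`` is False when
    even the chosen rank falls below ``stability_floor``, flagging inputs
    with no reproducible factorisation (e.g. pure noise).
    """
    x, _ = _spectra_matrix(spectra)
    ks = sorted(set(k_range))
    if not ks:
        raise SignatureError("empty k_range")
    if ks[-1] > len(spectra):
        raise SignatureError("k_range exceeds the number of samples")
    rng = np.random.default_rng(seed)
    stability: dict[int, float] = {}
    coph: dict[int, float] = {}
    for k in ks:
        runs = []
        for _ in range(n_runs):
            _w, h, _kl = _fit_one(x, k, int(rng.integers(0, 2**31 - 1)))
            runs.append(h / h.sum(axis=1, keepdims=True))
        stability[k], coph[k] = _rank_stability(np.vstack(runs), k)
    chosen = None
    for i in range(len(ks) - 1):
        if stability[ks[i]] - stability[ks[i + 1]] > delta:
            chosen = ks[i]
            break
    if chosen is None:
        chosen = min(ks, key=lambda k: (-stability[k], k))
    if stability[chosen] < stability_floor:
        logger.warning(
            "no stable factorisation in k_range (best stability %.3f at k=%d)",
            stability[chosen], chosen,
        )
    return RankSelection(
        chosen_k=chosen,
        stability=stability,
        cophenetic=coph,
        stable=stability[chosen] >= stability_floor,
    )


@dataclass
class SignatureClustering:
    linkage: np.ndarray
    labels: list[str]


def cluster_signatures(sigs: SignatureMatrix) -> SignatureClustering:
    """Average-linkage hierarchical clustering of signatures at cosine distance."""
    if sigs.k < 1:
        raise SignatureError("no signatures to cluster")
    if len(set(sigs.names)) != len(sigs.names):
        raise SignatureError("duplicate signature labels")
    if sigs.k == 1:
        return SignatureClustering(linkage=np.empty((0, 4)), labels=list(sigs.names))
    dist = pdist(sigs.matrix.T, metric="cosine")
    dist = np.clip(dist, 0.0, None)
    z = linkage(dist, method="average")
    return SignatureClustering(linkage=z, labels=list(sigs.names))


def refit_exposures(spectrum: TripletSpectrum, sigs: SignatureMatrix) -> ExposureVector:
    """Fractional signature contributions by non-negative least squares.

    The spectrum is normalised to sum 1 and fitted on the signature columns;
    exposures are returned as fractions of the fitted total, together with
    the cosine of the reconstruction against the observed spectrum.
    """
    total = spectrum.total
    if total <= 0:
        raise SignatureError("cannot refit an empty spectrum")
    if np.linalg.matrix_rank(sigs.matrix) < sigs.k:
        logger.warning("rank-deficient signature set; refit solution is not unique")
    b = spectrum.counts / total
    w, _ = nnls(sigs.matrix, b)
    fitted = sigs.matrix @ w
    if fitted.sum() > 0:
        residual_cos = cosine_similarity(b, fitted)
        fractions = w / w.sum()
    else:
        residual_cos = 0.0
        fractions = np.zeros(sigs.k)
    return ExposureVector(fractions, list(sigs.names), residual_cosine=residual_cos)


def threshold_contributions(
    spectrum: TripletSpectrum,
    sigs: SignatureMatrix,
    cutoff: float = 0.05,
) -> ExposureVector:
    """Iterative sub-cutoff elimination refit.

    Signatures contributing ``cutoff`` or less of the fitted spectrum are
    removed and the remainder refitted, until every retained contribution is
    strictly above the cutoff.  Removed signatures report an exposure of 0
    and count as not detected.
    """
    active = list(range(sigs.k))
    exposure = None
    while active:
        sub = SignatureMatrix(sigs.matrix[:, active], [sigs.names[i] for i in active])
        exposure = refit_exposures(spectrum, sub)
        # strict ">cutoff" rule, with an absolute tolerance so a contribution
        # equal to the cutoff at machine precision is removed
        keep = [i for i, frac in zip(active, exposure.values) if frac > cutoff + 1e-9]
        if keep == active:
            break
        active = keep
    values = np.zeros(sigs.k)
    residual = 0.0
    if active and exposure is not None:
        for i, frac in zip(active, exposure.values):
            values[i] = frac
        residual = exposure.residual_cosine
    return ExposureVector(values, list(sigs.names), residual_cosine=residual)


def detected_signatures(exposure: ExposureVector, cutoff: float = 0.05) -> dict[str, bool]:
    """Presence call per signature: detected iff retained above the cutoff."""
    return {name: bool(v > cutoff) for name, v in zip(exposure.names, exposure.values)}


def match_signatures(
    estimated: SignatureMatrix, truth: SignatureMatrix
) -> tuple[list[int], np.ndarray]:
    """Best one-to-one assignment of estimated to true signatures.

    Returns, for each true signature j, the index of the matched estimated
    signature and the cosine similarities of the matched pairs.
    """
    from scipy.optimize import linear_sum_assignment

    if estimated.k != truth.k:
        raise SignatureError("signature sets must have equal size to match")
    sim = np.zeros((truth.k, estimated.k))
    for j in range(truth.k):
        for i in range(estimated.k):
            sim[j, i] = cosine_similarity(truth.matrix[:, j], estimated.matrix[:, i])
    rows, cols = linear_sum_assignment(-sim)
    order = np.empty(truth.k, dtype=int)
    for r, c in zip(rows, cols):
        order[r] = c
    return order.tolist(), sim[np.arange(truth.k), order]
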