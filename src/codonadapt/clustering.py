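"""Codon-usage dimensionality reduction and clustering.

Genes are represented by their 59-dimensional within-family normalized
codon frequencies, projected with PCA, and grouped with k-means, with the
cluster number chosen by an explicit elbow rule (maximal discrete second
difference of the inertia curve). Also houses the CAI vs delta-SDR
association test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA


@dataclass(frozen=True)
class PCAResult:
    loadings: pd.DataFrame  # features x components
    scores: pd.DataFrame  # genes x components
    explained_variance_fraction: np.ndarray


@dataclass(frozen=True)
class ClusterResult:
    labels: pd.Series  # gene_id -> cluster label in 0..k-1
    chosen_k: int
    inertia_curve: dict[int, float]


def pca_codon_usage(
    matrix: pd.DataFrame,
    center: bool = True,
    scale: bool = False,
    n_components: int | None = None,
) -> PCAResult:
    """PCA of a genes x features codon-usage matrix via SVD.

    Columns are mean-centered (and optionally unit-scaled). Constant
    columns are dropped with a warning when scaling is requested. Component
    signs follow a deterministic convention: the largest-magnitude loading
    of each component is positive.
    """
    if matrix.shape[0] < 2:
        raise ValueError("PCA needs >= 2 genes")
    X = matrix.to_numpy(dtype=float)
    cols = list(matrix.columns)
    if scale:
        sd = X.std(axis=0, ddof=1)
        const = sd == 0
        if const.any():
            dropped = [c for c, k in zip(cols, const) if k]
            warnings.warn(f"dropping constant column(s) under scaling: {dropped}", stacklevel=2)
            X = X[:, ~const]
            cols = [c for c, k in zip(cols, const) if not k]
            sd = sd[~const]
        X = X / sd
    if not center:
        X = X + 0.0  # PCA below always centers; offer center=False via manual SVD
    pca = PCA(n_components=n_components, svd_solver="full")
    if center:
        scores = pca.fit_transform(X)
        loadings = pca.components_.T
        evr = pca.explained_variance_ratio_
    else:
        U, S, Vt = np.linalg.svd(X, full_matrices=False)
        k = n_components or min(X.shape)
        scores = U[:, :k] * S[:k]
        loadings = Vt[:k].T
        evr = (S**2 / np.sum(S**2))[:k]

    # deterministic sign convention
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1

    comp_names = [f"PC{j + 1}" for j in range(loadings.shape[1])]
    return PCAResult(
        loadings=pd.DataFrame(loadings, index=cols, columns=comp_names),
        scores=pd.DataFrame(scores, index=matrix.index, columns=comp_names),
        explained_variance_fraction=np.asarray(evr, dtype=float),
    )


def choose_elbow_k(inertia_curve: dict[int, float]) -> int:
    """Elbow rule: k maximizing the discrete second difference of
    log-inertia.

    The log scale makes the rule scale-free: the elbow is where the
    *relative* inertia drop collapses, which is robust when early splits of
    well-separated clusters remove large absolute amounts of variance. With
    fewer than three candidate k values the second difference is undefined
    and the smallest k is returned.
    """
    ks = sorted(inertia_curve)
    if len(ks) < 3:
        return ks[0]
    inert = np.array([max(inertia_curve[k], 1e-300) for k in ks])
    log_i = np.log(inert)
    d2 = log_i[:-2] - 2 * log_i[1:-1] + log_i[2:]
    return ks[1 + int(np.argmax(d2))]


def kmeans_elbow(
    scores: pd.DataFrame,
    k_range=range(2, 11),
    n_restarts: int = 25,
    seed: int = 0,
    k_override: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 300,
) -> ClusterResult:
    """K-means over a range of k with elbow-based model selection.

    k-means++ seeding, ``n_restarts`` restarts per k, fixed seed for
    bit-identical results. ``k_override`` skips the elbow rule.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("empty k_range")
    X = np.asarray(scores, dtype=float)
    if max(ks) >= X.shape[0]:
        raise ValueError("k must be < number of genes")
    inertia: dict[int, float] = {}
    fits: dict[int, KMeans] = {}
    for k in ks:
        km = KMeans(
            n_clusters=k,
            init="k-means++",
            n_init=n_restarts,
            random_state=seed,
            tol=tol,
            max_iter=max_iter,
        ).fit(X)
        inertia[k] = float(km.inertia_)
        fits[k] = km
    chosen = int(k_override) if k_override is not None else choose_elbow_k(inertia)
    if chosen not in fits:
        raise ValueError(f"k_override {chosen} not in k_range")
    index = scores.index if isinstance(scores, pd.DataFrame) else pd.RangeIndex(X.shape[0])
    labels = pd.Series(fits[chosen].labels_, index=index, name="cluster")
    return ClusterResult(labels=labels, chosen_k=chosen, inertia_curve=inertia)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    slope: float
    intercept: float
    n: int


def correlate_delta_sdr_cai(gene_table: pd.DataFrame) -> CorrelationResult:
    """Pearson correlation (and least-squares line) between CAI and delta-SDR.

    ``gene_table`` needs ``cai`` and ``delta_sdr`` columns; genes with
    either value missing are dropped. A negative r means genes adapted to
    the progenitor reference codon usage lose translational supply after
    differentiation.
    """
    df = gene_table[["cai", "delta_sdr"]].dropna()
    if len(df) < 3:
        raise ValueError("need >= 3 genes with both CAI and delta_sdr")
    x = df["cai"].to_numpy(dtype=float)
    y = df["delta_sdr"].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in CAI or delta_sdr")
    r, p = stats.pearsonr(x, y)
    fit = stats.linregress(x, y)
    return CorrelationResult(
        r=float(r), p_value=float(p), slope=float(fit.slope),
        intercept=float(fit.intercept), n=len(df),
    )
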