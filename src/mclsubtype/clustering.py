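"""NMF consensus clustering of the lesion matrix.

The lesion score matrix (samples x lesions, entries {0,1,2}) is factorized
repeatedly under random nonnegative initialisations, each restart assigning
every sample to its argmax coefficient component. Co-assignment
frequencies across restarts form a per-K consensus matrix; the cophenetic
correlation of its average-linkage dendrogram (with silhouette as
tie-breaker) selects K over a scanned range, and the final labels come
from cutting that dendrogram.

The factorization minimises generalised Kullback-Leibler divergence by
multiplicative updates (tolerance 1e-6 on the relative objective change,
checked every 10 iterations; at most 2000 iterations). The update kernel
is implemented here directly so that the hundreds of restarts a consensus
run needs stay cheap; it follows the standard Lee-Seung KL rules and is
cross-checked against scikit-learn's KL solver in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.optimize import nnls
from scipy.spatial.distance import squareform
from scipy.stats import fisher_exact
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

from . import constants
from .encoding import LesionMatrix

_EPS = 1e-12


@dataclass
class ConsensusResult:
    """Outcome of an NMF consensus clustering run."""

    labels: pd.Series  # sample -> cluster (1..chosen_k)
    consensus: dict[int, np.ndarray]  # per-K samples x samples co-assignment
    cophenetic: dict[int, float]
    silhouette: dict[int, float]
    chosen_k: int
    basis: pd.DataFrame  # chosen-K H: components x lesions
    coefficients: pd.DataFrame  # chosen-K W: samples x components
    centroids: pd.DataFrame = field(default=None)  # cluster x components means

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels.index)


def _kl_divergence(X: np.ndarray, WH: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(X > 0, X * np.log((X + _EPS) / (WH + _EPS)), 0.0)
    return float(np.sum(term - X + WH))


def nmf_kl(
    X: np.ndarray,
    k: int,
    rng: np.random.Generator,
    *,
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> tuple[np.ndarray, np.ndarray, float]:
    """One KL-NMF fit X ~ W @ H from a random nonnegative initialisation.

    Returns (W, H, final KL objective). W is samples x k (per-sample
    coefficients), H is k x lesions (lesion basis). The basis H is drawn
    randomly while W starts at ones: a row-symmetric start makes every
    update exactly equivariant under sample reordering, so consensus
    matrices permute with the input rather than merely approximately.
    """
    n, m = X.shape
    W = np.ones((n, k))
    H = rng.random((k, m)) + 1e-3
    prev = None
    for it in range(1, max_iter + 1):
        WH = W @ H + _EPS
        W *= (X / WH) @ H.T / (H.sum(axis=1)[None, :] + _EPS)
        WH = W @ H + _EPS
        H *= W.T @ (X / WH) / (W.sum(axis=0)[:, None] + _EPS)
        if it % 10 == 0:
            obj = _kl_divergence(X, W @ H)
            if prev is not None and abs(prev - obj) <= tol * max(abs(prev), 1.0):
                break
            prev = obj
    return W, H, _kl_divergence(X, W @ H)


def cophenetic_coefficient(consensus: np.ndarray) -> float:
    """Cophenetic correlation of the consensus matrix.

    Pearson correlation between the cophenetic distances of the
    average-linkage dendrogram built on (1 - consensus) and the
    (1 - consensus) distances themselves. A constant distance matrix is
    degenerate and defined as 1 with a warning.
    """
    _check_consensus(consensus)
    dist = squareform(1.0 - consensus, checks=False)
    if np.allclose(dist, dist[0] if dist.size else 0.0):
        warnings.warn("constant consensus distances: cophenetic coefficient degenerate, "
                      "defined as 1", stacklevel=2)
        return 1.0
    Z = hierarchy.linkage(dist, method="average")
    coph, _ = hierarchy.cophenet(Z, dist)
    return float(coph)


def _check_consensus(consensus: np.ndarray) -> None:
    if consensus.ndim != 2 or consensus.shape[0] != consensus.shape[1]:
        raise ValueError("consensus must be square")
    if not np.allclose(consensus, consensus.T):
        raise ValueError("consensus must be symmetric")
    if not np.allclose(np.diag(consensus), 1.0):
        raise ValueError("consensus diagonal must be 1")
    if consensus.min() < -1e-12 or consensus.max() > 1 + 1e-12:
        raise ValueError("consensus entries must lie in [0,1]")


def _consensus_labels(consensus: np.ndarray, k: int) -> np.ndarray:
    dist = squareform(1.0 - consensus, checks=False)
    Z = hierarchy.linkage(dist, method="average")
    return hierarchy.fcluster(Z, t=k, criterion="maxclust")


def _silhouette(consensus: np.ndarray, labels: np.ndarray) -> float:
    if len(set(labels)) < 2:
        return float("nan")
    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    return float(silhouette_score(dist, labels, metric="precomputed"))


def nmf_consensus(
    matrix: LesionMatrix,
    k_range: range | tuple[int, ...] = range(constants.K_MIN, constants.K_MAX + 1),
    n_restarts: int = constants.N_RESTARTS,
    seed: int = 0,
    *,
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> ConsensusResult:
    """Consensus-cluster the lesion matrix over a range of K.

    For each K, ``n_restarts`` KL-NMF fits are run from random
    initialisations (restart r of K uses an independent child stream of
    ``seed``); restart labels are argmax coefficients, and the consensus
    matrix is the co-assignment frequency. chosen_k maximises the
    cophenetic coefficient, ties broken by higher silhouette then smaller
    K. Final labels cut the chosen-K consensus dendrogram; the basis and
    coefficients of the lowest-objective restart at chosen_k are kept for
    validation-cohort projection.
    """
    X = matrix.scores.to_numpy(dtype=float)
    n = X.shape[0]
    if X.size == 0 or not X.any():
        raise ValueError("lesion matrix is empty or all-zero")
    if (X < 0).any():
        raise ValueError("lesion matrix must be nonnegative")
    k_list = list(k_range)
    if not k_list:
        raise ValueError("empty K range")
    if max(k_list) > n - 1:
        raise ValueError(f"K={max(k_list)} exceeds n_samples-1={n - 1}")
    if min(k_list) < 2:
        raise ValueError("K must be >= 2")

    root = np.random.SeedSequence(seed)
    per_k_children = root.spawn(len(k_list))
    consensus: dict[int, np.ndarray] = {}
    coph: dict[int, float] = {}
    sil: dict[int, float] = {}
    best_fit: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    for ki, k in enumerate(k_list):
        streams = per_k_children[ki].spawn(n_restarts)
        co = np.zeros((n, n))
        best_obj = np.inf
        for r in range(n_restarts):
            rng = np.random.default_rng(streams[r])
            W, H, obj = nmf_kl(X, k, rng, tol=tol, max_iter=max_iter)
            assign = W.argmax(axis=1)
            co += assign[:, None] == assign[None, :]
            if obj < best_obj:
                best_obj = obj
                best_fit[k] = (W, H)
        co /= n_restarts
        np.fill_diagonal(co, 1.0)
        consensus[k] = co
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coph[k] = cophenetic_coefficient(co)
        sil[k] = _silhouette(co, _consensus_labels(co, k))

    # max cophenetic; ties -> higher silhouette, then smaller K
    chosen_k = max(
        k_list,
        key=lambda k: (round(coph[k], 12), round(np.nan_to_num(sil[k], nan=-2.0), 12), -k),
    )
    raw_labels = _consensus_labels(consensus[chosen_k], chosen_k)
    labels = pd.Series(raw_labels, index=matrix.scores.index, name="Cluster")

    W, H = best_fit[chosen_k]
    comp_names = [f"F{j + 1}" for j in range(chosen_k)]
    coeff = pd.DataFrame(W, index=matrix.scores.index, columns=comp_names)
    basis = pd.DataFrame(H, index=comp_names, columns=matrix.scores.columns)
    centroids = coeff.groupby(labels).mean()

    return ConsensusResult(
        labels=labels,
        consensus=consensus,
        cophenetic=coph,
        silhouette=sil,
        chosen_k=chosen_k,
        basis=basis,
        coefficients=coeff,
        centroids=centroids,
    )


def find_markers(
    matrix: LesionMatrix,
    labels: pd.Series,
    q_cutoff: float = constants.MARKER_Q_CUTOFF,
) -> pd.DataFrame:
    """Per-cluster lesion markers by one-sided Fisher's exact test.

    For every lesion x cluster, tests whether the lesion's presence
    (score >= 1) is more frequent inside the cluster than outside
    (alternative='greater'); Benjamini-Hochberg correction is applied
    across all lesion x cluster tests jointly. Rows with q < ``q_cutoff``
    are flagged as markers.
    """
    clusters = sorted(labels.unique())
    if len(clusters) < 2:
        raise ValueError("marker discovery needs at least two clusters")
    present = matrix.binarized().loc[labels.index]
    rows = []
    for lesion in present.columns:
        vec = present[lesion]
        for c in clusters:
            inside = labels == c
            a = int(vec[inside].sum())
            b = int(inside.sum() - a)
            cc = int(vec[~inside].sum())
            d = int((~inside).sum() - cc)
            _, p = fisher_exact([[a, b], [cc, d]], alternative="greater")
            rows.append((lesion, c, a, int(inside.sum()), cc, int((~inside).sum()), p))
    table = pd.DataFrame(
        rows, columns=["Lesion", "Cluster", "CountIn", "NIn", "CountOut", "NOut", "P"]
    )
    odds_num = table["CountIn"] * (table["NOut"] - table["CountOut"])
    odds_den = table["CountOut"] * (table["NIn"] - table["CountIn"])
    with np.errstate(divide="ignore", invalid="ignore"):
        table["OddsRatio"] = np.where(odds_den > 0, odds_num / odds_den, np.inf)
    _, q, _, _ = multipletests(table["P"], method="fdr_bh")
    table["Q"] = q
    table["Marker"] = table["Q"] < q_cutoff
    return table.sort_values(["Cluster", "Q", "Lesion"]).reset_index(drop=True)


def project_cohort(
    validation: LesionMatrix,
    trained: ConsensusResult,
) -> pd.Series:
    """Assign validation samples to the discovery clusters.

    Each validation sample's score vector, restricted to the lesions
    shared with the discovery matrix, is projected onto the trained lesion
    basis by nonnegative least squares; the sample takes the cluster of
    the nearest discovery centroid in coefficient space under cosine
    distance. All-zero samples are unassignable and labelled -1.
    """
    shared = [c for c in trained.basis.columns if c in validation.scores.columns]
    if not shared:
        raise ValueError("validation and discovery cohorts share no lesions")
    H = trained.basis[shared].to_numpy()
    V = validation.scores[shared].to_numpy(dtype=float)
    centroids = trained.centroids.to_numpy()
    cent_norm = np.linalg.norm(centroids, axis=1)

    out = np.empty(V.shape[0], dtype=int)
    for i, x in enumerate(V):
        if not x.any():
            out[i] = -1
            continue
        w, _ = nnls(H.T, x)
        wn = np.linalg.norm(w)
        if wn == 0:
            out[i] = -1
            continue
        cosine = 1.0 - (centroids @ w) / (cent_norm * wn + _EPS)
        out[i] = trained.centroids.index[int(np.argmin(cosine))]
    return pd.Series(out, index=validation.scores.index, name="Cluster")


def associate_outcome(labels: pd.Series, survival: pd.DataFrame):
    """Kaplan-Meier estimates per cluster and the multi-group log-rank test.

    ``survival`` must carry Time (positive) and Event (0/1) indexed by
    sample. Returns (km_table, logrank_result) where km_table stacks each
    cluster's KM survival function and logrank_result is the lifelines
    StatisticalResult (``.test_statistic``, ``.p_value``).
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    joined = survival.loc[labels.index]
    if (joined["Time"] <= 0).any():
        raise ValueError("survival times must be positive")
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValueError("outcome association needs at least two clusters")

    km_frames = []
    for c in sorted(counts.index):
        sel = labels == c
        kmf = KaplanMeierFitter(label=str(c))
        kmf.fit(joined.loc[sel, "Time"], joined.loc[sel, "Event"])
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["Time", "Survival"]
        sf.insert(0, "Cluster", c)
        km_frames.append(sf)
    km_table = pd.concat(km_frames, ignore_index=True)

    result = multivariate_logrank_test(joined["Time"], labels, joined["Event"])
    return km_table, result
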