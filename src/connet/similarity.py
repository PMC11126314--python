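"""Similarity among pre-processing pipelines: edge-wise correlation,
hierarchical clustering, bootstrap cluster stability and 2-D embedding.

Pipelines from different montages live on different node sets (contacts for
the common average, derived pairs for bipolar); their edge vectors are
aligned by identifying every bipolar derivative with its anchor (lower-
numbered) contact and restricting the compared pipelines to the common
contact set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .connectivity import ConnectivityNetwork, PipelineSpec, enumerate_pipelines
from .rereference import anchor_label

logger = logging.getLogger("connet")


class ComparabilityError(ValueError):
    pass


@dataclass
class SimilarityMatrix:
    """Pipeline x pipeline Pearson-r similarity, in canonical pipeline order."""

    S: np.ndarray
    pipelines: list[PipelineSpec]

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=float)
        n = len(self.pipelines)
        if self.S.shape != (n, n):
            raise ValueError("similarity matrix shape mismatch")

    @property
    def labels(self) -> list[str]:
        return [p.label for p in self.pipelines]


@dataclass
class ClusterResult:
    k: int
    labels: np.ndarray              # cluster id per pipeline
    linkage: np.ndarray | None = None
    stability: np.ndarray | None = None  # per reference cluster

    @property
    def mean_stability(self) -> float:
        return float(np.mean(self.stability)) if self.stability is not None else np.nan


# --------------------------------------------------------------------------
# Edge vectors and similarity
# --------------------------------------------------------------------------

def edge_vector(net: ConnectivityNetwork,
                node_map: dict[str, str] | None = None,
                restrict_to: list[str] | None = None) -> np.ndarray:
    """Upper-triangle edge weights in canonical (sorted anchor-label) order.

    ``node_map`` maps node names to alignment identities (default: the anchor
    contact, so "LA01-LA02" aligns with contact "LA01").  ``restrict_to``
    keeps only nodes whose identity is in the given set, which is how two
    pipelines on different montages are compared on their common contacts.
    """
    if node_map is None:
        node_map = {name: anchor_label(name) for name in net.nodes}
    ids = [node_map[name] for name in net.nodes]
    keep = [i for i, ident in enumerate(ids)
            if restrict_to is None or ident in restrict_to]
    if len(keep) < 2:
        raise ComparabilityError("fewer than 2 alignable nodes")
    order = sorted(keep, key=lambda i: ids[i])
    sub = net.W[np.ix_(order, order)]
    iu = np.triu_indices(len(order), k=1)
    return sub[iu]


def _pearson_pairwise(vectors: np.ndarray) -> np.ndarray:
    """Correlation matrix over rows, NaN-aware per pair (NaN edges are
    dropped pairwise); pairs with a constant vector get NaN."""
    n = vectors.shape[0]
    S = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = vectors[i], vectors[j]
            ok = np.isfinite(a) & np.isfinite(b)
            if ok.sum() < 3 or a[ok].std() == 0 or b[ok].std() == 0:
                S[i, j] = S[j, i] = np.nan
                continue
            r = np.corrcoef(a[ok], b[ok])[0, 1]
            S[i, j] = S[j, i] = r
    return S


def patient_similarity(nets: dict[PipelineSpec, ConnectivityNetwork],
                       pipelines: list[PipelineSpec] | None = None) -> SimilarityMatrix:
    """Pipeline x pipeline edge-weight correlation for one patient.

    Same-montage pairs are compared on their full shared edge set;
    cross-montage pairs on the edges of the common (anchor-aligned) contact
    set, dropped symmetrically from both.
    """
    if pipelines is None:
        pipelines = [p for p in enumerate_pipelines() if p in nets]
    schemes = {p.scheme for p in pipelines}
    identities = {}
    for scheme in schemes:
        net = nets[next(p for p in pipelines if p.scheme == scheme)]
        identities[scheme] = {anchor_label(n) for n in net.nodes}
    common = sorted(set.intersection(*identities.values()))
    if len(common) < 2:
        raise ComparabilityError("fewer than 2 contacts shared across montages")

    full_vec = {}
    common_vec = {}
    for p in pipelines:
        full_vec[p] = edge_vector(nets[p])
        common_vec[p] = edge_vector(nets[p], restrict_to=common)

    n = len(pipelines)
    S = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            pi, pj = pipelines[i], pipelines[j]
            if pi.scheme == pj.scheme:
                a, b = full_vec[pi], full_vec[pj]
            else:
                a, b = common_vec[pi], common_vec[pj]
            ok = np.isfinite(a) & np.isfinite(b)
            if ok.sum() < 3 or a[ok].std() == 0 or b[ok].std() == 0:
                logger.info("similarity undefined for %s vs %s", pi.label, pj.label)
                S[i, j] = S[j, i] = np.nan
                continue
            S[i, j] = S[j, i] = np.corrcoef(a[ok], b[ok])[0, 1]
    return SimilarityMatrix(S=S, pipelines=list(pipelines))


def pipeline_similarity(per_patient_nets: list[dict[PipelineSpec, ConnectivityNetwork]],
                        pipelines: list[PipelineSpec] | None = None
                        ) -> tuple[SimilarityMatrix, list[SimilarityMatrix]]:
    """Group similarity matrix: per-patient matrices averaged element-wise
    (plain mean of r values; undefined cells excluded per patient)."""
    per_patient = [patient_similarity(nets, pipelines) for nets in per_patient_nets]
    stack = np.stack([m.S for m in per_patient])
    with np.errstate(invalid="ignore"):
        mean_S = np.nanmean(stack, axis=0)
    return SimilarityMatrix(S=mean_S, pipelines=per_patient[0].pipelines), per_patient


# --------------------------------------------------------------------------
# Clustering
# --------------------------------------------------------------------------

def _linkage(S: np.ndarray) -> np.ndarray:
    D = 1.0 - S
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    D = np.clip(D, 0.0, None)
    return sch.linkage(squareform(D, checks=False), method="average")


def hierarchical_clusters(sim: SimilarityMatrix, k: int = 3) -> ClusterResult:
    """Agglomerative clustering with average linkage on distance 1 - r,
    cut at k clusters."""
    n = len(sim.pipelines)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range for {n} pipelines")
    Z = _linkage(sim.S)
    labels = sch.fcluster(Z, t=k, criterion="maxclust")
    return ClusterResult(k=k, labels=labels, linkage=Z)


def _jaccard(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.sum(a & b)
    union = np.sum(a | b)
    return inter / union if union else 0.0


def _cluster_sets(labels: np.ndarray) -> list[np.ndarray]:
    return [labels == c for c in np.unique(labels)]


def bootstrap_stability(per_patient_S: list[SimilarityMatrix], k: int,
                        n_boot: int = 1000, seed: int | None = None) -> ClusterResult:
    """Cluster stability under patient resampling.

    The reference clustering is taken from the full-cohort mean similarity;
    each bootstrap resamples patients with replacement, re-averages,
    re-clusters, and records per-reference-cluster maximum Jaccard overlap.
    Stability is the mean Jaccard over resamples, per cluster and overall.
    """
    if len(per_patient_S) < 2:
        raise ValueError("bootstrap stability needs >= 2 patients")
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    stack = np.stack([m.S for m in per_patient_S])
    with np.errstate(invalid="ignore"):
        full = np.nanmean(stack, axis=0)
    pipelines = per_patient_S[0].pipelines
    ref = hierarchical_clusters(SimilarityMatrix(full, pipelines), k)
    ref_sets = _cluster_sets(ref.labels)
    jac = np.zeros((n_boot, len(ref_sets)))
    n_pat = len(per_patient_S)
    for b in range(n_boot):
        idx = rng.integers(0, n_pat, size=n_pat)
        with np.errstate(invalid="ignore"):
            Sb = np.nanmean(stack[idx], axis=0)
        lab_b = hierarchical_clusters(SimilarityMatrix(Sb, pipelines), k).labels
        boot_sets = _cluster_sets(lab_b)
        for c, rs in enumerate(ref_sets):
            jac[b, c] = max(_jaccard(rs, bs) for bs in boot_sets)
    return ClusterResult(k=k, labels=ref.labels, linkage=ref.linkage,
                         stability=jac.mean(axis=0))


def select_n_clusters(per_patient_S: list[SimilarityMatrix],
                      k_candidates=range(2, 7), n_select: int = 20,
                      seed: int | None = None) -> int:
    """Pick the cluster count maximizing mean bootstrap stability (a small
    number of resamples is used for the sweep, as for model selection)."""
    best_k, best = None, -np.inf
    for i, k in enumerate(k_candidates):
        res = bootstrap_stability(per_patient_S, k, n_boot=n_select,
                                  seed=None if seed is None else seed + i)
        if res.mean_stability > best:
            best, best_k = res.mean_stability, k
    return best_k


# --------------------------------------------------------------------------
# Embedding
# --------------------------------------------------------------------------

def embed_2d(sim: SimilarityMatrix, perplexity: float = 10.0,
             seed: int | None = None) -> np.ndarray:
    """t-SNE of the pipelines on distance 1 - r; reproducible for fixed seed."""
    from sklearn.manifold import TSNE

    n = len(sim.pipelines)
    if perplexity >= (n - 1) / 3:
        raise ValueError(f"perplexity {perplexity} too large for {n} items")
    D = 1.0 - sim.S
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    D = np.clip(np.nan_to_num(D, nan=1.0), 0.0, None)
    tsne = TSNE(n_components=2, metric="precomputed", init="random",
                perplexity=perplexity, random_state=seed)
    return tsne.fit_transform(D)


# --------------------------------------------------------------------------
# Output helpers
# --------------------------------------------------------------------------

def similarity_frame(sim: SimilarityMatrix):
    import pandas as pd

    return pd.DataFrame(sim.S, index=sim.labels, columns=sim.labels)


def plot_similarity_heatmap(sim: SimilarityMatrix, ax=None):
    """Heatmap of the pipeline similarity matrix (rows/cols in canonical
    order)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 9))
    im = ax.imshow(sim.S, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(sim.labels)))
    ax.set_yticks(range(len(sim.labels)))
    ax.set_xticklabels(sim.labels, rotation=90, fontsize=5)
    ax.set_yticklabels(sim.labels, fontsize=5)
    ax.figure.colorbar(im, ax=ax, label="Pearson r")
    return ax
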