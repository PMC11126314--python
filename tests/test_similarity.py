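import numpy as np
import pytest

from connet.connectivity import ConnectivityNetwork, PipelineSpec, enumerate_pipelines
from connet.similarity import (
    ClusterResult,
    ComparabilityError,
    SimilarityMatrix,
    bootstrap_stability,
    edge_vector,
    embed_2d,
    hierarchical_clusters,
    patient_similarity,
    pipeline_similarity,
    select_n_clusters,
)


def net_from(W, nodes, spec=None):
    W = np.asarray(W, dtype=float)
    np.fill_diagonal(W, np.nan)
    return ConnectivityNetwork(nodes=list(nodes), W=W, spec=spec)


# --------------------------------------------------------------------------
# Edge vectors
# --------------------------------------------------------------------------

def test_edge_vector_length():
    W = np.arange(9).reshape(3, 3).astype(float)
    W = (W + W.T) / 2
    net = net_from(W, ["LA01", "LA02", "LA03"])
    assert edge_vector(net).shape == (3,)


def test_edge_vector_permutation_invariance(rng):
    nodes = ["LA01", "LA02", "LA03", "LB01"]
    W = rng.standard_normal((4, 4))
    W = (W + W.T) / 2
    net = net_from(W.copy(), nodes)
    perm = [2, 0, 3, 1]
    net_shuffled = net_from(W[np.ix_(perm, perm)].copy(),
                            [nodes[i] for i in perm])
    assert np.allclose(edge_vector(net), edge_vector(net_shuffled))


def test_edge_vector_anchor_alignment(rng):
    """Bipolar nodes are identified with their anchor contacts, and the
    comparison set is the common contacts."""
    car_nodes = ["LA01", "LA02", "LA03", "LA04"]
    bip_nodes = ["LA01-LA02", "LA02-LA03", "LA03-LA04"]
    Wc = rng.standard_normal((4, 4))
    Wc = (Wc + Wc.T) / 2
    Wb = rng.standard_normal((3, 3))
    Wb = (Wb + Wb.T) / 2
    car = net_from(Wc, car_nodes)
    bip = net_from(Wb, bip_nodes)
    common = sorted(set(n[:4] for n in car_nodes)
                    & {"LA01", "LA02", "LA03"})
    vc = edge_vector(car, restrict_to=common)
    vb = edge_vector(bip, restrict_to=common)
    assert vc.shape == vb.shape == (3,)  # C(3,2) aligned edges


def test_edge_vector_too_few_nodes():
    net = net_from(np.zeros((2, 2)), ["LA01", "LA02"])
    with pytest.raises(ComparabilityError):
        edge_vector(net, restrict_to=["LA01"])


# --------------------------------------------------------------------------
# Pipeline similarity
# --------------------------------------------------------------------------

def _toy_patient(rng, specs):
    """Three toy 'pipelines' on 4 shared nodes with hand-controllable W."""
    nodes = ["LA01", "LA02", "RA01", "RA02"]
    nets = {}
    for spec in specs:
        W = rng.standard_normal((4, 4))
        W = (W + W.T) / 2
        nets[spec] = net_from(W, nodes, spec)
    return nets


def test_similarity_self_and_affine(rng):
    specs = [PipelineSpec("car", "pearson"), PipelineSpec("car", "xcorr")]
    nets = _toy_patient(rng, specs)
    # second pipeline = affine transform of the first: r must be 1
    nets[specs[1]] = net_from(3.0 * nets[specs[0]].W + 0.5,
                              nets[specs[0]].nodes, specs[1])
    sim = patient_similarity(nets, pipelines=specs)
    assert sim.S[0, 0] == pytest.approx(1.0)
    assert sim.S[0, 1] == pytest.approx(1.0)


def test_similarity_matches_hand_computed(rng):
    specs = [PipelineSpec("car", "pearson"), PipelineSpec("car", "xcorr"),
             PipelineSpec("car", "pearson_sq")]
    nets = _toy_patient(rng, specs)
    sim = patient_similarity(nets, pipelines=specs)
    vecs = [edge_vector(nets[s]) for s in specs]
    oracle = np.corrcoef(np.stack(vecs))
    assert np.allclose(sim.S, oracle, rtol=1e-9)


def test_group_similarity_plain_mean(rng):
    specs = [PipelineSpec("car", "pearson"), PipelineSpec("car", "xcorr")]
    pats = [_toy_patient(rng, specs) for _ in range(3)]
    group, per_pat = pipeline_similarity(pats, pipelines=specs)
    stack = np.stack([m.S for m in per_pat])
    assert np.allclose(group.S, stack.mean(axis=0))
    assert np.allclose(np.diag(group.S), 1.0)
    assert np.allclose(group.S, group.S.T)


# --------------------------------------------------------------------------
# Clustering
# --------------------------------------------------------------------------

def planted_similarity(sizes, within=0.9, between=0.1, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    n = sum(sizes)
    labels = np.repeat(np.arange(len(sizes)), sizes)
    S = np.where(labels[:, None] == labels[None, :], within, between)
    S = S + noise * rng.standard_normal((n, n))
    S = (S + S.T) / 2
    np.fill_diagonal(S, 1.0)
    specs = enumerate_pipelines()[:n]
    return SimilarityMatrix(S=S, pipelines=specs), labels


def _partitions_equal(a, b):
    return len({(x, y) for x, y in zip(a, b)}) == len(set(a)) == len(set(b))


@pytest.mark.parametrize("sizes", [(10, 14), (8, 8, 8)])
def test_planted_partition_recovery(sizes):
    sim, truth = planted_similarity(sizes, noise=0.02)
    res = hierarchical_clusters(sim, k=len(sizes))
    assert _partitions_equal(res.labels, truth)


def test_singleton_clusters_at_k_equals_n():
    sim, _ = planted_similarity((4, 4))
    res = hierarchical_clusters(sim, k=8)
    assert len(set(res.labels)) == 8


def test_clustering_invariant_to_item_order(rng):
    sim, truth = planted_similarity((6, 6, 6), noise=0.05, seed=3)
    res = hierarchical_clusters(sim, k=3)
    perm = rng.permutation(18)
    sim_p = SimilarityMatrix(S=sim.S[np.ix_(perm, perm)],
                             pipelines=[sim.pipelines[i] for i in perm])
    res_p = hierarchical_clusters(sim_p, k=3)
    assert _partitions_equal(res_p.labels, res.labels[perm])


def test_cluster_k_bounds():
    sim, _ = planted_similarity((4, 4))
    with pytest.raises(ValueError):
        hierarchical_clusters(sim, k=9)


# --------------------------------------------------------------------------
# Bootstrap stability
# --------------------------------------------------------------------------

def test_stability_one_for_identical_patients():
    sim, _ = planted_similarity((6, 6, 6))
    res = bootstrap_stability([sim] * 5, k=3, n_boot=50, seed=0)
    assert res.mean_stability == pytest.approx(1.0)
    assert np.all(res.stability == 1.0)


def test_stability_low_for_structureless_noise():
    rng = np.random.default_rng(7)
    pats = []
    for _ in range(6):
        S = 0.3 * rng.standard_normal((20, 20))
        S = (S + S.T) / 2
        np.fill_diagonal(S, 1.0)
        pats.append(SimilarityMatrix(S=S, pipelines=enumerate_pipelines()[:20]))
    res = bootstrap_stability(pats, k=3, n_boot=100, seed=1)
    assert res.mean_stability < 0.6


def test_stability_seed_determinism():
    sim, _ = planted_similarity((6, 6), noise=0.3, seed=5)
    sims = [sim] * 4
    a = bootstrap_stability(sims, k=2, n_boot=30, seed=11)
    b = bootstrap_stability(sims, k=2, n_boot=30, seed=11)
    assert np.array_equal(a.stability, b.stability)


def test_select_n_clusters_finds_planted_k():
    rng = np.random.default_rng(2)
    pats = []
    for _ in range(5):
        sim, _ = planted_similarity((8, 8, 8), noise=0.05,
                                    seed=int(rng.integers(1 << 30)))
        pats.append(sim)
    assert select_n_clusters(pats, k_candidates=range(2, 6), n_select=20,
                             seed=0) in (2, 3)


# --------------------------------------------------------------------------
# Embedding
# --------------------------------------------------------------------------

def test_embedding_separates_planted_blocks():
    hits = 0
    for seed in range(10):
        sim, truth = planted_similarity((8, 8, 8), noise=0.02, seed=seed)
        xy = embed_2d(sim, perplexity=5.0, seed=seed)
        d = np.linalg.norm(xy[:, None] - xy[None, :], axis=-1)
        same = truth[:, None] == truth[None, :]
        off = ~np.eye(len(truth), dtype=bool)
        if d[same & off].mean() < d[~same].mean():
            hits += 1
    assert hits >= 9


def test_embedding_deterministic_for_seed():
    sim, _ = planted_similarity((8, 8), noise=0.05)
    a = embed_2d(sim, perplexity=4.0, seed=3)
    b = embed_2d(sim, perplexity=4.0, seed=3)
    assert np.array_equal(a, b)


def test_embedding_duplicates_are_nearest_pair():
    """A duplicated pipeline embeds closest to its twin (t-SNE's point-wise
    repulsion keeps even exact duplicates a small finite distance apart, so
    the assertable property is nearest-neighbourhood, bounded well under the
    embedding diameter)."""
    rng = np.random.default_rng(0)
    n = 16
    S = 0.5 * rng.standard_normal((n, n))
    S = (S + S.T) / 2
    np.fill_diagonal(S, 1.0)
    S[1, :] = S[0, :]
    S[:, 1] = S[:, 0]
    S[0, 1] = S[1, 0] = S[1, 1] = 1.0
    sim = SimilarityMatrix(S=S, pipelines=enumerate_pipelines()[:n])
    for seed in range(3):
        xy = embed_2d(sim, perplexity=4.0, seed=seed)
        d = np.linalg.norm(xy[:, None] - xy[None, :], axis=-1)
        off = d[np.triu_indices(n, 1)]
        assert d[0, 1] == off.min()
        assert d[0, 1] < 0.15 * d.max()


def test_embedding_perplexity_bound():
    sim, _ = planted_similarity((8, 8))
    with pytest.raises(ValueError):
        embed_2d(sim, perplexity=10.0, seed=0)
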