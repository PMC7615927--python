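"""RN graph, Moran's I and Moran eigenvector maps."""

import numpy as np
import pytest

from macrodiv.predictors import haversine_km
from macrodiv.spatial import (
    SpatialWeights,
    mem_eigenvectors,
    moran_i,
    rn_graph,
    select_mems,
)


def test_rn_graph_triangle_drops_longest_side():
    # hand lune test: for 3 points the strictly longest side has the third
    # point inside its lune, so the RN graph keeps exactly the two shorter
    # sides
    pts = [(0.0, 0.0), (0.0, 1.0), (1.0, 0.3)]
    W = rn_graph(pts)
    d = {
        (i, j): haversine_km(pts[i], pts[j])
        for i in range(3)
        for j in range(i + 1, 3)
    }
    longest = max(d, key=d.get)
    assert W.adjacency.sum() == 4  # two undirected edges
    assert W.adjacency[longest] == 0


def test_rn_graph_matches_lune_condition_oracle(rng):
    pts = rng.uniform(-20, 20, (15, 2))
    W = rn_graph(pts)
    n = 15
    D = np.array([[haversine_km(pts[i], pts[j]) for j in range(n)] for i in range(n)])
    for i in range(n):
        for j in range(i + 1, n):
            lune_empty = not any(
                max(D[i, k], D[j, k]) < D[i, j] for k in range(n) if k not in (i, j)
            )
            assert bool(W.adjacency[i, j]) == lune_empty


def test_rn_graph_collinear_points_form_chain():
    pts = [(0.0, 0.0), (0.0, 1.0), (0.0, 2.0), (0.0, 3.0)]
    W = rn_graph(pts)
    expected = np.zeros((4, 4))
    for i in range(3):
        expected[i, i + 1] = expected[i + 1, i] = 1
    assert np.array_equal(W.adjacency, expected)


def test_rn_graph_order_invariant_and_subgraph_of_gabriel(rng):
    pts = rng.uniform(-30, 30, (25, 2))
    W = rn_graph(pts)
    perm = rng.permutation(25)
    Wp = rn_graph(pts[perm])
    assert np.array_equal(W.adjacency[np.ix_(perm, perm)], Wp.adjacency)
    # classical containment: RN graph is a subgraph of the Gabriel graph
    n = 25
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                D[i, j] = haversine_km(pts[i], pts[j])
    for i, j in W.edge_list():
        gabriel = all(
            D[i, k] ** 2 + D[j, k] ** 2 >= D[i, j] ** 2
            for k in range(n)
            if k not in (i, j)
        )
        assert gabriel


def test_rn_graph_jitters_duplicates():
    pts = [(0.0, 0.0), (0.0, 0.0), (1.0, 1.0), (2.0, 0.0)]
    with pytest.warns(UserWarning, match="jitter"):
        W = rn_graph(pts)
    assert W.n == 4


def test_moran_matches_r_reference():
    """Frozen output of the R tree/stats implementation (row-normalized
    weights, randomization variance) on a fixed 8-node fixture."""
    x = np.array([0.5, 1.2, -0.3, 2.2, 1.1, -0.7, 0.4, 1.9])
    A = np.zeros((8, 8))
    for i in range(7):
        A[i, i + 1] = A[i + 1, i] = 1
    A[0, 4] = A[4, 0] = 1
    m = moran_i(x, A)
    assert m.observed_i == pytest.approx(-0.318136653223, abs=1e-10)
    assert m.expected_i == pytest.approx(-1 / 7)
    assert np.sqrt(m.variance) == pytest.approx(0.324918208947, abs=1e-10)
    assert m.p_value == pytest.approx(0.589571330113, abs=1e-10)


def test_moran_equals_double_sum_oracle(rng):
    for _ in range(25):
        n = int(rng.integers(6, 15))
        A = (rng.random((n, n)) < 0.4).astype(float)
        A = np.triu(A, 1)
        A = A + A.T
        if A.sum() == 0 or np.any(A.sum(1) == 0):
            continue
        x = rng.normal(size=n)
        W = A / A.sum(axis=1, keepdims=True)
        z = x - x.mean()
        num = sum(W[i, j] * z[i] * z[j] for i in range(n) for j in range(n))
        expected = n / W.sum() * num / (z @ z)
        assert moran_i(x, A).observed_i == pytest.approx(expected, abs=1e-12)


def test_moran_positive_on_smooth_gradient():
    A = np.zeros((12, 12))
    for i in range(11):
        A[i, i + 1] = A[i + 1, i] = 1
    m = moran_i(np.arange(12.0), A)
    assert m.observed_i > 0 and m.p_value < 0.01


def test_moran_contract_errors():
    A = np.eye(6) * 0
    with pytest.raises(ValueError, match="zero total weight"):
        moran_i(np.arange(6.0), A)
    A2 = np.zeros((6, 6))
    A2[0, 1] = A2[1, 0] = 1
    A2[2, 3] = A2[3, 2] = 1
    A2[4, 5] = A2[5, 4] = 1
    with pytest.raises(ValueError, match="constant"):
        moran_i(np.ones(6), A2)


def test_mem_construction_properties(rng):
    pts = rng.uniform(-40, 40, (30, 2))
    E = mem_eigenvectors(rn_graph(pts))
    V = E.vectors
    assert np.abs(V.sum(axis=0)).max() < 1e-8          # centred
    G = V.T @ V
    assert np.abs(G - np.eye(G.shape[0])).max() < 1e-8  # orthonormal
    assert np.all(np.diff(E.eigenvalues) <= 1e-12)      # descending order
    assert E.names[0] == "MEM1"


def test_mem1_on_chain_is_coarsest_pattern():
    """On a chain the leading eigenvector of the doubly-centred adjacency is
    the coarsest wave: exactly one sign change along the chain."""
    A = np.zeros((10, 10))
    for i in range(9):
        A[i, i + 1] = A[i + 1, i] = 1
    E = mem_eigenvectors(A)
    m1 = E.vectors[:, 0]
    sign_changes = int(np.sum(np.diff(np.sign(m1)) != 0))
    assert sign_changes == 1


def test_mem_saturation_absorbs_autocorrelation(rng):
    pts = rng.uniform(-40, 40, (30, 2))
    W = rn_graph(pts)
    E = mem_eigenvectors(W)
    x = rng.normal(size=30) + 2.0 * E.vectors[:, 0]
    D = np.column_stack([np.ones(30), E.vectors])
    coef, *_ = np.linalg.lstsq(D, x, rcond=None)
    resid = x - D @ coef
    # residuals after projecting out the full MEM basis: essentially no
    # structure left for Moran's I beyond its null expectation
    m = moran_i(resid + rng.normal(0, 1e-8, 30), W)
    assert abs(m.observed_i - m.expected_i) < 2 * np.sqrt(m.variance)


def planted_provider(base):
    def provider(M, names):
        if M is None:
            return base
        D = np.column_stack([np.ones(len(base)), M])
        coef, *_ = np.linalg.lstsq(D, base, rcond=None)
        return base - D @ coef

    return provider


def test_select_mems_recovers_planted_vector(rng):
    pts = rng.uniform(-40, 40, (40, 2))
    W = rn_graph(pts)
    E = mem_eigenvectors(W)
    signal = E.vectors[:, 2] * np.sqrt(39)  # MEM3, unit variance
    hits = 0
    for trial in range(20):
        base = signal + np.random.default_rng(trial).normal(0, 0.3, 40)
        sel, trace = select_mems(planted_provider(base), E, W)
        hits += bool(sel) and sel[0] == "MEM3"
        assert {"step", "MEM", "moran_i", "p"} <= set(trace.columns)
    assert hits >= 19


def test_select_mems_null_returns_little(rng):
    pts = rng.uniform(-40, 40, (40, 2))
    W = rn_graph(pts)
    E = mem_eigenvectors(W)
    base = rng.normal(size=40)
    sel, trace = select_mems(planted_provider(base), E, W)
    assert len(sel) <= 1
    assert trace["p"].iloc[-1] >= 0.05 or len(sel) == 0


def test_select_mems_deterministic(rng):
    pts = rng.uniform(-40, 40, (30, 2))
    W = rn_graph(pts)
    E = mem_eigenvectors(W)
    base = E.vectors[:, 1] * np.sqrt(29) + np.random.default_rng(5).normal(0, 0.4, 30)
    s1, t1 = select_mems(planted_provider(base), E, W)
    s2, t2 = select_mems(planted_provider(base), E, W)
    assert s1 == s2 and t1.equals(t2)


def test_spatial_weights_validation():
    with pytest.raises(ValueError, match="symmetric"):
        SpatialWeights(np.array([[0, 1], [0, 0]]), np.zeros((2, 2)))
    with pytest.raises(ValueError, match="diagonal"):
        SpatialWeights(np.eye(3), np.zeros((3, 2)))
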