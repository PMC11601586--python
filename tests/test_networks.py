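"""Definitive assignment, nested factorization and subnetwork assembly.

Oracles are brute-force reimplementations (per-gene loops, explicit edge
scans) on small inputs.
"""

import networkx as nx
import numpy as np
import pytest

from rewirekit import (
    build_subnetwork,
    definitive_assignment,
    make_truth,
    median_nonzero_filter,
    nested_love,
    principal_split,
    simulate_gaussian,
    top_features,
)
from rewirekit.love import LoveModel

from conftest import build_matrix


def small_model(A):
    A = np.asarray(A, dtype=float)
    return LoveModel(
        K=A.shape[1],
        pure_sets=[[0, 1], [2, 3]],
        allocation=A,
        latent_cov=np.eye(A.shape[1]),
        delta=0.1,
        lam=0.0,
    )


def test_definitive_assignment_against_per_gene_loop(rng):
    A = rng.normal(size=(30, 4))
    A[5] = 0.0  # unassigned row
    A[6] = [0.5, -0.5, 0.1, 0.0]  # |weight| tie -> lowest factor index
    got = definitive_assignment(A)
    for g in range(30):
        if np.all(A[g] == 0):
            assert got[g] == -1
        else:
            best = max(range(4), key=lambda f: (abs(A[g, f]), -f))
            assert got[g] == best
    with pytest.raises(ValueError, match="genes x factors"):
        definitive_assignment(np.zeros(5))


def test_principal_split_returns_two_largest_groups():
    A = np.zeros((7, 3))
    A[[0, 1], 0] = 1.0            # factor 0: two pure genes
    A[2, 1], A[3, 1] = 1.0, -1.0  # factor 1: two pure genes ...
    A[4] = [0.1, 0.8, 0.1]        # ... plus a mixed gene -> three members
    A[[5, 6], 2] = 1.0            # factor 2: two pure genes
    model = LoveModel(K=3, pure_sets=[[0, 1], [2, 3], [5, 6]], allocation=A,
                      latent_cov=np.eye(3), delta=0.1, lam=0.0)
    g1, g2 = principal_split(model)
    assert set(g1) == {2, 3, 4}  # largest group is factor 1
    assert set(g2) == {0, 1}     # size tie between factors 0 and 2 -> lower index

    B = np.zeros((4, 1))
    B[[0, 1], 0] = 1.0
    B[2, 0], B[3, 0] = 0.4, -0.2
    single = LoveModel(K=1, pure_sets=[[0, 1]], allocation=B,
                       latent_cov=np.eye(1), delta=0.1, lam=0.0)
    with pytest.raises(ValueError, match="single factor"):
        principal_split(single)


def test_top_features_matches_brute_force(rng):
    A = rng.normal(size=(25, 3))
    model = LoveModel(
        K=3, pure_sets=[[0], [1], [2]],
        allocation=np.vstack([np.eye(3), A[3:]]),
        latent_cov=np.eye(3), delta=0.1, lam=0.0,
    )
    k = 4
    got = top_features(model, k=k)
    assign = definitive_assignment(model.allocation)
    for f in range(3):
        members = [g for g in range(25) if assign[g] == f]
        expected = sorted(members, key=lambda g: (-abs(model.allocation[g, f]), g))[:k]
        assert got[f] == expected


def test_median_nonzero_filter_requires_low_in_both_conditions():
    # gene 'lo_both' is bottom-quartile in both conditions -> dropped;
    # 'lo_one' is low only under condition 0 -> kept; zeros are ignored
    # when computing medians.
    genes = ["lo_both", "lo_one", "mid", "hi", "top"]
    cond0 = build_matrix(
        np.array(
            [
                [0.1, 0.2, 1.0, 2.0, 3.0],
                [0.1, 0.0, 1.0, 2.0, 3.0],
                [0.0, 0.2, 1.0, 2.0, 3.0],
            ]
        ),
        gene_ids=genes,
        normalized=True,
    )
    cond1 = build_matrix(
        np.array(
            [
                [0.1, 5.0, 1.0, 2.0, 3.0],
                [0.1, 5.0, 1.0, 2.0, 3.0],
                [0.1, 5.0, 1.0, 2.0, 3.0],
            ]
        ),
        gene_ids=genes,
        normalized=True,
    )
    kept = median_nonzero_filter(cond0, cond1, genes, q=0.25)
    assert kept == ["lo_one", "mid", "hi", "top"]
    assert median_nonzero_filter(cond0, cond1, [], q=0.25) == []


def test_subnetwork_logic_matches_edge_scan():
    ppi = nx.Graph(
        [("A", "B"), ("B", "C"), ("C", "D"), ("A", "C"), ("D", "E")]
    )
    markers = ["a", "c"]  # case-insensitive match to A, C
    for logic in ("OR", "AND"):
        net = build_subnetwork(markers, ppi, logic=logic)
        expected = set()
        for u, v in ppi.edges():
            hits = (u in {"A", "C"}) + (v in {"A", "C"})
            if (hits >= 1 if logic == "OR" else hits == 2):
                expected.add(frozenset((u, v)))
        assert set(map(frozenset, net.graph.edges())) == expected
        assert net.graph.nodes["A"]["role"] == "marker"
    orr = build_subnetwork(markers, ppi, logic="OR")
    assert orr.graph.nodes["B"]["role"] == "interactor"
    with pytest.raises(ValueError, match="logic"):
        build_subnetwork(markers, ppi, logic="XOR")
    with pytest.raises(ValueError, match="non-empty"):
        build_subnetwork([], ppi)
    assert build_subnetwork(["zzz"], ppi).n_nodes == 0


def test_subnetwork_intensity_is_group_mean_expression():
    ppi = nx.Graph([("A", "B")])
    X = build_matrix(np.array([[1.0, 3.0], [3.0, 5.0]]), gene_ids=["a", "b"],
                     normalized=True)
    net = build_subnetwork(["a"], ppi, logic="OR", X_group=X)
    assert net.graph.nodes["A"]["intensity"] == pytest.approx(2.0)
    assert net.graph.nodes["B"]["intensity"] == pytest.approx(4.0)


def test_nested_love_refits_groups_and_skips_small_ones(caplog):
    truth = make_truth(p=60, K=4, pure_per_factor=5, n_mixed=40,
                       signal_factors=(), interaction_pairs=(), seed=2)
    X, _, _ = simulate_gaussian(truth, 800, seed=4)
    groups = {
        "factor0": [g for g in range(60) if truth.A_true[g, 0] != 0],
        "tiny": [0, 1, 2],
    }
    models = nested_love(X, groups, delta_grid=(0.05, 0.1, 0.2),
                         lambda_grid=(0.0, 0.05), seed=0, min_genes=10)
    assert set(models) == {"factor0"}
    assert models["factor0"].n_genes == len(groups["factor0"])
    assert models["factor0"].K >= 1
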