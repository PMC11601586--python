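"""QC, normalization, differential expression and enrichment.

Statistical routines are checked against independent implementations:
sklearn's ROC AUC, scipy's exact Mann-Whitney / Fisher tests, and a
hand-written Benjamini-Hochberg.
"""

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import roc_auc_score

from rewirekit import (
    de_significant,
    fisher_enrichment,
    gene_condition_auc,
    normalize_log,
    qc_filter_cells,
    read_gmt,
    sparsity_filter,
    wilcoxon_de,
)
from rewirekit.preprocess import _exact_ranksum_p, _ranksum_p

from conftest import build_matrix


def test_qc_removes_low_quality_cells():
    # cell 0: 1 detected gene; cell 1: mito-dominated; cell 2: healthy
    values = np.array(
        [
            [5, 0, 0, 0],
            [1, 1, 9, 0],
            [2, 3, 1, 4],
        ],
        dtype=float,
    )
    X = build_matrix(values, gene_ids=["a", "b", "MT-co1", "d"], condition=[0, 1, 1])
    kept = qc_filter_cells(X, min_genes=1, max_genes=10, max_mito_frac=0.5)
    assert list(kept.cell_ids) == ["c2"]
    with pytest.raises(ValueError, match="removed all"):
        qc_filter_cells(X, min_genes=100, max_genes=101, max_mito_frac=0.5)


def test_qc_requires_raw_counts():
    X = build_matrix(np.ones((3, 3)), normalized=True)
    with pytest.raises(ValueError, match="raw counts"):
        qc_filter_cells(X)


def test_normalization_formula_and_guards():
    values = np.array([[1.0, 3.0], [2.0, 2.0]])
    X = build_matrix(values)
    out = normalize_log(X, scale=100.0)
    expected = np.log1p(100.0 * values / values.sum(axis=1, keepdims=True))
    assert np.allclose(out.values, expected)
    assert out.normalized
    with pytest.raises(ValueError, match="already normalized"):
        normalize_log(out)
    with pytest.raises(ValueError, match="zero-total"):
        normalize_log(build_matrix(np.array([[0.0, 0.0], [1.0, 1.0]])))


def test_sparsity_filter_drops_genes_then_cells():
    # gene 2 is zero in 3/4 cells (0.75 > 0.5 -> dropped); after that
    # cell 3 is zero on every remaining gene and is dropped too.
    values = np.array(
        [
            [1, 1, 1],
            [1, 2, 0],
            [2, 1, 0],
            [0, 0, 0],
        ],
        dtype=float,
    )
    X = build_matrix(values)
    out = sparsity_filter(X, gene_zero_max=0.5, cell_zero_max=0.5)
    assert list(out.gene_ids) == ["g0", "g1"]
    assert list(out.cell_ids) == ["c0", "c1", "c2"]
    with pytest.raises(ValueError, match="removed everything"):
        sparsity_filter(build_matrix(np.zeros((2, 2)) + np.eye(2)), gene_zero_max=0.1,
                        cell_zero_max=0.1)


def test_condition_auc_matches_sklearn(rng):
    y = rng.integers(0, 2, size=60)
    y[:2] = [0, 1]
    values = rng.poisson(3.0, size=60).astype(float)  # ties included
    assert gene_condition_auc(values, y) == pytest.approx(roc_auc_score(y, values))
    assert gene_condition_auc(np.ones(60), y) == 0.5
    with pytest.raises(ValueError, match="non-empty"):
        gene_condition_auc(values, np.zeros(60, dtype=int))


def test_exact_ranksum_matches_scipy_exact_enumeration(rng):
    a = rng.normal(size=6)
    b = rng.normal(size=5) + 0.8
    mine = _exact_ranksum_p(a, b)
    ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
    assert mine == pytest.approx(float(ref))


def test_exact_ranksum_handles_ties_via_permutation_null():
    a = np.array([1.0, 2.0, 2.0, 5.0])
    b = np.array([2.0, 3.0, 4.0])

    # two-sided by deviation of U from its null mean (the documented
    # convention), as an exact permutation test on scipy's U statistic
    def u_dev(x, y):
        u = stats.mannwhitneyu(x, y, alternative="two-sided").statistic
        return abs(u - len(x) * len(y) / 2)

    ref = stats.permutation_test(
        (a, b), u_dev, permutation_type="independent",
        alternative="greater", n_resamples=100_000,
    ).pvalue
    assert _exact_ranksum_p(a, b) == pytest.approx(float(ref))


def test_ranksum_dispatch_small_vs_large():
    rng = np.random.default_rng(3)
    small_a, small_b = rng.normal(size=7), rng.normal(size=8)
    assert _ranksum_p(small_a, small_b) == pytest.approx(
        _exact_ranksum_p(small_a, small_b)
    )
    big_a, big_b = rng.normal(size=30), rng.normal(size=30) + 1
    ref = stats.mannwhitneyu(
        big_a, big_b, alternative="two-sided", method="asymptotic",
        use_continuity=False,
    ).pvalue
    assert _ranksum_p(big_a, big_b) == pytest.approx(float(ref))
    assert _ranksum_p(np.ones(3), np.ones(4)) == 1.0


def test_differential_expression_direction_and_bh(rng):
    n = 40
    y = np.repeat([0, 1], n // 2)
    up = np.concatenate([rng.poisson(1.0, n // 2), rng.poisson(6.0, n // 2)])
    flat = rng.poisson(2.0, n)
    X = build_matrix(
        np.log1p(np.column_stack([up, flat]).astype(float)),
        condition=y,
        normalized=True,
    )
    de = wilcoxon_de(X)
    assert de.lnfc[0] > 0 and de.p_value[0] < 0.01
    # independent BH: padj_i = min_{j >= i} p_(j) * m / rank_j, then clip
    order = np.argsort(de.p_value)
    m = len(de.p_value)
    stairs = de.p_value[order] * m / (np.arange(m) + 1)
    bh = np.minimum.accumulate(stairs[::-1])[::-1]
    expected = np.empty(m)
    expected[order] = np.minimum(bh, 1.0)
    assert np.allclose(de.p_adjusted, np.maximum(expected, de.p_value))
    up_genes, down_genes = de_significant(de, p_max=0.05, lnfc_min=0.1)
    assert "g0" in up_genes and "g1" not in up_genes + down_genes


def test_enrichment_matches_fisher_exact(tmp_path):
    universe = [f"g{i}" for i in range(40)]
    hits = universe[:10]
    pathways = {"pw_hit": set(universe[:8]) | {"outside"}, "pw_miss": set(universe[30:])}
    table = fisher_enrichment(hits, universe, pathways, fdr_max=0.1)
    row = table.set_index("pathway").loc["pw_hit"]
    overlap = len(set(hits) & set(universe[:8]))
    in_pw = 8  # 'outside' is not in the universe and must be ignored
    ref = stats.fisher_exact(
        [[overlap, in_pw - overlap], [10 - overlap, 40 - in_pw - (10 - overlap)]],
        alternative="greater",
    )[1]
    assert row["p"] == pytest.approx(float(ref))
    assert row["overlap"] == overlap and row["size"] == in_pw
    assert bool(row["significant"])
    with pytest.raises(ValueError, match="subset"):
        fisher_enrichment(["nope"], universe, pathways)

    gmt = tmp_path / "sets.gmt"
    gmt.write_text("pw1\tdesc\tg1\tg2\nshort\tonly-two-fields\n")
    assert read_gmt(gmt) == {"pw1": {"g1", "g2"}}
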