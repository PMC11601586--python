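"""Shared fixtures and builders for the test suite."""

import numpy as np
import pytest

from rewirekit import ExpressionMatrix


def build_matrix(
    values,
    condition=None,
    gene_ids=None,
    cell_ids=None,
    cell_type=None,
    sample_id=None,
    dataset_tag="T",
    normalized=False,
):
    """ExpressionMatrix with auto-generated annotations where omitted."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    if condition is None:
        condition = np.arange(n) % 2
    if gene_ids is None:
        gene_ids = np.array([f"g{j}" for j in range(p)], dtype=object)
    if cell_ids is None:
        cell_ids = np.array([f"c{i}" for i in range(n)], dtype=object)
    if cell_type is None:
        cell_type = np.array(["epithelial"] * n, dtype=object)
    if sample_id is None:
        sample_id = np.array([f"m{i % 4}" for i in range(n)], dtype=object)
    return ExpressionMatrix(
        values=values,
        gene_ids=np.asarray(gene_ids, dtype=object),
        cell_ids=np.asarray(cell_ids, dtype=object),
        condition=np.asarray(condition, dtype=int),
        cell_type=np.asarray(cell_type, dtype=object),
        sample_id=np.asarray(sample_id, dtype=object),
        dataset_tag=dataset_tag,
        normalized=normalized,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def matrix_factory():
    return build_matrix


@pytest.fixture
def counts_matrix(rng):
    """A small raw-count matrix with both conditions present."""
    values = rng.poisson(2.0, size=(40, 12)).astype(float)
    values[:, 0] += 1  # guarantee a non-constant, never-all-zero gene
    return build_matrix(values)
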