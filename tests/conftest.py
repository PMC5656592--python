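import numpy as np
import pytest

from refreo import ExpressionMatrix


def make_matrix(values, gene_ids=None, group=None, age=None, subtype=None,
                dataset="test"):
    """Build an ExpressionMatrix from a 2-D list with generated ids."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n_genes)]
    sample_ids = [f"s{j}" for j in range(n_samples)]
    return ExpressionMatrix(gene_ids, sample_ids, values, group=group, age=age,
                            subtype=subtype, dataset=dataset)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def tiny_purified(rng):
    """6 genes x (3 subtypes x 3 samples) with well-spaced means."""
    means = np.linspace(2, 12, 6)
    values = means[:, None] + 0.2 * rng.standard_normal((6, 9))
    subtype = np.repeat(["a", "b", "c"], 3)
    return make_matrix(values, subtype=subtype)


def brute_stable_pairs(matrix, frac=1.0):
    """Exhaustive nested-loop oracle for stable_pairs (canonical keys)."""
    from refreo.matrix import gene_sort_key

    labels = [s for s in np.unique(matrix.subtype) if s != "none"]
    out = {}
    genes = list(matrix.gene_ids)
    order = sorted(range(len(genes)), key=lambda i: gene_sort_key(genes[i]))
    for pi in range(len(order)):
        for pj in range(pi + 1, len(order)):
            i, j = order[pi], order[pj]
            ok_pos, ok_neg = True, True
            for s in labels:
                cols = np.flatnonzero(matrix.subtype == s)
                npos = sum(matrix.values[i, c] > matrix.values[j, c] for c in cols)
                nneg = sum(matrix.values[i, c] < matrix.values[j, c] for c in cols)
                n = len(cols)
                if not (npos >= frac * n - 1e-9 and npos > nneg):
                    ok_pos = False
                if not (nneg >= frac * n - 1e-9 and nneg > npos):
                    ok_neg = False
            if ok_pos:
                out[(genes[i], genes[j])] = 1
            elif ok_neg:
                out[(genes[i], genes[j])] = -1
    return out
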