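import numpy as np
import pandas as pd
import pytest

import cellvec as cv


@pytest.fixture(scope="session")
def small_sim():
    """3 planted clusters x 50 cells, 300 genes; shared across tests."""
    design = cv.SimulationDesign.default(
        n_clusters=3, n_cells_per_cluster=50, n_genes=300, n_markers=20,
        marker_fold=8.0, aggressive="C1", hazard_coef=3.0, n_bulk=120,
        censor_rate=0.3, seed=7,
    )
    E, labels = cv.simulate_counts(design)
    return design, E, labels


@pytest.fixture(scope="session")
def small_scaled(small_sim):
    _, E, _ = small_sim
    return cv.preprocess_chain(E, min_genes_per_cell=10, min_cells_per_gene=3, n_top_hvg=100)


@pytest.fixture(scope="session")
def small_corpus(small_scaled):
    return cv.build_documents(small_scaled, seed=11)


@pytest.fixture(scope="session")
def small_model(small_corpus):
    return cv.pretrain(small_corpus, dim=16, window=5, epochs=8, seed=11)


@pytest.fixture(scope="session")
def small_embeddings(small_model, small_corpus):
    return cv.infer_vectors(small_model, small_corpus, infer_epochs=8, seed=11)


@pytest.fixture(scope="session")
def blob_embeddings():
    """Two far-separated Gaussian blobs in 10-D embedding space."""
    rng = np.random.default_rng(3)
    a = rng.normal(loc=0.0, scale=0.05, size=(40, 10)) + np.r_[np.ones(5), np.zeros(5)]
    b = rng.normal(loc=0.0, scale=0.05, size=(40, 10)) + np.r_[np.zeros(5), np.ones(5)]
    ids = [f"a{i}" for i in range(40)] + [f"b{i}" for i in range(40)]
    truth = pd.Series(["A"] * 40 + ["B"] * 40, index=ids)
    return cv.EmbeddingMatrix(ids=ids, vectors=np.vstack([a, b])), truth


def toy_matrix(values, layer="raw", unit="umi", genes=None, cells=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    cells = cells or [f"c{i}" for i in range(values.shape[1])]
    return cv.ExpressionMatrix(values, genes, cells, layer=layer, unit=unit)
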