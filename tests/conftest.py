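import numpy as np
import pytest

from crispr_coverage import ExperimentDesign, GuideLibrary


@pytest.fixture
def default_design() -> ExperimentDesign:
    return ExperimentDesign(seed=7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_library(freqs, genes_of, eps_edit=None, gene_names=None) -> GuideLibrary:
    """Small hand-specified library for targeted tests."""
    freqs = np.asarray(freqs, dtype=float)
    genes_of = np.asarray(genes_of, dtype=np.int64)
    n_genes = int(genes_of.max()) + 1
    if gene_names is None:
        gene_names = tuple(f"G{i + 1}" for i in range(n_genes))
    if eps_edit is None:
        eps_edit = np.ones_like(freqs)
    return GuideLibrary(
        genes=tuple(gene_names),
        guides=tuple(f"g{i}" for i in range(len(freqs))),
        gene_of=genes_of,
        freq=freqs / freqs.sum(),
        eps_edit=np.asarray(eps_edit, dtype=float),
    )


@pytest.fixture
def uniform_20x6() -> GuideLibrary:
    """120 guides over 20 genes, uniform frequencies, perfect editing."""
    return make_library(np.ones(120), np.repeat(np.arange(20), 6))
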