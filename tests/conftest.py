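"""Shared fixtures: a hand-built toy annotation and a small simulated study."""

import pytest

from srnakit import GeneModel, SampleSpec, SimConfig, build_truth, simulate_library


@pytest.fixture(scope="session")
def toy_genes():
    """Hand-placed loci on two chromosomes, including a piRNA locus nested in an mRNA."""
    return [
        GeneModel("gA", "chr1", 100, 600, "+", "mRNA", "WAGO"),
        GeneModel("gB", "chr1", 700, 1200, "-", "mRNA", "CSR1"),
        GeneModel("gC", "chr2", 50, 550, "+", "mRNA", "none"),
        GeneModel("piX", "chr1", 300, 321, "+", "piRNA", "none"),  # nested in gA
        GeneModel("miY", "chr2", 600, 622, "-", "miRNA", "none"),
    ]


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(
        n_mrna=60,
        n_pirna=8,
        n_mirna=4,
        n_wago=10,
        n_csr1=15,
        n_both=3,
        mrna_len=(300, 800),
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    genes, truth = build_truth(small_config, seed=7)
    frame, sidecar = simulate_library(
        genes, truth, SampleSpec("fixture_input", "wt", "input", None, 8000)
    )
    return genes, truth, frame, sidecar
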