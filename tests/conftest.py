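import numpy as np
import pandas as pd
import pytest

from epidermis_evo import SimConfig, Simulation, build_gene_panel
from epidermis_evo.genome import GenePanel


@pytest.fixture(scope="session")
def default_panel():
    """The default synthetic 72-gene panel."""
    return build_gene_panel()


@pytest.fixture(scope="session")
def hot_panel():
    """A small panel with a strongly elevated mutation rate, so short small
    simulations accumulate enough clones for distributional tests."""
    return build_gene_panel(n_genes=8, target_mean_rate=3.2e-7, seed=5)


@pytest.fixture()
def tiny_config():
    """An 8x8x12 lattice: big enough for dynamics, cheap enough for tests."""
    return SimConfig(biopsy_area_mm2=0.0144, lz=12, seed=0)


def make_panel_df(rows):
    """Hand-written panel table helper: rows of
    (gene, chrom, start, end, nA, nC, nG, nT, mu_g, driver_class)."""
    cols = ["gene", "chrom", "start", "end", "nA", "nC", "nG", "nT", "mu_g", "driver_class"]
    return pd.DataFrame(rows, columns=cols)


@pytest.fixture()
def three_gene_panel():
    df = make_panel_df([
        ("ALPHA", "chr1", 100, 300, 60, 40, 40, 60, 1e-9, "passenger"),
        ("NOTCH1", "chr9", 1000, 1500, 150, 100, 100, 150, 2e-9, "NOTCH1-like"),
        ("TP53", "chr17", 5000, 5400, 100, 100, 100, 100, 4e-9, "TP53-like"),
    ])
    return GenePanel(df)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
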