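import numpy as np
import pytest

from esmmtx import (
    GenerativeSpec,
    PriorConfig,
    StratifiedTable,
    generate_esm_gene,
    read_stratified_table,
)

# The worked example table: one gene family stratified into five species and
# an unclassified row, three samples, CPM units.
EXAMPLE_MTX_TSV = """\
# Gene Family\tCSM5FZ3T\tCSM5FZ46\tCSM5FZ4G
UniRef90_A0A015QIN6\t56.1085\t5.34637\t5.04212
UniRef90_A0A015QIN6|g_Bacteroides.s_Bacteroides_fragilis\t34.9527\t4.45395\t0
UniRef90_A0A015QIN6|g_Bacteroides.s_Bacteroides_ovatus\t0\t0\t1.67376
UniRef90_A0A015QIN6|g_Bacteroides.s_Bacteroides_uniformis\t0\t0\t1.75071
UniRef90_A0A015QIN6|g_Bacteroides.s_Bacteroides_vulgatus\t21.1558\t0.89242\t0
UniRef90_A0A015QIN6|g_Parabacteroides.s_Parabacteroides_distasonis\t0\t0\t1.61765
UniRef90_A0A015QIN6|unclassified\t0\t0\t0
"""


@pytest.fixture(scope="session")
def example_mtx(tmp_path_factory) -> StratifiedTable:
    path = tmp_path_factory.mktemp("tables") / "example_mtx.tsv"
    path.write_text(EXAMPLE_MTX_TSV)
    return read_stratified_table(path)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250928)


@pytest.fixture()
def small_gene():
    """A small model-generated gene for sampler unit tests."""
    spec = GenerativeSpec(
        n_samples=40, n_subjects=10, taxa_per_sample=2, alpha=1.0,
        beta=0.8, theta1=2.0, theta2=0.05, rho=0.6, seed=7,
    )
    data, truth = generate_esm_gene(spec)
    return data, truth, spec


@pytest.fixture()
def fast_prior():
    return PriorConfig(C=0.05, n_iter=60, n_burn=20, thin=1, n_inner=2, seed=0)
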