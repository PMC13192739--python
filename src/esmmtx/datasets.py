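"""Small bundled example data.

One stratified MTX gene-family block (UniRef90_A0A015QIN6 across three
IBDMDB samples, CPM units) used in documentation, tests and the acceptance
script as a worked example of the HUMAnN table layout.
"""

from io import StringIO

from .io_humann import StratifiedTable, read_stratified_table

EXAMPLE_GENE_FAMILY_TSV = """\
# Gene Family\tCSM5FZ3T\tCSM5FZ46\tCSM5FZ4G
UniRef90_A0A015QIN6\t56.1085\t5.34637\t5.04212
UniRef90_A0A015QIN6|g_Bacteroides.s_Bacteroides_fragilis\t34.9527\t4.45395\t0
UniRef90_A0A015QIN6|g_Bacteroides.s_Bacteroides_ovatus\t0\t0\t1.67376
UniRef90_A0A015QIN6|g_Bacteroides.s_Bacteroides_uniformis\t0\t0\t1.75071
UniRef90_A0A015QIN6|g_Bacteroides.s_Bacteroides_vulgatus\t21.1558\t0.89242\t0
UniRef90_A0A015QIN6|g_Parabacteroides.s_Parabacteroides_distasonis\t0\t0\t1.61765
UniRef90_A0A015QIN6|unclassified\t0\t0\t0
"""


def load_example_mtx() -> StratifiedTable:
    """The example gene-family block as a parsed stratified table."""
    return read_stratified_table(StringIO(EXAMPLE_GENE_FAMILY_TSV))
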