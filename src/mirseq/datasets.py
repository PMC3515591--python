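"""Bundled reference tables.

Published per-library read accounting and conserved-miRNA family counts
from a peach (Prunus persica) leaf/root drought small RNA sequencing
experiment: four libraries, leaf control (LC), leaf stress (LS), root
control (RC), root stress (RS). The family table carries the printed
log2 fold changes where the published value is a plausible log2 ratio;
entries whose printed value is magnitudes away from any possible ratio
of the stated counts are left NA.
"""

from importlib import resources

import pandas as pd

from .io import read_tsv

LIBRARIES = ["LC", "LS", "RC", "RS"]


def _data_path(name: str):
    return resources.files("mirseq.data").joinpath(name)


def peach_library_stats() -> pd.DataFrame:
    with resources.as_file(_data_path("peach_library_stats.tsv")) as p:
        return read_tsv(p).set_index("library")


def peach_conserved_mirnas() -> pd.DataFrame:
    with resources.as_file(_data_path("peach_conserved_mirnas.tsv")) as p:
        return read_tsv(p).set_index("family")
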