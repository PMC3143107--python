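"""Packaged reference data.

Two small tables from the published sorghum stem small-RNA study ship with
the package: the per-library deep-sequencing statistics of the five SOLiD
libraries, and the nine novel MIR genes (sbi-MIR5381..sbi-MIR5389, GenBank
JN205291..JN205299) with their mature/star sequences.  Coordinates in the
novel-MIR table are kept as published (1-based, closed).
"""

from importlib import resources

import pandas as pd

__all__ = ["load_published_library_stats", "load_novel_mir_genes"]


def _load(name: str) -> pd.DataFrame:
    ref = resources.files("stemsrna.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def load_published_library_stats() -> pd.DataFrame:
    """Per-library sequencing statistics of the five sorghum stem libraries.

    Columns mirror the pipeline's own ``library_stats.tsv``; the last row is
    the across-library total.
    """
    return _load("sorghum_stem_library_stats.tsv")


def load_novel_mir_genes() -> pd.DataFrame:
    """The nine novel sorghum MIR genes with mature and star sequences."""
    return _load("sorghum_novel_mir_genes.tsv")
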