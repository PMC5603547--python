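"""Bundled small datasets.

Currently a single read-accounting table from a 16-sample rainbow trout
skeletal-muscle RNA-seq experiment (two treatment groups, 17beta-estradiol
vs vehicle control, sampled 24 h and 72 h post-injection, four biological
replicates each), used to exercise the QC summaries on real numbers.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from ..qc import MappingRecord, read_mapping_table

__all__ = ["load_trout_e2_read_accounting", "trout_e2_mapping_records"]


def _data_path(name: str):
    return resources.files(__package__).joinpath(name)


def load_trout_e2_read_accounting() -> pd.DataFrame:
    """Per-sample raw/clean/mapped read counts as a DataFrame."""
    with resources.as_file(_data_path("trout_e2_read_accounting.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def trout_e2_mapping_records() -> list[MappingRecord]:
    """The same table as validated :class:`~lncnet.qc.MappingRecord` objects."""
    with resources.as_file(_data_path("trout_e2_read_accounting.tsv")) as p:
        return read_mapping_table(p)
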