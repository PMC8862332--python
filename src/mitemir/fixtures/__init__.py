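"""Packaged reference tables from the published wheat screen.

``table2.tsv`` lists the 38 MITE-derived miRNAs (name, locus, strand,
mature sequence, size, best MITE, known-miRNA annotation, genomic
context, host genes); ``table3.tsv`` lists their validated cleavage
sites that carry a MITE insertion in the target region;
``cohort_counts.json`` carries the cohort-level totals the two row
tables are subsets of.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd


def _path(name: str):
    return resources.files(__package__) / name


def load_table2() -> pd.DataFrame:
    df = pd.read_csv(_path("table2.tsv"), sep="\t", keep_default_na=False)
    return df


def load_table3() -> pd.DataFrame:
    return pd.read_csv(_path("table3.tsv"), sep="\t", keep_default_na=False)


def load_cohort_counts() -> dict[str, int]:
    doc = json.loads(_path("cohort_counts.json").read_text())
    return {k: v for k, v in doc.items() if isinstance(v, int)}
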