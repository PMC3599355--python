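"""Packaged reference tables for the nitrilase mining study.

``table1`` is the 39-entry mined-candidate annotation table (16 of which
carry an experimentally defined function); ``table2`` is the predicted
mandelonitrile-hydrolase subgroup's seven uncharacterized members with their
measured specific activities and enantioselectivities; ``table3`` is the
24-substrate relative-activity profile of the purified BCJ2315 nitrilase
(phenylacetonitrile = 100%).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

#: the five reference enzymes experimentally characterized as
#: mandelonitrile hydrolases (the anchors of the subgroup designation)
MANDELONITRILE_HYDROLASE_ACCESSIONS = (
    "NP_773042",   # Bradyrhizobium japonicum USDA110 bll6402 — the mining query
    "YP_559838",   # Burkholderia xenovorans LB400
    "AAW79573",    # Pseudomonas fluorescens EBC191
    "AAR97509",    # uncultured organism, nitrilase I (2A6)
    "P20960",      # Alcaligenes faecalis JM3
)

#: printed kinetic constants of the purified BCJ2315 toward mandelonitrile
BCJ2315_KM_MM = 0.14
BCJ2315_VMAX = 45.4          # umol min^-1 mg^-1
BCJ2315_KCAT_S = 15.4        # s^-1, measured independently (MW basis unstated)
BCJ2315_NATIVE_KDA = 450.0
BCJ2315_SUBUNIT_KDA = 37.0


def _data_path(name: str) -> Path:
    return Path(resources.files("pessp").joinpath("data", name))


def table1_path() -> Path:
    """Path of the packaged 39-entry reference-annotation TSV."""
    return _data_path("table1.tsv")


def load_table1() -> pd.DataFrame:
    return pd.read_csv(table1_path(), sep="\t", keep_default_na=False)


def load_table2() -> pd.DataFrame:
    df = pd.read_csv(_data_path("table2.tsv"), sep="\t", keep_default_na=False)
    df["amide_pct"] = pd.to_numeric(df["amide_pct"], errors="coerce")
    return df


def load_table3() -> pd.DataFrame:
    df = pd.read_csv(_data_path("table3.tsv"), sep="\t", keep_default_na=False)
    df["relative_activity_pct"] = pd.to_numeric(
        df["relative_activity_pct"], errors="coerce"
    )
    df["sd"] = pd.to_numeric(df["sd"], errors="coerce")
    return df


def subgroup_candidates() -> pd.DataFrame:
    """Cross-reference the subgroup members against the candidate table.

    Returns the uncharacterized entries of the predicted subgroup joined
    with their mined annotation row (identity to the query in particular).
    """
    t1 = load_table1()
    t2 = load_table2()
    merged = t2.merge(t1, on="accession", suffixes=("", "_t1"), validate="1:1")
    uncharacterized = merged[merged["defined_function"].astype(str).str.strip() == ""]
    return uncharacterized.reset_index(drop=True)
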