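"""Packaged reference dataset accessors.

The package ships the fatty-acid composition tables of a modified-
atmosphere growth study of 20 food-associated fungal strains (9 yeasts and
11 filamentous fungi; three conditions each) together with the published
per-row WAMT and DU values.  The composition tables are the primary data —
no external accession exists for them.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import read_profiles
from .profiles import ProfileSet

__all__ = ["load_fungal_profiles", "load_printed_reference"]


def _data_path(name: str):
    return resources.as_file(resources.files("fametrics").joinpath(f"data/{name}"))


def load_fungal_profiles() -> ProfileSet:
    """The packaged 20-organism × 3-condition profile set (60 profiles)."""
    with _data_path("fungal_profiles_wide.tsv") as path:
        return read_profiles(path, dialect="wide")


def load_printed_reference() -> pd.DataFrame:
    """Published WAMT (mean ± sd, °C) and DU per (organism, condition),
    with the ``du_discrepant`` flag for the four rows whose published DU is
    not recomputable from the published composition."""
    with _data_path("printed_reference.tsv") as path:
        df = pd.read_csv(path, sep="\t", comment="#")
    df["du_discrepant"] = df["du_discrepant"].eq("yes")
    return df
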