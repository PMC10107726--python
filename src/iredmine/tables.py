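"""Bundled reference tables for the characterised 29-member IRED panel.

Two small text tables ship with the package: the subgroup assignments of
the panel (residue-187/196 pair per pQR identifier) and the published
biotransformation outcomes (THIQ yields with and without G6PDH cofactor
recycling, and product enantiomeric excess).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .mining import Classification, assign_subgroup
from .records import GAP
from .refmap import KEY_POSITIONS, KeyResidueProfile


def _data_path(name: str):
    return resources.files("iredmine.data") / name


def load_table1() -> pd.DataFrame:
    """Panel subgroup assignments: columns ``pqr``, ``r187``, ``r196``."""
    with resources.as_file(_data_path("table1_subgroups.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype=str)


def load_table2() -> pd.DataFrame:
    """Published THIQ biotransformation outcomes.

    Columns: enzyme, substrate, product, mode, yield_uncoupled,
    yield_coupled, ee (text, may be ``>99`` or ``ND``), major_isomer.
    """
    with resources.as_file(_data_path("table2_yields.tsv")) as p:
        df = pd.read_csv(p, sep="\t", dtype=str)
    df["yield_uncoupled"] = df["yield_uncoupled"].astype(float)
    df["yield_coupled"] = df["yield_coupled"].astype(float)
    return df


def panel_profiles() -> list:
    """Minimal key-residue profiles for the panel (187/196 known, rest gap)."""
    profiles = []
    for row in load_table1().itertuples():
        residue_at = {pos: GAP for pos in KEY_POSITIONS}
        residue_at[187] = row.r187
        residue_at[196] = row.r196
        profiles.append(KeyResidueProfile(row.pqr, residue_at))
    return profiles


def panel_classifications() -> list:
    """Subgroup classification of every panel member."""
    return [assign_subgroup(p) for p in panel_profiles()]
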