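"""Lipid classification: headgroup class, tail saturation class, headgroup charge.

Coarse-grained plasma-membrane lipids are grouped two ways: by headgroup
architecture (PC, PE, SM, GM, CE, LPC, DAG, PS, PI, PA, PIP, CHOL) and by
tail saturation (FS = fully saturated, MU = exactly one double bond, PU = at
least two double bonds in one or both tails). Cholesterol belongs to no
saturation class. The mapping ships as package data; unknown residue names
raise rather than being dropped silently.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import pandas as pd

HEAD_GROUPS = ["PC", "PE", "SM", "GM", "PS", "PI", "PA", "PIP", "LPC", "CE", "DAG", "CHOL"]
TAIL_GROUPS = ["FS", "MU", "PU"]
#: the 15 lipid-group density features, in reporting order
DENSITY_GROUPS = ["PC", "PE", "SM", "GM", "PS", "PI", "PA", "PIP", "LPC", "CE", "DAG",
                  "CHOL", "FS", "MU", "PU"]

#: zwitterionic headgroup classes carrying a phosphate->amine dipole
ZWITTERIONIC_HEADS = {"PC", "PE", "SM"}


class UnknownResidueError(KeyError):
    """Residue name absent from the lipid classification table."""


@lru_cache(maxsize=1)
def classification_table() -> pd.DataFrame:
    """Load the resname -> (head_group, tail_group, charge) table."""
    with resources.files("poremap.data").joinpath("lipid_groups.csv").open() as fh:
        df = pd.read_csv(fh, dtype={"resname": str, "head_group": str}, keep_default_na=False)
    return df.set_index("resname")


def head_group(resname: str) -> str:
    try:
        return classification_table().loc[resname, "head_group"]
    except KeyError:
        raise UnknownResidueError(f"unknown lipid residue name: {resname!r}")


def tail_group(resname: str) -> str | None:
    """Saturation class, or None for cholesterol."""
    try:
        val = classification_table().loc[resname, "tail_group"]
    except KeyError:
        raise UnknownResidueError(f"unknown lipid residue name: {resname!r}")
    return val or None


def head_charge(resname: str) -> float:
    """Net headgroup charge in elementary charges (PS/PI/PA = -1, PIPs more)."""
    try:
        return float(classification_table().loc[resname, "charge"])
    except KeyError:
        raise UnknownResidueError(f"unknown lipid residue name: {resname!r}")


def in_group(resname: str, group: str) -> bool:
    """Membership indicator used for 0/1 density fields.

    ``group`` may be a headgroup class or a saturation class; cholesterol is
    a member of CHOL only.
    """
    if group in TAIL_GROUPS:
        return tail_group(resname) == group
    if group in HEAD_GROUPS:
        return head_group(resname) == group
    raise ValueError(f"unknown lipid group: {group!r}")
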