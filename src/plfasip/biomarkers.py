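"""Fatty-acid biomarker nomenclature and microbial-group assignment.

PLFA profiling names fatty acids with a compact shorthand such as
``i15:0`` (iso-branched, 15 carbons, saturated) or ``18:2w6``
(18 carbons, two double bonds, omega-6).  Each biomarker is attributed
to one microbial group; group biomass is the combined mass of the fatty
acids attributed to it.  The default assignment follows the common
convention for soil PLFA work:

* terminally branched (``i``/``a``) saturates -> Gram-positive bacteria
* cyclopropyl fatty acids and omega-7 monounsaturates -> Gram-negative
  bacteria
* straight-chain saturates -> general (non-specific) bacteria
* ``18:2w6`` and ``18:3w3`` (with ``18:1w9`` by default) -> fungi
* ``20:4w6`` -> protozoa

The mapping ships as an editable CSV and can be replaced wholesale with
:func:`load_group_mapping`.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path

import pandas as pd

logger = logging.getLogger("plfasip")

__all__ = [
    "Group",
    "BACTERIAL_GROUPS",
    "FattyAcidBiomarker",
    "normalize_name",
    "carbon_count",
    "default_group_mapping",
    "load_group_mapping",
    "assign_group",
]


class Group(str, Enum):
    """Microbial group attributed to a PLFA biomarker."""

    GENERAL_BACTERIA = "general_bacteria"
    GRAM_POSITIVE = "gram_positive"
    GRAM_NEGATIVE = "gram_negative"
    FUNGI = "fungi"
    PROTOZOA = "protozoa"
    UNASSIGNED = "unassigned"


#: Groups pooled into the "bacteria" denominator of the fungi:bacteria ratio.
BACTERIAL_GROUPS = (
    Group.GENERAL_BACTERIA,
    Group.GRAM_POSITIVE,
    Group.GRAM_NEGATIVE,
)

# shorthand: optional branching/ring prefix, chain length, unsaturation,
# optional omega position and geometry suffix
_NAME_RE = re.compile(r"^(?:i|a|cy|me)?(\d+):(\d+)(?:w\d+[a-z]*)?$")


def normalize_name(name: str) -> str:
    """Canonicalize a biomarker label for use as a dictionary key.

    Unicode "ω" is accepted and mapped to ASCII "w"; surrounding
    whitespace is stripped and the label lower-cased.
    """
    return str(name).strip().replace("ω", "w").replace("Ω", "w").lower()


def carbon_count(name: str) -> int:
    """Number of carbon atoms in the free fatty acid named ``name``.

    The chain-length field of the shorthand is the carbon count of the
    underivatized acid (the methyl ester carries one extra carbon).
    Cyclopropyl names already count the ring carbon in the chain length.
    """
    m = _NAME_RE.match(normalize_name(name))
    if m is None:
        raise ValueError(f"cannot parse fatty acid name {name!r}")
    n = int(m.group(1))
    if n < 2:
        raise ValueError(f"fatty acid {name!r}: carbon count {n} < 2")
    return n


@dataclass(frozen=True)
class FattyAcidBiomarker:
    """A named fatty acid with carbon count and group assignment."""

    name: str
    n_carbon: int
    group: Group = Group.UNASSIGNED

    def __post_init__(self) -> None:
        if self.n_carbon < 2:
            raise ValueError(f"{self.name}: n_carbon must be >= 2")


def _mapping_from_frame(df: pd.DataFrame, source: str) -> dict[str, Group]:
    for col in ("biomarker", "group"):
        if col not in df.columns:
            raise ValueError(f"group mapping {source}: missing column {col!r}")
    mapping: dict[str, Group] = {}
    for _, row in df.iterrows():
        key = normalize_name(row["biomarker"])
        if key in mapping:
            raise ValueError(f"group mapping {source}: duplicate biomarker {key!r}")
        mapping[key] = Group(str(row["group"]))
    return mapping


def default_group_mapping() -> dict[str, Group]:
    """The biomarker -> group table shipped with the package."""
    with resources.files("plfasip.data").joinpath("biomarker_groups.csv").open() as fh:
        df = pd.read_csv(fh)
    return _mapping_from_frame(df, "package default")


def load_group_mapping(path: str | Path) -> dict[str, Group]:
    """Read a user-supplied biomarker -> group CSV (columns: biomarker, group)."""
    return _mapping_from_frame(pd.read_csv(path), str(path))


def assign_group(name: str, mapping: dict[str, Group] | None = None) -> Group:
    """Group for ``name``; unknown biomarkers become ``unassigned`` with a warning."""
    if mapping is None:
        mapping = default_group_mapping()
    key = normalize_name(name)
    if key not in mapping:
        logger.warning("biomarker %r not in group mapping; assigned 'unassigned'", name)
        return Group.UNASSIGNED
    return mapping[key]
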