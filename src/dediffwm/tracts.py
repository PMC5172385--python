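"""Catalog of the 27 tract-averaged white-matter phenotypes.

The unit of analysis throughout the package is a *tract entry*: a named
white-matter pathway on one side of the brain (or a midline structure).
Twelve pathways are bilateral, giving 24 lateralised entries, and three are
midline (forceps major/minor, middle cerebellar peduncle), for 27 entries in
total.  Five entries — the middle cerebellar peduncle, both medial lemnisci
and both parahippocampal cingula — covary only weakly with the rest and are
excluded from the general-factor models, leaving a 22-entry core set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

__all__ = [
    "TractSpec",
    "make_tract_catalog",
    "core_tract_entries",
    "weak_tract_entries",
    "TRACT_ALIASES",
]

ASSOCIATION = "association"
THALAMIC = "thalamic_radiation"
PROJECTION = "projection"
CALLOSAL = "callosal"

# (short name, category, bilateral?, member of 22-tract core set?)
_CATALOG_DEF = [
    ("MCP", PROJECTION, False, False),       # middle cerebellar peduncle
    ("FMaj", CALLOSAL, False, True),         # forceps major
    ("FMin", CALLOSAL, False, True),         # forceps minor
    ("ML", PROJECTION, True, False),         # medial lemniscus
    ("CST", PROJECTION, True, True),         # corticospinal tract
    ("AR", PROJECTION, True, True),          # acoustic radiation
    ("ATR", THALAMIC, True, True),           # anterior thalamic radiation
    ("PTR", THALAMIC, True, True),           # posterior thalamic radiation
    ("STR", THALAMIC, True, True),           # superior thalamic radiation
    ("SLF", ASSOCIATION, True, True),        # superior longitudinal fasciculus
    ("ILF", ASSOCIATION, True, True),        # inferior longitudinal fasciculus
    ("IFOF", ASSOCIATION, True, True),       # inferior fronto-occipital fasc.
    ("Unc", ASSOCIATION, True, True),        # uncinate fasciculus
    ("CingG", ASSOCIATION, True, True),      # cingulum bundle (gyrus)
    ("CingPH", ASSOCIATION, True, False),    # cingulum (parahippocampal)
]


@dataclass(frozen=True)
class TractSpec:
    """One tract entry: a pathway on one hemisphere or a midline structure."""

    name: str
    category: str
    laterality: str  # "left" | "right" | "midline"
    core_factor_member: bool

    @property
    def entry(self) -> str:
        """Unique column label, e.g. ``SLF_L`` or ``FMaj``."""
        if self.laterality == "midline":
            return self.name
        return f"{self.name}_{'L' if self.laterality == 'left' else 'R'}"


def make_tract_catalog() -> List[TractSpec]:
    """Return the fixed 27-entry tract catalog.

    12 bilateral pathways contribute a left and a right entry, 3 midline
    structures contribute one each; 22 entries are members of the core
    general-factor set.
    """
    catalog: List[TractSpec] = []
    for name, cat, bilateral, core in _CATALOG_DEF:
        if bilateral:
            catalog.append(TractSpec(name, cat, "left", core))
            catalog.append(TractSpec(name, cat, "right", core))
        else:
            catalog.append(TractSpec(name, cat, "midline", core))
    return catalog


def core_tract_entries() -> List[str]:
    """Labels of the 22 entries retained in the general-factor models."""
    return [t.entry for t in make_tract_catalog() if t.core_factor_member]


def weak_tract_entries() -> List[str]:
    """Labels of the 5 weak-loading entries excluded from factor models."""
    return [t.entry for t in make_tract_catalog() if not t.core_factor_member]


# Accepted spellings for tract names in user-supplied tables, mapped to the
# catalog short names.
TRACT_ALIASES = {
    "forceps major": "FMaj",
    "forceps minor": "FMin",
    "middle cerebellar peduncle": "MCP",
    "medial lemniscus": "ML",
    "corticospinal tract": "CST",
    "acoustic radiation": "AR",
    "anterior thalamic radiation": "ATR",
    "posterior thalamic radiation": "PTR",
    "superior thalamic radiation": "STR",
    "superior longitudinal fasciculus": "SLF",
    "inferior longitudinal fasciculus": "ILF",
    "inferior fronto-occipital fasciculus": "IFOF",
    "uncinate": "Unc",
    "uncinate fasciculus": "Unc",
    "cingulum gyrus": "CingG",
    "cingulate gyrus part of cingulum": "CingG",
    "parahippocampal cingulum": "CingPH",
    "parahippocampal part of cingulum": "CingPH",
}


def normalize_tract_name(name: str) -> str:
    """Map a tract name or accepted alias to its catalog short name.

    Raises ``ValueError`` listing accepted names for unknown input.
    """
    short = {t.name for t in make_tract_catalog()}
    if name in short:
        return name
    key = name.strip().lower()
    if key in TRACT_ALIASES:
        return TRACT_ALIASES[key]
    accepted = sorted(short | set(TRACT_ALIASES))
    raise ValueError(f"unknown tract name {name!r}; accepted: {accepted}")
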