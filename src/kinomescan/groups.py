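"""Subfamily -> group lookup for the 19-group plant kinase scheme.

Subfamily names carry their group as a prefix (e.g. ``RLK-Pelle_DLSV`` is in
the RLK-Pelle group, ``Group-Pl-2`` is plant-specific).  Unknown prefixes
fall back to the token before the first underscore.
"""

from __future__ import annotations

# ordered: longest/most specific prefixes first
GROUP_PREFIXES: tuple[tuple[str, str], ...] = (
    ("RLK-Pelle", "RLK-Pelle"),
    ("Group-Pl", "Plant-specific"),
    ("CAMK", "CAMK"),
    ("CMGC", "CMGC"),
    ("AGC", "AGC"),
    ("CK1", "CK1"),
    ("STE", "STE"),
    ("TKL", "TKL"),
    ("TLK", "TLK"),
    ("TTK", "TTK"),
    ("ULK", "ULK"),
    ("Aur", "Aur"),
    ("BUB", "BUB"),
    ("IRE1", "IRE1"),
    ("NEK", "NEK"),
    ("PEK", "PEK"),
    ("SCY1", "SCY1"),
    ("WEE", "WEE"),
    ("WNK", "WNK"),
)

UNCLASSIFIED = "Unclassified"


def group_for_subfamily(subfamily: str) -> str:
    if subfamily == UNCLASSIFIED:
        return UNCLASSIFIED
    for prefix, group in GROUP_PREFIXES:
        if subfamily.startswith(prefix):
            return group
    return subfamily.split("_", 1)[0]
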