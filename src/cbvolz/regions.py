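"""Canonical cerebellar region schema.

The analysis works on six segmented volumes — four cerebellar lobes
(anterior = lobules I–V, superior posterior = VI–VII, inferior posterior =
VIII–IX, flocculonodular = X), the midline vermis, and the cerebellar white
matter (cWM) — plus the aggregate cerebellar grey matter (cGM), defined as
the sum of the four hemispheric lobes and the vermis.
"""

from __future__ import annotations

#: regions expected in an input table (raw mm^3)
BASE_REGIONS: tuple[str, ...] = (
    "anterior",
    "superior_posterior",
    "inferior_posterior",
    "flocculonodular",
    "vermis",
    "cwm",
)

#: grey-matter constituents of cGM
GM_REGIONS: tuple[str, ...] = (
    "anterior",
    "superior_posterior",
    "inferior_posterior",
    "flocculonodular",
    "vermis",
)

CGM = "cgm"
CWM = "cwm"

#: fixed axis order for trajectory tables and radar profiles
ANALYSIS_REGIONS: tuple[str, ...] = (
    "anterior",
    "superior_posterior",
    "inferior_posterior",
    "flocculonodular",
    "vermis",
    CGM,
    CWM,
)

#: regions that may arrive split into left/right hemisphere columns
#: (the vermis is a midline structure and is never split)
HEMISPHERIC_REGIONS: tuple[str, ...] = (
    "anterior",
    "superior_posterior",
    "inferior_posterior",
    "flocculonodular",
    "cwm",
)
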