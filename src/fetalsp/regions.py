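"""Canonical region vocabulary for regional subplate analysis.

Seventeen bilateral cerebral regions (a fetal adaptation of the
Desikan-Killiany scheme with split temporal gyri and cuneus/lingual
subdivision, peri-cingular regions excluded for data-quality reasons).
"""

from __future__ import annotations

REGIONS_17: tuple[str, ...] = (
    "superior_frontal",
    "middle_frontal",
    "inferior_frontal",
    "precentral",
    "postcentral",
    "paracentral_lobule",
    "superior_parietal",
    "inferior_parietal",
    "supramarginal",
    "precuneus",
    "cuneus",
    "lingual",
    "lateral_occipital",
    "fusiform",
    "superior_temporal",
    "middle_temporal",
    "inferior_temporal",
)

HEMISPHERES: tuple[str, str] = ("L", "R")

#: Morphometric measures carried through the analysis.
METRICS: tuple[str, ...] = ("thickness", "area", "volume", "depth")

#: Measures that enter group statistics (depth is a covariate, not an outcome).
ANALYSIS_METRICS: tuple[str, ...] = ("thickness", "area", "volume")


def region_id(name: str) -> int:
    """1-based integer id of a canonical region name."""
    return REGIONS_17.index(name) + 1


def validate_regions(names) -> list[str]:
    """Check a region vocabulary: unique names, exactly 17 of them."""
    names = list(names)
    if len(names) != 17:
        raise ValueError(f"expected 17 regions, got {len(names)}")
    if len(set(names)) != 17:
        raise ValueError("region names must be unique")
    return names
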