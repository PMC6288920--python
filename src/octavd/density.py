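"""Vessel pixel density per region and tidy per-subject density tables.

Vessel pixel density is the fraction of pixels classified as vessel within
a region of an en-face image; it is stored as a fraction in [0, 1]
(formatted to 3 decimals in reports) and becomes a percentage only in
display layers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Tuple

import numpy as np
import pandas as pd

from .preprocess import DISC_SEGMENTS, MACULA_SEGMENTS
from .regions import RegionSet

logger = logging.getLogger(__name__)

__all__ = ["DensityRecord", "REGION_ORDER", "vessel_density", "density_table"]

#: Region reporting order within a segment.
REGION_ORDER = ("segment", "superior", "inferior", "nasal", "temporal")

DENSITY_COLUMNS = ["subject_id", "eye", "scan_type", "segment_label", "region",
                   "scan_index", "density", "vessel_pixels", "region_pixels"]


@dataclass(frozen=True)
class DensityRecord:
    """One vessel pixel-density value for one (subject, eye, segment, region, scan)."""

    subject_id: str
    eye: str
    scan_type: str
    segment_label: str
    region: str
    scan_index: int
    density: float
    vessel_pixels: int
    region_pixels: int


def vessel_density(vessel_map: np.ndarray,
                   region_mask: np.ndarray) -> Tuple[int, int, float]:
    """Count vessel pixels within a region and return the density fraction.

    Returns ``(vessel_pixels, region_pixels, density)`` with
    ``density = vessel_pixels / region_pixels`` exactly. An empty region is
    an error (distinct from a region that contains no vessel pixels).
    """
    vessel_map = np.asarray(vessel_map, dtype=bool)
    region_mask = np.asarray(region_mask, dtype=bool)
    if vessel_map.shape != region_mask.shape:
        raise ValueError("vessel map and region mask must have the same shape")
    region_pixels = int(region_mask.sum())
    if region_pixels == 0:
        raise ValueError("empty region mask")
    vessel_pixels = int((vessel_map & region_mask).sum())
    return vessel_pixels, region_pixels, vessel_pixels / region_pixels


def density_table(vessel_maps: Mapping[str, np.ndarray],
                  region_sets: Mapping[str, RegionSet],
                  subject_id: str, eye: str, scan_type: str,
                  scan_index: int) -> pd.DataFrame:
    """Assemble density records for one scan: five regions per segment.

    ``vessel_maps`` and ``region_sets`` are keyed by segment label and must
    carry the same keys. Records are emitted in deterministic order:
    segments in their canonical device order, then segment, superior,
    inferior, nasal, temporal. When the quadrants tile the segment, the
    per-count aggregation consistency (segment counts equal the sum of the
    quadrant counts) is asserted.
    """
    if set(vessel_maps) != set(region_sets):
        missing = set(vessel_maps) ^ set(region_sets)
        raise ValueError(f"segment keys do not align: {sorted(missing)}")
    canonical = MACULA_SEGMENTS if scan_type == "macula" else DISC_SEGMENTS
    unknown = set(vessel_maps) - set(canonical)
    if unknown:
        raise ValueError(f"unknown segment labels for {scan_type}: {sorted(unknown)}")

    rows = []
    for segment in canonical:
        if segment not in vessel_maps:
            continue
        vmap = vessel_maps[segment]
        rset = region_sets[segment]
        masks = {"segment": rset.segment_mask, **rset.quadrant_masks}
        counts = {}
        for region in REGION_ORDER:
            vp, rp, dens = vessel_density(vmap, masks[region])
            counts[region] = (vp, rp)
            rows.append(DensityRecord(subject_id, eye, scan_type, segment,
                                      region, scan_index, dens, vp, rp))
        quad_vp = sum(counts[q][0] for q in REGION_ORDER[1:])
        quad_rp = sum(counts[q][1] for q in REGION_ORDER[1:])
        if quad_rp == counts["segment"][1] and quad_vp != counts["segment"][0]:
            raise RuntimeError(
                f"aggregation inconsistency in {segment}: "
                f"{quad_vp} quadrant vessel pixels vs {counts['segment'][0]}")
    logger.debug("density_table: %d records for subject=%s eye=%s scan=%d",
                 len(rows), subject_id, eye, scan_index)
    return pd.DataFrame([r.__dict__ for r in rows], columns=DENSITY_COLUMNS)
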