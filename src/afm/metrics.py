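"""Per-tile fibrotic metric and the per-tubule record table.

The fibrotic metric of a tile is the fraction of counted pixels classified
fibrotic by the color threshold, stored as a fraction in [0, 1] and reported
in percent in human-readable output (1.0 corresponds to 100%). The
denominator is the tile's pixel count after edge clipping and, optionally,
after excluding the annotated tubule's own interior.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotations import TubuleAnnotation
from .errors import AFMError, DegenerateInputError
from .imaging import (
    FibrosisMask,
    FibrosisParams,
    SlideImage,
    TileWindow,
    segment_fibrosis,
    tile_window,
)

logger = logging.getLogger(__name__)

#: fixed column order of the per-tile CSV so the stats stage can re-run alone
TILE_CSV_COLUMNS = [
    "slide_id",
    "tubule_id",
    "tubule_class",
    "x0",
    "y0",
    "x1",
    "y1",
    "clipped",
    "denominator_px",
    "fibrotic_fraction",
]


@dataclass
class TileMetricRecord:
    """One tubule's tile window and fibrotic metric, with provenance."""

    tubule_id: str
    tubule_class: str
    window: TileWindow
    fibrotic_fraction: float
    denominator_px: int
    slide_id: str

    def __post_init__(self) -> None:
        assert 0.0 <= self.fibrotic_fraction <= 1.0
        assert self.denominator_px >= 1


def fibrotic_metric(mask: FibrosisMask, denominator_px: int) -> float:
    """Fibrotic-pixel count divided by ``denominator_px``, as a fraction."""
    if denominator_px < 1:
        raise DegenerateInputError(f"denominator_px={denominator_px} < 1 (degenerate tile)")
    count = int(np.count_nonzero(mask.mask))
    if count > denominator_px:
        raise DegenerateInputError(
            f"fibrotic count {count} exceeds denominator {denominator_px}"
        )
    return count / denominator_px


def compute_tile_metrics(
    image: SlideImage,
    annotations: list[TubuleAnnotation],
    params: FibrosisParams,
    *,
    nominal_size: int = 512,
    edge_policy: str = "clip",
    exclude_tubule_interior: bool = False,
    slide_id: str = "",
    strict: bool = False,
) -> list[TileMetricRecord]:
    """Extract one tile per tubule, segment it, and compute its metric.

    Exactly one record is produced per non-skipped annotation, in input
    order; the whole path is deterministic. A per-tubule failure is logged
    and skipped unless ``strict``.
    """
    records: list[TileMetricRecord] = []
    dims = (image.width, image.height)
    for ann in annotations:
        try:
            window = tile_window(
                ann.centroid, nominal_size, dims, edge_policy, tubule_id=ann.tubule_id
            )
            if window is None:
                logger.info(
                    "skipping tubule %s: tile extends outside image (edge_policy=skip)",
                    ann.tubule_id,
                )
                continue
            tile = window.crop(image)
            exclusion = None
            if exclude_tubule_interior:
                exclusion = [(x - window.x0, y - window.y0) for x, y in ann.vertices]
            seg = segment_fibrosis(tile, params, exclusion_polygon=exclusion)
            denominator = window.area_px - seg.excluded_px
            records.append(
                TileMetricRecord(
                    tubule_id=ann.tubule_id,
                    tubule_class=ann.tubule_class,
                    window=window,
                    fibrotic_fraction=fibrotic_metric(seg, denominator),
                    denominator_px=denominator,
                    slide_id=slide_id,
                )
            )
        except AFMError:
            if strict:
                raise
            logger.warning("tubule %s failed; skipping", ann.tubule_id, exc_info=True)
    return records


def records_to_frame(records: list[TileMetricRecord]) -> pd.DataFrame:
    """Flatten records into the fixed per-tile CSV schema."""
    rows = [
        {
            "slide_id": r.slide_id,
            "tubule_id": r.tubule_id,
            "tubule_class": r.tubule_class,
            "x0": r.window.x0,
            "y0": r.window.y0,
            "x1": r.window.x1,
            "y1": r.window.y1,
            "clipped": r.window.clipped,
            "denominator_px": r.denominator_px,
            "fibrotic_fraction": r.fibrotic_fraction,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=TILE_CSV_COLUMNS)
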