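"""Tubule polygon annotations: GeoJSON I/O, validation, centroids.

Annotations are polygons drawn over a trichrome-stained kidney section, each
labelled ``distal`` or ``proximal`` (in practice the label comes from E-cadherin
staining on a consecutive section; here it is simply an input). Coordinates are 0-based pixel coordinates, x rightward, y downward,
matching image array indexing; fractional vertices are allowed.

Two GeoJSON label dialects are accepted: the digital-pathology annotator
convention ``properties.classification.name`` (QuPath-style exports) and the
plain ``properties.class`` key. Matching is case-insensitive with surrounding
whitespace stripped.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    AnnotationError,
    InvalidPolygonError,
    LabellingError,
    UnsupportedGeometryError,
)

logger = logging.getLogger(__name__)

DISTAL = "distal"
PROXIMAL = "proximal"
ALLOWED_CLASSES = (DISTAL, PROXIMAL)

#: area below which the shoelace centroid is considered numerically degenerate
#: and the vertex mean is used instead (square pixels)
_DEGENERATE_AREA = 1e-9


def polygon_area(vertices: Sequence[tuple[float, float]]) -> float:
    """Unsigned polygon area by the shoelace formula."""
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[0] < 3 or v.shape[1] != 2:
        raise InvalidPolygonError(
            f"polygon needs >= 3 (x, y) vertices, got shape {v.shape}"
        )
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    return float(abs(np.sum(x * yn - xn * y)) / 2.0)


def polygon_centroid(
    vertices: Sequence[tuple[float, float]],
) -> tuple[float, float]:
    """Area-weighted centroid of a simple polygon (shoelace formula).

    For near-zero-area (degenerate) polygons the arithmetic mean of the
    vertices is returned instead, with a warning logged, so that collinear or
    sliver annotations still get a usable tile center.
    """
    v = _dedup_consecutive(np.asarray(vertices, dtype=float))
    if v.shape[0] < 3:
        raise InvalidPolygonError(
            f"polygon needs >= 3 distinct vertices, got {v.shape[0]}"
        )
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    signed_area = float(np.sum(cross) / 2.0)
    if abs(signed_area) < _DEGENERATE_AREA:
        logger.warning("degenerate polygon (area ~ 0); falling back to vertex mean")
        return float(np.mean(x)), float(np.mean(y))
    cx = float(np.sum((x + xn) * cross) / (6.0 * signed_area))
    cy = float(np.sum((y + yn) * cross) / (6.0 * signed_area))
    return cx, cy


def _dedup_consecutive(v: np.ndarray) -> np.ndarray:
    """Drop consecutive duplicate vertices and an explicit closing vertex."""
    if v.ndim != 2 or v.shape[1] != 2:
        raise InvalidPolygonError(f"vertices must be an N x 2 sequence, got {v.shape}")
    if v.shape[0] >= 2 and np.array_equal(v[0], v[-1]):
        v = v[:-1]
    if v.shape[0] == 0:
        return v
    keep = np.ones(v.shape[0], dtype=bool)
    keep[1:] = np.any(v[1:] != v[:-1], axis=1)
    return v[keep]


@dataclass
class TubuleAnnotation:
    """One labelled tubule polygon with its derived centroid.

    ``vertices`` is the open ring (no repeated closing vertex), in input
    order. ``centroid`` is the area-weighted polygon centroid, computed on
    construction unless supplied.
    """

    tubule_id: str
    vertices: list[tuple[float, float]]
    tubule_class: str
    centroid: tuple[float, float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        v = _dedup_consecutive(np.asarray(self.vertices, dtype=float))
        if v.shape[0] < 3:
            raise InvalidPolygonError(
                f"tubule {self.tubule_id!r}: polygon needs >= 3 distinct vertices"
            )
        if self.tubule_class not in ALLOWED_CLASSES:
            raise LabellingError(
                f"tubule {self.tubule_id!r}: class {self.tubule_class!r} "
                f"not in {ALLOWED_CLASSES}"
            )
        if polygon_area(v) <= 0.0:
            # degenerate ring: centroid falls back to vertex mean, but the
            # annotation itself must enclose area to be a tubule
            raise InvalidPolygonError(
                f"tubule {self.tubule_id!r}: polygon area is zero"
            )
        self.vertices = [(float(x), float(y)) for x, y in v]  # open deduplicated ring
        if self.centroid is None:
            self.centroid = polygon_centroid(self.vertices)

    @property
    def bounding_box(self) -> tuple[float, float, float, float]:
        v = np.asarray(self.vertices, dtype=float)
        return (
            float(v[:, 0].min()),
            float(v[:, 1].min()),
            float(v[:, 0].max()),
            float(v[:, 1].max()),
        )


def _extract_label(props: dict) -> str | None:
    """Pull the class label out of either supported GeoJSON dialect."""
    if not isinstance(props, dict):
        return None
    cls = props.get("classification")
    if isinstance(cls, dict) and isinstance(cls.get("name"), str):
        return cls["name"]
    if isinstance(cls, str):
        return cls
    raw = props.get("class")
    if isinstance(raw, str):
        return raw
    return None


def _normalize_label(raw: str | None) -> str | None:
    if raw is None:
        return None
    label = raw.strip().lower()
    return label if label in ALLOWED_CLASSES else None


def _polygon_exterior(geometry: dict, where: str) -> list[tuple[float, float]]:
    gtype = geometry.get("type")
    if gtype == "Polygon":
        rings = geometry.get("coordinates", [])
    elif gtype == "MultiPolygon":
        parts = geometry.get("coordinates", [])
        if len(parts) != 1:
            raise UnsupportedGeometryError(
                f"{where}: MultiPolygon with {len(parts)} parts; a tubule is one region"
            )
        rings = parts[0]
    else:
        raise UnsupportedGeometryError(f"{where}: geometry type {gtype!r} unsupported")
    if not rings:
        raise UnsupportedGeometryError(f"{where}: polygon has no rings")
    return [(float(x), float(y)) for x, y in rings[0]]


def read_annotations(
    path, *, strict: bool = False
) -> list[TubuleAnnotation]:
    """Read tubule annotations from a GeoJSON FeatureCollection.

    Features whose label is missing or not distal/proximal are skipped with a
    log message, or raise :class:`LabellingError` when ``strict``. Feature
    order is preserved; ``tubule_id`` comes from the feature ``id`` when
    present, else is assigned sequentially (``t0000``, ``t0001``, ...).
    """
    with open(path, "r") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise AnnotationError(f"{path}: not valid JSON: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("type") != "FeatureCollection":
        raise AnnotationError(f"{path}: expected a GeoJSON FeatureCollection")
    annotations: list[TubuleAnnotation] = []
    for i, feature in enumerate(doc.get("features", [])):
        where = f"{path} feature {i}"
        fid = feature.get("id")
        tubule_id = str(fid) if fid is not None else f"t{i:04d}"
        label = _normalize_label(_extract_label(feature.get("properties", {})))
        if label is None:
            msg = (
                f"{where} (id {tubule_id!r}): no distal/proximal class label "
                f"(raw: {_extract_label(feature.get('properties', {}))!r})"
            )
            if strict:
                raise LabellingError(msg)
            logger.info("skipping %s", msg)
            continue
        vertices = _polygon_exterior(feature.get("geometry", {}), where)
        annotations.append(
            TubuleAnnotation(tubule_id=tubule_id, vertices=vertices, tubule_class=label)
        )
    return annotations


def write_annotations(annotations: Iterable[TubuleAnnotation], path) -> None:
    """Write annotations as a GeoJSON FeatureCollection.

    Round trip contract: ``read_annotations`` on the written file reproduces
    ids, classes, and vertices exactly (floats serialized with full ``repr``
    precision).
    """
    features = []
    for ann in annotations:
        ring = [[x, y] for x, y in ann.vertices]
        ring.append(list(ring[0]))  # closed ring per the GeoJSON spec
        features.append(
            {
                "type": "Feature",
                "id": ann.tubule_id,
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {
                    "class": ann.tubule_class,
                    "classification": {"name": ann.tubule_class},
                },
            }
        )
    doc = {"type": "FeatureCollection", "features": features}
    with open(path, "w") as fh:
        json.dump(doc, fh)
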