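"""Census-tract geometries and point-to-tract assignment.

Tracts arrive as a GeoJSON FeatureCollection; each geolocated post is
assigned to a tract either by bounding-box containment (the default) or by
true point-in-polygon.  Real adjacent tracts have overlapping bounding
boxes, so bbox mode disambiguates deterministically: the smallest-area
containing box wins, ties broken by lexicographic tract id.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import shapely
from shapely import STRtree
from shapely.geometry import Point, shape
from shapely.geometry import box as shapely_box
from shapely.geometry.base import BaseGeometry

from .ingest import TweetCorpus


class GeometryError(ValueError):
    """Raised for malformed tract GeoJSON."""


@dataclass(frozen=True)
class TractGeometry:
    """One census tract: id, optional polygon, and its bounding box."""

    tract_id: str
    bbox: tuple[float, float, float, float]  # (min_lon, min_lat, max_lon, max_lat)
    polygon: BaseGeometry | None = None

    @property
    def bbox_area(self) -> float:
        min_lon, min_lat, max_lon, max_lat = self.bbox
        return (max_lon - min_lon) * (max_lat - min_lat)

    def bbox_contains(self, lon: float, lat: float) -> bool:
        min_lon, min_lat, max_lon, max_lat = self.bbox
        return min_lon <= lon <= max_lon and min_lat <= lat <= max_lat


def load_tracts(
    path: str | Path, id_property: str = "GEOID"
) -> list[TractGeometry]:
    """Load tract geometries from a GeoJSON FeatureCollection.

    Each feature must carry the tract id under ``id_property`` in its
    properties; the bounding box is the tight envelope of the geometry.
    """
    data = json.loads(Path(path).read_text())
    features = data.get("features")
    if features is None:
        raise GeometryError("not a GeoJSON FeatureCollection")
    tracts: list[TractGeometry] = []
    seen: set[str] = set()
    for i, feature in enumerate(features):
        props = feature.get("properties") or {}
        tract_id = props.get(id_property)
        if tract_id is None:
            raise GeometryError(f"feature {i} lacks id property {id_property!r}")
        tract_id = str(tract_id)
        if tract_id in seen:
            raise GeometryError(f"duplicate tract id {tract_id!r}")
        seen.add(tract_id)
        try:
            geom = shape(feature["geometry"])
        except Exception as exc:
            raise GeometryError(f"invalid geometry in feature {tract_id!r}: {exc}") from exc
        if geom.is_empty or not geom.is_valid:
            raise GeometryError(f"invalid geometry in feature {tract_id!r}")
        tracts.append(TractGeometry(tract_id=tract_id, bbox=geom.bounds, polygon=geom))
    return tracts


def assign_tract(
    lat: float,
    lon: float,
    tracts: Iterable[TractGeometry],
    mode: str = "bbox",
) -> str | None:
    """Assign a WGS84 point to a tract, or None if no tract contains it.

    bbox mode (the default): candidates are tracts whose bounding box
    contains the point, edges inclusive; the smallest-area box wins, ties
    broken by lexicographic tract id.  polygon mode: point-in-polygon with
    the bbox as prefilter (boundary points count as inside), same
    tie-break on polygon area.
    """
    if mode not in ("bbox", "polygon"):
        raise ValueError(f"unknown assignment mode {mode!r}")
    candidates = [t for t in tracts if t.bbox_contains(lon, lat)]
    if mode == "polygon":
        point = Point(lon, lat)
        candidates = [
            t for t in candidates if t.polygon is not None and t.polygon.covers(point)
        ]
        if not candidates:
            return None
        best = min(candidates, key=lambda t: (t.polygon.area, t.tract_id))
        return best.tract_id
    if not candidates:
        return None
    best = min(candidates, key=lambda t: (t.bbox_area, t.tract_id))
    return best.tract_id


@dataclass(frozen=True)
class TractAssignment:
    """Result of mapping a corpus onto tracts."""

    mapping: Mapping[str, str]  # tweet id -> tract id
    unmapped: tuple[str, ...]  # tweet ids outside every tract


def map_corpus(
    corpus: TweetCorpus,
    tracts: Sequence[TractGeometry],
    mode: str = "bbox",
) -> TractAssignment:
    """Map every geolocated tweet in the corpus to at most one tract.

    Uses an STR packed tree over the tract envelopes (or polygons) for the
    containment queries; the result is identical to calling
    :func:`assign_tract` per tweet, including the deterministic tie-break.
    """
    if mode not in ("bbox", "polygon"):
        raise ValueError(f"unknown assignment mode {mode!r}")
    geolocated = [t for t in corpus if t.has_coordinates]
    unmapped: list[str] = [t.id for t in corpus if not t.has_coordinates]
    mapping: dict[str, str] = {}
    if not geolocated or not tracts:
        unmapped.extend(t.id for t in geolocated)
        return TractAssignment(mapping=mapping, unmapped=tuple(unmapped))

    if mode == "bbox":
        geoms = [shapely_box(*t.bbox) for t in tracts]
        keys = [(t.bbox_area, t.tract_id) for t in tracts]
    else:
        geoms = [t.polygon if t.polygon is not None else shapely_box(*t.bbox) for t in tracts]
        keys = [(g.area, t.tract_id) for g, t in zip(geoms, tracts)]
    tree = STRtree(geoms)
    points = shapely.points(
        [t.longitude for t in geolocated], [t.latitude for t in geolocated]
    )
    # "intersects" is boundary-inclusive, matching the edges-inclusive rule.
    pt_idx, geom_idx = tree.query(points, predicate="intersects")
    best: dict[int, tuple[tuple[float, str], str]] = {}
    for pi, gi in zip(pt_idx.tolist(), geom_idx.tolist()):
        key = keys[gi]
        if pi not in best or key < best[pi][0]:
            best[pi] = (key, tracts[gi].tract_id)
    for i, tweet in enumerate(geolocated):
        if i in best:
            mapping[tweet.id] = best[i][1]
        else:
            unmapped.append(tweet.id)
    return TractAssignment(mapping=mapping, unmapped=tuple(unmapped))
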