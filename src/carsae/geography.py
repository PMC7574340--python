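"""Spatial adjacency structures for areal models.

Builds the binary, first-order spatial weights matrix ``W`` used by
conditional-autoregressive priors. Neighbourhood is defined by contiguity
of region polygons: under the Queen criterion two regions are neighbours
if their boundaries share at least one point (an edge or a single vertex,
like the reach of a chess queen); under the Rook criterion a shared
boundary of positive length is required. An explicit edge-list path is
provided so the rest of the pipeline can run without geometry files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

import numpy as np
import pandas as pd
from shapely import STRtree
from shapely.geometry import shape as shapely_shape
from shapely.geometry.base import BaseGeometry

__all__ = [
    "RegionGraph",
    "queen_adjacency",
    "adjacency_from_edges",
    "find_and_remove_isolated",
    "read_geojson_regions",
    "read_edge_csv",
    "write_edge_csv",
    "write_weights_coo",
]


class GeographyError(ValueError):
    """Raised for malformed geometries, duplicate ids or degenerate graphs."""


@dataclass(frozen=True)
class RegionGraph:
    """Region identifiers plus a symmetric binary adjacency matrix.

    ``W[i, j] == 1`` iff regions ``region_ids[i]`` and ``region_ids[j]``
    are neighbours. The diagonal is zero (a region is not its own
    neighbour) and ``neighbor_counts`` holds the per-region degree.
    Region ordering is the input order; every downstream vector and
    matrix uses this single ordering.
    """

    region_ids: tuple
    W: np.ndarray
    neighbor_counts: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        W = np.asarray(self.W)
        n = len(self.region_ids)
        if len(set(self.region_ids)) != n:
            raise GeographyError("duplicate region ids")
        if W.shape != (n, n):
            raise GeographyError(f"W has shape {W.shape}, expected {(n, n)}")
        if not np.array_equal(W, W.T):
            raise GeographyError("adjacency matrix is not symmetric")
        if np.any(np.diag(W) != 0):
            raise GeographyError("adjacency matrix has nonzero diagonal")
        if not np.isin(W, (0, 1)).all():
            raise GeographyError("adjacency entries must be 0 or 1")
        object.__setattr__(self, "W", W.astype(np.int8))
        object.__setattr__(self, "neighbor_counts", W.sum(axis=1).astype(np.int64))

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def index_of(self, region_id: Hashable) -> int:
        try:
            return self.region_ids.index(region_id)
        except ValueError:
            raise GeographyError(f"unknown region id {region_id!r}") from None

    def edges(self) -> list[tuple]:
        """Unordered neighbour pairs as (id_i, id_j) with i < j positionally."""
        ii, jj = np.nonzero(np.triu(self.W))
        return [(self.region_ids[i], self.region_ids[j]) for i, j in zip(ii, jj)]


def queen_adjacency(
    polygons: dict | Sequence,
    *,
    rook: bool = False,
    tolerance: float = 0.0,
) -> RegionGraph:
    """Build first-order contiguity weights from region polygons.

    Parameters
    ----------
    polygons
        Mapping of region id -> shapely geometry, or a sequence of
        ``(region_id, geometry)`` pairs. One (possibly multi-part)
        geometry per region.
    rook
        If True, require a shared boundary of positive length (Rook
        contiguity); corner-only contact then does not count. Default is
        Queen contiguity: any shared boundary point makes a neighbour.
    tolerance
        Optional distance slack for contact detection, for boundary files
        carrying floating-point slivers. 0 uses exact predicates.
    """
    if isinstance(polygons, dict):
        items = list(polygons.items())
    else:
        items = list(polygons)
    if not items:
        raise GeographyError("empty polygon collection")
    ids = [rid for rid, _ in items]
    if len(set(ids)) != len(ids):
        dup = pd.Series(ids).value_counts()
        raise GeographyError(f"duplicate region ids: {list(dup[dup > 1].index)}")
    geoms = []
    for rid, geom in items:
        if not isinstance(geom, BaseGeometry):
            geom = shapely_shape(geom)
        if geom.is_empty or not geom.is_valid:
            raise GeographyError(f"invalid or empty geometry for region {rid!r}")
        geoms.append(geom)

    n = len(geoms)
    W = np.zeros((n, n), dtype=np.int8)
    tree = STRtree(geoms)
    for i, geom in enumerate(geoms):
        query = geom if tolerance == 0 else geom.buffer(tolerance)
        for j in tree.query(query, predicate="intersects"):
            j = int(j)
            if j <= i:
                continue
            inter = geoms[i].intersection(geoms[j]) if tolerance == 0 else None
            if tolerance > 0:
                # with slack, fall back to a buffered intersection test
                inter = geoms[i].buffer(tolerance).intersection(geoms[j])
            if inter.is_empty:
                continue
            if geoms[i].overlaps(geoms[j]) or inter.area > 0:
                touch = True  # overlapping interiors certainly share boundary
            elif rook:
                touch = inter.length > 0
            else:
                touch = True  # any nonempty contact (point or line) counts
            if touch:
                W[i, j] = W[j, i] = 1
    return RegionGraph(tuple(ids), W)


def adjacency_from_edges(region_ids: Sequence, edges: Iterable[tuple]) -> RegionGraph:
    """Build a RegionGraph from an explicit neighbour-pair list.

    Every id in ``edges`` must appear in ``region_ids``; self-loops are
    rejected. Listing a pair in either or both orders is equivalent.
    """
    ids = tuple(region_ids)
    if len(set(ids)) != len(ids):
        raise GeographyError("duplicate region ids")
    index = {rid: k for k, rid in enumerate(ids)}
    W = np.zeros((len(ids), len(ids)), dtype=np.int8)
    for a, b in edges:
        if a == b:
            raise GeographyError(f"self-loop on region {a!r}")
        try:
            i, j = index[a], index[b]
        except KeyError as exc:
            raise GeographyError(f"unknown region id {exc.args[0]!r}") from None
        W[i, j] = W[j, i] = 1
    return RegionGraph(ids, W)


def find_and_remove_isolated(graph: RegionGraph) -> tuple[RegionGraph, list]:
    """Drop regions with no neighbours, returning (subgraph, removed ids).

    CAR priors condition each region on its neighbours, so degree-0
    regions carry no spatial information and the intrinsic (ICAR) prior
    is undefined for them; islands and non-contiguous administrative
    codes are removed before fitting.
    """
    keep = graph.neighbor_counts >= 1
    if not keep.any():
        raise GeographyError("all regions are isolated; no analyzable graph")
    removed = [rid for rid, k in zip(graph.region_ids, keep) if not k]
    if not removed:
        return graph, []
    idx = np.nonzero(keep)[0]
    sub_ids = tuple(graph.region_ids[i] for i in idx)
    subW = graph.W[np.ix_(idx, idx)]
    return RegionGraph(sub_ids, subW), removed


# ---------------------------------------------------------------------------
# I/O

def read_geojson_regions(path, id_property: str = "region_id") -> dict:
    """Read a GeoJSON FeatureCollection into {region_id: shapely geometry}."""
    with open(path) as fh:
        fc = json.load(fh)
    if fc.get("type") != "FeatureCollection":
        raise GeographyError("expected a GeoJSON FeatureCollection")
    out = {}
    for feat in fc["features"]:
        props = feat.get("properties") or {}
        if id_property not in props:
            raise GeographyError(f"feature missing property {id_property!r}")
        rid = props[id_property]
        if rid in out:
            raise GeographyError(f"duplicate region ids: [{rid!r}]")
        out[rid] = shapely_shape(feat["geometry"])
    return out


def read_edge_csv(path) -> pd.DataFrame:
    """Read a two-column neighbour-pair CSV (columns id_a, id_b)."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise GeographyError("edge CSV needs two columns")
    return df.iloc[:, :2].set_axis(["id_a", "id_b"], axis=1)


def write_edge_csv(graph: RegionGraph, path) -> None:
    pd.DataFrame(graph.edges(), columns=["id_a", "id_b"]).to_csv(path, index=False)


def write_weights_coo(graph: RegionGraph, path) -> None:
    """Write W in sparse coordinate (row_id, col_id, weight) CSV form."""
    ii, jj = np.nonzero(graph.W)
    pd.DataFrame(
        {
            "row_id": [graph.region_ids[i] for i in ii],
            "col_id": [graph.region_ids[j] for j in jj],
            "weight": 1,
        }
    ).to_csv(path, index=False)
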