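"""Raster/vector computations for spatially explicit impact prediction.

* **Topographic impedance surface (TIS)** — a per-cell index of how much
  terrain deviates below the line of sight connecting the cell to a point
  source of noise and light (e.g. a power plant).  For every start cell, the
  straight segment of cells to the source is traced (supercover: every cell
  the segment touches), a baseline elevation is interpolated at constant
  slope between the start- and end-cell elevations, and the maximum of
  (baseline - elevation) along the line is assigned to the start cell.  A
  sign flag flips the convention to occlusion by high terrain.
* Distance covariates to the nearest infrastructure feature (Euclidean or
  exponential-decay form).
* Neighbourhood percent cover within a radius of a point (cell-centre
  inclusion rule).
* Single-linkage clustering of candidate development sites within a radius,
  merged clusters carrying summed attributes at their centroid.
* Impact ranking of candidate sites by the buffered sum of a
  (delta lambda_P x abundance index) surface.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .raster import PointSet, RasterGrid

__all__ = [
    "supercover_line",
    "compute_tis",
    "distance_covariates",
    "neighborhood_percent_cover",
    "cluster_candidates",
    "rank_sites",
]


def supercover_line(r0: int, c0: int, r1: int, c1: int) -> np.ndarray:
    """All (row, col) cells touched by the segment joining the centres of
    (r0, c0) and (r1, c1), in traversal order (Amanatides-Woo grid walk)."""
    cells = [(r0, c0)]
    x, y = c0 + 0.5, r0 + 0.5          # continuous coords, cell units
    x1, y1 = c1 + 0.5, r1 + 0.5
    dx, dy = x1 - x, y1 - y
    n_steps = abs(c1 - c0) + abs(r1 - r0)
    c, r = c0, r0
    step_c = 1 if dx > 0 else -1
    step_r = 1 if dy > 0 else -1
    t_max_x = np.inf if dx == 0 else ((c + (step_c > 0)) - x) / dx
    t_max_y = np.inf if dy == 0 else ((r + (step_r > 0)) - y) / dy
    t_dx = np.inf if dx == 0 else abs(1.0 / dx)
    t_dy = np.inf if dy == 0 else abs(1.0 / dy)
    for _ in range(n_steps):
        if t_max_x < t_max_y:
            c += step_c
            t_max_x += t_dx
        elif t_max_y < t_max_x:
            r += step_r
            t_max_y += t_dy
        else:  # exact corner: step both (supercover includes both neighbours)
            cells.append((r, c + step_c))
            cells.append((r + step_r, c))
            c += step_c
            r += step_r
            t_max_x += t_dx
            t_max_y += t_dy
        cells.append((r, c))
        if (r, c) == (r1, c1):
            break
    # corner stepping can append duplicates/overshoot; keep unique order
    seen = set()
    out = []
    for rc in cells:
        if rc not in seen:
            seen.add(rc)
            out.append(rc)
    return np.asarray(out, dtype=int)


def compute_tis(
    dem: RasterGrid,
    source_cell: tuple[int, int],
    extent_mask: np.ndarray | None = None,
    sign: str = "below_line",
) -> RasterGrid:
    """Topographic impedance surface toward a point-source cell.

    For each start cell in the extent, trace the supercover line of cells to
    the source, interpolate a constant-slope baseline between the start and
    source elevations, and assign the maximum (baseline - elevation)
    difference along the line.  ``sign='above_line'`` flips the subtraction
    (occlusion by terrain rising above the sightline).  Nodata anywhere on a
    line propagates nodata to its start cell.
    """
    nr, nc = dem.shape
    sr, sc = source_cell
    if not (0 <= sr < nr and 0 <= sc < nc):
        raise ValueError("source cell outside the DEM")
    if sign not in ("below_line", "above_line"):
        raise ValueError("sign must be 'below_line' or 'above_line'")
    if extent_mask is None:
        extent_mask = np.ones(dem.shape, dtype=bool)
    elif extent_mask.shape != dem.shape:
        raise ValueError("extent mask must match the DEM shape")

    z = dem.values
    valid = dem.mask_valid()
    out = np.full(dem.shape, dem.nodata)
    n_nodata = 0
    z_src = z[sr, sc]
    for r in range(nr):
        for c in range(nc):
            if not extent_mask[r, c]:
                continue
            line = supercover_line(r, c, sr, sc)
            lv = z[line[:, 0], line[:, 1]]
            if not (valid[line[:, 0], line[:, 1]].all() and valid[sr, sc]):
                n_nodata += 1
                continue
            # fractional position of each cell along the start->source segment
            if len(line) == 1:
                out[r, c] = 0.0
                continue
            d = np.hypot(line[:, 0] - r, line[:, 1] - c)
            frac = d / max(np.hypot(sr - r, sc - c), 1e-12)
            baseline = z[r, c] + frac * (z_src - z[r, c])
            diff = baseline - lv if sign == "below_line" else lv - baseline
            out[r, c] = float(diff.max())
    if n_nodata:
        import warnings

        warnings.warn(f"{n_nodata} start cells hit nodata along their line", stacklevel=2)
    return RasterGrid(out, origin=dem.origin, cell_size=dem.cell_size,
                      crs=dem.crs, nodata=dem.nodata)


def distance_covariates(
    points_xy: np.ndarray,
    infrastructure,
    form: str = "euclidean",
    decay_scale: float | None = None,
) -> np.ndarray:
    """Distance from each point to the nearest infrastructure feature.

    ``infrastructure`` is a :class:`PointSet` or any iterable of shapely
    geometries (edges of lines/polygons count, matching distance-to-nearest-
    edge semantics).  ``form='expdecay'`` returns ``exp(-d / decay_scale)``.
    """
    from shapely.geometry import Point

    pts = np.atleast_2d(np.asarray(points_xy, dtype=float))
    if isinstance(infrastructure, PointSet):
        geoms = [Point(x, y) for x, y in infrastructure.xy]
    else:
        geoms = list(infrastructure)
    if not geoms:
        raise ValueError("empty infrastructure")
    d = np.array([min(g.distance(Point(x, y)) for g in geoms) for x, y in pts])
    if form == "euclidean":
        return d
    if form == "expdecay":
        if not decay_scale or decay_scale <= 0:
            raise ValueError("expdecay form needs a positive decay_scale")
        return np.exp(-d / decay_scale)
    raise ValueError("form must be 'euclidean' or 'expdecay'")


def neighborhood_percent_cover(
    raster: RasterGrid, points_xy: np.ndarray, radius_m: float
) -> np.ndarray:
    """Mean raster value over cells whose centres fall within ``radius_m``
    of each point (percent cover when the raster is binary/percent).

    The radius must be at least half a cell so the neighbourhood is
    non-empty; a point off the raster is an error.
    """
    if radius_m < raster.cell_size / 2:
        raise ValueError("radius must be >= half the cell size")
    pts = np.atleast_2d(np.asarray(points_xy, dtype=float))
    X, Y = raster.cell_centers()
    vals = raster.values
    valid = raster.mask_valid()
    out = np.empty(len(pts))
    for i, (x, y) in enumerate(pts):
        if not raster.contains(x, y):
            raise ValueError(f"point ({x}, {y}) is off the raster")
        inside = ((X - x) ** 2 + (Y - y) ** 2 <= radius_m**2) & valid
        out[i] = vals[inside].mean() if inside.any() else np.nan
    return out


def cluster_candidates(points: PointSet, radius_km: float = 4.0) -> PointSet:
    """Merge candidate sites within ``radius_km`` of one another
    (single-linkage connected components); each cluster becomes its
    centroid carrying summed numeric attributes."""
    if len(points) == 0:
        raise ValueError("need at least one candidate point")
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import pdist

    if len(points) == 1:
        return points
    d = pdist(points.xy)
    labels = fcluster(linkage(d, method="single"), t=radius_km * 1000.0, criterion="distance")
    ids, xy = [], []
    attrs: dict[str, list] = {k: [] for k, v in points.attributes.items()
                              if np.issubdtype(np.asarray(v).dtype, np.number)}
    for lab in np.unique(labels):
        members = np.flatnonzero(labels == lab)
        if len(members) == 1:
            ids.append(points.ids[members[0]])
        else:
            ids.append("+".join(str(points.ids[m]) for m in members))
        xy.append(points.xy[members].mean(axis=0))
        for k in attrs:
            attrs[k].append(np.asarray(points.attributes[k])[members].sum())
    return PointSet(ids, np.asarray(xy), {k: np.asarray(v) for k, v in attrs.items()},
                    crs=points.crs)


def rank_sites(
    delta_lambda: RasterGrid,
    aui: RasterGrid,
    sites: PointSet,
    buffers_km: tuple[float, ...] = (2.0, 5.0, 10.0),
) -> pd.DataFrame:
    """Rank candidate sites by summed (delta lambda_P x AUI) within buffers.

    For each site and buffer radius, cells whose centres fall inside the
    buffer contribute the product of the two aligned surfaces; sites are
    ranked descending per buffer (rank 1 = greatest potential impact).
    """
    if not delta_lambda.aligned_with(aui):
        raise ValueError("delta-lambda and AUI rasters are not aligned")
    X, Y = delta_lambda.cell_centers()
    prod = np.where(
        delta_lambda.mask_valid() & aui.mask_valid(),
        delta_lambda.values * aui.values,
        0.0,
    )
    rows = []
    for i, (x, y) in enumerate(sites.xy):
        row = {"site_id": sites.ids[i]}
        for b in buffers_km:
            inside = (X - x) ** 2 + (Y - y) ** 2 <= (b * 1000.0) ** 2
            row[f"score_{b:g}km"] = float(prod[inside].sum())
        rows.append(row)
    tab = pd.DataFrame(rows)
    for b in buffers_km:
        tab[f"rank_{b:g}km"] = (
            tab[f"score_{b:g}km"].rank(ascending=False, method="min").astype(int)
        )
    return tab
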