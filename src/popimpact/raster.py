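"""Lightweight planar raster and point-set containers.

Rasters are regular grids in projected metre coordinates, row-major from the
north-west origin with cell-centre semantics.  GeoTIFF round-tripping is done
with :mod:`tifffile`; the geotransform and CRS tag travel in a JSON
ImageDescription so files written here read back losslessly.  Point sets
serialise as GeoJSON FeatureCollections.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["RasterGrid", "PointSet"]

NODATA_DEFAULT = -9999.0


@dataclass
class RasterGrid:
    """Regular 2-D grid of cell values.

    ``origin`` is the (x, y) of the north-west corner of the grid; cell
    (row 0, col 0) is centred at ``origin + (cell/2, -cell/2)``.
    """

    values: np.ndarray
    origin: tuple[float, float] = (0.0, 0.0)
    cell_size: float = 30.0
    crs: str = "local-metres"
    nodata: float = NODATA_DEFAULT

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) arrays of cell-centre coordinates, shape = raster shape."""
        nr, nc = self.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(nc) + 0.5) * self.cell_size
        ys = y0 - (np.arange(nr) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) containing planar point (x, y)."""
        x0, y0 = self.origin
        col = int(np.floor((x - x0) / self.cell_size))
        row = int(np.floor((y0 - y) / self.cell_size))
        return row, col

    def contains(self, x: float, y: float) -> bool:
        r, c = self.cell_of(x, y)
        nr, nc = self.shape
        return 0 <= r < nr and 0 <= c < nc

    def center_of(self, row: int, col: int) -> tuple[float, float]:
        x0, y0 = self.origin
        return (
            x0 + (col + 0.5) * self.cell_size,
            y0 - (row + 0.5) * self.cell_size,
        )

    def mask_valid(self) -> np.ndarray:
        return self.values != self.nodata

    def aligned_with(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.origin, other.origin)
            and np.isclose(self.cell_size, other.cell_size)
            and self.crs == other.crs
        )

    # -- I/O ---------------------------------------------------------------

    def to_tiff(self, path) -> None:
        import tifffile

        meta = {
            "origin": list(self.origin),
            "cell_size": self.cell_size,
            "crs": self.crs,
            "nodata": self.nodata,
        }
        tifffile.imwrite(
            str(path), self.values.astype(np.float32), description=json.dumps(meta)
        )

    @classmethod
    def from_tiff(cls, path) -> "RasterGrid":
        import tifffile

        with tifffile.TiffFile(str(path)) as tf:
            page = tf.pages[0]
            values = page.asarray().astype(float)
            desc = page.tags.get("ImageDescription")
            meta = json.loads(desc.value) if desc is not None else {}
        return cls(
            values,
            origin=tuple(meta.get("origin", (0.0, 0.0))),
            cell_size=float(meta.get("cell_size", 30.0)),
            crs=meta.get("crs", "local-metres"),
            nodata=float(meta.get("nodata", NODATA_DEFAULT)),
        )


@dataclass
class PointSet:
    """Identified points with per-point attribute columns (same planar CRS
    as the rasters they accompany)."""

    ids: list
    xy: np.ndarray  # (n, 2)
    attributes: dict[str, np.ndarray] = field(default_factory=dict)
    crs: str = "local-metres"

    def __post_init__(self):
        self.xy = np.atleast_2d(np.asarray(self.xy, dtype=float))
        if self.xy.shape[1] != 2:
            raise ValueError("xy must be (n, 2)")
        if len(self.ids) != len(self.xy):
            raise ValueError("ids and xy length mismatch")
        if not np.all(np.isfinite(self.xy)):
            raise ValueError("coordinates must be finite")
        self.attributes = {
            k: np.asarray(v) for k, v in self.attributes.items()
        }
        for k, v in self.attributes.items():
            if len(v) != len(self.xy):
                raise ValueError(f"attribute {k!r} length mismatch")

    def __len__(self) -> int:
        return len(self.ids)

    # -- I/O ---------------------------------------------------------------

    def to_geojson(self, path) -> None:
        feats = []
        for i, pid in enumerate(self.ids):
            props = {"id": pid}
            for k, v in self.attributes.items():
                val = v[i]
                props[k] = val.item() if hasattr(val, "item") else val
            feats.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Point", "coordinates": list(self.xy[i])},
                    "properties": props,
                }
            )
        obj = {"type": "FeatureCollection", "crs_tag": self.crs, "features": feats}
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_geojson(cls, path) -> "PointSet":
        with open(path, encoding="utf-8") as fh:
            obj = json.load(fh)
        ids, xy = [], []
        attrs: dict[str, list] = {}
        for feat in obj["features"]:
            if feat["geometry"]["type"] != "Point":
                raise ValueError("only Point features supported")
            props = dict(feat.get("properties") or {})
            ids.append(props.pop("id", len(ids)))
            xy.append(feat["geometry"]["coordinates"][:2])
            for k, v in props.items():
                attrs.setdefault(k, []).append(v)
        return cls(
            ids,
            np.asarray(xy, dtype=float),
            {k: np.asarray(v) for k, v in attrs.items()},
            crs=obj.get("crs_tag", "local-metres"),
        )
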