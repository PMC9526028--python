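"""Simplified land-cover extraction around sites.

A class-label raster (plain integer grid with projected origin and square
pixels in meters) is reduced to per-site proportions of aggregated cover
classes within circular buffers. Pixels are counted when their centers lie
within the radius; water pixels are removed from both numerator and
denominator, so the remaining proportions sum to 1. Buffers that are not
fully contained in the raster extent are flagged and the site is skipped,
not silently truncated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ecofilter.data_model import COVER_CLASSES, SiteTable

AGGREGATED = COVER_CLASSES + ("water", "other")


@dataclass
class LandCoverRaster:
    """Integer class-label grid. Row 0 is the northern edge; ``origin`` is
    the (x, y) of the grid's lower-left corner in projected meters."""

    grid: np.ndarray
    pixel_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    legend: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise ValueError("raster grid must be 2-D")
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be positive")
        labels = set(np.unique(self.grid).tolist())
        unknown = labels - set(self.legend)
        if self.legend and unknown:
            raise ValueError(f"labels missing from legend: {sorted(unknown)}")

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) in projected meters."""
        ny, nx = self.grid.shape
        x0, y0 = self.origin
        return (x0, y0, x0 + nx * self.pixel_size, y0 + ny * self.pixel_size)

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.grid.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(nx) + 0.5) * self.pixel_size
        ys = y0 + (ny - np.arange(ny) - 0.5) * self.pixel_size
        return xs, ys

    def to_ascii(self, path: str | Path) -> None:
        """Write as an ESRI ASCII grid (plain text)."""
        ny, nx = self.grid.shape
        header = (f"ncols {nx}\nnrows {ny}\nxllcorner {self.origin[0]}\n"
                  f"yllcorner {self.origin[1]}\ncellsize {self.pixel_size}\n"
                  f"NODATA_value -9999\n")
        body = "\n".join(" ".join(str(int(v)) for v in row)
                         for row in self.grid)
        Path(path).write_text(header + body + "\n")

    @classmethod
    def from_ascii(cls, path: str | Path,
                   legend: dict[int, str] | None = None) -> "LandCoverRaster":
        lines = Path(path).read_text().splitlines()
        meta: dict[str, float] = {}
        body_start = 0
        for i, line in enumerate(lines):
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in (
                    "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                    "nodata_value"):
                meta[parts[0].lower()] = float(parts[1])
                body_start = i + 1
            else:
                break
        grid = np.array([[int(float(v)) for v in line.split()]
                         for line in lines[body_start:] if line.strip()])
        return cls(grid, meta["cellsize"],
                   (meta.get("xllcorner", 0.0), meta.get("yllcorner", 0.0)),
                   legend or {})


@dataclass
class ClassAggregation:
    """Mapping from raw raster classes to the aggregated cover classes."""

    mapping: dict[int, str]

    def __post_init__(self) -> None:
        bad = set(self.mapping.values()) - set(AGGREGATED)
        if bad:
            raise ValueError(f"unknown aggregated classes: {sorted(bad)}")

    def aggregate(self, labels: np.ndarray) -> np.ndarray:
        unknown = set(np.unique(labels).tolist()) - set(self.mapping)
        if unknown:
            raise ValueError(f"unmapped raster labels: {sorted(unknown)}")
        lut = np.empty(max(self.mapping) + 1, dtype=object)
        for k, v in self.mapping.items():
            lut[k] = v
        return lut[labels]


class BufferNotContainedError(ValueError):
    pass


def buffer_proportions(
    raster: LandCoverRaster,
    point: tuple[float, float],
    radius_m: float,
    aggregation: ClassAggregation,
) -> dict[str, float]:
    """Aggregated cover proportions within a circular buffer.

    Water is excluded from numerator and denominator; the returned
    proportions over the non-water classes sum to 1.
    """
    x, y = point
    xmin, ymin, xmax, ymax = raster.extent
    if (x - radius_m < xmin or x + radius_m > xmax
            or y - radius_m < ymin or y + radius_m > ymax):
        raise BufferNotContainedError(
            f"buffer of {radius_m} m around ({x}, {y}) exceeds raster extent")
    xs, ys = raster.pixel_centers()
    inside = ((xs[None, :] - x) ** 2 + (ys[:, None] - y) ** 2
              <= radius_m**2)
    labels = aggregation.aggregate(raster.grid[inside])
    counts = pd.Series(labels).value_counts()
    nonwater = counts.drop("water", errors="ignore")
    total = int(nonwater.sum())
    if total == 0:
        raise ValueError("buffer contains only water")
    out = {cls: 0.0 for cls in AGGREGATED if cls != "water"}
    for cls, n in nonwater.items():
        out[cls] = n / total
    return out


def attach_covariates(
    sites: SiteTable,
    raster: LandCoverRaster,
    aggregation: ClassAggregation,
    radii: tuple[int, ...] = (250, 500),
) -> tuple[SiteTable, list[str]]:
    """Extract land-cover proportions at each scale and add them to the
    site table. Sites whose largest buffer is not fully contained are
    dropped; their ids are returned for logging."""
    coords = sites.coordinates()
    if coords.isna().any().any():
        bad = list(coords.index[coords.isna().any(axis=1)])
        raise ValueError(f"missing coordinates for sites: {bad}")
    data = sites.data.copy()
    dropped: list[str] = []
    for site in sites.site_ids:
        x, y = float(coords.loc[site, "x"]), float(coords.loc[site, "y"])
        try:
            for radius in radii:
                props = buffer_proportions(raster, (x, y), radius, aggregation)
                for cls in COVER_CLASSES:
                    data.loc[site, f"{cls}_{radius}"] = props[cls]
        except BufferNotContainedError:
            dropped.append(site)
    data = data.drop(index=dropped)
    return SiteTable(data, tuple(radii)), dropped
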