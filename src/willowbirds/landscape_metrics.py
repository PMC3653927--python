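"""Willow-thicket areal extent and fragmentation metrics from binary rasters.

Metrics are computed inside a square quadrat (default 200 m, i.e. 4 ha)
centred on a sampling point: percent cover, patch density (distinct patches
under 8-connectivity, with components closer than a merge gap treated as one
patch) and edge density (metres of willow/non-willow interface).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree


@dataclass
class WillowMask:
    """Binary willow raster. ``grid[r, c]`` with row 0 at the origin corner."""

    grid: np.ndarray
    pixel_size: float = 0.20
    origin: tuple[float, float] = (0.0, 0.0)  # world (x, y) of grid corner

    def __post_init__(self):
        self.grid = np.asarray(self.grid)
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.grid.ndim != 2:
            raise ValueError("grid must be 2-D")
        if not np.isin(self.grid, (0, 1)).all():
            raise ValueError("grid entries must be 0/1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def write_text(self, path) -> None:
        """Whitespace-delimited grid with a 3-line header (nrows, ncols, pixel_size)."""
        nr, nc = self.grid.shape
        with open(path, "w") as fh:
            fh.write(f"nrows {nr}\nncols {nc}\npixel_size {self.pixel_size}\n")
            np.savetxt(fh, self.grid.astype(np.int8), fmt="%d")

    @classmethod
    def read_text(cls, path) -> "WillowMask":
        with open(path) as fh:
            header = {}
            for _ in range(3):
                key, value = fh.readline().split()
                header[key] = value
            grid = np.loadtxt(fh, dtype=np.int8)
        grid = np.atleast_2d(grid)
        if grid.shape != (int(header["nrows"]), int(header["ncols"])):
            raise ValueError("grid shape does not match header")
        return cls(grid=grid, pixel_size=float(header["pixel_size"]))

    @classmethod
    def read_geotiff(cls, path, pixel_size: float = 0.20) -> "WillowMask":
        import tifffile

        grid = np.asarray(tifffile.imread(path))
        if grid.ndim != 2:
            raise ValueError("expected a single-band raster")
        return cls(grid=(grid > 0).astype(np.int8), pixel_size=pixel_size)


@dataclass(frozen=True)
class Quadrat:
    centre: tuple[float, float]  # world (x, y)
    side: float = 200.0

    def __post_init__(self):
        if self.side <= 0:
            raise ValueError("quadrat side must be positive")


@dataclass
class PatchLabeling:
    labels: np.ndarray  # 0 = background, 1..P = patch ids
    n_patches: int


@dataclass(frozen=True)
class ThicketMetrics:
    area_pct: float
    patch_density: int
    edge_density: float

    def __post_init__(self):
        if not 0.0 <= self.area_pct <= 100.0:
            raise ValueError("area_pct out of [0, 100]")


class QuadratOutOfBounds(ValueError):
    pass


def extract_quadrat(mask: WillowMask, quadrat: Quadrat) -> WillowMask:
    """Cut the quadrat window out of the raster.

    The quadrat centre snaps to the nearest pixel-centre-aligned window so
    the result is exactly ``side / pixel_size`` pixels on a side.
    """
    n = int(round(quadrat.side / mask.pixel_size))
    if n <= 0:
        raise ValueError("quadrat smaller than one pixel")
    cx, cy = quadrat.centre
    ox, oy = mask.origin
    # fractional pixel index of the window's low corner
    col0 = int(round((cx - ox) / mask.pixel_size - n / 2))
    row0 = int(round((cy - oy) / mask.pixel_size - n / 2))
    nr, nc = mask.grid.shape
    if row0 < 0 or col0 < 0 or row0 + n > nr or col0 + n > nc:
        raise QuadratOutOfBounds(
            f"quadrat rows [{row0}, {row0 + n}) cols [{col0}, {col0 + n}) "
            f"exceed raster of shape {mask.grid.shape}"
        )
    sub = mask.grid[row0 : row0 + n, col0 : col0 + n]
    return WillowMask(
        grid=sub,
        pixel_size=mask.pixel_size,
        origin=(ox + col0 * mask.pixel_size, oy + row0 * mask.pixel_size),
    )


_EIGHT = np.ones((3, 3), dtype=int)


def _boundary_pixels(component: np.ndarray) -> np.ndarray:
    """Row/col coordinates of pixels on the 4-boundary of a boolean component."""
    eroded = ndimage.binary_erosion(component, border_value=0)
    return np.argwhere(component & ~eroded)


def label_patches(mask: WillowMask, merge_gap_m: float = 2.0) -> PatchLabeling:
    """Label willow patches: 8-connected components, then merge components
    whose minimum pixel-centre distance is <= ``merge_gap_m``.

    Labels are renumbered 1..P in row-major order of each patch's first pixel.
    """
    raw, n_raw = ndimage.label(mask.grid, structure=_EIGHT)
    if n_raw == 0:
        return PatchLabeling(labels=np.zeros_like(raw), n_patches=0)

    # minimum inter-component distance is attained between boundary pixels
    boundaries = [
        _boundary_pixels(raw == k) * mask.pixel_size for k in range(1, n_raw + 1)
    ]
    trees = [cKDTree(b) for b in boundaries]

    parent = list(range(n_raw))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    for i in range(n_raw):
        for j in range(i + 1, n_raw):
            d, _ = trees[i].query(boundaries[j], k=1)
            if d.min() <= merge_gap_m + 1e-12:
                union(i, j)

    groups = [find(i) for i in range(n_raw)]
    merged = np.zeros_like(raw)
    for k in range(1, n_raw + 1):
        merged[raw == k] = groups[k - 1] + 1

    # renumber by row-major first occurrence
    flat = merged.ravel()
    order = []
    seen = set()
    for v in flat[flat > 0]:
        if v not in seen:
            seen.add(v)
            order.append(v)
    remap = {old: new for new, old in enumerate(order, start=1)}
    labels = np.zeros_like(merged)
    for old, new in remap.items():
        labels[merged == old] = new
    return PatchLabeling(labels=labels, n_patches=len(order))


def edge_length(mask: WillowMask, include_border: bool = False) -> float:
    """Metres of willow/non-willow interface between 4-adjacent pixel pairs.

    The grid border contributes nothing unless ``include_border`` is set, in
    which case willow pixels on the border add their outward sides.
    """
    g = mask.grid
    n_pairs = int(np.sum(g[:, 1:] != g[:, :-1])) + int(np.sum(g[1:, :] != g[:-1, :]))
    total = n_pairs * mask.pixel_size
    if include_border:
        border = (
            int(g[0, :].sum())
            + int(g[-1, :].sum())
            + int(g[:, 0].sum())
            + int(g[:, -1].sum())
        )
        total += border * mask.pixel_size
    return float(total)


def thicket_metrics(
    mask: WillowMask,
    quadrat: Quadrat | None = None,
    merge_gap_m: float = 2.0,
    include_border: bool = False,
) -> ThicketMetrics:
    """Percent cover, patch count and edge metres within the quadrat."""
    window = mask if quadrat is None else extract_quadrat(mask, quadrat)
    n_willow = int(window.grid.sum())
    area_pct = 100.0 * n_willow / window.grid.size
    if n_willow == 0:
        return ThicketMetrics(area_pct=0.0, patch_density=0, edge_density=0.0)
    labeling = label_patches(window, merge_gap_m=merge_gap_m)
    return ThicketMetrics(
        area_pct=area_pct,
        patch_density=labeling.n_patches,
        edge_density=edge_length(window, include_border=include_border),
    )
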