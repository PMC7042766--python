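"""Gridded covariate layers and the operations that prepare them as resistance inputs.

A :class:`RasterLayer` is a single-band grid in a projected coordinate system
(meters), row 0 at the north edge, with an optional nodata mask.  The module
covers the four covariate layers used as gene-flow hypotheses — a water/land
barrier, percent tree cover, road density, and interpolated annual snowfall —
plus block aggregation onto a common coarse grid.

Raster I/O uses the ESRI ASCII grid format (plain text, ``.asc``), which keeps
the affine metadata (cell size, lower-left origin, nodata value) round-trippable
without a GIS dependency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage


@dataclass
class RasterLayer:
    """Single-band raster: 2-D values, cell size in meters, nodata mask.

    Parameters
    ----------
    values : ndarray of shape (nrows, ncols)
        Cell values.  Masked cells may hold any value (conventionally NaN).
    cell_size : float
        Edge length of a square cell, in meters.
    origin : tuple of float
        (x, y) of the *top-left corner* of the grid in projected meters;
        row 0 is the north edge.
    mask : ndarray of bool, optional
        True where the cell is valid.  Defaults to all-valid (non-NaN).
    kind : {"continuous", "categorical"}
        Aggregation and transform semantics.
    levels : tuple, optional
        Declared level set for categorical layers.
    """

    values: np.ndarray
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    mask: np.ndarray | None = None
    kind: str = "continuous"
    levels: tuple = field(default_factory=tuple)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape must match values")
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"unknown raster kind {self.kind!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy_with(self, **kw) -> "RasterLayer":
        return replace(self, **kw)

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """Projected (x, y) of a cell center; row 0 is the north edge."""
        x0, y0 = self.origin
        return (x0 + (col + 0.5) * self.cell_size,
                y0 - (row + 0.5) * self.cell_size)

    def nearest_cell(self, x: float, y: float) -> tuple[int, int]:
        x0, y0 = self.origin
        col = int(np.floor((x - x0) / self.cell_size))
        row = int(np.floor((y0 - y) / self.cell_size))
        nr, nc = self.shape
        return (min(max(row, 0), nr - 1), min(max(col, 0), nc - 1))

    def same_grid(self, other: "RasterLayer", tol: float = 1e-6) -> bool:
        return (self.shape == other.shape
                and abs(self.cell_size - other.cell_size) <= tol
                and abs(self.origin[0] - other.origin[0]) <= tol
                and abs(self.origin[1] - other.origin[1]) <= tol)


# ---------------------------------------------------------------------------
# ASCII grid I/O

def write_ascii_grid(layer: RasterLayer, path, nodata: float = -9999.0) -> None:
    """Write a layer as an ESRI ASCII grid (text)."""
    vals = np.where(layer.mask, layer.values, nodata)
    nr, nc = layer.shape
    x0, ytop = layer.origin
    yll = ytop - nr * layer.cell_size
    header = (f"ncols {nc}\nnrows {nr}\nxllcorner {x0}\nyllcorner {yll}\n"
              f"cellsize {layer.cell_size}\nNODATA_value {nodata}\n")
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.8g")


def read_ascii_grid(path, kind: str = "continuous") -> RasterLayer:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for ln in lines:
        parts = ln.split()
        if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value"):
            meta[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    vals = np.loadtxt(lines[n_header:])
    vals = np.atleast_2d(vals)
    nodata = meta.get("nodata_value", -9999.0)
    mask = vals != nodata
    vals = np.where(mask, vals, np.nan)
    cs = meta["cellsize"]
    ytop = meta["yllcorner"] + meta["nrows"] * cs
    return RasterLayer(vals, cell_size=cs, origin=(meta["xllcorner"], ytop),
                       mask=mask, kind=kind)


# ---------------------------------------------------------------------------
# Station records (snowfall)

@dataclass
class StationRecords:
    """Climate-station point records for interpolation.

    x, y in projected meters; ``snow_cm`` is the station's mean annual
    snowfall (cm/yr); ``years`` the record length used for screening.
    """

    x: np.ndarray
    y: np.ndarray
    snow_cm: np.ndarray
    years: np.ndarray | None = None

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.snow_cm = np.asarray(self.snow_cm, dtype=float)
        if self.years is not None:
            self.years = np.asarray(self.years, dtype=float)
        if np.any(self.snow_cm < 0):
            raise ValueError("snowfall must be nonnegative")

    def screened(self, min_years: float = 15.0) -> "StationRecords":
        if self.years is None:
            return self
        keep = self.years >= min_years
        return StationRecords(self.x[keep], self.y[keep],
                              self.snow_cm[keep], self.years[keep])

    def __len__(self):
        return self.x.size


# ---------------------------------------------------------------------------
# Layer construction

def make_barrier_layer(water_mask: RasterLayer) -> RasterLayer:
    """Code a boolean water mask as a categorical barrier: 1 = water, 2 = land."""
    vals = water_mask.values[water_mask.mask]
    if not np.all(np.isin(vals, (0.0, 1.0))):
        raise ValueError("water mask must be boolean-valued (0/1)")
    coded = np.where(water_mask.values == 1.0, 1.0, 2.0)
    return water_mask.copy_with(values=coded, kind="categorical",
                                levels=(1, 2))


def recode_forest(raw: RasterLayer) -> RasterLayer:
    """Recode a percent-tree-cover layer to a usable continuous percentage.

    The source convention uses 10–80 for percent cover, 254 for nonvegetated
    and 255 for <10% vegetated.  Nonvegetated cells become 1 and sparsely
    vegetated cells 5; in-range percentages pass through unchanged.
    """
    vals = raw.values.copy()
    in_conv = np.isin(vals, np.concatenate([np.arange(10, 81), [254, 255]]))
    bad = raw.mask & ~in_conv
    if np.any(bad):
        warnings.warn(f"{int(bad.sum())} cells outside the 10-80/254/255 "
                      "convention passed through unchanged")
    vals[vals == 254] = 1.0
    vals[vals == 255] = 5.0
    return raw.copy_with(values=vals, kind="continuous")


def road_density(road_length_per_cell: RasterLayer, radius_m: float,
                 mode: str = "constant") -> RasterLayer:
    """Road density (km/km²) in a circular window around every cell.

    The input gives total road length (m) intersecting each cell; output cell
    i is the summed length within ``radius_m`` of i's center divided by the
    window area.  ``mode`` is the boundary handling passed to the convolution
    ("constant" pads with zero roads; "wrap" treats the grid as periodic).
    """
    cs = road_length_per_cell.cell_size
    if radius_m < cs / 2:
        raise ValueError("radius must be at least half a cell")
    r_cells = int(np.floor(radius_m / cs))
    yy, xx = np.mgrid[-r_cells:r_cells + 1, -r_cells:r_cells + 1]
    kernel = ((xx * cs) ** 2 + (yy * cs) ** 2) <= radius_m ** 2
    lengths = np.where(road_length_per_cell.mask,
                       road_length_per_cell.values, 0.0)
    total_m = ndimage.convolve(lengths, kernel.astype(float), mode=mode,
                               cval=0.0)
    area_km2 = np.pi * (radius_m / 1000.0) ** 2
    dens = (total_m / 1000.0) / area_km2
    dens = np.where(road_length_per_cell.mask, dens, np.nan)
    return road_length_per_cell.copy_with(values=dens, kind="continuous")


# ---------------------------------------------------------------------------
# Ordinary kriging with a spherical variogram

def spherical_variogram(h, nugget: float, sill: float, vrange: float):
    """Spherical semivariogram γ(h); sill is the total sill (nugget + partial)."""
    h = np.asarray(h, dtype=float)
    hr = np.minimum(h / vrange, 1.0)
    gamma = nugget + (sill - nugget) * (1.5 * hr - 0.5 * hr ** 3)
    return np.where(h == 0, 0.0, gamma)


def fit_spherical_variogram(stations: StationRecords, n_bins: int = 15):
    """Weighted-least-squares fit of (nugget, sill, range) to the empirical
    semivariogram with ``n_bins`` equal-width lag bins (weights N(h)/γ²)."""
    from scipy.optimize import least_squares

    pts = np.column_stack([stations.x, stations.y])
    z = stations.snow_cm
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    iu = np.triu_indices(len(z), k=1)
    h = d[iu]
    sv = 0.5 * (z[iu[0]] - z[iu[1]]) ** 2
    edges = np.linspace(0, h.max(), n_bins + 1)
    idx = np.clip(np.digitize(h, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        gamma_emp = np.bincount(idx, weights=sv, minlength=n_bins) / counts
        h_mid = np.bincount(idx, weights=h, minlength=n_bins) / counts
    ok = counts > 0
    gamma_emp, h_mid, counts = gamma_emp[ok], h_mid[ok], counts[ok]

    s0 = max(sv.mean(), 1e-12)
    r0 = h.max() / 2

    def resid(p):
        nug, psill, rng = np.exp(p)
        g = spherical_variogram(h_mid, nug, nug + psill, rng)
        w = np.sqrt(counts) / np.maximum(g, 1e-12)
        return w * (gamma_emp - g)

    sol = least_squares(resid, x0=np.log([s0 * 0.1 + 1e-9, s0, r0]))
    nug, psill, rng = np.exp(sol.x)
    return float(nug), float(nug + psill), float(rng)


def krige_snow(stations: StationRecords, grid: RasterLayer,
               variogram: tuple[float, float, float] | None = None,
               min_years: float = 0.0) -> RasterLayer:
    """Ordinary kriging of station snowfall onto ``grid``'s geometry.

    ``variogram`` is (nugget, sill, range) for the spherical model; if None it
    is fitted to the stations by weighted least squares.  The kriging weights
    solve the ordinary-kriging system with the unbiasedness constraint
    (weights sum to 1), so the predictor is exact at stations when nugget = 0.
    """
    st = stations.screened(min_years) if min_years else stations
    if len(st) < 2:
        raise ValueError("need at least 2 stations")
    pts = np.column_stack([st.x, st.y])
    # duplicate stations make the system singular
    d_st = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    dup = np.argwhere((d_st < 1e-9) & ~np.eye(len(st), dtype=bool))
    if dup.size:
        i, j = dup[0]
        raise ValueError(f"duplicate station locations at indices {i} and {j}")
    if variogram is None:
        variogram = fit_spherical_variogram(st)
    nug, sill, rng = variogram

    n = len(st)
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = spherical_variogram(d_st, nug, sill, rng)
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    A[n, n] = 0.0
    lu = np.linalg.inv(A)

    nr, nc = grid.shape
    cols, rows = np.meshgrid(np.arange(nc), np.arange(nr))
    x0, ytop = grid.origin
    gx = x0 + (cols + 0.5) * grid.cell_size
    gy = ytop - (rows + 0.5) * grid.cell_size
    dg = np.sqrt((gx[..., None] - st.x) ** 2 + (gy[..., None] - st.y) ** 2)
    b = np.empty((nr, nc, n + 1))
    b[..., :n] = spherical_variogram(dg, nug, sill, rng)
    b[..., n] = 1.0
    w = b @ lu.T  # weights + Lagrange multiplier
    pred = w[..., :n] @ st.snow_cm
    pred = np.where(grid.mask, pred, np.nan)
    return grid.copy_with(values=pred, kind="continuous", levels=())


def kriging_weights(stations: StationRecords, x: float, y: float,
                    variogram: tuple[float, float, float]) -> np.ndarray:
    """Ordinary-kriging weights for one prediction point (diagnostic helper)."""
    nug, sill, rng = variogram
    pts = np.column_stack([stations.x, stations.y])
    n = len(stations)
    d_st = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = spherical_variogram(d_st, nug, sill, rng)
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    A[n, n] = 0.0
    d0 = np.sqrt((stations.x - x) ** 2 + (stations.y - y) ** 2)
    b = np.append(spherical_variogram(d0, nug, sill, rng), 1.0)
    sol = np.linalg.solve(A, b)
    return sol[:n]


# ---------------------------------------------------------------------------
# Aggregation to the analysis grid

def aggregate(layer: RasterLayer, factor: int) -> RasterLayer:
    """Block-aggregate by ``factor``: mean for continuous layers (ignoring
    nodata), mode for categorical (ties break to the lowest level)."""
    if factor < 2:
        raise ValueError("factor must be >= 2")
    nr, nc = layer.shape
    pr = (-nr) % factor
    pc = (-nc) % factor
    vals = np.pad(layer.values, ((0, pr), (0, pc)), constant_values=np.nan)
    msk = np.pad(layer.mask, ((0, pr), (0, pc)), constant_values=False)
    R, C = vals.shape[0] // factor, vals.shape[1] // factor
    blocks = vals.reshape(R, factor, C, factor).swapaxes(1, 2).reshape(R, C, -1)
    bmask = msk.reshape(R, factor, C, factor).swapaxes(1, 2).reshape(R, C, -1)

    if layer.kind == "continuous":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out = np.nanmean(np.where(bmask, blocks, np.nan), axis=-1)
    else:
        levels = (np.array(sorted(layer.levels)) if layer.levels
                  else np.unique(layer.values[layer.mask]))
        counts = np.stack([np.sum(bmask & (blocks == lv), axis=-1)
                           for lv in levels], axis=-1)
        # argmax takes the first (lowest) level on ties
        out = levels[np.argmax(counts, axis=-1)].astype(float)
        out[counts.sum(-1) == 0] = np.nan
    omask = bmask.any(axis=-1)
    out = np.where(omask, out, np.nan)
    return RasterLayer(out, cell_size=layer.cell_size * factor,
                       origin=layer.origin, mask=omask, kind=layer.kind,
                       levels=layer.levels)


def rescale_to_range(layer: RasterLayer, lo: float, hi: float) -> RasterLayer:
    """Linearly rescale unmasked values onto [lo, hi] (constant layers → lo)."""
    v = layer.values[layer.mask]
    vmin, vmax = v.min(), v.max()
    if vmax - vmin < 1e-12:
        out = np.full_like(layer.values, lo)
    else:
        out = lo + (hi - lo) * (layer.values - vmin) / (vmax - vmin)
    out = np.where(layer.mask, out, np.nan)
    return layer.copy_with(values=out)
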