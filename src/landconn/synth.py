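"""Synthetic landscapes, sample sites, genotypes and pairwise similarities.

The generator emulates the study design the pipeline targets: a few hundred
georeferenced individuals genotyped at ~14 microsatellite loci across a
region dominated by a large lake barrier, with a continuous percent-cover
field, a smooth snowfall field and a sparse road network as candidate
gene-flow covariates.  Every output is a pure function of (config, seed), so
downstream recovery tests run against known ground truth.

Genetic similarity can be produced two ways: (a) genotypes drawn under
Hardy–Weinberg from spatially clined allele frequencies, which exercise the
Dps/sPCA stages, and (b) pairwise similarities drawn directly from the MLPE
generative model given a true resistance structure, which make fitter and
model-selection recovery tests exact-model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon, Point

from .genetics import GenotypeTable
from .rasters import RasterLayer, make_barrier_layer


@dataclass
class SynthConfig:
    """Study-scale defaults: ~500 km extent, 240 individuals, 14 loci."""

    n_rows: int = 50
    n_cols: int = 50
    cell_size: float = 10_000.0          # m
    lake_center: tuple = (0.5, 0.45)     # fraction of extent (x, y)
    lake_axes: tuple = (0.30, 0.18)      # semi-axes as fraction of extent
    cover_corr_length: float = 80_000.0  # m (e^-1 correlation distance)
    cover_range: tuple = (0.0, 80.0)     # percent tree cover
    snow_corr_length: float = 150_000.0
    snow_range: tuple = (0.0, 700.0)     # cm/yr (0–7 m)
    n_roads: int = 12
    road_length_scale: float = 1.0
    n_individuals: int = 240
    n_loci: int = 14
    alleles_per_locus: int = 8
    cline_strength: float = 3.0
    beta0: float = -1.0
    beta1: float = -0.08
    sigma_u: float = 0.05
    sigma_eps: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals < 2:
            raise ValueError("need at least 2 individuals")
        if min(self.sigma_u, self.sigma_eps) < 0:
            raise ValueError("variances must be nonnegative")

    @property
    def extent(self) -> tuple[float, float]:
        return (self.n_cols * self.cell_size, self.n_rows * self.cell_size)


def gaussian_random_field(shape, corr_length_cells: float, rng,
                          variance: float = 1.0) -> np.ndarray:
    """Stationary Gaussian field with ~Gaussian autocorrelation dropping to
    e^-1 at ``corr_length_cells`` (periodic smoothing of white noise)."""
    white = rng.standard_normal(shape)
    if corr_length_cells <= 0 or variance == 0:
        return (np.zeros(shape) if variance == 0
                else white * np.sqrt(variance))
    sigma = corr_length_cells / 2.0
    f = ndimage.gaussian_filter(white, sigma=sigma, mode="wrap")
    sd = f.std()
    if sd > 0:
        f = f / sd
    return f * np.sqrt(variance)


def lake_polygon(cfg: SynthConfig, n_vertices: int = 90) -> Polygon:
    """Elliptical lake in projected coordinates."""
    ex, ey = cfg.extent
    cx, cy = cfg.lake_center[0] * ex, cfg.lake_center[1] * ey
    ax, ay = cfg.lake_axes[0] * ex, cfg.lake_axes[1] * ey
    th = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    return Polygon(np.column_stack([cx + ax * np.cos(th),
                                    cy + ay * np.sin(th)]))


def rasterize_polygon(poly: Polygon, grid: RasterLayer) -> np.ndarray:
    """Boolean grid: cell center inside the polygon."""
    nr, nc = grid.shape
    out = np.zeros((nr, nc), dtype=bool)
    from shapely.prepared import prep
    prepped = prep(poly)
    for r in range(nr):
        for c in range(nc):
            out[r, c] = prepped.contains(Point(*grid.cell_center(r, c)))
    return out


def rasterize_lines(lines, grid: RasterLayer,
                    step_frac: float = 0.1) -> np.ndarray:
    """Approximate road length (m) per cell by dense sampling along each
    line segment (for the synthetic generator only)."""
    nr, nc = grid.shape
    out = np.zeros((nr, nc))
    step = grid.cell_size * step_frac
    for (x1, y1), (x2, y2) in lines:
        length = np.hypot(x2 - x1, y2 - y1)
        n = max(int(np.ceil(length / step)), 1)
        t = (np.arange(n) + 0.5) / n
        xs = x1 + t * (x2 - x1)
        ys = y1 + t * (y2 - y1)
        seg = length / n
        for x, y in zip(xs, ys):
            r, c = grid.nearest_cell(x, y)
            out[r, c] += seg
    return out


def generate_landscape(cfg: SynthConfig) -> dict[str, RasterLayer]:
    """Generate the four covariate layers: barrier (1 water / 2 land), percent
    cover, snowfall (cm/yr) and road length per cell.  Deterministic given
    the config seed."""
    rng = np.random.default_rng(cfg.seed)
    nr, nc = cfg.n_rows, cfg.n_cols
    ex, ey = cfg.extent
    template = RasterLayer(np.zeros((nr, nc)), cell_size=cfg.cell_size,
                           origin=(0.0, ey))

    poly = lake_polygon(cfg)
    water = rasterize_polygon(poly, template)
    if water.all():
        raise ValueError("lake covers the entire landscape")
    barrier = make_barrier_layer(template.copy_with(
        values=water.astype(float)))

    cl_cells = cfg.cover_corr_length / cfg.cell_size
    f = gaussian_random_field((nr, nc), cl_cells, rng)
    lo, hi = cfg.cover_range
    cover_vals = np.clip(lo + (hi - lo) * _to_unit(f), lo, hi)
    cover = template.copy_with(values=cover_vals, kind="continuous")

    sl_cells = cfg.snow_corr_length / cfg.cell_size
    g = gaussian_random_field((nr, nc), sl_cells, rng)
    slo, shi = cfg.snow_range
    snow_vals = np.clip(slo + (shi - slo) * _to_unit(g), slo, shi)
    snow = template.copy_with(values=snow_vals, kind="continuous")

    lines = []
    for _ in range(cfg.n_roads):
        p1 = rng.uniform([0, 0], [ex, ey])
        p2 = rng.uniform([0, 0], [ex, ey])
        lines.append((tuple(p1), tuple(p2)))
    road_vals = rasterize_lines(lines, template) * cfg.road_length_scale
    roads = template.copy_with(values=road_vals, kind="continuous")

    return {"barrier": barrier, "cover": cover, "snow": snow, "roads": roads}


def _to_unit(f: np.ndarray) -> np.ndarray:
    """Map a standard-normal field through its CDF to [0, 1] (keeps spatial
    smoothness, bounds the range without hard truncation artifacts)."""
    from scipy.stats import norm
    return norm.cdf(f)


def land_mask(barrier: RasterLayer) -> np.ndarray:
    return barrier.mask & (barrier.values == 2.0)


def place_samples(mask: np.ndarray, grid: RasterLayer, n: int,
                  min_spacing: float = 0.0, seed: int = 0,
                  max_attempts_factor: int = 200) -> np.ndarray:
    """Rejection-sample ``n`` points on True cells of ``mask``, pairwise at
    least ``min_spacing`` apart.  Deterministic given seed."""
    rng = np.random.default_rng(seed)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("mask has no valid cells")
    pts = []
    attempts = 0
    budget = max_attempts_factor * n
    while len(pts) < n and attempts < budget:
        attempts += 1
        k = rng.integers(rows.size)
        # jitter within the cell so points are not all on centers
        cx, cy = grid.cell_center(rows[k], cols[k])
        x = cx + rng.uniform(-0.5, 0.5) * grid.cell_size
        y = cy + rng.uniform(-0.5, 0.5) * grid.cell_size
        if min_spacing > 0 and pts:
            arr = np.asarray(pts)
            if np.min(np.hypot(arr[:, 0] - x, arr[:, 1] - y)) < min_spacing:
                continue
        pts.append((x, y))
    if len(pts) < n:
        raise ValueError(f"could only place {len(pts)} of {n} points at "
                         f"spacing {min_spacing}")
    return np.asarray(pts)


def simulate_genotypes(sites: np.ndarray, n_loci: int = 14,
                       alleles_per_locus: int = 8,
                       cline_strength: float = 3.0,
                       seed: int = 0,
                       missing_rate: float = 0.0,
                       fixed_freqs=None) -> GenotypeTable:
    """Diploid genotypes under HWE with logistically clined allele frequencies.

    Per locus, allele frequencies follow a softmax of logits with a random
    baseline (several segregating alleles of moderate frequency, as in real
    microsatellite panels) plus a per-allele linear trend along a random
    spatial axis with overall slope ``cline_strength``; 0 gives frequencies
    with no spatial structure.  ``fixed_freqs`` overrides the model with one
    constant frequency vector used everywhere (e.g. a fixed allele).
    ``missing_rate`` knocks out locus calls at random to exercise filtering.
    """
    if alleles_per_locus < 2:
        raise ValueError("need at least 2 alleles per locus")
    rng = np.random.default_rng(seed)
    sites = np.asarray(sites, dtype=float)
    n = len(sites)
    center = sites.mean(axis=0)
    half_span = max((sites - center).std(axis=0).max(), 1e-12)
    alleles = np.empty((n, n_loci, 2), dtype=object)
    for l in range(n_loci):
        if fixed_freqs is not None:
            probs = np.tile(np.asarray(fixed_freqs, float), (n, 1))
        else:
            th = rng.uniform(0, 2 * np.pi)
            axis = np.array([np.cos(th), np.sin(th)])
            t = (sites - center) @ axis / half_span
            base = rng.normal(0.0, 1.0, alleles_per_locus)
            trend = rng.normal(0.0, 1.0, alleles_per_locus)
            trend -= trend.mean()
            # the /4 scale keeps extreme-site frequencies off fixation, so
            # simulated Dps spans the range typical of microsatellite panels
            logits = base[None, :] + cline_strength * t[:, None] * trend / 4.0
            ex = np.exp(logits - logits.max(axis=1, keepdims=True))
            probs = ex / ex.sum(axis=1, keepdims=True)
        for i in range(n):
            draws = rng.choice(alleles_per_locus, size=2, p=probs[i])
            alleles[i, l, 0] = str(100 + draws[0])
            alleles[i, l, 1] = str(100 + draws[1])
    if missing_rate > 0:
        knock = rng.random((n, n_loci)) < missing_rate
        for i, l in zip(*np.nonzero(knock)):
            alleles[i, l, :] = ""
    ids = [f"ind{i+1:03d}" for i in range(n)]
    return GenotypeTable(ids, sites, alleles)


def simulate_pairwise_similarity(distance_matrix, beta0: float,
                                 beta1: float, sigma_u: float,
                                 sigma_eps: float, seed: int = 0,
                                 standardize: bool = True) -> np.ndarray:
    """Pairwise similarities drawn from the MLPE generative model.

    y_pq = exp(b0 + b1·d_pq + u_p + u_q) + eps_pq, clipped to (0, 1];
    ``standardize`` applies b1 to the standardized distances (matching the
    fitting convention).  Warns if more than 5% of pairs clip.
    """
    D = np.asarray(distance_matrix, dtype=float)
    n = D.shape[0]
    if not np.all(np.isfinite(D)):
        raise ValueError("distance matrix must be finite")
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, k=1)
    d = D[iu]
    if standardize:
        sd = d.std()
        d = (d - d.mean()) / (sd if sd > 0 else 1.0)
    u = rng.normal(0.0, sigma_u, n)
    eta = beta0 + beta1 * d + u[iu[0]] + u[iu[1]]
    y = np.exp(eta) + rng.normal(0.0, sigma_eps, len(d))
    clipped = (y <= 0) | (y > 1)
    if clipped.mean() > 0.05:
        warnings.warn(f"{int(clipped.sum())} of {len(y)} pairs clipped to "
                      "(0, 1]; generating parameters push the mean out of "
                      "range")
    y = np.clip(y, 1e-9, 1.0)
    S = np.eye(n)
    S[iu] = y
    S[(iu[1], iu[0])] = y
    return S
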