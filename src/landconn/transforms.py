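"""Parametric resistance transformations and genetic-algorithm optimization.

Each continuous covariate layer is rescaled to x in [0, 10] and mapped to
resistance through one of eight curve families built from two base shapes —
monomolecular (saturating, 1 − exp(−x/s)) and Ricker (unimodal,
(x/s)·exp(1 − x/s), peaking at x = s) — each optionally "reversed"
(applied to 10 − x) and/or "inverted" (flipped vertically, so e.g. the
inverse-Ricker is U-shaped: high resistance at both extremes, minimum at the
optimum).  The curve is then stretched onto [1, m]: shape parameter s > 0
controls where the curve bends, magnitude m > 1 the maximum resistance.
Categorical layers (the water/land barrier) carry one resistance value per
level with the reference level fixed at 1.

A composite surface is the cellwise sum of the transformed layers, shifted so
its unmasked minimum is 1.  The unknown transformation parameters are
optimized by a real-coded genetic algorithm against the MLPE log-likelihood
of genetic similarity regressed on the composite's effective resistance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .circuits import pairwise_effective_resistance, raster_to_graph
from .mlpe import MLPERegressor, ModelFit, design_from_matrices
from .rasters import RasterLayer, rescale_to_range

FAMILIES = (
    "monomolecular", "reverse-monomolecular",
    "inverse-monomolecular", "inverse-reverse-monomolecular",
    "ricker", "reverse-ricker", "inverse-ricker", "inverse-reverse-ricker",
)


@dataclass
class ContinuousTransform:
    family: str
    shape: float        # s > 0
    magnitude: float    # m > 1

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.shape <= 0:
            raise ValueError("shape must be > 0")
        if self.magnitude <= 1:
            raise ValueError("magnitude must be > 1")


@dataclass
class CategoricalTransform:
    """Resistance per level; the reference level is fixed at 1."""
    values: dict

    def __post_init__(self):
        if any(v < 1 for v in self.values.values()):
            raise ValueError("categorical resistance values must be >= 1")


@dataclass
class TransformSpec:
    """Per-layer transformation specification, keyed by layer name."""
    entries: dict = field(default_factory=dict)

    def __getitem__(self, name):
        return self.entries[name]

    def items(self):
        return self.entries.items()

    def to_dict(self) -> dict:
        out = {}
        for name, e in self.entries.items():
            if isinstance(e, ContinuousTransform):
                out[name] = {"family": e.family, "shape": e.shape,
                             "magnitude": e.magnitude}
            else:
                out[name] = {"values": {str(k): v
                                        for k, v in e.values.items()}}
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "TransformSpec":
        entries = {}
        for name, e in d.items():
            if "family" in e:
                entries[name] = ContinuousTransform(e["family"], e["shape"],
                                                    e["magnitude"])
            else:
                entries[name] = CategoricalTransform(
                    {float(k): v for k, v in e["values"].items()})
        return cls(entries)


def _base_curve(x: np.ndarray, family: str, s: float) -> np.ndarray:
    fam = family
    inverse = fam.startswith("inverse-")
    if inverse:
        fam = fam[len("inverse-"):]
    reverse = fam.startswith("reverse-")
    if reverse:
        fam = fam[len("reverse-"):]
    xx = 10.0 - x if reverse else x
    if fam == "monomolecular":
        f = 1.0 - np.exp(-xx / s)
    elif fam == "ricker":
        f = (xx / s) * np.exp(1.0 - xx / s)
    else:
        raise ValueError(f"unknown family {family!r}")
    if inverse:
        f = f.max() - f + f.min()
    return f


def transform_continuous(layer: RasterLayer,
                         spec: ContinuousTransform) -> RasterLayer:
    """Apply a curve-family transform; output resistance spans [1, m] exactly
    over the layer's observed range (constant layers return constant 1)."""
    x = rescale_to_range(layer, 0.0, 10.0)
    v = x.values[x.mask]
    if v.max() - v.min() < 1e-12:
        warnings.warn("constant layer; transform returns constant 1")
        out = np.where(layer.mask, 1.0, np.nan)
        return layer.copy_with(values=out, kind="continuous")
    f_full = np.full(layer.shape, np.nan)
    f = _base_curve(v, spec.family, spec.shape)
    fmin, fmax = f.min(), f.max()
    if fmax - fmin < 1e-12:
        res = np.ones_like(f)
    else:
        res = 1.0 + (spec.magnitude - 1.0) * (f - fmin) / (fmax - fmin)
    f_full[layer.mask] = res
    return layer.copy_with(values=f_full, mask=layer.mask.copy(),
                           kind="continuous")


def transform_categorical(layer: RasterLayer,
                          spec: CategoricalTransform) -> RasterLayer:
    out = np.full(layer.shape, np.nan)
    for level, value in spec.values.items():
        out[layer.mask & (layer.values == level)] = value
    missing = layer.mask & np.isnan(out)
    if np.any(missing):
        raise ValueError("categorical layer has levels without a resistance "
                         "value")
    return layer.copy_with(values=out, kind="continuous")


@dataclass
class CompositeSurface:
    resistance: RasterLayer
    layer_names: list
    spec: TransformSpec


def composite_resistance(layers: dict, spec: TransformSpec) -> CompositeSurface:
    """Cellwise sum of transformed layers, rescaled so the minimum is 1."""
    names = list(spec.entries)
    first = layers[names[0]]
    total = np.zeros(first.shape)
    mask = first.mask.copy()
    for name in names:
        lyr = layers[name]
        if not lyr.same_grid(first):
            raise ValueError(f"layer {name!r} is not on the common grid")
        entry = spec[name]
        if isinstance(entry, ContinuousTransform):
            t = transform_continuous(lyr, entry)
        else:
            t = transform_categorical(lyr, entry)
        mask &= t.mask
        total = total + np.where(t.mask, t.values, 0.0)
    total = total - total[mask].min() + 1.0
    total = np.where(mask, total, np.nan)
    out = first.copy_with(values=total, mask=mask, kind="continuous")
    return CompositeSurface(out, names, spec)


def contribution_percentages(spec: TransformSpec, layers: dict) -> dict:
    """Share of each layer in the composite, as the range of its transformed
    values over unmasked cells divided by the summed ranges (×100)."""
    ranges = {}
    for name, entry in spec.items():
        lyr = layers[name]
        if isinstance(entry, ContinuousTransform):
            t = transform_continuous(lyr, entry)
        else:
            t = transform_categorical(lyr, entry)
        v = t.values[t.mask]
        ranges[name] = float(v.max() - v.min())
    total = sum(ranges.values())
    if total == 0:
        return {name: 100.0 / len(ranges) for name in ranges}
    return {name: 100.0 * r / total for name, r in ranges.items()}


def standardized_average_resistance(surfaces) -> RasterLayer:
    """Mean-standardized average of composite surfaces: each surface is
    divided by its unmasked mean, then averaged cellwise."""
    if len(surfaces) == 0:
        raise ValueError("need at least one surface")
    layers = [s.resistance if isinstance(s, CompositeSurface) else s
              for s in surfaces]
    first = layers[0]
    acc = np.zeros(first.shape)
    mask = first.mask.copy()
    for lyr in layers:
        if not lyr.same_grid(first):
            raise ValueError("surfaces are not co-registered")
        mask &= lyr.mask
    for lyr in layers:
        acc += lyr.values / lyr.values[mask].mean()
    out = np.where(mask, acc / len(layers), np.nan)
    return first.copy_with(values=out, mask=mask, kind="continuous")


# ---------------------------------------------------------------------------
# Genetic-algorithm optimization

@dataclass
class GAConfig:
    """Real-coded GA settings (tournament selection, blend crossover,
    Gaussian mutation, elitism)."""

    population: int = 25
    generations: int = 50
    stagnation: int = 10
    tournament: int = 3
    crossover_rate: float = 0.7
    blend_alpha: float = 0.5
    mutation_rate: float = 0.25
    mutation_scale: float = 0.3
    shape_bounds: tuple = (0.1, 10.0)
    magnitude_bounds: tuple = (1.5, 2500.0)
    categorical_bounds: tuple = (1.0, 2500.0)
    seed: int = 0


class ResistanceOptimizer:
    """Optimize per-layer resistance transformations against MLPE fit.

    ``fit(layers, similarity, sample_xy)`` searches TransformSpec space with
    a real-coded genetic algorithm, scoring each candidate by the MLPE
    log-likelihood of the pairwise similarity regressed on the candidate
    composite's effective resistance between the sample locations.  Elitism
    guarantees the returned spec is never worse than the best individual of
    generation 0.  Deterministic given the config seed.

    Attributes
    ----------
    best_spec_ : TransformSpec
    best_fit_ : ModelFit
    trace_ : list of (generation, best objective, spec dict)
    """

    def __init__(self, config: GAConfig | None = None, connectivity: int = 8,
                 mlpe_kwargs: dict | None = None):
        self.config = config or GAConfig()
        self.connectivity = connectivity
        self.mlpe_kwargs = mlpe_kwargs or {}

    # genome layout: per continuous layer (family_idx, log shape, log magnitude),
    # per categorical layer one log-value gene per non-reference level
    def _genome_layout(self, layers, optimize_layers):
        layout = []
        for name in optimize_layers:
            lyr = layers[name]
            if lyr.kind == "categorical":
                levels = sorted(lyr.levels or
                                np.unique(lyr.values[lyr.mask]).tolist())
                ref = levels[-1]  # land (highest label) is the reference
                layout.append(("cat", name, [lv for lv in levels
                                             if lv != ref], ref))
            else:
                layout.append(("cont", name))
        return layout

    def _decode(self, genome, layout) -> TransformSpec:
        entries = {}
        pos = 0
        for item in layout:
            if item[0] == "cont":
                fam = FAMILIES[int(genome[pos]) % len(FAMILIES)]
                s = float(np.exp(genome[pos + 1]))
                m = float(np.exp(genome[pos + 2]))
                entries[item[1]] = ContinuousTransform(fam, s, m)
                pos += 3
            else:
                _, name, free_levels, ref = item
                vals = {ref: 1.0}
                for lv in free_levels:
                    vals[lv] = float(np.exp(genome[pos]))
                    pos += 1
                entries[name] = CategoricalTransform(vals)
        return TransformSpec(entries)

    def _random_genome(self, layout, rng):
        cfg = self.config
        g = []
        for item in layout:
            if item[0] == "cont":
                g.append(rng.integers(0, len(FAMILIES)))
                g.append(rng.uniform(*np.log(cfg.shape_bounds)))
                g.append(rng.uniform(*np.log(cfg.magnitude_bounds)))
            else:
                for _ in item[2]:
                    g.append(rng.uniform(*np.log(cfg.categorical_bounds)))
        return np.array(g, dtype=float)

    def _clip(self, genome, layout):
        cfg = self.config
        pos = 0
        for item in layout:
            if item[0] == "cont":
                genome[pos] = int(round(genome[pos])) % len(FAMILIES)
                genome[pos + 1] = np.clip(genome[pos + 1],
                                          *np.log(cfg.shape_bounds))
                genome[pos + 2] = np.clip(genome[pos + 2],
                                          *np.log(cfg.magnitude_bounds))
                pos += 3
            else:
                for _ in item[2]:
                    genome[pos] = np.clip(genome[pos],
                                          *np.log(cfg.categorical_bounds))
                    pos += 1
        return genome

    def _objective(self, spec, layers, similarity, nodes):
        comp = composite_resistance(layers, spec)
        graph = raster_to_graph(comp.resistance,
                                connectivity=self.connectivity)
        R = pairwise_effective_resistance(graph, nodes)
        y, d, pairs, n_drop = design_from_matrices(similarity, R)
        if len(y) == 0 or len(np.unique(pairs)) < 3:
            return -np.inf, None
        est = MLPERegressor(link="log", n_restarts=1, xatol=1e-3,
                            **self.mlpe_kwargs)
        est.fit(d, y, pairs)
        return est.loglik_, est

    def fit(self, layers: dict, similarity, sample_xy,
            optimize_layers=None):
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        if optimize_layers is None:
            optimize_layers = list(layers)
        layout = self._genome_layout(layers, optimize_layers)
        first = layers[optimize_layers[0]]
        graph0 = raster_to_graph(
            composite_resistance(
                layers, self._decode(self._random_genome(layout, rng),
                                     layout)).resistance,
            connectivity=self.connectivity)
        nodes = snap_samples_to_nodes(graph0, sample_xy, first)

        pop = [self._random_genome(layout, rng) for _ in range(cfg.population)]
        scores = []
        fits = []
        for g in pop:
            s, f = self._objective(self._decode(g, layout), layers,
                                   similarity, nodes)
            scores.append(s)
            fits.append(f)
        scores = np.array(scores)
        if not np.any(np.isfinite(scores)):
            raise RuntimeError("all candidates yield disconnected sample "
                               "pairs or degenerate fits")
        best_i = int(np.argmax(scores))
        best = (scores[best_i], pop[best_i].copy(), fits[best_i])
        self.trace_ = [(0, float(best[0]),
                        self._decode(best[1], layout).to_dict())]

        stagnant = 0
        for gen in range(1, cfg.generations + 1):
            new_pop = [best[1].copy()]  # elitism
            while len(new_pop) < cfg.population:
                a = self._tournament(pop, scores, rng)
                b = self._tournament(pop, scores, rng)
                if rng.random() < cfg.crossover_rate:
                    child = self._blend(a, b, rng)
                else:
                    child = a.copy()
                child = self._mutate(child, layout, rng)
                new_pop.append(self._clip(child, layout))
            pop = new_pop
            scores = []
            fits = []
            for g in pop:
                s, f = self._objective(self._decode(g, layout), layers,
                                       similarity, nodes)
                scores.append(s)
                fits.append(f)
            scores = np.array(scores)
            gi = int(np.argmax(scores))
            if scores[gi] > best[0] + 1e-9:
                best = (scores[gi], pop[gi].copy(), fits[gi])
                stagnant = 0
            else:
                stagnant += 1
            self.trace_.append((gen, float(best[0]),
                                self._decode(best[1], layout).to_dict()))
            if stagnant >= cfg.stagnation:
                break

        self.best_spec_ = self._decode(best[1], layout)
        self.best_fit_ = best[2].to_modelfit("optimized")
        self.best_loglik_ = float(best[0])
        self.sample_nodes_ = nodes
        return self

    def _tournament(self, pop, scores, rng):
        idx = rng.integers(0, len(pop), size=self.config.tournament)
        return pop[idx[np.argmax(np.asarray(scores)[idx])]]

    def _blend(self, a, b, rng):
        al = self.config.blend_alpha
        lo = np.minimum(a, b)
        hi = np.maximum(a, b)
        span = hi - lo
        return rng.uniform(lo - al * span, hi + al * span + 1e-12)

    def _mutate(self, g, layout, rng):
        cfg = self.config
        g = g.copy()
        pos = 0
        for item in layout:
            if item[0] == "cont":
                if rng.random() < cfg.mutation_rate:
                    g[pos] = rng.integers(0, len(FAMILIES))
                for k in (1, 2):
                    if rng.random() < cfg.mutation_rate:
                        g[pos + k] += rng.normal(0, cfg.mutation_scale)
                pos += 3
            else:
                for _ in item[2]:
                    if rng.random() < cfg.mutation_rate:
                        g[pos] += rng.normal(0, cfg.mutation_scale)
                    pos += 1
        return g


def snap_samples_to_nodes(graph, sample_xy, layer: RasterLayer) -> np.ndarray:
    """Snap each sample to the nearest unmasked cell center (graph node);
    ties break in row-major order."""
    sample_xy = np.asarray(sample_xy, dtype=float)
    rc = graph.node_rc
    x0, ytop = layer.origin
    cx = x0 + (rc[:, 1] + 0.5) * layer.cell_size
    cy = ytop - (rc[:, 0] + 0.5) * layer.cell_size
    nodes = np.empty(len(sample_xy), dtype=np.int64)
    for k, (sx, sy) in enumerate(sample_xy):
        d2 = (cx - sx) ** 2 + (cy - sy) ** 2
        nodes[k] = int(np.argmin(d2))  # argmin = first (row-major) on ties
    return nodes


def ga_optimize(layers, similarity, sample_xy, config: GAConfig | None = None,
                optimize_layers=None):
    """Functional wrapper: returns (TransformSpec, ModelFit, trace)."""
    opt = ResistanceOptimizer(config=config)
    opt.fit(layers, similarity, sample_xy, optimize_layers=optimize_layers)
    return opt.best_spec_, opt.best_fit_, opt.trace_
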