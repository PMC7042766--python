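"""Genotype handling, proportion-of-shared-alleles similarity, and spatial PCA.

Individuals are diploid and genotyped at L microsatellite loci (two allele
calls per locus).  The analysis response is the pairwise proportion of shared
alleles Dps, a similarity in [0, 1]; 1 − Dps is a genetic distance.  Spatial
structure in the allele scores is screened with a spatial principal component
analysis (sPCA) whose eigenvalues weight variance by spatial autocorrelation:
positive eigenvalues flag global structure (clines/clusters), negative ones
local structure.  A Monte Carlo permutation test decides whether any global
structure is worth modelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

MISSING_DEFAULT = ("0", "", "NA", "nan")


@dataclass
class GenotypeTable:
    """Diploid genotypes with projected sample coordinates.

    ``alleles`` has shape (n, L, 2) and holds allele labels as strings;
    missing calls are empty strings.
    """

    ids: list
    coords: np.ndarray          # (n, 2) projected meters
    alleles: np.ndarray         # (n, L, 2) object/str
    locus_names: list = field(default_factory=list)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.alleles = np.asarray(self.alleles, dtype=object)
        n = len(self.ids)
        if self.coords.shape != (n, 2):
            raise ValueError("coords must be (n, 2)")
        if self.alleles.shape[0] != n or self.alleles.ndim != 3 \
                or self.alleles.shape[2] != 2:
            raise ValueError("alleles must be (n, L, 2)")
        if not self.locus_names:
            self.locus_names = [f"locus{i+1}" for i in range(self.n_loci)]
        if len(set(self.ids)) != n:
            raise ValueError("duplicate individual ids")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return self.alleles.shape[1]

    def missing_mask(self) -> np.ndarray:
        """(n, L) boolean: locus call is missing for that individual."""
        return (self.alleles == "").any(axis=2)

    def subset(self, index) -> "GenotypeTable":
        index = np.asarray(index)
        return GenotypeTable([self.ids[i] for i in index],
                             self.coords[index], self.alleles[index],
                             list(self.locus_names))


# ---------------------------------------------------------------------------
# Readers

def read_genotypes_csv(path, missing=MISSING_DEFAULT) -> GenotypeTable:
    """Read a genotype CSV: columns id, x, y, then two columns per locus
    (``<locus>_1``, ``<locus>_2``).  Missing calls use any of the declared
    sentinel strings (default "0", empty, "NA")."""
    df = pd.read_csv(path, dtype=str)
    required = {"id", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError("genotype CSV needs columns id, x, y")
    allele_cols = [c for c in df.columns if c not in required]
    loci = []
    for c in allele_cols:
        base = c.rsplit("_", 1)[0]
        if base not in loci:
            loci.append(base)
    for lc in loci:
        if f"{lc}_1" not in df.columns or f"{lc}_2" not in df.columns:
            raise ValueError(f"locus {lc} is missing one of its two columns")
    n = len(df)
    alleles = np.empty((n, len(loci), 2), dtype=object)
    for j, lc in enumerate(loci):
        for k in (0, 1):
            col = df[f"{lc}_{k+1}"].fillna("").astype(str).str.strip()
            col = col.where(~col.isin(missing), "")
            alleles[:, j, k] = col.to_numpy()
    coords = df[["x", "y"]].astype(float).to_numpy()
    return GenotypeTable(df["id"].tolist(), coords, alleles, loci)


def read_genepop(path, coords: np.ndarray | None = None) -> GenotypeTable:
    """Read a GENEPOP file (2- or 3-digit allele codes) via biopython.

    GENEPOP has no coordinate slots, so ``coords`` (n, 2) must be supplied
    separately (defaults to zeros)."""
    from Bio.PopGen.GenePop import read as gp_read

    with open(path) as fh:
        rec = gp_read(fh)
    ids, rows = [], []
    for pop in rec.populations:
        for name, genotype in pop:
            ids.append(str(name).strip())
            row = []
            for call in genotype:
                if call is None or any(a is None for a in call):
                    row.append(("", ""))
                else:
                    row.append(tuple(str(a) for a in call))
            rows.append(row)
    alleles = np.array(rows, dtype=object)
    if coords is None:
        coords = np.zeros((len(ids), 2))
    return GenotypeTable(ids, np.asarray(coords, float), alleles,
                         list(rec.loci_list))


# ---------------------------------------------------------------------------
# Filtering

def filter_complete(raw: GenotypeTable) -> GenotypeTable:
    """Keep only individuals with zero missing loci and finite coordinates.

    Input order is preserved; an empty result is an error."""
    miss = raw.missing_mask().any(axis=1)
    bad_xy = ~np.isfinite(raw.coords).all(axis=1)
    keep = np.flatnonzero(~miss & ~bad_xy)
    if keep.size == 0:
        raise ValueError("no complete individuals after filtering")
    return raw.subset(keep)


# ---------------------------------------------------------------------------
# Proportion of shared alleles

def _locus_shared(pair_a, pair_b) -> float:
    """Shared allele count at one locus via min of per-allele counts (0..2)."""
    shared = 0
    for al in set(pair_a):
        shared += min(list(pair_a).count(al), list(pair_b).count(al))
    return shared


def proportion_shared_alleles(a, b) -> float:
    """Dps between two individuals: mean over loci of shared/2.

    ``a`` and ``b`` are (L, 2) allele arrays over the same loci."""
    a = np.asarray(a, dtype=object)
    b = np.asarray(b, dtype=object)
    if a.shape != b.shape:
        raise ValueError("individuals genotyped at different locus sets")
    L = a.shape[0]
    total = sum(_locus_shared(a[l], b[l]) for l in range(L))
    return total / (2.0 * L)


def pairwise_similarity(g: GenotypeTable) -> pd.DataFrame:
    """Symmetric n×n Dps matrix (diagonal 1) indexed by individual id."""
    if g.n < 2:
        raise ValueError("need at least 2 individuals")
    # encode alleles as small integers for a vectorized min-count computation
    n, L = g.n, g.n_loci
    sim = np.eye(n)
    counts = []  # per locus: (n, n_alleles) count matrix
    for l in range(L):
        labels = np.unique(g.alleles[:, l, :].astype(str))
        lut = {lab: k for k, lab in enumerate(labels)}
        cm = np.zeros((n, len(labels)), dtype=np.int8)
        for k in (0, 1):
            col = np.array([lut[str(v)] for v in g.alleles[:, l, k]])
            np.add.at(cm, (np.arange(n), col), 1)
        counts.append(cm)
    for i in range(n):
        shared = np.zeros(n)
        for cm in counts:
            shared += np.minimum(cm[i][None, :], cm).sum(axis=1)
        sim[i, :] = shared / (2.0 * L)
        sim[i, i] = 1.0
    sim = (sim + sim.T) / 2.0
    return pd.DataFrame(sim, index=g.ids, columns=g.ids)


# ---------------------------------------------------------------------------
# Allele scores and spatial weights

def allele_score_matrix(g: GenotypeTable, center: bool = True):
    """Per-individual allele counts (0/1/2) over all distinct alleles across
    loci, optionally column-centered.  Returns (X, column labels)."""
    cols, labels = [], []
    for l in range(g.n_loci):
        alls = np.unique(g.alleles[:, l, :].astype(str))
        for al in alls:
            cnt = (g.alleles[:, l, :].astype(str) == al).sum(axis=1)
            cols.append(cnt.astype(float))
            labels.append(f"{g.locus_names[l]}.{al}")
    X = np.column_stack(cols)
    if center:
        X = X - X.mean(axis=0, keepdims=True)
    return X, labels


def spatial_weights(coords: np.ndarray, radius_km: float = 300.0,
                    row_standardize: bool = True) -> np.ndarray:
    """Distance-threshold neighbor matrix: W_ij > 0 iff 0 < d(i,j) ≤ radius.

    Rows are standardized to sum to 1; individuals with no neighbors keep a
    zero row rather than erroring."""
    coords = np.asarray(coords, float)
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    W = ((d <= radius_km * 1000.0) & (d > 0)).astype(float)
    if row_standardize:
        rs = W.sum(axis=1, keepdims=True)
        W = np.divide(W, rs, out=np.zeros_like(W), where=rs > 0)
    return W


# ---------------------------------------------------------------------------
# Spatial PCA

class SpatialPCA(BaseEstimator, TransformerMixin):
    """Spatial principal component analysis of allele scores.

    Eigen-decomposes C = Xᵀ ((W + Wᵀ)/2) X / n, where X is the centered
    allele-score matrix and W a row-standardized spatial weight matrix.
    Eigenvalues are the product of variance and spatial autocorrelation along
    each axis: large positive values indicate global structure, negative
    values local structure.  With W = I the eigenvalues reduce to ordinary
    PCA eigenvalues of X (covariance convention, divisor n).

    Attributes
    ----------
    eigenvalues_ : ndarray, descending
    components_ : ndarray (n_features, n_axes), matching eigenvectors
    scores_ : ndarray (n, n_axes), X @ components_
    lagged_scores_ : ndarray (n, n_axes), W @ scores_ (the mapped "lag" axes)
    """

    def __init__(self, weights: np.ndarray | None = None):
        self.weights = weights

    def fit(self, X, y=None, weights: np.ndarray | None = None):
        X = np.asarray(X, dtype=float)
        W = self.weights if weights is None else weights
        if W is None:
            raise ValueError("spatial weights are required")
        W = np.asarray(W, dtype=float)
        n = X.shape[0]
        if W.shape != (n, n):
            raise ValueError("weights shape does not match X rows")
        M = (W + W.T) / 2.0
        C = X.T @ M @ X / n
        evals, evecs = np.linalg.eigh((C + C.T) / 2.0)
        order = np.argsort(evals)[::-1]
        self.eigenvalues_ = evals[order]
        self.components_ = evecs[:, order]
        self.scores_ = X @ self.components_
        self.lagged_scores_ = W @ self.scores_
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        return np.asarray(X, float) @ self.components_


def spca(X: np.ndarray, W: np.ndarray):
    """Functional wrapper: returns (eigenvalues, scores, lagged scores)."""
    est = SpatialPCA(weights=W).fit(X)
    return est.eigenvalues_, est.scores_, est.lagged_scores_


def spca_global_test(X: np.ndarray, W: np.ndarray, n_perm: int = 999,
                     seed: int | None = None):
    """Monte Carlo test for global spatial structure in the allele scores.

    The statistic is the largest positive sPCA eigenvalue; the null is built
    by jointly permuting the rows of X (genotypes kept intact) ``n_perm``
    times.  Returns (observed statistic, p) with
    p = (1 + #{perm ≥ obs}) / (n_perm + 1).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    X = np.asarray(X, float)
    W = np.asarray(W, float)
    n = X.shape[0]
    if W.shape != (n, n):
        raise ValueError("weights shape does not match X rows")
    rng = np.random.default_rng(seed)
    M = (W + W.T) / 2.0

    def stat(Xp):
        C = Xp.T @ M @ Xp / n
        return float(np.linalg.eigvalsh((C + C.T) / 2.0)[-1])

    obs = stat(X)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if stat(X[perm]) >= obs:
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    return obs, p


def similarity_to_csv(sim: pd.DataFrame, path) -> None:
    sim.to_csv(path, index_label="id")


def read_similarity_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)
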