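"""Genotype filtering, Dps similarity, and spatial PCA."""

import numpy as np
import pandas as pd
import pytest

from landconn.genetics import (GenotypeTable, SpatialPCA, allele_score_matrix,
                               filter_complete, pairwise_similarity,
                               proportion_shared_alleles, read_genotypes_csv,
                               spatial_weights, spca, spca_global_test)
from landconn.synth import place_samples, simulate_genotypes
from landconn.rasters import RasterLayer


# ---------------------------------------------------------------------------
# filtering

def test_filter_drops_individuals_with_missing_loci(small_table):
    out = filter_complete(small_table)
    assert out.ids == ["i1", "i3"]
    assert out.n == 2


def test_filter_is_identity_without_missing_data(small_table):
    complete = small_table.subset([0, 2])
    out = filter_complete(complete)
    assert out.ids == complete.ids
    np.testing.assert_array_equal(out.coords, complete.coords)


def test_filter_rejects_empty_result():
    alleles = np.array([[["", ""]]], dtype=object)
    t = GenotypeTable(["a"], np.array([[0.0, 0.0]]), alleles)
    with pytest.raises(ValueError, match="no complete individuals"):
        filter_complete(t)


def test_filter_drops_bad_coordinates(small_table):
    t = small_table
    t.coords[0, 0] = np.nan
    out = filter_complete(t)
    assert out.ids == ["i3"]


def test_duplicate_ids_rejected():
    alleles = np.array([[["A", "A"]], [["A", "A"]]], dtype=object)
    with pytest.raises(ValueError, match="duplicate"):
        GenotypeTable(["x", "x"], np.zeros((2, 2)), alleles)


def test_study_scale_filter_retains_complete_individuals():
    """260 simulated individuals with 20 given missing loci leave 240."""
    grid = RasterLayer(np.zeros((20, 20)), cell_size=25_000.0,
                       origin=(0.0, 500_000.0))
    sites = place_samples(np.ones((20, 20), bool), grid, 260, seed=5)
    g = simulate_genotypes(sites, n_loci=14, alleles_per_locus=8, seed=5)
    # knock out one locus for exactly 20 individuals
    rng = np.random.default_rng(7)
    victims = rng.choice(260, size=20, replace=False)
    for i in victims:
        g.alleles[i, rng.integers(14), :] = ""
    out = filter_complete(g)
    assert out.n == 240


# ---------------------------------------------------------------------------
# proportion of shared alleles

def test_dps_identical_genotypes_is_one():
    a = np.array([["A", "B"]] * 5, dtype=object)
    assert proportion_shared_alleles(a, a) == 1.0


def test_dps_disjoint_alleles_is_zero():
    a = np.array([["A", "A"]] * 3, dtype=object)
    b = np.array([["B", "B"]] * 3, dtype=object)
    assert proportion_shared_alleles(a, b) == 0.0


def test_dps_two_locus_worked_example(two_locus_pair):
    a, b = two_locus_pair
    assert proportion_shared_alleles(a, b) == pytest.approx(0.75)


def test_dps_symmetric_and_bounded():
    rng = np.random.default_rng(3)
    for _ in range(20):
        a = rng.choice(list("ABCD"), size=(6, 2)).astype(object)
        b = rng.choice(list("ABCD"), size=(6, 2)).astype(object)
        d1 = proportion_shared_alleles(a, b)
        d2 = proportion_shared_alleles(b, a)
        assert d1 == d2
        assert 0.0 <= d1 <= 1.0


def test_dps_invariant_to_allele_relabeling():
    rng = np.random.default_rng(4)
    a = rng.choice(list("ABCD"), size=(5, 2)).astype(object)
    b = rng.choice(list("ABCD"), size=(5, 2)).astype(object)
    relabel = {"A": "W", "B": "X", "C": "Y", "D": "Z"}
    ar = np.vectorize(relabel.get)(a).astype(object)
    br = np.vectorize(relabel.get)(b).astype(object)
    assert proportion_shared_alleles(a, b) == \
        proportion_shared_alleles(ar, br)


def test_dps_mismatched_loci_error():
    a = np.array([["A", "A"]], dtype=object)
    b = np.array([["A", "A"], ["B", "B"]], dtype=object)
    with pytest.raises(ValueError):
        proportion_shared_alleles(a, b)


# ---------------------------------------------------------------------------
# pairwise similarity matrix

def _random_table(rng, n=6, L=4):
    alleles = rng.choice(list("ABCDEF"), size=(n, L, 2)).astype(object)
    coords = rng.uniform(0, 1e5, (n, 2))
    return GenotypeTable([f"i{k}" for k in range(n)], coords, alleles)


def test_pairwise_similarity_matches_scalar_function():
    rng = np.random.default_rng(0)
    t = _random_table(rng)
    sim = pairwise_similarity(t)
    for i in range(t.n):
        for j in range(t.n):
            expect = 1.0 if i == j else proportion_shared_alleles(
                t.alleles[i], t.alleles[j])
            assert sim.iloc[i, j] == pytest.approx(expect)
    np.testing.assert_allclose(sim.to_numpy(), sim.to_numpy().T)


def test_pairwise_similarity_clone_block_structure():
    rng = np.random.default_rng(1)
    t = _random_table(rng, n=4)
    clone = GenotypeTable(
        t.ids + [f"c{k}" for k in range(4)],
        np.vstack([t.coords, t.coords + 10.0]),
        np.concatenate([t.alleles, t.alleles]), list(t.locus_names))
    sim = pairwise_similarity(clone).to_numpy()
    np.testing.assert_allclose(sim[:4, :4], sim[4:, 4:])
    assert np.all(np.diag(sim[:4, 4:]) == 1.0)


def test_pairwise_similarity_needs_two_individuals():
    alleles = np.array([[["A", "A"]]], dtype=object)
    t = GenotypeTable(["a"], np.zeros((1, 2)), alleles)
    with pytest.raises(ValueError):
        pairwise_similarity(t)


def test_cline_similarity_within_plausible_envelope():
    """Synthetic cline genotypes yield an off-diagonal Dps range near the
    band observed in real 14-locus microsatellite panels (~0.07–0.63);
    checked as a loose sanity envelope, not an equality."""
    grid = RasterLayer(np.zeros((20, 20)), cell_size=25_000.0,
                       origin=(0.0, 500_000.0))
    sites = place_samples(np.ones((20, 20), bool), grid, 60, seed=11)
    g = simulate_genotypes(sites, n_loci=14, alleles_per_locus=8,
                           cline_strength=3.0, seed=12)
    sim = pairwise_similarity(g).to_numpy()
    off = sim[np.triu_indices(60, k=1)]
    assert 0.0 <= off.min() <= 0.15
    assert 0.50 <= off.max() <= 0.72


# ---------------------------------------------------------------------------
# allele scores and weights

def test_allele_scores_row_sums_and_centering():
    rng = np.random.default_rng(2)
    t = _random_table(rng, n=8, L=5)
    X_raw, _ = allele_score_matrix(t, center=False)
    np.testing.assert_allclose(X_raw.sum(axis=1), 2 * t.n_loci)
    X, _ = allele_score_matrix(t, center=True)
    np.testing.assert_allclose(X.sum(axis=0), 0.0, atol=1e-9)


def test_spatial_weights_threshold_and_row_sums():
    coords = np.array([[0, 0], [100_000, 0], [500_000, 0]], dtype=float)
    W = spatial_weights(coords, radius_km=300.0)
    assert W[0, 1] > 0 and W[1, 0] > 0
    assert W[0, 2] == 0            # 500 km apart
    assert np.all(np.diag(W) == 0)
    rs = W.sum(axis=1)
    assert np.all((np.abs(rs - 1) < 1e-12) | (rs == 0))


def test_isolated_individual_keeps_zero_row():
    coords = np.array([[0, 0], [1000, 0], [10_000_000, 0]], dtype=float)
    W = spatial_weights(coords, radius_km=300.0)
    assert np.all(W[2] == 0)


# ---------------------------------------------------------------------------
# spatial PCA

def test_spca_identity_weights_reduce_to_pca():
    rng = np.random.default_rng(5)
    X = rng.standard_normal((30, 8))
    X -= X.mean(axis=0)
    evals, _, _ = spca(X, np.eye(30))
    pca_evals = np.sort(np.linalg.eigvalsh(X.T @ X / 30))[::-1]
    np.testing.assert_allclose(evals, pca_evals, atol=1e-8)


def test_spca_eigenvalue_sum_equals_trace():
    rng = np.random.default_rng(6)
    X = rng.standard_normal((25, 6))
    X -= X.mean(axis=0)
    W = spatial_weights(rng.uniform(0, 3e5, (25, 2)), radius_km=150.0)
    evals, _, _ = spca(X, W)
    M = (W + W.T) / 2
    C = X.T @ M @ X / 25
    assert np.sum(evals) == pytest.approx(np.trace(C), abs=1e-8)


def test_spca_small_worked_example_dense_oracle():
    """4 individuals × 2 allele-score columns against explicit products."""
    X = np.array([[1.0, -1.0], [0.5, 0.5], [-0.5, 1.0], [-1.0, -0.5]])
    X -= X.mean(axis=0)
    W = np.array([[0, 1, 0, 0], [1, 0, 1, 0], [0, 1, 0, 1], [0, 0, 1, 0]],
                 dtype=float)
    W /= W.sum(axis=1, keepdims=True)
    M = (W + W.T) / 2
    C = X.T @ M @ X / 4
    expect = np.sort(np.linalg.eigvalsh(C))[::-1]
    est = SpatialPCA(weights=W).fit(X)
    np.testing.assert_allclose(est.eigenvalues_, expect, atol=1e-10)
    np.testing.assert_allclose(est.scores_, X @ est.components_)
    np.testing.assert_allclose(est.lagged_scores_, W @ est.scores_)


def test_spca_shape_mismatch_error():
    with pytest.raises(ValueError):
        spca(np.zeros((5, 2)), np.eye(4))


def test_cline_has_larger_leading_eigenvalue_than_noise():
    grid = RasterLayer(np.zeros((20, 20)), cell_size=25_000.0,
                       origin=(0.0, 500_000.0))
    sites = place_samples(np.ones((20, 20), bool), grid, 50, seed=21)
    W = spatial_weights(sites, radius_km=200.0)
    g_cline = simulate_genotypes(sites, 10, 4, cline_strength=4.0, seed=21)
    g_null = simulate_genotypes(sites, 10, 4, cline_strength=0.0, seed=21)
    ev_c, _, _ = spca(allele_score_matrix(g_cline)[0], W)
    ev_n, _, _ = spca(allele_score_matrix(g_null)[0], W)
    assert ev_c[0] > 2.0 * ev_n[0]


def test_global_test_detects_strong_cline():
    grid = RasterLayer(np.zeros((20, 20)), cell_size=25_000.0,
                       origin=(0.0, 500_000.0))
    sites = place_samples(np.ones((20, 20), bool), grid, 50, seed=31)
    g = simulate_genotypes(sites, 12, 6, cline_strength=4.0, seed=31)
    X, _ = allele_score_matrix(g)
    W = spatial_weights(sites, radius_km=200.0)
    obs, p = spca_global_test(X, W, n_perm=999, seed=1)
    assert p <= 0.01


def test_global_test_exchangeability_and_determinism():
    """Jointly relabeling individuals (rows of X and of W) leaves the
    observed statistic unchanged, and the test is deterministic given its
    seed — the operational content of row-exchangeability under the null."""
    rng = np.random.default_rng(8)
    X = rng.standard_normal((20, 5))
    X -= X.mean(axis=0)
    W = spatial_weights(rng.uniform(0, 2e5, (20, 2)), radius_km=150.0)
    obs1, p1 = spca_global_test(X, W, n_perm=99, seed=3)
    obs1b, p1b = spca_global_test(X, W, n_perm=99, seed=3)
    assert (obs1, p1) == (obs1b, p1b)
    perm = rng.permutation(20)
    obs2, _ = spca_global_test(X[perm], W[np.ix_(perm, perm)], n_perm=99,
                               seed=3)
    assert obs1 == pytest.approx(obs2, abs=1e-10)


def test_global_test_requires_enough_permutations():
    with pytest.raises(ValueError):
        spca_global_test(np.zeros((5, 2)), np.eye(5), n_perm=10)


# ---------------------------------------------------------------------------
# I/O

def test_genotype_csv_roundtrip(tmp_path):
    df = pd.DataFrame({
        "id": ["a", "b"],
        "x": [0.0, 1000.0], "y": [0.0, 2000.0],
        "Fca031_1": ["101", "0"], "Fca031_2": ["103", "105"],
        "Lc106_1": ["200", "202"], "Lc106_2": ["200", "204"],
    })
    p = tmp_path / "geno.csv"
    df.to_csv(p, index=False)
    t = read_genotypes_csv(p)
    assert t.n == 2
    assert t.locus_names == ["Fca031", "Lc106"]
    assert t.alleles[1, 0, 0] == ""          # "0" sentinel is missing
    out = filter_complete(t)
    assert out.ids == ["a"]


def test_genepop_reader(tmp_path):
    txt = ("Synthetic two-locus example\n"
           "loc1\nloc2\n"
           "Pop\n"
           "ind1 , 0101 0202\n"
           "ind2 , 0102 0203\n")
    p = tmp_path / "pop.gen"
    p.write_text(txt)
    from landconn.genetics import read_genepop
    t = read_genepop(p, coords=np.array([[0, 0], [1, 1]]))
    assert t.n == 2 and t.n_loci == 2
    assert proportion_shared_alleles(t.alleles[0], t.alleles[1]) == \
        pytest.approx((1 + 1) / 4)
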