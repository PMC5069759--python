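"""Fst identities, geographic distances, diversity indices, and Mantel
permutation behaviour (with an independent library cross-check)."""

import math

import numpy as np
import pytest

from strainscope.popgen import (
    DistanceMatrix,
    SnpMatrix,
    bray_curtis,
    distance_decay,
    diversity,
    fst_matrix,
    fst_per_snp,
    geographic_distance_matrix,
    haversine_km,
    load_caws_sites,
    mantel,
    pairwise_fst,
)
from strainscope.synthetic import generate_snp_profiles


# --- Fst ---------------------------------------------------------------------


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ([5, 5], [50, 50], 0.0),
        ([10, 0], [0, 10], 1.0),
        ([8, 2], [2, 8], 0.36),  # Hw = 0.32, Ht = 0.5 by hand
    ],
)
def test_fst_per_snp_hand_values(a, b, expected):
    assert fst_per_snp(a, b) == pytest.approx(expected)


def test_fst_per_snp_monomorphic_nan_and_zero_depth():
    assert math.isnan(fst_per_snp([10, 0], [10, 0]))
    with pytest.raises(ValueError):
        fst_per_snp([0, 0], [5, 5])


def test_fst_per_snp_bounded():
    rng = np.random.default_rng(0)
    for _ in range(200):
        a = rng.integers(0, 50, size=2) + [1, 0]
        b = rng.integers(0, 50, size=2) + [0, 1]
        v = fst_per_snp(a, b)
        if not math.isnan(v):
            assert -1e-9 <= v <= 1.0 + 1e-9


def test_pairwise_fst_limits():
    undiff = SnpMatrix(
        counts=np.tile([[50, 50], [50, 50]], (20, 1, 1)),
        populations=["p1", "p2"],
        loci=[f"s{i}" for i in range(20)],
    )
    assert pairwise_fst(undiff, "p1", "p2") == pytest.approx(0.0)
    fixed = SnpMatrix(
        counts=np.tile([[100, 0], [0, 100]], (20, 1, 1)),
        populations=["p1", "p2"],
        loci=[f"s{i}" for i in range(20)],
    )
    assert pairwise_fst(fixed, "p1", "p2") == pytest.approx(1.0)


def test_mean_fst_increases_with_divergence():
    means = []
    for div in (0.05, 0.2, 0.4, 0.7):
        m = generate_snp_profiles(300, 2, div, depth=200, seed=21)
        means.append(pairwise_fst(m, "pop_1", "pop_2"))
    assert all(a < b for a, b in zip(means, means[1:]))


def test_fst_matrix_symmetric_zero_diagonal():
    m = generate_snp_profiles(100, 4, 0.3, depth=100, seed=3)
    dm = fst_matrix(m)
    assert dm.labels == m.populations
    assert np.allclose(dm.values, dm.values.T)


# --- geography, Bray-Curtis, diversity --------------------------------------


def test_haversine_identities():
    assert haversine_km((41.0, -87.0), (41.0, -87.0)) == 0.0
    a, b = (41.6575, -87.6411), (41.6503, -87.6171)
    assert haversine_km(a, b) == pytest.approx(haversine_km(b, a))


def test_haversine_against_independent_oracle():
    """Two published waterway stations ~2.15 km apart, cross-checked with
    sklearn's haversine kernel."""
    from sklearn.metrics.pairwise import haversine_distances

    sites = load_caws_sites()
    a = sites.loc["WW76"]
    b = sites.loc["WW56"]
    got = haversine_km(a, b)
    rad = np.radians(
        [[a["latitude"], a["longitude"]], [b["latitude"], b["longitude"]]]
    )
    oracle = haversine_distances(rad)[0, 1] * 6371.0
    assert got == pytest.approx(oracle, abs=1e-6)
    assert got == pytest.approx(2.15, abs=0.05)


def test_haversine_invalid_coordinates():
    with pytest.raises(ValueError):
        haversine_km((95.0, 0.0), (0.0, 0.0))


@pytest.mark.parametrize(
    "x,y,expected",
    [([1, 2, 3], [1, 2, 3], 0.0), ([1, 0], [0, 1], 1.0), ([2, 1], [1, 1], 0.2)],
)
def test_bray_curtis_examples(x, y, expected):
    assert bray_curtis(x, y) == pytest.approx(expected)


def test_bray_curtis_both_zero_raises():
    with pytest.raises(ValueError):
        bray_curtis([0, 0], [0, 0])


def test_diversity_identities():
    h, j = diversity([1, 1, 1, 1])
    assert h == pytest.approx(math.log(4))
    assert j == pytest.approx(1.0)
    h, j = diversity([5])
    assert h == 0.0 and math.isnan(j)
    h, j = diversity([0.5, 0.5, 0.0])
    assert h == pytest.approx(math.log(2)) and j == pytest.approx(1.0)


# --- distance matrices, Mantel, decay ---------------------------------------


def _random_distance_matrix(n, rng, labels=None):
    m = rng.uniform(0.1, 1.0, size=(n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return DistanceMatrix(labels=labels or [f"s{i}" for i in range(n)], values=m)


def test_distance_matrix_validation():
    with pytest.raises(ValueError):
        DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))
    with pytest.raises(ValueError):
        DistanceMatrix(["a", "b"], np.array([[1.0, 1.0], [1.0, 0.0]]))


def test_mantel_identical_matrices_r_one():
    dm = _random_distance_matrix(7, np.random.default_rng(1))
    res = mantel(dm, dm, n_perm=99, seed=0)
    assert res.r == pytest.approx(1.0)
    assert res.p >= 1 / 100


def test_mantel_r_matches_skbio():
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        from skbio.stats.distance import DistanceMatrix as SkbioDM
        from skbio.stats.distance import mantel as skbio_mantel

    rng = np.random.default_rng(2)
    d1 = _random_distance_matrix(8, rng)
    d2 = _random_distance_matrix(8, rng, labels=d1.labels)
    mine = mantel(d1, d2, n_perm=99, seed=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r_ref, _, _ = skbio_mantel(
            SkbioDM(d1.values, d1.labels),
            SkbioDM(d2.values, d2.labels),
            method="pearson",
            permutations=0,
        )
    assert mine.r == pytest.approx(float(r_ref), abs=1e-9)


def test_mantel_exchangeable_under_joint_relabeling():
    rng = np.random.default_rng(3)
    d1 = _random_distance_matrix(7, rng)
    d2 = _random_distance_matrix(7, rng, labels=d1.labels)
    base = mantel(d1, d2, n_perm=99, seed=0).r
    perm = rng.permutation(7)
    relabel = lambda dm: DistanceMatrix(  # noqa: E731
        labels=[dm.labels[i] for i in perm],
        values=dm.values[np.ix_(perm, perm)],
    )
    assert mantel(relabel(d1), relabel(d2), n_perm=99, seed=0).r == pytest.approx(
        base, abs=1e-12
    )


def test_mantel_detects_noisy_linear_relation():
    rng = np.random.default_rng(4)
    d1 = _random_distance_matrix(10, rng)
    noise = rng.normal(0, 1e-4, size=d1.values.shape)
    noise = (noise + noise.T) / 2
    np.fill_diagonal(noise, 0.0)
    d2 = DistanceMatrix(d1.labels, 0.5 * d1.values + np.abs(noise))
    res = mantel(d1, d2, n_perm=199, seed=0)
    assert res.r > 0.999
    assert res.p <= 0.05


def test_mantel_requires_matching_labels_and_size():
    rng = np.random.default_rng(5)
    d1 = _random_distance_matrix(4, rng)
    d2 = _random_distance_matrix(4, rng)  # same default labels
    d3 = DistanceMatrix(["x"] * 0 + ["a", "b", "c", "d"], d2.values)
    with pytest.raises(ValueError):
        mantel(d1, d3, 99, 0)
    small = _random_distance_matrix(2, rng)
    with pytest.raises(ValueError):
        mantel(small, small, 99, 0)


def test_distance_decay_exact_linear():
    sites = load_caws_sites()
    geo = geographic_distance_matrix(sites)
    comm = DistanceMatrix(geo.labels, 0.1 * geo.values)
    res = distance_decay(geo, comm, n_perm=99, seed=0)
    assert res.slope == pytest.approx(0.1)
    assert res.r2 == pytest.approx(1.0)
    assert res.mantel.r == pytest.approx(1.0)


def test_distance_decay_constant_geo_raises():
    dm = DistanceMatrix(["a", "b", "c"], np.ones((3, 3)) - np.eye(3))
    with pytest.raises(ValueError):
        distance_decay(dm, dm, 99, 0)
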