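"""Numerics oracles (Bray-Curtis, PCoA, Kruskal-Wallis) and the sweeps."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bloomcull import (
    DistanceMatrix,
    FeatureTable,
    SampleMetadata,
    ValidationError,
    bray_curtis,
    class_taxonomy_summary,
    cross_study_distance_sweep,
    distance_matrix,
    kruskal_wallis,
    observed_richness,
    pcoa,
    rarefy,
)
from bloomcull.tables import TaxonomyMap


# ---------------------------------------------------------------------------
# rarefaction / richness
# ---------------------------------------------------------------------------

def test_rarefy_contract_and_determinism():
    rng = np.random.default_rng(5)
    counts = rng.integers(0, 40, size=(4, 10))
    counts[0] = 0  # empty sample is dropped (total < depth)
    table = FeatureTable([f"s{i}" for i in range(4)],
                         [f"F{i}" for i in range(10)], counts)
    depth = int(min(counts[1:].sum(axis=1)))
    r1 = rarefy(table, depth, seed=11)
    r2 = rarefy(table, depth, seed=11)
    assert r1 == r2  # deterministic
    assert r1.sample_ids == ["s1", "s2", "s3"]
    assert (r1.sample_totals() == depth).all()
    # subsample without replacement: never exceeds the original counts
    for sid in r1.sample_ids:
        i, j = table.sample_ids.index(sid), r1.sample_ids.index(sid)
        assert (r1.counts[j] <= table.counts[i]).all()
    # a sample already at depth passes through unchanged
    exact = table.counts[1].copy()
    t2 = FeatureTable(["x"], table.feature_ids, exact[None, :])
    assert rarefy(t2, int(exact.sum()), seed=3).counts.tolist() == [exact.tolist()]


def test_rarefy_rejects_nonpositive_depth(tiny_table):
    with pytest.raises(ValueError):
        rarefy(tiny_table, 0, seed=1)


def test_observed_richness():
    assert observed_richness(np.array([3, 0, 1])) == 2
    assert observed_richness(np.zeros(5)) == 0


@settings(max_examples=20, deadline=None)
@given(st.integers(0, 2**32 - 1))
def test_rarefaction_never_increases_richness(seed):
    rng = np.random.default_rng(seed)
    counts = rng.integers(0, 30, size=(1, 15))
    if counts.sum() < 5:
        return
    table = FeatureTable(["s"], [f"F{i}" for i in range(15)], counts)
    r = rarefy(table, 5, seed=seed)
    assert observed_richness(r.counts[0]) <= observed_richness(counts[0])


# ---------------------------------------------------------------------------
# Bray-Curtis
# ---------------------------------------------------------------------------

def test_bray_curtis_examples():
    assert bray_curtis([1, 2, 3], [1, 2, 3]) == 0.0
    assert bray_curtis([1, 0], [0, 4]) == 1.0  # disjoint support
    assert bray_curtis([6, 0, 2], [2, 2, 0]) == pytest.approx((4 + 2 + 2) / 12)


def test_bray_curtis_rejects_double_zero():
    with pytest.raises(ValueError):
        bray_curtis([0, 0], [0, 0])


@settings(max_examples=100, deadline=None)
@given(st.integers(0, 2**32 - 1))
def test_bray_curtis_matches_direct_formula_and_is_bounded(seed):
    rng = np.random.default_rng(seed)
    u = rng.random(8) * rng.integers(1, 100)
    v = rng.random(8) * rng.integers(1, 100)
    d = bray_curtis(u, v)
    direct = sum(abs(a - b) for a, b in zip(u, v)) / sum(a + b for a, b in zip(u, v))
    assert d == pytest.approx(direct, abs=1e-12)
    assert 0.0 <= d <= 1.0
    assert bray_curtis(v, u) == pytest.approx(d, abs=1e-12)  # symmetry


def test_distance_matrix_consistency_and_scale_invariance():
    counts = np.array([[6, 0, 2], [2, 2, 0], [1, 1, 1]])
    table = FeatureTable(["a", "b", "c"], ["AA", "CC", "GG"], counts)
    dm = distance_matrix(table)
    # matches pairwise calls on frequency vectors
    freqs = counts / counts.sum(axis=1, keepdims=True)
    for i, si in enumerate(dm.sample_ids):
        for j, sj in enumerate(dm.sample_ids):
            expected = 0.0 if i == j else bray_curtis(freqs[i], freqs[j])
            assert dm.data[i, j] == pytest.approx(expected, abs=1e-12)
    # scaling one sample's counts is invisible after normalization
    scaled = counts.copy()
    scaled[0] *= 10
    dm2 = distance_matrix(FeatureTable(["a", "b", "c"], ["AA", "CC", "GG"], scaled))
    np.testing.assert_allclose(dm2.data, dm.data, atol=1e-12)


def test_duplicate_samples_have_zero_distance():
    counts = np.array([[3, 1], [6, 2]])  # same composition
    dm = distance_matrix(FeatureTable(["a", "b"], ["AA", "CC"], counts))
    assert dm.data[0, 1] == pytest.approx(0.0, abs=1e-12)


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

def test_pcoa_recovers_collinear_points():
    pts = np.array([0.0, 1.0, 2.0])
    d = np.abs(pts[:, None] - pts[None, :])
    res = pcoa(DistanceMatrix(["a", "b", "c"], d))
    # one informative axis; spacing reconstructed up to sign/translation
    assert res.eigenvalues[0] > 0
    assert abs(res.eigenvalues[1]) < 1e-9
    axis = res.coordinates[:, 0]
    rec = np.abs(axis[:, None] - axis[None, :])
    np.testing.assert_allclose(rec, d, atol=1e-9)


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 2**32 - 1))
def test_pcoa_reproduces_euclidean_distances(seed):
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(6, 2))
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    res = pcoa(DistanceMatrix([f"s{i}" for i in range(6)], d))
    coords = res.coordinates
    rec = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    np.testing.assert_allclose(rec, d, atol=1e-9)
    # eigenvalues sorted, proportions over positive ones sum to 1
    assert (np.diff(res.eigenvalues) <= 1e-9).all()
    assert res.proportion_explained.sum() == pytest.approx(1.0)


def test_pcoa_matches_scikit_bio_on_braycurtis_distances():
    """Cross-check coordinates against an independent implementation."""
    skbio_ordination = pytest.importorskip("skbio.stats.ordination")
    import skbio

    rng = np.random.default_rng(7)
    counts = rng.integers(0, 50, size=(5, 12))
    counts[counts.sum(axis=1) == 0, 0] = 1
    table = FeatureTable([f"s{i}" for i in range(5)],
                         [f"F{i}" for i in range(12)], counts)
    dm = distance_matrix(table)
    mine = pcoa(dm)
    theirs = skbio_ordination.pcoa(skbio.DistanceMatrix(dm.data, ids=dm.sample_ids))
    n_axes = min(mine.coordinates.shape[1], 3)
    for ax in range(n_axes):
        a = mine.coordinates[:, ax]
        b = theirs.samples.values[:, ax]
        # same axis up to sign
        assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8


def test_pcoa_duplicated_sample_identical_coordinates():
    counts = np.array([[5, 1, 0], [5, 1, 0], [0, 3, 3]])
    dm = distance_matrix(FeatureTable(["a", "a2", "b"], ["x", "y", "z"], counts))
    res = pcoa(dm)
    np.testing.assert_allclose(res.coordinates[0], res.coordinates[1], atol=1e-9)


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------

def _kw_bruteforce(groups):
    """Independent tie-corrected rank-sum computation of H."""
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    n = len(pooled)
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(n)
    i = 0
    sorted_vals = pooled[order]
    while i < n:
        j = i
        while j < n and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0  # average rank, 1-based
        i = j
    h = 0.0
    start = 0
    for g in groups:
        g = np.asarray(g, float)
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    return h / correction


def test_kruskal_wallis_hand_computed_example():
    h, p = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
    assert h == pytest.approx(7.2)
    assert 0 < p < 0.05


def test_kruskal_wallis_all_identical_is_degenerate():
    h, p = kruskal_wallis([[5, 5], [5, 5, 5]])
    assert h == 0.0 and p == 1.0


def test_kruskal_wallis_validates_inputs():
    with pytest.raises(ValueError):
        kruskal_wallis([[1, 2, 3]])
    with pytest.raises(ValueError):
        kruskal_wallis([[1, 2], []])


def test_kruskal_wallis_matches_bruteforce_with_ties():
    rng = np.random.default_rng(42)
    for _ in range(200):
        k = int(rng.integers(2, 5))
        groups = [
            rng.integers(0, 8, size=int(rng.integers(2, 9))).astype(float)
            for _ in range(k)
        ]
        pooled = np.concatenate(groups)
        if np.all(pooled == pooled[0]):
            continue
        h, _ = kruskal_wallis(groups)
        assert h == pytest.approx(_kw_bruteforce(groups), abs=1e-10)


# ---------------------------------------------------------------------------
# distance sweep: exhaustive oracle on tiny studies
# ---------------------------------------------------------------------------

def test_distance_sweep_matches_exhaustive_mean_on_tiny_studies():
    rng = np.random.default_rng(3)
    counts = rng.integers(1, 30, size=(4, 6))
    seqs = ["AAAA", "CCCC", "GGGG", "TTTT", "ACAC", "GTGT"]
    table = FeatureTable(["a1", "a2", "b1", "b2"], seqs, counts)
    md = SampleMetadata.from_records(
        [{"sample_id": s, "study_id": s[0]} for s in table.sample_ids]
    )
    recs = cross_study_distance_sweep(table, md, [], n_pairs=4000, seed=9)
    assert len(recs) == 1 and recs[0].depth == 0
    freqs = counts / counts.sum(axis=1, keepdims=True)
    exhaustive = np.mean(
        [bray_curtis(freqs[i], freqs[j]) for i in (0, 1) for j in (2, 3)]
    )
    # 4000 resampled pairs over 4 possible combinations
    assert recs[0].mean_distance == pytest.approx(exhaustive, abs=3 * recs[0].se_distance)


def test_distance_sweep_is_reproducible(default_bundle):
    from bloomcull import merge_tables

    merged = merge_tables(default_bundle["cohort_tables"])
    md = default_bundle["cohort_metadata"]
    blooms = default_bundle["truth"].bloom_feature_ids
    r1 = cross_study_distance_sweep(merged, md, blooms, n_pairs=50, seed=4)
    r2 = cross_study_distance_sweep(merged, md, blooms, n_pairs=50, seed=4)
    assert [(a.depth, a.mean_distance) for a in r1] == [
        (b.depth, b.mean_distance) for b in r2
    ]


# ---------------------------------------------------------------------------
# taxonomy summary
# ---------------------------------------------------------------------------

def _md_one_study(sample_ids, study="S"):
    return SampleMetadata.from_records(
        [{"sample_id": s, "study_id": study} for s in sample_ids]
    )


def test_single_class_sums_to_one():
    table = FeatureTable(["s1"], ["AA", "CC"], np.array([[3, 7]]))
    tax = TaxonomyMap({"AA": "k__B; p__P; c__X", "CC": "k__B; p__P; c__X"})
    out = class_taxonomy_summary(table, tax, _md_one_study(["s1"]))
    assert out.loc["S", "X"] == pytest.approx(1.0)


def test_study_mean_is_unweighted_over_samples():
    # one sample pure class A (low depth), one pure class B (high depth)
    table = FeatureTable(["s1", "s2"], ["AA", "CC"], np.array([[10, 0], [0, 1000]]))
    tax = TaxonomyMap({"AA": "c__A", "CC": "c__B"})
    out = class_taxonomy_summary(table, tax, _md_one_study(["s1", "s2"]))
    assert out.loc["S", "A"] == pytest.approx(0.5)
    assert out.loc["S", "B"] == pytest.approx(0.5)


def test_missing_taxonomy_goes_to_unclassified_and_conserves_mass():
    table = FeatureTable(["s1"], ["AA", "CC"], np.array([[1, 3]]))
    tax = TaxonomyMap({"AA": "c__A"})
    out = class_taxonomy_summary(table, tax, _md_one_study(["s1"]))
    assert out.loc["S", "unclassified"] == pytest.approx(0.75)
    assert out.loc["S"].sum() == pytest.approx(1.0, abs=1e-9)
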