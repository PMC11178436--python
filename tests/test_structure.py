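"""Group summaries, dispersion (betadisper-style), Mantel, geo, IBD."""

import numpy as np
import pytest

import lemnapop as lp
from lemnapop.distance import DistanceMatrix
from lemnapop.structure import (
    EARTH_RADIUS_M,
    dispersion_test,
    distances_to_centroid,
    geo_distance_matrix,
    haversine_m,
    ibd_test,
    mantel_test,
    within_between_summary,
)

import pandas as pd


def dm_from(values, ids=None):
    v = np.asarray(values, dtype=float)
    if ids is None:
        ids = [f"S{i}" for i in range(v.shape[0])]
    return DistanceMatrix(ids, v)


def euclidean_dm(points, ids=None):
    p = np.asarray(points, dtype=float)
    d = np.sqrt(((p[:, None, :] - p[None, :, :]) ** 2).sum(-1))
    return dm_from(d, ids)


# ---------------------------------------------------------------- summaries

def test_within_between_trivial_cases():
    v = np.full((6, 6), 0.3)
    v[:3, :3] = 0.0
    v[3:, 3:] = 0.0
    np.fill_diagonal(v, 0)
    dm = dm_from(v)
    groups = {s: ("g1" if i < 3 else "g2") for i, s in enumerate(dm.ids)}
    s = within_between_summary(dm, groups)
    assert s.mean_within == 0.0
    assert s.mean_between == pytest.approx(0.3)
    assert s.n_between_pairs == 9

    one = within_between_summary(dm, {s: "all" for s in dm.ids})
    assert np.isnan(one.mean_between)  # between undefined with one group


def test_within_between_min_size_filter():
    v = np.full((5, 5), 0.2)
    np.fill_diagonal(v, 0)
    dm = dm_from(v)
    groups = dict(zip(dm.ids, ["a", "a", "a", "b", "b"]))
    s = within_between_summary(dm, groups, min_size=3)
    assert s.groups_used == ["a"]
    assert np.isnan(s.mean_between)


# ---------------------------------------------------- centroid distances

def test_centroid_distance_identical_points_zero():
    dm = dm_from(np.zeros((4, 4)))
    d = distances_to_centroid(dm, ["g"] * 4)
    assert np.allclose(d, 0.0)


def test_centroid_distance_equilateral_closed_form():
    # three equidistant points at pairwise distance d: centroid distance d/sqrt(3)
    d0 = 0.6
    v = np.full((3, 3), d0)
    np.fill_diagonal(v, 0)
    d = distances_to_centroid(dm_from(v), ["g"] * 3)
    assert np.allclose(d, d0 / np.sqrt(3), atol=1e-10)


def test_centroid_distance_matches_coordinate_oracle():
    rng = np.random.default_rng(2)
    pts = rng.normal(size=(12, 4))
    groups = np.array(["a"] * 6 + ["b"] * 6)
    dm = euclidean_dm(pts)
    got = distances_to_centroid(dm, groups)
    expected = np.empty(12)
    for g in ("a", "b"):
        sel = groups == g
        c = pts[sel].mean(axis=0)
        expected[sel] = np.sqrt(((pts[sel] - c) ** 2).sum(axis=1))
    assert np.allclose(got, expected, atol=1e-8)


def test_centroid_distance_matches_vegan_betadisper(tmp_path):
    """Cross-check the PCoA/negative-eigenvalue construction against the
    reference R implementation on a non-Euclidean toy matrix."""
    import subprocess

    rng = np.random.default_rng(5)
    gt = rng.integers(0, 3, size=(80, 8)).astype(np.int8)
    from .conftest import make_table

    dm = lp.pairwise_allele_distance(make_table(gt))
    groups = ["a"] * 4 + ["b"] * 4
    got = distances_to_centroid(dm, groups)

    mat = tmp_path / "d.tsv"
    np.savetxt(mat, dm.values, delimiter="\t")
    script = tmp_path / "bd.R"
    script.write_text(
        f"""
        suppressMessages(library(vegan))
        d <- as.dist(as.matrix(read.table("{mat}", sep="\t")))
        g <- factor(c(rep("a",4), rep("b",4)))
        b <- betadisper(d, g, type="centroid")
        cat(sprintf("%.12f\\n", b$distances))
        """
    )
    out = subprocess.run(["Rscript", str(script)], capture_output=True, text=True)
    assert out.returncode == 0, out.stderr
    expected = np.array([float(x) for x in out.stdout.split()])
    assert np.allclose(got, expected, atol=1e-6)


def test_centroid_requires_three_samples():
    with pytest.raises(ValueError):
        distances_to_centroid(dm_from(np.zeros((2, 2))), ["a", "b"])


# ------------------------------------------------------------- dispersion

def test_dispersion_detects_unequal_spread():
    rng = np.random.default_rng(3)
    tight = rng.normal(0, 0.1, size=(10, 3))
    wide = rng.normal(0, 1.5, size=(10, 3))
    dm = euclidean_dm(np.vstack([tight, wide]))
    groups = ["t"] * 10 + ["w"] * 10
    res = dispersion_test(dm, groups, nperm=199, seed=1)
    assert res.p_value == pytest.approx(1 / 200)  # permutation floor
    assert res.group_means["w"] > res.group_means["t"]


def test_dispersion_null_p_not_extreme_and_reproducible():
    rng = np.random.default_rng(4)
    pts = rng.normal(size=(16, 3))
    dm = euclidean_dm(pts)
    groups = ["a"] * 8 + ["b"] * 8
    r1 = dispersion_test(dm, groups, nperm=99, seed=7)
    r2 = dispersion_test(dm, groups, nperm=99, seed=7)
    assert r1.p_value == r2.p_value
    assert r1.p_value > 0.05  # same generating process for both groups


def test_dispersion_minimum_p_formula():
    rng = np.random.default_rng(5)
    pts = np.vstack([rng.normal(0, 0.01, (5, 2)), rng.normal(0, 2.0, (5, 2))])
    dm = euclidean_dm(pts)
    res = dispersion_test(dm, ["a"] * 5 + ["b"] * 5, nperm=9, seed=0)
    assert res.p_value >= 0.1  # (1 + x) / (1 + 9) can never go below 0.1


def test_dispersion_degenerate_groups_rejected():
    dm = dm_from(np.zeros((3, 3)))
    with pytest.raises(ValueError):
        dispersion_test(dm, ["a", "a", "b"], nperm=9)


# ------------------------------------------------------------------ Mantel

def test_mantel_identity():
    rng = np.random.default_rng(6)
    dm = euclidean_dm(rng.normal(size=(10, 2)))
    res = mantel_test(dm, dm, nperm=99, seed=0)
    assert res.r == pytest.approx(1.0)
    assert res.p_value == pytest.approx(1 / 100)


def test_mantel_constant_matrix_rejected():
    v = np.full((4, 4), 0.5)
    np.fill_diagonal(v, 0)
    with pytest.raises(ValueError):
        mantel_test(dm_from(v), dm_from(v), nperm=9)


def test_mantel_floor_with_9999_permutations():
    """Perfectly monotonically related 20-sample matrices: p is exactly the
    +1-convention floor, 0.0001."""
    rng = np.random.default_rng(7)
    d1 = euclidean_dm(rng.uniform(size=(20, 3)))
    d2 = dm_from(d1.values**2, ids=d1.ids)  # monotone transform
    res = mantel_test(d1, d2, nperm=9999, seed=11)
    assert res.p_value == 0.0001


def test_mantel_matches_skbio():
    from skbio.stats.distance import DistanceMatrix as SkbioDM
    from skbio.stats.distance import mantel as skbio_mantel

    rng = np.random.default_rng(8)
    d1 = euclidean_dm(rng.normal(size=(12, 2)))
    d2 = euclidean_dm(rng.normal(size=(12, 2)), ids=d1.ids)
    res = mantel_test(d1, d2, nperm=999, seed=1)
    r_sk, p_sk, _ = skbio_mantel(
        SkbioDM(d1.values, ids=d1.ids), SkbioDM(d2.values, ids=d2.ids),
        method="pearson", permutations=999, alternative="greater",
    )
    assert res.r == pytest.approx(float(r_sk), abs=1e-12)
    # permutation p-values from different streams agree within Monte-Carlo noise
    assert abs(res.p_value - float(p_sk)) < 0.08


def test_mantel_invariant_to_joint_relabeling():
    rng = np.random.default_rng(9)
    d1 = euclidean_dm(rng.normal(size=(9, 2)))
    d2 = euclidean_dm(rng.normal(size=(9, 2)), ids=d1.ids)
    r0 = mantel_test(d1, d2, nperm=49, seed=3).r
    perm = rng.permutation(9)
    ids_p = [d1.ids[i] for i in perm]
    d1p = d1.reorder(ids_p)
    d2p = d2.reorder(ids_p)
    assert mantel_test(d1p, d2p, nperm=49, seed=3).r == pytest.approx(r0)


def test_mantel_null_p_uniform():
    rng = np.random.default_rng(10)
    ps = []
    for _ in range(300):
        d1 = euclidean_dm(rng.normal(size=(10, 2)))
        d2 = euclidean_dm(rng.normal(size=(10, 2)), ids=d1.ids)
        ps.append(mantel_test(d1, d2, nperm=99, seed=int(rng.integers(2**31))).p_value)
    from scipy import stats

    assert stats.kstest(ps, "uniform").pvalue > 0.01
    assert abs(np.mean(np.asarray(ps) <= 0.05) - 0.05) < 0.04


# ------------------------------------------------------------------- geo

def test_haversine_closed_forms():
    assert haversine_m(0, 0, 0, 0) == 0.0
    # one degree along the equator: 2 pi R / 360
    assert haversine_m(0, 0, 0, 1) == pytest.approx(2 * np.pi * EARTH_RADIUS_M / 360, rel=1e-9)
    # antipodal points: pi R
    assert haversine_m(0, 0, 0, 180) == pytest.approx(np.pi * EARTH_RADIUS_M, rel=1e-9)


def test_geo_matrix_rejects_bad_latitude():
    meta = pd.DataFrame({"sample": ["a", "b"], "lat": [47.0, 95.0], "lon": [8.0, 8.5]})
    with pytest.raises(ValueError, match="latitude"):
        geo_distance_matrix(meta)


# ------------------------------------------------------------------- IBD

def test_ibd_perfect_linear_relation():
    rng = np.random.default_rng(11)
    meta = pd.DataFrame({
        "sample": [f"s{i}" for i in range(8)],
        "lat": rng.uniform(46, 48, 8),
        "lon": rng.uniform(6, 10, 8),
    })
    d_geo = geo_distance_matrix(meta)
    logd = np.log10(np.maximum(d_geo.values, 1.0))
    np.fill_diagonal(logd, 0)
    d_gen = DistanceMatrix(d_geo.ids, 0.05 * logd)
    res = ibd_test(d_gen, meta, nperm=99, seed=0)
    assert res.pearson_r == pytest.approx(1.0)
    assert res.mantel.r == pytest.approx(1.0)


def test_ibd_colocated_samples_rejected():
    meta = pd.DataFrame({"sample": ["a", "b", "c"], "lat": [47.0] * 3, "lon": [8.0] * 3})
    v = np.array([[0, 0.1, 0.2], [0.1, 0, 0.3], [0.2, 0.3, 0]])
    with pytest.raises(ValueError, match="co-located"):
        ibd_test(dm_from(v, ids=["a", "b", "c"]), meta, nperm=9)


def test_ibd_positive_signal_on_simulated_cohort():
    spec = lp.CohortSpec(n_pops_sp1=8, n_pops_sp2=0, samples_per_pop=2,
                         n_sites=800, ibd_strength=1.0, seed=19)
    table, truth = lp.simulate_cohort(spec)
    dm = lp.pairwise_allele_distance(table)
    res = ibd_test(dm, truth.samples[["sample", "lat", "lon"]], nperm=999, seed=2)
    assert res.mantel.r > 0
    assert res.mantel.p_value < 0.05
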