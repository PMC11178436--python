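"""Per-SNP GLM assignment scan: deviances, codings, FDR, calibration."""

import numpy as np
import pytest
from scipy import stats
from scipy.optimize import minimize

import lemnapop as lp
from lemnapop.scan import (
    CodingScheme,
    best_coding_fit,
    bh_fdr,
    fit_snp_glm,
    null_calibration_pit,
    scan_assignment_markers,
)

from .conftest import make_table


def brute_force_logistic_deviances(y, levels):
    """Independent oracle: maximize the Bernoulli likelihood over per-level
    probabilities numerically and return (null deviance, residual deviance)."""
    y = np.asarray(y, dtype=float)
    uniq = sorted(set(levels))
    idx = np.asarray([uniq.index(l) for l in levels])

    def nll(theta):
        mu = 1 / (1 + np.exp(-theta))[idx]
        mu = np.clip(mu, 1e-10, 1 - 1e-10)
        return -np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu))

    res = minimize(nll, np.zeros(len(uniq)), method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
    d_res = 2 * res.fun
    res0 = minimize(lambda t: nll(np.repeat(t, len(uniq))), [0.0], method="Nelder-Mead",
                    options={"xatol": 1e-10, "fatol": 1e-12})
    d_null = 2 * res0.fun
    return d_null, d_res


def test_perfect_separation():
    y = np.array(["a"] * 3 + ["b"] * 3)
    gt = np.array([0, 0, 0, 2, 2, 2], dtype=np.int8)
    coding, fit = best_coding_fit(gt, y)
    assert fit.pct_dev == 100.0
    assert fit.separated
    assert coding is CodingScheme.FACTOR_A  # tie broken toward 2-level factors
    assert fit.p_value < 1e-6


def test_independent_genotypes_near_zero_deviance():
    y = np.array(["a", "a", "b", "b"] * 5)
    gt = np.array([0, 2, 0, 2] * 5, dtype=np.int8)  # balanced, independent
    fit = fit_snp_glm(y, gt)
    assert fit.pct_dev == pytest.approx(0.0, abs=1e-9)


def test_worked_example_matches_brute_force_mle_and_statsmodels():
    """8-sample table (4/4; 0/0,0/0,0/0,0/1 | 0/1,1/1,1/1,1/1), three-level
    coding: deviances agree with a numeric ML oracle and statsmodels IRLS."""
    y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
    gt = np.array([0, 0, 0, 1, 1, 2, 2, 2], dtype=np.int8)
    fit = fit_snp_glm(y, gt)

    d_null_o, d_res_o = brute_force_logistic_deviances(y, gt)
    pct_o = 100 * (d_null_o - d_res_o) / d_null_o
    assert fit.pct_dev == pytest.approx(pct_o, abs=1e-4)

    import statsmodels.api as sm

    x = np.zeros((8, 3))
    x[:, 0] = 1
    x[:, 1] = gt == 1
    x[:, 2] = gt == 2
    glm = sm.GLM(y, x, family=sm.families.Binomial()).fit()
    assert glm.deviance == pytest.approx(d_res_o, abs=1e-6)
    assert glm.null_deviance == pytest.approx(d_null_o, abs=1e-6)
    # F statistic against the model's Pearson dispersion
    disp = glm.pearson_chi2 / glm.df_resid
    f_expect = ((glm.null_deviance - glm.deviance) / 2) / disp
    assert fit.f_stat == pytest.approx(f_expect, rel=1e-8)
    assert fit.p_value == pytest.approx(stats.f.sf(f_expect, 2, 5), rel=1e-8)


def test_best_coding_is_max_over_individual_codings():
    rng = np.random.default_rng(0)
    y = np.array(["a"] * 8 + ["b"] * 8)
    for _ in range(50):
        gt = rng.integers(0, 3, size=16).astype(np.int8)
        if len(np.unique(gt)) < 2:
            continue
        res = best_coding_fit(gt, y)
        assert res is not None
        _, best = res
        for coding in CodingScheme:
            enc = gt if coding is CodingScheme.THREE_LEVEL else (
                (gt >= 1).astype(np.int8) if coding is CodingScheme.FACTOR_A
                else (gt == 2).astype(np.int8)
            )
            if len(np.unique(enc)) < 2:
                continue
            assert best.pct_dev >= fit_snp_glm(y, enc).pct_dev - 1e-9


def test_single_level_rejected():
    with pytest.raises(ValueError):
        fit_snp_glm(np.array([0, 0, 1, 1]), np.array([1, 1, 1, 1]))


def test_bh_fdr_hand_computed():
    assert bh_fdr([0.02])[0] == pytest.approx(0.02)
    np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
    np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), [1.0] * 3)
    # general case against statsmodels
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(1)
    p = rng.uniform(size=100)
    _, expected, _, _ = multipletests(p, method="fdr_bh")
    np.testing.assert_allclose(bh_fdr(p), expected, atol=1e-12)


def test_bh_fdr_nan_propagation():
    out = bh_fdr([0.01, np.nan, 0.5])
    assert np.isnan(out[1])
    # ranking done over the 2 valid entries only
    np.testing.assert_allclose(out[[0, 2]], [0.02, 0.5])


def test_scan_recovers_fixed_differences_and_site_order_invariance():
    rng = np.random.default_rng(7)
    n1 = n2 = 6
    fixed = np.hstack([np.zeros((40, n1)), np.full((40, n2), 2)]).astype(np.int8)
    null = rng.integers(0, 3, size=(200, n1 + n2)).astype(np.int8)
    gt = np.vstack([fixed, null])
    t = make_table(gt)
    groups = {s: ("a" if i < n1 else "b") for i, s in enumerate(t.samples)}
    results, summary = scan_assignment_markers(t, groups)
    sig_pos = {r.pos for r in results if r.significant}
    assert set(t.pos[:40].tolist()) <= sig_pos
    assert all(r.diff_class == "hom_vs_hom" for r in results[:40])

    # permuting site order leaves per-site results unchanged
    perm = rng.permutation(gt.shape[0])
    t2 = make_table(gt[perm])
    res2, _ = scan_assignment_markers(t2, groups)
    by_pos = {r.pos: r for r in results}
    for r in res2:
        orig = by_pos[t.pos[perm][t2.pos.tolist().index(r.pos)]]
        assert r.pct_dev == pytest.approx(orig.pct_dev)
        assert r.fdr == pytest.approx(orig.fdr)


def test_scan_group_errors():
    t = make_table(np.zeros((5, 4), dtype=np.int8))
    with pytest.raises(ValueError):
        scan_assignment_markers(t, {s: "a" for s in t.samples})


def test_all_monomorphic_sites_yield_empty_result():
    t = make_table(np.ones((10, 8), dtype=np.int8))
    groups = {s: ("a" if i < 4 else "b") for i, s in enumerate(t.samples)}
    results, summary = scan_assignment_markers(t, groups)
    assert results == []
    assert summary.n_skipped == 10


def test_null_pvalues_uniform_after_discreteness_adjustment():
    """Under permuted labels the best-coding p-values, mapped through their
    exact permutation-null CDF (discreteness-adjusted PIT), are uniform."""
    rng = np.random.default_rng(21)
    n = 24
    labels = np.array([0] * 12 + [1] * 12)
    gts = []
    while len(gts) < 800:
        p = rng.uniform(0.1, 0.9)
        gt = rng.binomial(2, p, size=n)
        if len(np.unique(gt)) >= 2:
            gts.append(gt)
    u = null_calibration_pit(np.array(gts), labels, seed=3)
    ks = stats.kstest(u, "uniform")
    assert ks.pvalue > 0.01
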