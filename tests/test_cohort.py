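"""Synthetic-cohort generator: determinism, drift law, dosage, VCF round-trip."""

import numpy as np
import pytest

import lemnapop as lp
from lemnapop.cohort import CohortSpec, place_populations, simulate_founders
from lemnapop.structure import haversine_m


def test_placement_inside_box_and_deterministic():
    spec = CohortSpec(n_pops_sp1=20, n_pops_sp2=3, region_extent_km=200, seed=9)
    a = place_populations(spec)
    b = place_populations(spec)
    assert a.equals(b)
    # max pairwise great-circle distance bounded by the box diagonal
    diag = 200 * np.sqrt(2) * 1000 * 1.01
    lat, lon = a["lat"].to_numpy(), a["lon"].to_numpy()
    dmax = max(
        haversine_m(lat[i], lon[i], lat[j], lon[j])
        for i in range(len(a))
        for j in range(i + 1, len(a))
    )
    assert dmax <= diag


def test_single_population_single_coordinate():
    spec = CohortSpec(n_pops_sp1=1, n_pops_sp2=0, seed=0)
    coords = place_populations(spec)
    assert len(coords) == 1


def test_zero_drift_returns_ancestral_frequencies():
    spec = CohortSpec(n_pops_sp1=4, n_pops_sp2=2, fst_drift=0.0, n_sites=200, seed=2)
    coords = place_populations(spec)
    f = simulate_founders(spec, coords)
    assert np.allclose(f.pop_freq[:, ~f.is_fixed_diff], f.p_anc[~f.is_fixed_diff])


def test_balding_nichols_drift_matches_monte_carlo_oracle():
    """E[(p1-p2)^2 / (pbar(1-pbar))] from the generator agrees with a direct
    Monte-Carlo draw from the Balding-Nichols Beta law."""
    fst = 0.3
    spec = CohortSpec(
        n_pops_sp1=2, n_pops_sp2=0, fst_drift=fst, ibd_strength=0.0,
        fixed_diff_fraction=0.0, n_sites=10_000, seed=3,
    )
    coords = place_populations(spec)
    f = simulate_founders(spec, coords)
    p1, p2, pa = f.pop_freq[0], f.pop_freq[1], f.p_anc
    pbar = (p1 + p2) / 2
    stat = np.mean((p1 - p2) ** 2 / (pbar * (1 - pbar)))

    # independent brute-force oracle from the same prior
    rng = np.random.default_rng(12345)
    pa_o = rng.uniform(0.05, 0.95, size=200_000)
    scale = (1 - fst) / fst
    q1 = rng.beta(pa_o * scale, (1 - pa_o) * scale)
    q2 = rng.beta(pa_o * scale, (1 - pa_o) * scale)
    qbar = (q1 + q2) / 2
    stat_o = np.mean((q1 - q2) ** 2 / (qbar * (1 - qbar)))
    assert stat == pytest.approx(stat_o, rel=0.05)


def test_dosage_fractions_match_ploidy():
    spec = CohortSpec(n_pops_sp1=1, n_pops_sp2=1, samples_per_pop=2, n_sites=500,
                      fixed_diff_fraction=0.3, clone_mutation_rate=0.0, seed=4)
    _, truth = lp.simulate_cohort(spec)
    allowed = {0.0, 1 / 3, 0.5, 2 / 3, 1.0}
    assert set(np.round(np.unique(truth.dosage), 9)) <= {round(v, 9) for v in allowed}
    # M/M/T at a fixed difference (M=ref, T=alt): dosage exactly 1/3
    fixed = truth.founders.is_fixed_diff
    sp2 = truth.samples["species"] == "japonica"
    assert np.allclose(truth.dosage[np.ix_(fixed, sp2.to_numpy())], 1 / 3)


def test_mtt_dosage_at_fixed_sites_is_two_thirds():
    spec = CohortSpec(n_pops_sp1=1, n_pops_sp2=1, samples_per_pop=1, n_sites=300,
                      fixed_diff_fraction=0.5, clone_mutation_rate=0.0,
                      sp2_ploidy="MTT", seed=4)
    _, truth = lp.simulate_cohort(spec)
    fixed = truth.founders.is_fixed_diff
    sp2 = (truth.samples["species"] == "japonica").to_numpy()
    assert np.allclose(truth.dosage[np.ix_(fixed, sp2)], 2 / 3)


def test_clones_identical_without_mutation():
    spec = CohortSpec(n_pops_sp1=2, n_pops_sp2=1, samples_per_pop=4, n_sites=400,
                      clone_mutation_rate=0.0, seed=5)
    _, truth = lp.simulate_cohort(spec)
    for pop, sub in truth.samples.groupby("population"):
        idx = sub.index.to_numpy()
        for j in idx[1:]:
            assert np.array_equal(truth.haplotypes[:, idx[0]], truth.haplotypes[:, j])


def test_read_simulation_binomial_mean():
    """Mean alt fraction at dosage 1/3 lands within 3 SE of 1/3."""
    table = lp.single_sample_table("MMT", n_sites=10_000, mean_depth=60,
                                   error_rate=0.0, seed=6)
    depth = table.ad_ref[:, 0] + table.ad_alt[:, 0]
    frac = table.ad_alt[depth > 0, 0] / depth[depth > 0]
    se = np.sqrt((1 / 3) * (2 / 3) / depth[depth > 0]).mean() / np.sqrt(len(frac))
    assert abs(frac.mean() - 1 / 3) < 3 * se


def test_zero_dosage_zero_error_gives_ref_calls():
    table = lp.single_sample_table("MMT", n_sites=100, mean_depth=50, seed=0)
    # construct explicitly: dosage 0 sites via a diploid cohort with no alt
    spec = CohortSpec(n_pops_sp1=1, n_pops_sp2=0, samples_per_pop=1, n_sites=200,
                      error_rate=0.0, missing_rate=0.0, fst_drift=0.0, seed=7)
    t, truth = lp.simulate_cohort(spec)
    zero = truth.dosage[:, 0] == 0
    assert np.all(t.ad_alt[zero, 0] == 0)
    assert np.all(t.gt[zero, 0] == 0)
    del table


def test_vcf_round_trip_and_missing_convention(tmp_path):
    spec = CohortSpec(n_pops_sp1=2, n_pops_sp2=1, samples_per_pop=2, n_sites=150,
                      missing_rate=0.1, seed=8)
    table, truth = lp.simulate_cohort(spec)
    paths = lp.write_cohort(table, truth, str(tmp_path / "coh"))
    back = lp.read_vcf(paths["vcf"])
    assert back.samples == table.samples
    assert np.array_equal(back.gt, table.gt)
    assert np.array_equal(back.ad_alt, table.ad_alt)
    assert np.array_equal(back.dp, table.dp)
    assert back.contig_subgenome == table.contig_subgenome
    # missing calls written as ./.
    text = open(paths["vcf"]).read()
    assert (table.gt == -1).any()
    assert "./." in text
    # every contig carries its sub-genome tag in the header
    for ctg, tag in table.contig_subgenome.items():
        assert f"##contig=<ID={ctg}," in text and f"SUBGENOME={tag}>" in text


def test_identical_spec_and_seed_give_identical_vcf_bytes(tmp_path):
    spec = CohortSpec(n_pops_sp1=2, n_pops_sp2=1, samples_per_pop=2, n_sites=100, seed=9)
    for tag in ("a", "b"):
        table, truth = lp.simulate_cohort(CohortSpec(**{**spec.__dict__}))
        lp.write_cohort(table, truth, str(tmp_path / tag))
    assert (tmp_path / "a.vcf").read_bytes() == (tmp_path / "b.vcf").read_bytes()


def test_spec_validation():
    with pytest.raises(ValueError):
        CohortSpec(fst_drift=1.5)
    with pytest.raises(ValueError):
        CohortSpec(mean_depth=0)
    with pytest.raises(ValueError):
        CohortSpec(sp2_ploidy="XXX")
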