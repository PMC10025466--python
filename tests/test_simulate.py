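"""Trio simulation: phenotype models, pairing, scenarios, serialization."""

import io

import numpy as np
import pandas as pd
import pytest

from triomr.genetics import additive_code, dominance_code
from triomr.simulate import (
    SimParams,
    TrioDataError,
    TrioDataset,
    assortative_pairing,
    default_params,
    make_offspring,
    phenotype_x,
    phenotype_y,
    simulate_assortative,
    simulate_parent_pool,
    simulate_scenario,
    simulate_stratified,
)


def test_simparams_validation():
    with pytest.raises(ValueError):
        default_params(p_assort=1.5)
    with pytest.raises(ValueError):
        default_params(freq_A=-0.1)
    with pytest.raises(ValueError):
        default_params(var_U=-1)
    with pytest.raises(ValueError):
        default_params(n_trios=0)
    with pytest.raises(ValueError):
        default_params(rho_u_parent_offspring=0.9)


@pytest.mark.parametrize("g,h,u,expected", [
    (0, 0, 0.0, 0.0),     # reference genotypes, all zero inputs
    (1, 0, 0.0, 1.0),     # heterozygote at G: pure dominance effect
    (2, 1, 0.5, 1.5),     # no additive effect; fD(H)=1 plus confounder
])
def test_phenotype_x_default_effects(g, h, u, expected):
    p = default_params()
    assert phenotype_x(g, h, u, 0.0, p) == pytest.approx(expected)


@pytest.mark.parametrize("x,h,u,expected", [
    (0.0, 0, 0.0, 0.0),
    (2.0, 0, 0.0, 2.0),   # unit causal effect of X
    (1.0, 1, 1.0, 3.0),   # X + dominance of H + confounder
])
def test_phenotype_y_default_effects(x, h, u, expected):
    p = default_params(beta_XY=1.0)
    assert phenotype_y(x, h, u, 0.0, p) == pytest.approx(expected)


def test_parent_pool_hwe_frequencies_and_independence(rng):
    n = 100_000
    pool = simulate_parent_pool(n, default_params(freq_A=0.1), rng)
    frac_aa = np.mean(pool.g == 2)
    se = np.sqrt(0.01 * 0.99 / n)
    assert abs(frac_aa - 0.01) < 4 * se
    # loci are unlinked and independently sampled before mating
    corr = np.corrcoef(dominance_code(pool.g), dominance_code(pool.h))[0, 1]
    assert abs(corr) < 4 / np.sqrt(n)


def test_parent_pool_degenerate_noise(rng):
    p = default_params(beta1=2.5, beta_GD_X=0, beta_HD_X=0, beta_U_X=0,
                       var_U=0.0, var_eps_X=0.0)
    pool = simulate_parent_pool(500, p, rng)
    assert np.all(pool.x == 2.5)


def test_full_rank_pairing_matches_sorted_order(rng):
    m_idx, f_idx = assortative_pairing([3.0, 1.0, 2.0], [10.0, 30.0, 20.0],
                                       1.0, rng)
    xm = np.array([3.0, 1.0, 2.0])[m_idx]
    xf = np.array([10.0, 30.0, 20.0])[f_idx]
    assert list(zip(xm, xf)) == [(1.0, 10.0), (2.0, 20.0), (3.0, 30.0)]


def test_random_pairing_is_a_permutation(rng):
    n = 20_000
    xm = rng.normal(size=n)
    xf = rng.normal(size=n)
    m_idx, f_idx = assortative_pairing(xm, xf, 0.0, rng)
    assert sorted(m_idx) == list(range(n))
    assert sorted(f_idx) == list(range(n))
    assert abs(np.corrcoef(xm[m_idx], xf[f_idx])[0, 1]) < 0.03


def test_partial_assortment_induces_spousal_correlation(rng):
    n = 5_000
    xm = rng.normal(size=n)
    xf = rng.normal(size=n)
    m_idx, f_idx = assortative_pairing(xm, xf, 0.8, rng)
    assert np.corrcoef(xm[m_idx], xf[f_idx])[0, 1] > 0.3


def test_pairing_length_mismatch_rejected(rng):
    with pytest.raises(ValueError):
        assortative_pairing([1.0, 2.0], [1.0], 0.5, rng)


def test_make_offspring_mendelian_fractions(rng):
    from triomr.simulate import Cohort
    n = 10_000
    params = default_params()
    mk = lambda g: Cohort(np.full(n, g), np.zeros(n, dtype=int),
                          np.zeros(n), np.zeros(n), np.zeros(n))
    off = make_offspring(mk(1), mk(1), params, rng)
    frac = np.bincount(off.g, minlength=3) / n
    assert np.allclose(frac, [0.25, 0.5, 0.25], atol=0.02)
    off2 = make_offspring(mk(2), mk(2), params, rng)
    assert np.all(off2.g == 2)


def test_parent_offspring_confounder_correlation(rng):
    from triomr.simulate import Cohort
    n = 50_000
    params = default_params(rho_u_parent_offspring=0.5)
    sd = np.sqrt(params.var_U)
    mothers = Cohort(np.ones(n, dtype=int), np.ones(n, dtype=int),
                     rng.normal(0, sd, n), np.zeros(n), np.zeros(n))
    fathers = Cohort(np.ones(n, dtype=int), np.ones(n, dtype=int),
                     rng.normal(0, sd, n), np.zeros(n), np.zeros(n))
    off = make_offspring(mothers, fathers, params, rng)
    assert np.corrcoef(off.u, mothers.u)[0, 1] == pytest.approx(0.5, abs=0.02)
    assert np.std(off.u) == pytest.approx(sd, rel=0.03)


def test_assortative_dataset_deterministic_and_mendelian():
    params = default_params(p_assort=0.8, n_trios=300, seed=99)
    d1 = simulate_assortative(params)
    d2 = simulate_assortative(params)
    buf1, buf2 = io.StringIO(), io.StringIO()
    d1.to_csv(buf1)
    d2.to_csv(buf2)
    assert buf1.getvalue() == buf2.getvalue()
    d1.validate()  # exhaustive Mendelian-consistency check


def test_assortment_induces_offspring_locus_association():
    """Rank-pairing on X associates the unlinked loci G and H in offspring."""
    def mean_corr(p, reps=60):
        cs = []
        for r in range(reps):
            d = simulate_assortative(
                default_params(p_assort=p, n_trios=1000, seed=7000 + r))
            cs.append(np.corrcoef(dominance_code(d.df["G"].to_numpy()),
                                  dominance_code(d.df["H"].to_numpy()))[0, 1])
        cs = np.asarray(cs)
        return cs.mean(), cs.std(ddof=1) / np.sqrt(reps)

    m0, se0 = mean_corr(0.0)
    m8, se8 = mean_corr(0.8)
    assert abs(m0) < 4 * se0
    assert m8 > 4 * se8


def test_spousal_correlation_monotone_in_assortment():
    grid = [0.0, 0.2, 0.4, 0.6, 0.8]
    means = []
    for i, p in enumerate(grid):
        cs = [np.corrcoef(d.df["Xm"], d.df["Xf"])[0, 1]
              for d in (simulate_assortative(
                  default_params(p_assort=p, n_trios=300, seed=i * 1000 + r))
                  for r in range(200))]
        means.append(np.mean(cs))
    assert all(b > a for a, b in zip(means, means[1:]))


def test_stratified_requires_random_mating():
    p1 = default_params(p_assort=0.3, n_trios=50)
    p2 = default_params(n_trios=50)
    with pytest.raises(ValueError, match="p_assort"):
        simulate_stratified(p1, p2)


def test_stratification_induces_pooled_locus_association():
    def pooled_corr(freq2, reps=50):
        cs = []
        for r in range(reps):
            p1 = default_params(n_trios=500, seed=3000 + r)
            p2 = p1.replace(freq_A=freq2, freq_B=freq2)
            d = simulate_stratified(p1, p2)
            cs.append(np.corrcoef(additive_code(d.df["G"].to_numpy()),
                                  additive_code(d.df["H"].to_numpy()))[0, 1])
        cs = np.asarray(cs)
        return cs.mean(), cs.std(ddof=1) / np.sqrt(reps)

    m_same, se_same = pooled_corr(0.1)
    m_diff, se_diff = pooled_corr(0.9)
    assert abs(m_same) < 4 * se_same
    assert m_diff > 4 * se_diff


def test_stratified_labels_and_determinism():
    p1 = default_params(n_trios=40, seed=5)
    p2 = p1.replace(freq_A=0.5, freq_B=0.5)
    d1 = simulate_stratified(p1, p2)
    d2 = simulate_stratified(p1, p2)
    assert d1.df.equals(d2.df)
    assert list(np.unique(d1.df["subpop"])) == [0, 1]
    assert d1.n_trios == 80
    assert d1.df["family_id"].is_unique


def test_csv_round_trip(tmp_path):
    d = simulate_assortative(default_params(n_trios=60, seed=8))
    path = tmp_path / "trios.csv"
    d.to_csv(path)
    back = TrioDataset.from_csv(path)
    for col in ("Gm", "Gf", "G", "Hm", "Hf", "H", "family_id", "subpop"):
        assert np.array_equal(back.df[col], d.df[col])
    for col in ("Xm", "Xf", "X", "Ym", "Yf", "Y"):
        assert np.allclose(back.df[col], d.df[col], rtol=0, atol=0)


def test_csv_mendelian_validation_names_family(tmp_path):
    d = simulate_assortative(default_params(n_trios=30, seed=8))
    path = tmp_path / "bad.csv"
    d.to_csv(path)
    table = pd.read_csv(path)
    table.loc[4, ["Gm", "Gf", "G"]] = ["aa", "aa", "AA"]
    table.to_csv(path, index=False)
    with pytest.raises(TrioDataError, match=r"family 4\b.*locus G"):
        TrioDataset.from_csv(path)


def test_csv_bad_genotype_label(tmp_path):
    d = simulate_assortative(default_params(n_trios=5, seed=8))
    path = tmp_path / "bad.csv"
    d.to_csv(path)
    text = path.read_text().replace("Aa", "AZ")
    path.write_text(text)
    with pytest.raises(TrioDataError, match="label"):
        TrioDataset.from_csv(path)


def test_scenario_presets():
    d1 = simulate_scenario("sim1-assortative", seed=1, n_trios=50)
    assert d1.n_trios == 50
    d2 = simulate_scenario("sim2-stratified", seed=1, n_trios=50, freq2=0.5)
    assert d2.n_trios == 100
    with pytest.raises(ValueError, match="scenario"):
        simulate_scenario("sim3-unknown", seed=1)
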