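"""Tests for the synthetic F2-cross / bulk / panel / CDS generator."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import qtlbsa as q
from qtlbsa.candidates import PatternRule, annotate_effect, pattern_filter
from qtlbsa.simdata import genetic_value


def test_identical_config_is_bit_reproducible():
    cfg = q.CrossConfig(n_individuals=50, n_sites=40, seed=42)
    a, b = q.simulate_f2(cfg), q.simulate_f2(cfg)
    np.testing.assert_array_equal(a.genotypes, b.genotypes)
    np.testing.assert_array_equal(a.phenotypes, b.phenotypes)
    np.testing.assert_array_equal(a.site_positions, b.site_positions)
    ea, la = q.make_bulks(a, cfg.bulk_size)
    eb, lb = q.make_bulks(b, cfg.bulk_size)
    pd.testing.assert_frame_equal(
        q.sample_depths(a, ea, la), q.sample_depths(b, eb, lb)
    )


def test_causal_position_outside_chromosome_rejected():
    with pytest.raises(ValueError, match="outside"):
        q.CrossConfig(chrom_length_bp=1000, causal_pos_bp=2000).validate()


def test_no_effect_null_has_no_genotype_phenotype_correlation():
    corrs = []
    for seed in range(20):
        cfg = q.CrossConfig(
            n_individuals=500, n_sites=1, effect_days=0.0, noise_sd=2.0, seed=seed
        )
        pop = q.simulate_f2(cfg)
        corrs.append(np.corrcoef(pop.causal_dose, pop.phenotypes)[0, 1])
    assert abs(np.mean(corrs)) < 0.05


def test_mendelian_ratio_at_large_n():
    cfg = q.CrossConfig(n_individuals=10_000, n_sites=5, causal_pos_bp=None, seed=3)
    pop = q.simulate_f2(cfg)
    n = pop.n_individuals
    for k, p in [(0, 0.25), (1, 0.5), (2, 0.25)]:
        freq = (pop.genotypes == k).mean(axis=1)
        se = np.sqrt(p * (1 - p) / n)
        assert (np.abs(freq - p) < 3 * se).all()


def test_mendelian_chi2_rarely_rejects_across_seeds():
    """1:2:1 chi-square at alpha=0.01 should pass for >= 98% of seeds."""
    n_reject = 0
    seeds = range(100)
    for seed in seeds:
        cfg = q.CrossConfig(n_individuals=1000, n_sites=1, causal_pos_bp=None, seed=seed)
        pop = q.simulate_f2(cfg)
        obs = [(pop.genotypes[0] == k).sum() for k in (0, 1, 2)]
        n = sum(obs)
        p = stats.chisquare(obs, f_exp=[n / 4, n / 2, n / 4]).pvalue
        n_reject += p < 0.01
    assert n_reject <= 2  # >= 98 of 100 seeds retained


def test_linkage_decays_with_map_distance():
    cfg = q.CrossConfig(
        n_individuals=10_000, n_sites=60, chrom_length_bp=10_000_000,
        causal_pos_bp=None, seed=5,
    )
    pop = q.simulate_f2(cfg)
    g = pop.genotypes.astype(float)
    d0 = g[0]
    dist = pop.site_positions - pop.site_positions[0]
    corr = np.array([np.corrcoef(d0, g[i])[0, 1] for i in range(1, pop.n_sites)])
    bins = np.digitize(dist[1:], np.linspace(0, cfg.chrom_length_bp, 6)[1:-1])
    means = [corr[bins == b].mean() for b in range(5) if (bins == b).any()]
    assert all(a > b for a, b in zip(means, means[1:]))


# --- bulk selection --------------------------------------------------------


def _pop_from_doses(doses, effect_days=20.0, dominance=0.0, baseline=80.0):
    doses = np.asarray(doses, dtype=np.int8)
    cfg = q.CrossConfig(
        n_individuals=len(doses), bulk_size=len(doses) // 2 or 1, n_sites=1,
        effect_days=effect_days, dominance=dominance, noise_sd=0.0,
        baseline_days=baseline, seed=0,
    )
    pheno = baseline + genetic_value(doses, effect_days, dominance)
    return q.F2Population(
        genotypes=doses[None, :], phenotypes=pheno,
        site_positions=np.array([500_000]), config=cfg, causal_dose=doses,
    )


def test_tails_selection_takes_extremes():
    pop = _pop_from_doses([0, 0, 1, 1, 2, 2])
    pop.phenotypes = np.arange(1.0, 7.0)
    e, l = q.make_bulks(pop, 2)
    assert list(e) == [0, 1] and list(l) == [4, 5]


def test_threshold_selection_matches_day_ranges():
    pop = _pop_from_doses([0, 0, 1, 2, 2])
    pop.phenotypes = np.array([35.0, 37.0, 39.0, 53.0, 60.0])
    e, l = q.make_bulks(pop, 2, mode="thresholds", thresholds=((36, 40), 52))
    assert list(e) == [1, 2]  # the 37 d and 39 d plants
    assert list(l) == [3, 4]  # the 53 d and 60 d plants


def test_threshold_selection_error_names_deficient_pool():
    pop = _pop_from_doses([0, 1, 2, 2])
    pop.phenotypes = np.array([35.0, 37.0, 53.0, 60.0])
    with pytest.raises(ValueError, match="E-pool"):
        q.make_bulks(pop, 2, mode="thresholds", thresholds=((36, 40), 52))
    pop2 = _pop_from_doses([0, 0, 1, 2])
    pop2.phenotypes = np.array([31.0, 35.0, 37.0, 53.0])
    with pytest.raises(ValueError, match="L-pool"):
        q.make_bulks(pop2, 2, mode="thresholds", thresholds=((30, 40), 52))


def test_all_equal_phenotypes_fall_back_to_index_order():
    pop = _pop_from_doses([1] * 8, effect_days=0.0)
    e, l = q.make_bulks(pop, 3)
    assert list(e) == [0, 1, 2] and list(l) == [5, 6, 7]
    assert not set(e) & set(l)


@pytest.mark.parametrize("dominance", [0.0, 1.0])
def test_bulk_frequencies_match_exhaustive_enumeration(dominance):
    """Brute-force oracle over all 3^6 causal genotype assignments (n=6,
    bulks of 2, no noise) reproduces the simulator's bulk allele
    frequencies exactly, including stable tie-breaking."""
    import itertools

    def oracle(doses):
        # independent reimplementation: stable sort by (phenotype, index)
        eff = {0: 0.0, 1: 20.0 * (1 - dominance) / 2.0, 2: 20.0}
        pheno = [80.0 + eff[d] for d in doses]
        order = sorted(range(6), key=lambda i: (pheno[i], i))
        e_sel, l_sel = order[:2], order[-2:]
        return (
            sum(doses[i] for i in e_sel) / 4.0,
            sum(doses[i] for i in l_sel) / 4.0,
        )

    for doses in itertools.product((0, 1, 2), repeat=6):
        pop = _pop_from_doses(doses, dominance=dominance)
        e, l = q.make_bulks(pop, 2)
        got = (q.pool_alt_freq(pop, e)[0], q.pool_alt_freq(pop, l)[0])
        assert got == pytest.approx(oracle(doses)), doses


# --- depth sampling --------------------------------------------------------


def test_fixed_pools_give_fixed_allele_depths():
    pop = _pop_from_doses([2, 2, 2, 2, 0, 0, 0, 0], dominance=0.0)
    e, l = q.make_bulks(pop, 4)  # E-pool all dose 0, L-pool all dose 2
    pop.config.fixed_depth = True
    pop.config.mean_depth = 20.0
    sites = q.sample_depths(pop, e, l)
    assert sites.loc[0, "e_alt"] == 0 and sites.loc[0, "e_ref"] == 20
    assert sites.loc[0, "l_alt"] == 20 and sites.loc[0, "l_ref"] == 0


def test_null_sites_mean_alt_fraction_matches_binomial_oracle():
    """Given the pool allele frequencies, read sampling is Binomial(depth, f):
    the mean read alt fraction over 10 000 null sites must track the mean
    pool frequency within 3 standard errors of the binomial residuals."""
    cfg = q.CrossConfig(
        n_individuals=100, bulk_size=20, n_sites=10_000,
        chrom_length_bp=100_000_000, causal_pos_bp=None, mean_depth=30.0, seed=9,
    )
    pop = q.simulate_f2(cfg)
    e, l = q.make_bulks(pop, cfg.bulk_size)
    sites = q.sample_depths(pop, e, l)
    freq = q.pool_alt_freq(pop, e)
    frac = (sites["e_alt"] / (sites["e_ref"] + sites["e_alt"])).to_numpy()
    ok = np.isfinite(frac)
    resid = frac[ok] - freq[ok]
    sem = resid.std() / np.sqrt(ok.sum())
    assert abs(resid.mean()) < 3 * sem
    # and the null pool frequency itself is centred at 1/2
    assert abs(freq.mean() - 0.5) < 0.05


def test_empty_pool_is_an_error():
    pop = _pop_from_doses([0, 1, 2, 2])
    with pytest.raises(ValueError, match="empty pool"):
        q.sample_depths(pop, np.array([], dtype=int), np.array([0, 1]))


# --- variety panel ---------------------------------------------------------


def test_panel_plants_exact_number_of_pattern_sites():
    panel = q.simulate_variety_panel(n_sites=10, n_pattern_sites=4, seed=1)
    assert len(pattern_filter(panel)) == 4
    empty = q.simulate_variety_panel(n_sites=10, n_pattern_sites=0, seed=1)
    assert len(pattern_filter(empty)) == 0


def test_too_many_pattern_sites_rejected():
    with pytest.raises(ValueError):
        q.simulate_variety_panel(n_sites=3, n_pattern_sites=4)


def test_missing_xis_call_disqualifies_a_planted_site():
    panel = q.simulate_variety_panel(n_sites=6, n_pattern_sites=6, seed=2)
    xis = [v for v, g in panel.groups.items() if g == "xis"][0]
    panel.genotypes.loc[0, xis] = "missing"
    kept = pattern_filter(panel, PatternRule(missing_policy="fail"))
    assert len(kept) == 5
    assert 0 not in kept.index


# --- coding sequences ------------------------------------------------------


def test_cds_is_valid_and_carries_planted_bases():
    seq, variants = q.simulate_cds_with_variants(20, [(14, "A", "G"), (30, "T", "C")])
    assert seq.startswith("ATG") and len(seq) == 60
    assert all(seq[i : i + 3] not in ("TAA", "TAG", "TGA") for i in range(0, 60, 3))
    assert seq[13] == "A" and seq[29] == "T"
    assert variants == [(14, "A", "G"), (30, "T", "C")]


def test_conflicting_planted_bases_rejected():
    with pytest.raises(ValueError, match="conflict"):
        q.simulate_cds_with_variants(10, [(7, "A", "G"), (7, "C", "T")])
    with pytest.raises(ValueError):  # clashes with the ATG start codon
        q.simulate_cds_with_variants(10, [(1, "C", "T")])


def test_zero_planted_variants_yield_empty_effect_list():
    seq, variants = q.simulate_cds_with_variants(10, [])
    assert variants == []
    calls = [annotate_effect("g", seq, "+", pos, ref, alt) for pos, ref, alt in variants]
    assert calls == []
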