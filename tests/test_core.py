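"""Tests for SNP-index computation, windowing, null band and QTL calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import qtlbsa as q
from qtlbsa.core import compute_indices, polarize_sites, window_profile


# --- polarization ----------------------------------------------------------


def test_opposite_homozygotes_kept_unchanged(site_table_factory):
    sites = site_table_factory([dict(p1_gt="ref_hom", p2_gt="alt_hom")])
    kept, rejected = polarize_sites(sites)
    assert len(kept) == 1 and len(rejected) == 0
    pd.testing.assert_frame_equal(kept, sites)


def test_reversed_parents_swap_alleles_and_depths(site_table_factory):
    sites = site_table_factory(
        [dict(p1_gt="alt_hom", p2_gt="ref_hom", ref="A", alt="G",
              e_ref=3, e_alt=17, l_ref=19, l_alt=1)]
    )
    kept, _ = polarize_sites(sites)
    row = kept.iloc[0]
    assert (row.ref, row.alt) == ("G", "A")
    assert (row.e_ref, row.e_alt) == (17, 3)
    assert (row.l_ref, row.l_alt) == (1, 19)
    assert (row.p1_gt, row.p2_gt) == ("ref_hom", "alt_hom")


@pytest.mark.parametrize(
    "p1,p2,reason",
    [
        ("het", "alt_hom", "het_parent"),
        ("ref_hom", "missing", "missing_parent"),
        ("ref_hom", "ref_hom", "concordant_parents"),
        ("alt_hom", "alt_hom", "concordant_parents"),
    ],
)
def test_uninformative_parents_rejected_with_reason(site_table_factory, p1, p2, reason):
    sites = site_table_factory([dict(p1_gt=p1, p2_gt=p2)])
    kept, rejected = polarize_sites(sites)
    assert len(kept) == 0
    assert rejected["reason"].tolist() == [reason]


# --- SNP-index and delta ---------------------------------------------------


@pytest.mark.parametrize(
    "ref,alt,expected",
    [(20, 0, 0.0), (0, 20, 1.0), (15, 5, 0.25)],
)
def test_snp_index_values(ref, alt, expected):
    assert q.snp_index(ref, alt, min_depth=7) == pytest.approx(expected)


def test_snp_index_missing_below_min_depth():
    assert np.isnan(q.snp_index(3, 3, min_depth=7))
    assert np.isnan(q.snp_index(0, 0, min_depth=0))


def test_snp_index_rejects_negative_depths():
    with pytest.raises(ValueError):
        q.snp_index(-1, 5)


@given(ref=st.integers(0, 500), alt=st.integers(0, 500))
def test_snp_index_bounded(ref, alt):
    v = q.snp_index(ref, alt, min_depth=1)
    assert np.isnan(v) or 0.0 <= v <= 1.0


@given(
    e=st.floats(0, 1, allow_nan=False),
    l=st.floats(0, 1, allow_nan=False),
)
def test_delta_bounded_and_antisymmetric(e, l):
    d = q.delta_snp_index(e, l)
    assert -1.0 <= d <= 1.0
    assert q.delta_snp_index(l, e) == pytest.approx(-d)


def test_delta_examples():
    assert q.delta_snp_index(0, 1) == 1
    assert q.delta_snp_index(0.37, 0.37) == 0
    assert q.delta_snp_index(1, 0) == -1
    assert np.isnan(q.delta_snp_index(np.nan, 0.5))


def test_orientation_switch_flips_delta(site_table_factory):
    sites = site_table_factory([dict(e_ref=20, e_alt=0, l_ref=0, l_alt=20)])
    a = compute_indices(sites, orientation="l_minus_e")["delta"].iloc[0]
    b = compute_indices(sites, orientation="e_minus_l")["delta"].iloc[0]
    assert a == 1.0 and b == -1.0


# --- window scan -----------------------------------------------------------


def _indexed(positions, deltas, chrom="chr1"):
    return pd.DataFrame(
        {"chrom": chrom, "pos": positions, "delta": deltas,
         "e_ref": 15, "e_alt": 15, "l_ref": 15, "l_alt": 15}
    )


def test_constant_deltas_give_constant_window_means():
    sites = _indexed(np.arange(1, 5002, 50), 0.5)
    prof = q.window_scan(sites, window_bp=1000, step_bp=500, min_sites=3)
    ok = prof["mean_delta"].dropna()
    assert len(ok) > 0 and (ok == 0.5).all()


def test_window_means_match_bruteforce_oracle():
    rng = np.random.default_rng(17)
    pos = np.sort(rng.choice(np.arange(1, 100_000), 50, replace=False))
    deltas = rng.uniform(-1, 1, 50)
    sites = _indexed(pos, deltas)
    prof = q.window_scan(
        sites, window_bp=20_000, step_bp=5_000, min_sites=1,
        chrom_lengths={"chr1": 100_000},
    )
    for row in prof.itertuples(index=False):
        member = deltas[(pos >= row.start) & (pos < row.end)]
        if len(member) == 0:
            assert np.isnan(row.mean_delta)
        else:
            assert row.mean_delta == pytest.approx(member.sum() / len(member))
        assert row.n_sites == len(member)


def test_empty_window_is_missing_not_zero():
    sites = _indexed([10, 20, 30, 90_010, 90_020, 90_030], 0.8)
    prof = q.window_scan(
        sites, window_bp=1000, step_bp=1000, min_sites=3,
        chrom_lengths={"chr1": 100_000},
    )
    mid = prof[(prof["start"] > 2000) & (prof["end"] < 90_000)]
    assert mid["mean_delta"].isna().all()
    assert (mid["n_sites"] == 0).all()


def test_unsorted_sites_rejected():
    sites = _indexed([500, 100], 0.1)
    with pytest.raises(ValueError, match="sorted"):
        q.window_scan(sites)


# --- null band -------------------------------------------------------------


def test_single_read_single_plant_band_is_full_range():
    """With one plant per bulk and one read per pool, Δ takes values
    -1/0/+1 with probability 1/4, 1/2, 1/4 (exact enumeration), so the 95%
    band is the full [-1, 1]."""
    lo, hi = q.null_band([1], [1], bulk_size=1, reps=2000, seed=0)
    assert lo[0] == -1.0 and hi[0] == 1.0


def test_band_contains_zero_for_any_setting():
    rng = np.random.default_rng(1)
    e = rng.integers(0, 60, 30)
    l = rng.integers(0, 60, 30)
    lo, hi = q.null_band(e, l, bulk_size=10, reps=500, seed=2)
    assert (lo <= 0).all() and (hi >= 0).all()
    assert lo[e == 0].tolist() == [-1.0] * int((e == 0).sum())


def test_band_width_shrinks_with_depth_and_bulk_size():
    """Half-width tracks the binomial variance: more reads and bigger bulks
    both shrink the null band in expectation."""

    def mean_halfwidth(depth, bulk):
        lo, hi = q.null_band([depth] * 200, [depth] * 200, bulk, reps=800, seed=5)
        return (hi - lo).mean() / 2

    assert mean_halfwidth(100, 17) < mean_halfwidth(10, 17)
    assert mean_halfwidth(30, 50) < mean_halfwidth(30, 5)


def test_null_band_input_validation():
    with pytest.raises(ValueError):
        q.null_band([10], [10], bulk_size=17, reps=10)
    with pytest.raises(ValueError):
        q.null_band([10], [10], bulk_size=17, level=0)


# --- QTL calling -----------------------------------------------------------


def _profile(means, lo=-0.3, hi=0.3, start0=1, window=1000, step=1000, chrom="chr1"):
    starts = start0 + step * np.arange(len(means))
    return pd.DataFrame(
        {"chrom": chrom, "start": starts, "end": starts + window,
         "n_sites": 5, "mean_delta": means, "band_lo": lo, "band_hi": hi}
    )


def test_profile_inside_band_yields_no_qtls():
    prof = _profile(np.linspace(-0.25, 0.25, 100))
    assert len(q.call_qtls(prof, min_run=10)) == 0


def test_long_exceedance_run_yields_single_interval():
    prof = _profile([0.9] * 2000)
    qtls = q.call_qtls(prof, min_run=10)
    assert len(qtls) == 1
    row = qtls.iloc[0]
    assert row.sign == 1 and row.n_windows == 2000
    assert row.start == 1 and row.end == 2000 * 1000


def test_short_runs_suppressed_and_gaps_merged():
    means = np.zeros(100)
    means[10:15] = 0.9  # 5 windows < min_run: suppressed
    prof = _profile(means)
    assert len(q.call_qtls(prof, min_run=10)) == 0

    means = np.full(60, 0.9)
    means[20:25] = np.nan  # short missing gap: merged through
    prof = _profile(means)
    qtls = q.call_qtls(prof, min_run=10)
    assert len(qtls) == 1 and qtls.iloc[0].n_windows == 55

    means = np.full(60, 0.9)
    means[30] = 0.0  # a window back inside the band splits the run
    prof = _profile(means)
    assert len(q.call_qtls(prof, min_run=10)) == 2


def test_pool_swap_negates_deltas_and_mirrors_calls(small_cross):
    cfg, pop, e_idx, l_idx, sites = small_cross
    idx = compute_indices(polarize_sites(sites)[0])
    swapped = sites.rename(
        columns={"e_ref": "l_ref", "e_alt": "l_alt", "l_ref": "e_ref", "l_alt": "e_alt"}
    )
    idx_sw = compute_indices(polarize_sites(swapped)[0])
    np.testing.assert_allclose(idx_sw["delta"], -idx["delta"])

    prof = _profile(np.full(40, 0.9))
    mirrored = prof.assign(
        mean_delta=-prof["mean_delta"],
        band_lo=-prof["band_hi"],
        band_hi=-prof["band_lo"],
    )
    a, b = q.call_qtls(prof), q.call_qtls(mirrored)
    assert a["start"].tolist() == b["start"].tolist()
    assert a["end"].tolist() == b["end"].tolist()
    assert (a["sign"].to_numpy() == -b["sign"].to_numpy()).all()


def test_effect_size_monotonically_raises_peak_delta():
    """Averaged over seeds, a bigger phenotype shift never shrinks the
    maximum window |Δ|."""
    peaks = []
    for effect in (0.0, 8.0, 25.0):
        vals = []
        for seed in range(3):
            cfg = q.CrossConfig(
                n_individuals=150, bulk_size=20, n_sites=300,
                chrom_length_bp=4_000_000, causal_pos_bp=2_000_000,
                effect_days=effect, noise_sd=3.0, seed=seed,
            )
            pop = q.simulate_f2(cfg)
            e, l = q.make_bulks(pop, cfg.bulk_size)
            idx = compute_indices(polarize_sites(q.sample_depths(pop, e, l))[0])
            prof = q.window_scan(idx, window_bp=1_000_000, step_bp=100_000)
            vals.append(np.nanmax(np.abs(prof["mean_delta"])))
        peaks.append(np.mean(vals))
    assert peaks[0] <= peaks[1] <= peaks[2]


def test_scan_profile_bands_bracket_zero(small_cross):
    cfg, pop, e_idx, l_idx, sites = small_cross
    idx, prof, rejected = q.scan(
        sites, bulk_size=cfg.bulk_size, window_bp=500_000, step_bp=100_000,
        reps=300, seed=4, chrom_lengths={cfg.chrom: cfg.chrom_length_bp},
    )
    ok = prof.dropna(subset=["band_lo", "band_hi"])
    assert len(ok) > 0
    assert (ok["band_lo"] <= 0).all() and (ok["band_hi"] >= 0).all()
    assert (idx["delta"].dropna().abs() <= 1).all()
    # windowed means stay within the member-site delta range
    for row in ok.itertuples(index=False):
        member = idx[(idx["pos"] >= row.start) & (idx["pos"] < row.end)]["delta"].dropna()
        if len(member) and np.isfinite(row.mean_delta):
            assert member.min() - 1e-12 <= row.mean_delta <= member.max() + 1e-12
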