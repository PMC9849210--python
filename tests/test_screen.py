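"""Regression screen, smoothness, cluster thresholding, group statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage, stats

from assrconn.errors import ConfigurationError, DegenerateDataError
from assrconn.screen import (
    build_screen_design,
    chi_square_2x2,
    cluster_threshold,
    compare_correlations,
    compare_groups_t,
    estimate_smoothness,
    fdr_bh,
    kernel_sigma_from_fwhm,
    select_candidates,
    t_from_summary,
    voxelwise_lm,
)
from assrconn.synth import MediationSimConfig, generate_cohort


def _toy_table(n=40, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "group": np.where(np.arange(n) < n // 2, "SZ", "HC"),
            "assr": rng.normal(80, 12, n),
            "age": rng.uniform(20, 60, n),
        }
    )


# ------------------------------------------------------------- voxel-wise LM


def test_noiseless_design_recovered_exactly():
    table = _toy_table(30)
    x, names = build_screen_design(table)
    beta_true = np.array([1.0, 0.05, -0.4, 0.02, -0.01])
    shape = (4, 4, 3)
    y = (x @ beta_true)[:, None].repeat(np.prod(shape), axis=1)
    maps = voxelwise_lm(y.reshape(30, *shape), table)
    np.testing.assert_allclose(
        maps.coefficients,
        np.broadcast_to(beta_true.reshape(-1, 1, 1, 1), maps.coefficients.shape),
        atol=1e-8,
    )


def test_f_matches_bruteforce_nested_rss(rng):
    """Explicit reduced-vs-full residual-sum-of-squares oracle, 3x3x3."""
    table = _toy_table(25, seed=3)
    x, names = build_screen_design(table)
    y = rng.standard_normal((25, 27))
    maps = voxelwise_lm(y.reshape(25, 3, 3, 3), table)
    n, p = x.shape
    for term, fmap in (("assr", maps.f_assr), ("assr_x_group", maps.f_interaction)):
        j = names.index(term)
        xr = np.delete(x, j, axis=1)
        for v in range(27):
            rf = y[:, v] - x @ np.linalg.lstsq(x, y[:, v], rcond=None)[0]
            rr = y[:, v] - xr @ np.linalg.lstsq(xr, y[:, v], rcond=None)[0]
            f_oracle = ((rr @ rr) - (rf @ rf)) / ((rf @ rf) / (n - p))
            assert np.isclose(fmap.reshape(-1)[v], f_oracle, atol=1e-8)


def test_null_maps_type_one_rate(rng):
    table = _toy_table(40, seed=5)
    y = rng.standard_normal((40, 24, 24, 16))
    maps = voxelwise_lm(y, table)
    p = stats.f.sf(maps.f_assr, maps.df_num, maps.df_den)
    frac = (p < 0.001).mean()
    # 9216 independent voxels: expect ~9 exceedances, Poisson-ish spread
    assert frac < 0.003


def test_design_validation():
    table = _toy_table(4)  # n <= parameters
    with pytest.raises(Exception):
        voxelwise_lm(np.zeros((4, 2, 2, 2)), table)
    bad = _toy_table(20)
    bad.loc[3, "assr"] = np.nan
    with pytest.raises(Exception):
        build_screen_design(bad)


# --------------------------------------------------------------- smoothness


def test_white_noise_fwhm_is_voxel_size(rng):
    maps = rng.standard_normal((8, 24, 24, 16))
    est = estimate_smoothness(maps, 4.0)
    assert abs(est - 4.0) < 0.5


def test_known_smoothing_recovered_within_15pct(rng):
    for kernel_fwhm in (4.0, 8.0):
        sigma = kernel_fwhm / (np.sqrt(8 * np.log(2)) * 4.0)
        maps = np.stack(
            [
                ndimage.gaussian_filter(rng.standard_normal((24, 24, 16)), sigma)
                for _ in range(8)
            ]
        )
        est = estimate_smoothness(maps, 4.0)
        effective = np.sqrt(kernel_fwhm**2 + 4.0**2)
        assert abs(est / effective - 1) < 0.15


def test_constant_map_degenerate():
    with pytest.raises(DegenerateDataError):
        estimate_smoothness(np.ones((2, 8, 8, 8)), 4.0)


def test_kernel_sigma_round_trip():
    for f in (4.0, 5.66, 9.0):
        s = kernel_sigma_from_fwhm(f, 4.0)
        back = 4.0 * np.sqrt(8 * np.log(2) * s**2 + 1)
        assert np.isclose(back, max(f, 4.0), rtol=1e-6)


# ------------------------------------------------------- cluster thresholding


def test_subthreshold_map_empty_table(rng):
    stat = np.full((10, 10, 8), 0.5)  # p >> 0.001 everywhere
    res = cluster_threshold(
        stat, df=(1, 100), fwhm_mm=6.0, voxel_mm=4.0, n_null=150, seed=0
    )
    assert res.table.empty


def test_flagged_clusters_respect_extent(rng):
    """Planted strong blob is found, flagged, and obeys the invariant."""
    table = _toy_table(60, seed=8)
    x, _ = build_screen_design(table)
    shape = (20, 20, 12)
    blob = np.zeros(shape, dtype=bool)
    blob[8:12, 8:12, 4:8] = True
    y = 0.3 * rng.standard_normal((60,) + shape)
    y[:, blob] += 0.05 * x[:, 1][:, None]  # ASSR effect inside the blob
    maps = voxelwise_lm(y, table)
    res = cluster_threshold(
        maps.f_assr,
        df=(maps.df_num, maps.df_den),
        fwhm_mm=4.0,
        voxel_mm=4.0,
        n_null=200,
        seed=1,
    )
    sig = res.table[res.table.significant]
    assert len(sig) >= 1
    assert (sig["size"] >= res.extent_threshold).all()
    assert sig["size"].max() >= 0.9 * blob.sum()


def test_strict_mode_rejects_tiny_null():
    with pytest.raises(ConfigurationError):
        cluster_threshold(
            np.zeros((5, 5, 5)), df=(1, 50), fwhm_mm=4, voxel_mm=4, n_null=50
        )


# --------------------------------------------------------------- candidates


def _circuit_table(rule, n_per=60, seed=0):
    rng = np.random.default_rng(seed)
    n = 2 * n_per
    group = np.where(np.arange(n) < n_per, "SZ", "HC")
    assr = rng.normal(80, 12, n)
    age = rng.uniform(20, 60, n)
    sz = group == "SZ"
    if rule == "rule2":  # equal positive slopes, lower SZ mean
        circuit = 0.01 * (assr - 80) + np.where(sz, 0.2, 0.45)
    else:  # opposite-sign slopes, equal means
        slope = np.where(sz, 0.012, -0.012)
        circuit = slope * (assr - 80) + 0.3
    circuit += rng.normal(0, 0.05, n)
    return pd.DataFrame(
        {"group": group, "assr": assr, "age": age, "c1": circuit}
    )


def test_rule2_selection():
    df = select_candidates(_circuit_table("rule2", seed=4), ["c1"])
    row = df.iloc[0]
    assert row.rule2 and row.selected
    assert row.r_hc > 0 and row.r_sz > 0 and row.group_diff_t > 0


def test_rule1_selection_only():
    df = select_candidates(_circuit_table("rule1", seed=4), ["c1"])
    row = df.iloc[0]
    assert row.rule1 and not row.rule2


def test_null_candidate_rate_near_alpha():
    hits, total = 0, 0
    for seed in range(30):
        cfg = MediationSimConfig(
            a_j=0.0, c_prime=0.0, kappa_j=0.0, seed=seed
        )
        t = generate_cohort(cfg)
        # break the mediator->outcome link: permute assr within the table
        t["assr"] = np.random.default_rng(seed).permutation(t["assr"].to_numpy())
        df = select_candidates(t, list(cfg.mediator_names))
        hits += int(df.selected.sum())
        total += len(df)
    assert hits / total < 0.12


# ----------------------------------------------------------- plain statistics


def test_table1_age_and_education_t():
    t_age = t_from_summary(33.92, 12.80, 66, 35.58, 13.98, 85)
    assert abs(abs(t_age.statistic) - 0.75) < 0.02
    t_edu = t_from_summary(12.97, 2.49, 66, 14.25, 2.48, 85)
    assert abs(abs(t_edu.statistic) - 3.13) < 0.02


def test_t_identical_groups_zero():
    assert np.isclose(t_from_summary(5, 1, 10, 5, 1, 12).statistic, 0.0)
    vals = np.r_[np.arange(6.0), np.arange(6.0)]
    groups = np.r_[np.zeros(6), np.ones(6)]
    assert np.isclose(compare_groups_t(vals, groups).statistic, 0.0)


def test_compare_groups_matches_closed_form_toy():
    a, b = np.array([1.0, 2.0, 3.0]), np.array([2.0, 4.0, 6.0])
    sp2 = (a.var(ddof=1) * 2 + b.var(ddof=1) * 2) / 4
    t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
    got = compare_groups_t(np.r_[a, b], np.r_[["x"] * 3, ["y"] * 3])
    assert np.isclose(got.statistic, t_hand)


def test_summary_t_agrees_with_sample_t(rng):
    a, b = rng.normal(0, 1, 30), rng.normal(0.4, 1.2, 40)
    full = compare_groups_t(np.r_[a, b], np.r_[["a"] * 30, ["b"] * 40])
    summ = t_from_summary(
        a.mean(), a.std(ddof=1), 30, b.mean(), b.std(ddof=1), 40
    )
    assert np.isclose(full.statistic, summ.statistic, rtol=1e-10)


def test_chi_square_table1_rows():
    chi_sex, _ = chi_square_2x2(44, 22, 51, 34)
    assert abs(chi_sex - 0.71) < 0.01
    chi_smoke, _ = chi_square_2x2(23, 43, 21, 64)
    assert abs(chi_smoke - 1.85) < 0.01
    chi_prop, _ = chi_square_2x2(10, 20, 30, 60)
    assert np.isclose(chi_prop, 0.0, atol=1e-12)


def test_compare_correlations_examples():
    assert np.isclose(compare_correlations(0.5, 85, 0.0, 66)[0], 3.28, atol=0.01)
    z, p = compare_correlations(-0.23, 85, 0.21, 66)
    assert np.isclose(abs(z), 2.67, atol=0.01)
    assert compare_correlations(0.4, 50, 0.4, 60)[0] == 0.0


# ------------------------------------------------------------------------ FDR


def _fdr_oracle(pvals, q):
    """Definition-based step-up: largest k with p_(k) <= q*k/m."""
    p = np.asarray(pvals, dtype=float)
    order = np.argsort(p)
    m = len(p)
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= q * k / m:
            k_star = k
    out = np.zeros(m, dtype=bool)
    out[order[:k_star]] = True
    return out


def test_fdr_examples():
    assert not fdr_bh(np.ones(5)).any()
    flags = fdr_bh([0.001, 0.01, 0.02, 0.9], q=0.05)
    np.testing.assert_array_equal(flags, [True, True, True, False])


@given(
    st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=6),
    st.sampled_from([0.01, 0.05, 0.1, 0.25]),
)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_fdr_matches_definition_oracle(pvals, q):
    np.testing.assert_array_equal(fdr_bh(pvals, q), _fdr_oracle(pvals, q))


@given(
    st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=8),
)
@settings(max_examples=100, deadline=None, derandomize=True)
def test_fdr_monotone_in_q(pvals):
    lo = fdr_bh(pvals, q=0.02)
    hi = fdr_bh(pvals, q=0.10)
    assert np.all(hi[lo])  # rejections grow with q
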