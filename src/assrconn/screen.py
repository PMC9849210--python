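"""Voxel-wise regression screen, cluster-extent correction, candidate
circuits, and group-comparison statistics.

The screen regresses per-subject Fisher-z connectivity maps on normalized
ASSR power, diagnostic group, their interaction, and age; voxel-wise F
maps for the ASSR main effect and the interaction are thresholded at a
height of p < 0.001 and corrected to a family-wise p < 0.05 by a Monte
Carlo cluster-extent simulation on smoothness-matched Gaussian null
fields.  Candidate circuits are then selected either by a significant
interaction or by same-sign within-group ASSR associations combined with
an FDR-corrected group difference in circuit strength.  The module also
carries the plain two-sample statistics (t from samples or from printed
summaries, a 2x2 chi-square without continuity correction, the Fisher-z
comparison of two correlations, and Benjamini-Hochberg FDR).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.optimize import brentq
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, DegenerateDataError, DesignError
from .rsfc import ConnectivityMap

__all__ = [
    "StatMaps",
    "ClusterResult",
    "build_screen_design",
    "voxelwise_lm",
    "estimate_smoothness",
    "kernel_sigma_from_fwhm",
    "simulate_null_max_cluster",
    "cluster_threshold",
    "select_candidates",
    "compare_groups_t",
    "t_from_summary",
    "chi_square_2x2",
    "compare_correlations",
    "fdr_bh",
]

_SQRT_8LN2 = float(np.sqrt(8.0 * np.log(2.0)))


@dataclass
class StatMaps:
    """Voxel-wise F maps and residuals from the screen regression."""

    f_assr: np.ndarray
    f_interaction: np.ndarray
    residuals: np.ndarray  # (n_subjects, x, y, z)
    df_num: int
    df_den: int
    coefficients: np.ndarray  # (p, x, y, z)
    term_names: list[str]

    def __post_init__(self) -> None:
        if np.any(self.f_assr < -1e-9) or np.any(self.f_interaction < -1e-9):
            raise ConfigurationError("F maps must be non-negative")


@dataclass
class ClusterResult:
    """Cluster table plus the Monte Carlo extent threshold that produced it."""

    table: pd.DataFrame
    extent_threshold: int
    null_max_sizes: np.ndarray
    height_p: float
    alpha: float


def build_screen_design(
    table: pd.DataFrame,
    assr_col: str = "assr",
    group_col: str = "group",
    age_col: str = "age",
    sz_label: str = "SZ",
) -> tuple[np.ndarray, list[str]]:
    """Design [intercept, ASSR, Group, ASSR x Group, age].

    Group is coded SZ = 1, HC = 0 and ASSR is mean-centered before forming
    the interaction, so the ASSR main effect is interpretable at the
    average group composition.
    """
    for col in (assr_col, group_col, age_col):
        if table[col].isna().any():
            raise DesignError(f"missing values in modeled column '{col}'")
    assr = table[assr_col].to_numpy(float)
    assr_c = assr - assr.mean()
    g = table[group_col]
    group = (
        (g == sz_label).to_numpy(float)
        if g.dtype == object or isinstance(g.dtype, pd.CategoricalDtype)
        else g.to_numpy(float)
    )
    age = table[age_col].to_numpy(float)
    x = np.column_stack([np.ones(len(table)), assr_c, group, assr_c * group, age])
    names = ["intercept", "assr", "group", "assr_x_group", "age"]
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise DesignError("screen design is rank deficient")
    return x, names


def _stack_zmaps(zmaps) -> np.ndarray:
    if isinstance(zmaps, np.ndarray):
        return zmaps
    arrs = []
    for m in zmaps:
        if isinstance(m, ConnectivityMap):
            if m.kind != "z":
                raise ConfigurationError("screen expects Fisher-z maps")
            arrs.append(m.values)
        else:
            arrs.append(np.asarray(m, dtype=float))
    return np.stack(arrs)


def voxelwise_lm(
    zmaps,
    table: pd.DataFrame,
    assr_col: str = "assr",
    group_col: str = "group",
    age_col: str = "age",
) -> StatMaps:
    """Voxel-wise OLS of z maps on [1, ASSR, Group, ASSR x Group, age].

    F statistics for the ASSR main effect and the interaction are computed
    from nested-model residual sums of squares (the single-coefficient F,
    equal to the squared t).  Residual maps are returned for smoothness
    estimation.
    """
    y4 = _stack_zmaps(zmaps)
    if y4.shape[0] != len(table):
        raise ConfigurationError("one z map per subject required")
    x, names = build_screen_design(table, assr_col, group_col, age_col)
    n, p = x.shape
    if n <= p:
        raise DesignError(f"n={n} subjects cannot identify {p} parameters")
    shape3d = y4.shape[1:]
    y = y4.reshape(n, -1)

    pinv = np.linalg.pinv(x)
    beta = pinv @ y
    resid = y - x @ beta
    rss_full = (resid**2).sum(axis=0)
    df_den = n - p

    def partial_f(drop: int) -> np.ndarray:
        xr = np.delete(x, drop, axis=1)
        br = np.linalg.pinv(xr) @ y
        rss_red = ((y - xr @ br) ** 2).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (rss_red - rss_full) / (rss_full / df_den)
        f[~np.isfinite(f)] = 0.0
        return np.maximum(f, 0.0)

    f_assr = partial_f(names.index("assr")).reshape(shape3d)
    f_inter = partial_f(names.index("assr_x_group")).reshape(shape3d)
    return StatMaps(
        f_assr=f_assr,
        f_interaction=f_inter,
        residuals=resid.reshape((n,) + shape3d),
        df_num=1,
        df_den=df_den,
        coefficients=beta.reshape((p,) + shape3d),
        term_names=names,
    )


def kernel_sigma_from_fwhm(fwhm_mm: float, voxel_mm: float) -> float:
    """Gaussian kernel sigma (in voxels) whose sampled smoothed field has
    the given Gaussian-equivalent FWHM (mm), inverting the one-voxel
    sampling contribution: ``fwhm**2 = (2.355 * sigma * voxel)**2 + voxel**2``.
    """
    ratio2 = (fwhm_mm / voxel_mm) ** 2 - 1.0
    if ratio2 <= 0:
        return 0.0
    return float(np.sqrt(ratio2) / _SQRT_8LN2)


def _rho1_discrete(sigma: float) -> float:
    """Lag-1 autocorrelation of white noise smoothed by the sampled
    Gaussian kernel with the given sigma (voxels)."""
    if sigma <= 0:
        return 0.0
    radius = int(np.ceil(4 * sigma)) + 1
    k = np.exp(-0.5 * (np.arange(-radius, radius + 1) / sigma) ** 2)
    return float((k[:-1] * k[1:]).sum() / (k * k).sum())


def _sigma_from_rho1(rho1: float) -> float:
    if rho1 <= 0:
        return 0.0
    hi = 0.05
    while _rho1_discrete(hi) < rho1 and hi < 64:
        hi *= 2
    if hi >= 64:
        return 64.0
    return float(brentq(lambda s: _rho1_discrete(s) - rho1, 1e-6, hi, xtol=1e-8))


def estimate_smoothness(residuals: np.ndarray, voxel_mm: float) -> float:
    """Gaussian-equivalent spatial FWHM (mm) of residual maps.

    For each map and axis the variance of spatial first differences of the
    standardized residuals gives the lag-1 autocorrelation
    ``rho1 = 1 - var_diff / 2``; the smoothing-kernel sigma is recovered by
    inverting the sampled-kernel autocorrelation, and the reported FWHM
    includes the one-voxel sampling contribution, so unsmoothed white noise
    reports a FWHM of one voxel.  Estimates are averaged over maps (via
    rho1) and axes (via FWHM).
    """
    r = np.asarray(residuals, dtype=float)
    if r.ndim == 3:
        r = r[None]
    if r.ndim != 4:
        raise ConfigurationError("residuals must be one or more 3-D maps")
    n_axes = 3
    fwhms = []
    for axis in range(1, n_axes + 1):
        rho1s = []
        for m in r:
            sd = m.std()
            if sd == 0:
                raise DegenerateDataError("constant residual map")
            z = (m - m.mean()) / sd
            var_diff = float(np.mean(np.diff(z, axis=axis - 1) ** 2))
            rho1s.append(1.0 - var_diff / 2.0)
        sigma = _sigma_from_rho1(float(np.mean(rho1s)))
        fwhms.append(voxel_mm * np.sqrt((_SQRT_8LN2 * sigma) ** 2 + 1.0))
    return float(np.mean(fwhms))


def _null_field(
    rng: np.random.Generator, shape: tuple[int, int, int], sigma_vox: float
) -> np.ndarray:
    field = rng.standard_normal(shape)
    if sigma_vox > 0:
        field = ndimage.gaussian_filter(field, sigma_vox)
        field /= field.std()
    return field


def simulate_null_max_cluster(
    shape: tuple[int, int, int],
    mask: np.ndarray | None,
    fwhm_mm: float,
    voxel_mm: float,
    p_height: float,
    n_null: int,
    rng: np.random.Generator,
    tail: str = "two",
) -> np.ndarray:
    """Maximum suprathreshold cluster size (6-connectivity) in each of
    ``n_null`` smoothness-matched Gaussian null fields."""
    sigma = kernel_sigma_from_fwhm(fwhm_mm, voxel_mm)
    if tail == "two":
        zcrit = stats.norm.isf(p_height / 2.0)
    elif tail == "upper":
        zcrit = stats.norm.isf(p_height)
    else:
        raise ConfigurationError("tail must be 'two' or 'upper'")
    maxima = np.empty(n_null, dtype=int)
    for i in range(n_null):
        field = _null_field(rng, shape, sigma)
        best = 0
        exceed = (np.abs(field) > zcrit) if tail == "two" else (field > zcrit)
        if mask is not None:
            exceed &= mask
        if tail == "two":
            # positive and negative exceedances form separate clusters
            for signed in (exceed & (field > 0), exceed & (field < 0)):
                labels, nlab = ndimage.label(signed)
                if nlab:
                    best = max(best, int(np.bincount(labels.ravel())[1:].max()))
        else:
            labels, nlab = ndimage.label(exceed)
            if nlab:
                best = int(np.bincount(labels.ravel())[1:].max())
        maxima[i] = best
    return maxima


def cluster_threshold(
    statmap: np.ndarray,
    mask: np.ndarray | None = None,
    df: tuple[int, int] | None = None,
    fwhm_mm: float = 4.0,
    voxel_mm: float = 4.0,
    p_height: float = 0.001,
    alpha: float = 0.05,
    n_null: int = 1000,
    seed: int | None = None,
    tail: str = "two",
    affine: np.ndarray | None = None,
    null_max_sizes: np.ndarray | None = None,
    strict: bool = True,
    dither: bool = True,
) -> ClusterResult:
    """Cluster-extent thresholding of an F map by Monte Carlo simulation.

    Suprathreshold voxels (F with p < ``p_height`` at ``df``) are grouped
    by face adjacency (6-connectivity).  The extent threshold is the
    smallest cluster size whose probability of being reached by the
    maximum null cluster is at most ``alpha``, estimated from ``n_null``
    Gaussian fields smoothed to ``fwhm_mm``.  Because sizes are integers
    that rule alone is conservative; with ``dither`` (default) the
    threshold is randomized between the two integers bracketing ``alpha``
    so the procedure is calibrated in expectation (set ``dither=False``
    for the strictly conservative integer threshold).  Null fields are
    thresholded two-sided by default, matching an F with one numerator
    degree of freedom (a squared t).  A precomputed null distribution can
    be passed to amortize simulations across maps of equal smoothness.
    """
    statmap = np.asarray(statmap, dtype=float)
    if df is None:
        raise ConfigurationError("df=(df_num, df_den) is required for an F map")
    rng = np.random.default_rng(seed)
    if null_max_sizes is None:
        if n_null < 100 and strict:
            raise ConfigurationError(
                "n_null < 100 gives an unreliable extent threshold (strict mode)"
            )
        null_max_sizes = simulate_null_max_cluster(
            statmap.shape, mask, fwhm_mm, voxel_mm, p_height, n_null, rng, tail
        )
    null_max_sizes = np.asarray(null_max_sizes)
    # smallest s with P(max null cluster >= s) <= alpha; because cluster
    # sizes are integers this is conservative, so by default the threshold
    # is dithered between the two bracketing integers with the mixing
    # probability that makes the expected family-wise rate exactly alpha
    candidates = np.arange(1, null_max_sizes.max() + 2)
    exceed_p = (null_max_sizes[None, :] >= candidates[:, None]).mean(axis=1)
    j = int(np.argmax(exceed_p <= alpha))
    extent = int(candidates[j])
    if dither and j > 0:
        p_lo, p_hi = exceed_p[j], exceed_p[j - 1]
        gamma = (alpha - p_lo) / (p_hi - p_lo) if p_hi > p_lo else 0.0
        if rng.random() < gamma:
            extent -= 1

    pmap = stats.f.sf(statmap, df[0], df[1])
    supra = pmap < p_height
    if mask is not None:
        supra &= np.asarray(mask, dtype=bool)
    labels, nlab = ndimage.label(supra)
    rows = []
    for lab in range(1, nlab + 1):
        voxels = labels == lab
        size = int(voxels.sum())
        flat = np.where(voxels, statmap, -np.inf)
        peak_idx = np.unravel_index(np.argmax(flat), statmap.shape)
        if affine is not None:
            peak = tuple(
                float(v) for v in (affine @ np.array([*peak_idx, 1.0]))[:3]
            )
        else:
            peak = tuple(int(v) for v in peak_idx)
        rows.append(
            {
                "cluster_id": lab,
                "peak_x": peak[0],
                "peak_y": peak[1],
                "peak_z": peak[2],
                "size": size,
                "peak_f": float(statmap[peak_idx]),
                "significant": size >= extent,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "cluster_id",
            "peak_x",
            "peak_y",
            "peak_z",
            "size",
            "peak_f",
            "significant",
        ],
    ).sort_values("size", ascending=False, ignore_index=True)
    return ClusterResult(table, extent, null_max_sizes, p_height, alpha)


def select_candidates(
    table: pd.DataFrame,
    circuit_cols: list[str],
    assr_col: str = "assr",
    group_col: str = "group",
    age_col: str = "age",
    sz_label: str = "SZ",
    alpha: float = 0.05,
    q: float = 0.05,
) -> pd.DataFrame:
    """Select candidate circuits for the ASSR deficit.

    Rule 1: a significant ASSR x Group interaction in the regression of the
    circuit value on [ASSR, Group, ASSR x Group, age].
    Rule 2: a significant same-sign ASSR association within both groups
    plus a group difference in circuit strength that survives
    Benjamini-Hochberg FDR over the circuit family and points the
    deficit way (weaker in patients for positive associations, stronger
    for negative ones).
    """
    is_sz = (table[group_col] == sz_label).to_numpy()
    out = []
    x_design, names = build_screen_design(table, assr_col, group_col, age_col)
    j_inter = names.index("assr_x_group")
    n, p = x_design.shape
    xtx_inv = np.linalg.inv(x_design.T @ x_design)
    for col in circuit_cols:
        y = table[col].to_numpy(float)
        beta, *_ = np.linalg.lstsq(x_design, y, rcond=None)
        resid = y - x_design @ beta
        s2 = (resid**2).sum() / (n - p)
        se = np.sqrt(s2 * xtx_inv[j_inter, j_inter])
        t_inter = beta[j_inter] / se
        p_inter = 2 * stats.t.sf(abs(t_inter), n - p)

        assr = table[assr_col].to_numpy(float)
        r_sz, p_sz = stats.pearsonr(assr[is_sz], y[is_sz])
        r_hc, p_hc = stats.pearsonr(assr[~is_sz], y[~is_sz])
        tt = stats.ttest_ind(y[~is_sz], y[is_sz], equal_var=True)  # HC - SZ
        out.append(
            {
                "circuit": col,
                "r_hc": r_hc,
                "p_hc": p_hc,
                "r_sz": r_sz,
                "p_sz": p_sz,
                "interaction_t": float(t_inter),
                "interaction_p": float(p_inter),
                "group_diff_t": float(tt.statistic),
                "group_diff_p": float(tt.pvalue),
            }
        )
    df = pd.DataFrame(out)
    df["group_diff_rejected"] = fdr_bh(df["group_diff_p"].to_numpy(), q=q)
    same_sign = (np.sign(df["r_hc"]) == np.sign(df["r_sz"])) & (df["r_hc"] != 0)
    both_sig = (df["p_hc"] < alpha) & (df["p_sz"] < alpha)
    deficit_direction = np.sign(df["group_diff_t"]) == np.sign(df["r_hc"])
    df["rule1"] = df["interaction_p"] < alpha
    df["rule2"] = same_sign & both_sig & df["group_diff_rejected"] & deficit_direction
    df["selected"] = df["rule1"] | df["rule2"]
    return df


def compare_groups_t(values, groups, pooled: bool = True):
    """Independent-samples t-test between the two labeled groups.

    Returns the scipy result object (statistic, pvalue, df).  ``pooled``
    selects the classic equal-variance t; otherwise Welch.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ConfigurationError("exactly two groups required")
    a, b = values[groups == labels[0]], values[groups == labels[1]]
    return stats.ttest_ind(a, b, equal_var=pooled)


def t_from_summary(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int, pooled: bool = True
):
    """Two-sample t from printed group means, SDs, and sizes."""
    return stats.ttest_ind_from_stats(
        m1, s1, n1, m2, s2, n2, equal_var=pooled
    )


def chi_square_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square for a 2x2 table, no continuity correction."""
    res = stats.chi2_contingency([[a, b], [c, d]], correction=False)
    return float(res.statistic), float(res.pvalue)


def compare_correlations(
    r1: float, n1: int, r2: float, n2: int
) -> tuple[float, float]:
    """Fisher-z test for the equality of two independent correlations:
    ``z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3))``.
    """
    if min(n1, n2) <= 3:
        raise ConfigurationError("need more than 3 observations per correlation")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    return float(z), float(2 * stats.norm.sf(abs(z)))


def fdr_bh(pvalues, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at FDR level ``q``."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ConfigurationError("p-values must lie in [0, 1]")
    return multipletests(p, alpha=q, method="fdr_bh")[0]
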