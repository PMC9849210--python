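"""Parallel multiple-mediator mediation with percentile bootstrap CIs.

Decomposes the diagnosis effect on the 40 Hz ASSR into a direct path and
indirect paths through circuit rsFC mediators, adjusting for age:

    c   : coefficient of X in      Y ~ X + covariates          (total)
    a_j : coefficient of X in      M_j ~ X + covariates
    b_j, c' : coefficients in      Y ~ X + M_1..M_k + covariates
    indirect_j = a_j * b_j,  indirect_total = sum_j indirect_j

With identical covariate sets in all three models the OLS decomposition
identity ``c = c' + indirect_total`` holds exactly.  Confidence intervals
come from a subject-level nonparametric bootstrap (percentile by default);
the resample index block is drawn once up front, so results are
reproducible bit-for-bit given a seed and independent of execution order.
Group coding is SZ = 1, HC = 0, so a negative total effect matches the
"reduced ASSR in patients" direction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DesignError, InsufficientDataError

__all__ = ["MediationResult", "fit_mediation", "bootstrap_mediation",
           "single_mediator_models"]


@dataclass
class MediationResult:
    """Point estimates (and optionally bootstrap CIs) of a mediation fit."""

    c: float
    c_prime: float
    a: np.ndarray
    b: np.ndarray
    mediator_names: list[str]
    covariate_names: list[str]
    covariate_coef_total: np.ndarray
    covariate_coef_full: np.ndarray
    c_t: float
    c_p: float
    c_prime_t: float
    c_prime_p: float
    n: int
    B: int = 0
    level: float | None = None
    seed: int | None = None
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_degenerate_redrawn: int = 0

    @property
    def indirect(self) -> np.ndarray:
        return self.a * self.b

    @property
    def indirect_total(self) -> float:
        return float(self.indirect.sum())

    def ci_excludes_zero(self, key: str) -> bool:
        lo, hi = self.ci[key]
        return lo > 0 or hi < 0

    def summary(self) -> pd.DataFrame:
        rows = [
            {"quantity": "c", "estimate": self.c},
            {"quantity": "c_prime", "estimate": self.c_prime},
        ]
        for j, name in enumerate(self.mediator_names):
            rows.append({"quantity": f"a:{name}", "estimate": float(self.a[j])})
            rows.append({"quantity": f"b:{name}", "estimate": float(self.b[j])})
            rows.append(
                {"quantity": f"indirect:{name}", "estimate": float(self.indirect[j])}
            )
        rows.append({"quantity": "indirect_total", "estimate": self.indirect_total})
        df = pd.DataFrame(rows)
        if self.ci:
            df["ci_lower"] = [self.ci.get(q, (np.nan, np.nan))[0] for q in df.quantity]
            df["ci_upper"] = [self.ci.get(q, (np.nan, np.nan))[1] for q in df.quantity]
        return df


def _encode_x(table: pd.DataFrame, x: str, sz_label: str) -> np.ndarray:
    col = table[x]
    if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
        return (col == sz_label).to_numpy(float)
    return col.to_numpy(float)


def _extract_arrays(table, x, mediators, y, covariates, sz_label):
    cols = [x, y, *mediators, *covariates]
    if table[cols].isna().any().any():
        raise DesignError("missing values in modeled columns")
    xv = _encode_x(table, x, sz_label)
    m = table[list(mediators)].to_numpy(float)
    yv = table[y].to_numpy(float)
    cov = (
        table[list(covariates)].to_numpy(float)
        if covariates
        else np.empty((len(table), 0))
    )
    return xv, m, yv, cov


def _ols_with_t(xmat: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n, p = xmat.shape
    xtx = xmat.T @ xmat
    try:
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded upstream
        raise DesignError("singular design matrix") from exc
    beta = xtx_inv @ (xmat.T @ y)
    resid = y - xmat @ beta
    s2 = (resid**2).sum() / (n - p)
    se = np.sqrt(np.maximum(s2 * np.diag(xtx_inv), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = 2 * stats.t.sf(np.abs(t), n - p)
    return beta, t, pvals


def fit_mediation(
    table: pd.DataFrame,
    x: str = "group",
    mediators: list[str] | None = None,
    y: str = "assr",
    covariates: list[str] = ("age",),
    sz_label: str = "SZ",
    cond_tol: float = 1e8,
) -> MediationResult:
    """OLS point estimates of the parallel mediation model."""
    if not mediators:
        raise ConfigurationError("at least one mediator column is required")
    covariates = list(covariates)
    xv, m, yv, cov = _extract_arrays(table, x, mediators, y, covariates, sz_label)
    n, k = m.shape
    p_full = 2 + k + cov.shape[1]
    if n <= p_full + 2:
        raise InsufficientDataError(f"n={n} too small for {p_full} parameters")

    predictors = np.column_stack([xv, m, cov])
    sd = predictors.std(axis=0)
    if np.any(sd == 0):
        raise DesignError("constant predictor column")
    if np.linalg.cond((predictors - predictors.mean(0)) / sd) > cond_tol:
        raise DesignError("mediators are collinear beyond tolerance")

    ones = np.ones(n)
    x_total = np.column_stack([ones, xv, cov])
    x_full = np.column_stack([ones, xv, m, cov])
    x_med = np.column_stack([ones, xv, cov])

    beta_c, t_c, p_c = _ols_with_t(x_total, yv)
    beta_f, t_f, p_f = _ols_with_t(x_full, yv)
    a = np.linalg.lstsq(x_med, m, rcond=None)[0][1]  # (k,)

    return MediationResult(
        c=float(beta_c[1]),
        c_prime=float(beta_f[1]),
        a=a,
        b=beta_f[2 : 2 + k].copy(),
        mediator_names=list(mediators),
        covariate_names=covariates,
        covariate_coef_total=beta_c[2:].copy(),
        covariate_coef_full=beta_f[2 + k :].copy(),
        c_t=float(t_c[1]),
        c_p=float(p_c[1]),
        c_prime_t=float(t_f[1]),
        c_prime_p=float(p_f[1]),
        n=n,
    )


def _batched_ols(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Solve OLS for a batch of designs.

    ``x`` is (B, n, p); ``y`` is (B, n) or (B, n, q).  Returns (B, p) or
    (B, p, q).  Singular members fall back to the pseudo-inverse.
    """
    squeeze = y.ndim == 2
    if squeeze:
        y = y[..., None]
    xtx = np.einsum("bnp,bnq->bpq", x, x)
    xty = np.einsum("bnp,bnq->bpq", x, y)
    try:
        beta = np.linalg.solve(xtx, xty)
    except np.linalg.LinAlgError:
        beta = np.empty_like(xty)
        for i in range(x.shape[0]):
            beta[i] = np.linalg.lstsq(x[i], y[i], rcond=None)[0]
    return beta[..., 0] if squeeze else beta


_RANK_TOL = 1e-9


def _degenerate_resamples(
    idx: np.ndarray, xv: np.ndarray, m: np.ndarray, cov: np.ndarray
) -> np.ndarray:
    """Resamples that cannot identify the model: a single diagnostic group
    or a rank-deficient full design (too few distinct subjects)."""
    B, n = idx.shape
    bad = np.all(xv[idx] == xv[idx][:, :1], axis=1)
    ones = np.ones((B, n, 1))
    d_full = np.concatenate(
        [ones, xv[idx][..., None], m[idx], cov[idx]], axis=2
    )
    xtx = np.einsum("bnp,bnq->bpq", d_full, d_full)
    eig = np.linalg.eigvalsh(xtx)
    bad |= eig[:, 0] <= _RANK_TOL * eig[:, -1]
    return bad


def _resample_stats(
    idx: np.ndarray,
    xv: np.ndarray,
    m: np.ndarray,
    yv: np.ndarray,
    cov: np.ndarray,
) -> dict[str, np.ndarray]:
    """Mediation statistics for a block of resample index rows (B, n)."""
    B, n = idx.shape
    k = m.shape[1]
    ones = np.ones((B, n, 1))
    xb = xv[idx][..., None]
    mb = m[idx]
    cb = cov[idx]
    yb = yv[idx]

    d_total = np.concatenate([ones, xb, cb], axis=2)
    d_full = np.concatenate([ones, xb, mb, cb], axis=2)
    beta_c = _batched_ols(d_total, yb)
    beta_f = _batched_ols(d_full, yb)
    beta_a = _batched_ols(d_total, mb)  # (B, p, k)
    a = beta_a[:, 1, :]
    b = beta_f[:, 2 : 2 + k]
    return {
        "c": beta_c[:, 1],
        "c_prime": beta_f[:, 1],
        "a": a,
        "b": b,
        "indirect": a * b,
    }


def _enumerate_indices(n: int, chunk: int):
    """All n**n resample index tuples in chunks, mixed-radix order."""
    total = n**n
    shape = (n,) * n
    for start in range(0, total, chunk):
        stop = min(start + chunk, total)
        yield np.array(
            np.unravel_index(np.arange(start, stop), shape)
        ).T.astype(np.intp)


def bootstrap_mediation(
    table: pd.DataFrame,
    x: str = "group",
    mediators: list[str] | None = None,
    y: str = "assr",
    covariates: list[str] = ("age",),
    B: int = 10_000,
    level: float = 0.95,
    seed: int | None = None,
    sz_label: str = "SZ",
    stratified: bool = False,
    exhaustive: bool = False,
    max_redraw_rounds: int = 100,
    chunk: int = 65_536,
) -> MediationResult:
    """Percentile bootstrap confidence intervals for the mediation paths.

    Subjects are resampled with replacement ``B`` times (unstratified by
    default; ``stratified`` resamples within diagnostic groups).  Resamples
    that cannot identify the model — a single diagnostic group, or too few
    distinct subjects for a full-rank design — are redrawn, with a round
    cap and a count reported on the result.  With
    ``exhaustive=True`` (n <= 8) every one of the n**n equally likely
    resamples is evaluated instead, excluding the degenerate ones, giving
    the exact percentile endpoints of the resampling distribution.
    """
    if not 0 < level < 1:
        raise ConfigurationError("level must lie in (0, 1)")
    if B < 100 and not exhaustive:
        raise ConfigurationError("B must be at least 100")
    point = fit_mediation(table, x, mediators, y, covariates, sz_label)
    xv, m, yv, cov = _extract_arrays(table, x, mediators, y, covariates, sz_label)
    n = len(xv)
    rng = np.random.default_rng(seed)
    n_redrawn = 0

    if exhaustive:
        if n > 8:
            raise ConfigurationError("exhaustive enumeration limited to n <= 8")
        pieces: list[dict[str, np.ndarray]] = []
        for idx in _enumerate_indices(n, chunk):
            idx = idx[~_degenerate_resamples(idx, xv, m, cov)]
            if idx.size:
                pieces.append(_resample_stats(idx, xv, m, yv, cov))
        stats_block = {
            key: np.concatenate([p[key] for p in pieces], axis=0)
            for key in pieces[0]
        }
        eff_b = stats_block["c"].shape[0]
    else:
        if stratified:
            idx = np.empty((B, n), dtype=np.intp)
            for val in (1.0, 0.0):
                members = np.flatnonzero(xv == val)
                cols = np.flatnonzero(xv == val)
                idx[:, cols] = members[
                    rng.integers(0, members.size, (B, members.size))
                ]
        else:
            idx = rng.integers(0, n, (B, n)).astype(np.intp)
            for _ in range(max_redraw_rounds):
                bad = _degenerate_resamples(idx, xv, m, cov)
                if not bad.any():
                    break
                n_redrawn += int(bad.sum())
                idx[bad] = rng.integers(0, n, (int(bad.sum()), n))
            else:
                raise InsufficientDataError(
                    "could not draw non-degenerate resamples within the round cap"
                )
        stats_block = _resample_stats(idx, xv, m, yv, cov)
        eff_b = B

    qs = [(1 - level) / 2, (1 + level) / 2]
    ci: dict[str, tuple[float, float]] = {}

    def put(key: str, values: np.ndarray) -> None:
        lo, hi = np.quantile(values, qs)
        ci[key] = (float(lo), float(hi))

    put("c", stats_block["c"])
    put("c_prime", stats_block["c_prime"])
    for j, name in enumerate(point.mediator_names):
        put(f"a:{name}", stats_block["a"][:, j])
        put(f"b:{name}", stats_block["b"][:, j])
        put(f"indirect:{name}", stats_block["indirect"][:, j])
    put("indirect_total", stats_block["indirect"].sum(axis=1))

    point.B = eff_b
    point.level = level
    point.seed = seed
    point.ci = ci
    point.n_degenerate_redrawn = n_redrawn
    return point


def single_mediator_models(
    table: pd.DataFrame,
    mediators: list[str],
    x: str = "group",
    y: str = "assr",
    covariates: list[str] = ("age",),
    B: int = 10_000,
    level: float = 0.95,
    seed: int | None = None,
    sz_label: str = "SZ",
) -> list[MediationResult]:
    """One simple-mediation fit and bootstrap per mediator (same covariates).

    Seeds for the per-mediator bootstraps are spawned deterministically
    from ``seed``.
    """
    seeds = (
        np.random.SeedSequence(seed).generate_state(len(mediators)) % (2**31)
        if seed is not None
        else [None] * len(mediators)
    )
    return [
        bootstrap_mediation(
            table,
            x=x,
            mediators=[med],
            y=y,
            covariates=covariates,
            B=B,
            level=level,
            seed=int(s) if s is not None else None,
            sz_label=sz_label,
        )
        for med, s in zip(mediators, seeds)
    ]
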