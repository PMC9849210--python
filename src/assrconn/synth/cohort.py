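"""Synthetic cohort with a known mediation structure.

The cohort emulates a case-control study of the 40 Hz ASSR deficit: a
binary diagnosis indicator X (SZ = 1, HC = 0), age as a covariate, a set of
circuit rsFC mediators M_j (Fisher-z units), and normalized ASSR power Y as
the outcome, generated from a linear structural model

    M_j = alpha_j + a_j * X + kappa_j * Age + eps_j
    Y   = beta + c' * X + sum_j b_j * M_j + gamma * Age + eps_Y

The defaults encode the full-mediation scenario: the direct effect c' is
zero and the diagnosis deficit flows entirely through the mediators, with
three "top" circuits carrying most of the indirect effect and four weaker
ones.  The intercept beta is calibrated in closed form so the healthy-group
population mean of Y equals ``mu_assr_hc``, and the default paths sum to
(approximately) ``mu_assr_sz - mu_assr_hc``; the outcome noise is derived
from ``sd_assr`` so the within-group spread of Y matches the configured
value.  Ages are truncated normal per group on [18, 65].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from ..errors import ConfigurationError

__all__ = ["MediationSimConfig", "generate_cohort", "DEFAULT_CIRCUITS"]

# seven circuit mediators; the first three are the strong ("top") paths
DEFAULT_CIRCUITS = [
    "r_stg__l_mpfc",
    "l_mpfc__l_pog",
    "l_prg__r_pog",
    "l_stg__r_stg",
    "r_stg__l_prg",
    "l_prg__l_smg",
    "l_prg__l_ifg",
]

AGE_BOUNDS = (18.0, 65.0)


def _truncnorm_dist(mu: float, sd: float):
    lo, hi = AGE_BOUNDS
    return truncnorm((lo - mu) / sd, (hi - mu) / sd, loc=mu, scale=sd)


@dataclass
class MediationSimConfig:
    """Ground-truth parameters of the synthetic cohort."""

    n_sz: int = 66
    n_hc: int = 85
    mu_assr_sz: float = 76.23
    mu_assr_hc: float = 81.52
    sd_assr: float = 12.4
    n_mediators: int = 7
    mediator_names: list[str] | None = None
    alpha_m: np.ndarray | float = 0.35
    a_j: np.ndarray | None = None  # diagnosis -> mediator
    b_j: np.ndarray | None = None  # mediator -> outcome
    c_prime: float = 0.0  # direct diagnosis -> outcome
    kappa_j: np.ndarray | float = -0.002  # age -> mediator, per year
    gamma: float = -0.05  # age -> outcome, per year
    noise_sd_m: np.ndarray | float = 0.2
    age_mean_sz: float = 33.92
    age_sd_sz: float = 12.80
    age_mean_hc: float = 35.58
    age_sd_hc: float = 13.98
    male_frac_sz: float = 44.0 / 66.0
    male_frac_hc: float = 51.0 / 85.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_sz < 2 or self.n_hc < 2:
            raise ConfigurationError("need at least 2 subjects per group")
        k = self.n_mediators
        if k < 1:
            raise ConfigurationError("need at least one mediator")
        if self.mediator_names is None:
            self.mediator_names = (
                list(DEFAULT_CIRCUITS) if k == 7 else [f"m{j + 1}" for j in range(k)]
            )
        if len(self.mediator_names) != k:
            raise ConfigurationError("mediator_names length mismatch")
        if self.a_j is None:
            self.a_j = (
                np.array([-0.15] * 3 + [-0.04] * 4) if k == 7 else np.full(k, -0.1)
            )
        if self.b_j is None:
            self.b_j = np.array([10.0] * 3 + [5.0] * 4) if k == 7 else np.full(k, 5.0)
        self.a_j = np.broadcast_to(np.asarray(self.a_j, float), (k,)).copy()
        self.b_j = np.broadcast_to(np.asarray(self.b_j, float), (k,)).copy()
        self.alpha_m = np.broadcast_to(np.asarray(self.alpha_m, float), (k,)).copy()
        self.kappa_j = np.broadcast_to(np.asarray(self.kappa_j, float), (k,)).copy()
        self.noise_sd_m = np.broadcast_to(
            np.asarray(self.noise_sd_m, float), (k,)
        ).copy()
        if np.any(self.noise_sd_m <= 0):
            raise ConfigurationError("mediator noise sds must be positive")
        if self.sd_assr <= 0:
            raise ConfigurationError("sd_assr must be positive")
        for sd in (self.age_sd_sz, self.age_sd_hc):
            if sd <= 0:
                raise ConfigurationError("age sds must be positive")
        _ = self.noise_sd_y  # raises if sd_assr is inconsistent with the paths

    # -- closed-form structural quantities ---------------------------------

    def age_dist(self, group: str):
        if group == "SZ":
            return _truncnorm_dist(self.age_mean_sz, self.age_sd_sz)
        return _truncnorm_dist(self.age_mean_hc, self.age_sd_hc)

    @property
    def indirect_total(self) -> float:
        return float(self.a_j @ self.b_j)

    @property
    def noise_sd_y(self) -> float:
        """Outcome noise derived so the within-group SD of Y is sd_assr."""
        age_slope = self.gamma + float(self.b_j @ self.kappa_j)
        var_age = float(
            np.mean(
                [self.age_dist("SZ").var(), self.age_dist("HC").var()]
            )
        )
        explained = float(self.b_j**2 @ self.noise_sd_m**2) + age_slope**2 * var_age
        resid = self.sd_assr**2 - explained
        if resid <= 0:
            raise ConfigurationError(
                "sd_assr too small for the configured mediator/age contributions"
            )
        return float(np.sqrt(resid))

    @property
    def intercept(self) -> float:
        """beta calibrated so E[Y | HC] == mu_assr_hc."""
        mu_age = self.age_dist("HC").mean()
        return float(
            self.mu_assr_hc
            - self.b_j @ (self.alpha_m + self.kappa_j * mu_age)
            - self.gamma * mu_age
        )

    def population_moments(self) -> dict:
        """Closed-form per-group mean and variance of the outcome."""
        out = {}
        age_slope = self.gamma + float(self.b_j @ self.kappa_j)
        for group, x in (("SZ", 1.0), ("HC", 0.0)):
            dist = self.age_dist(group)
            mu_age, var_age = dist.mean(), dist.var()
            mean_m = self.alpha_m + self.a_j * x + self.kappa_j * mu_age
            mean_y = (
                self.intercept
                + self.c_prime * x
                + float(self.b_j @ mean_m)
                + self.gamma * mu_age
            )
            var_y = (
                age_slope**2 * var_age
                + float(self.b_j**2 @ self.noise_sd_m**2)
                + self.noise_sd_y**2
            )
            out[group] = {"mean": float(mean_y), "var": float(var_y)}
        return out


def generate_cohort(config: MediationSimConfig) -> pd.DataFrame:
    """Draw a subject table from the structural model.

    Columns: ``subject_id, group, age, sex, assr`` followed by one column
    per mediator circuit (Fisher-z units).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_sz + config.n_hc
    x = np.concatenate([np.ones(config.n_sz), np.zeros(config.n_hc)])
    age = np.concatenate(
        [
            config.age_dist("SZ").rvs(config.n_sz, random_state=rng),
            config.age_dist("HC").rvs(config.n_hc, random_state=rng),
        ]
    )
    male = np.concatenate(
        [
            rng.random(config.n_sz) < config.male_frac_sz,
            rng.random(config.n_hc) < config.male_frac_hc,
        ]
    )
    k = config.n_mediators
    eps_m = rng.normal(0.0, 1.0, (n, k)) * config.noise_sd_m
    mediators = (
        config.alpha_m
        + np.outer(x, config.a_j)
        + np.outer(age, config.kappa_j)
        + eps_m
    )
    eps_y = rng.normal(0.0, config.noise_sd_y, n)
    y = (
        config.intercept
        + config.c_prime * x
        + mediators @ config.b_j
        + config.gamma * age
        + eps_y
    )
    group = np.where(x == 1, "SZ", "HC")
    ids = [
        f"{g}{i + 1:03d}"
        for g, i in zip(group, np.concatenate([np.arange(config.n_sz), np.arange(config.n_hc)]))
    ]
    table = pd.DataFrame(
        {
            "subject_id": ids,
            "group": group,
            "age": age,
            "sex": np.where(male, "M", "F"),
            "assr": y,
        }
    )
    for j, name in enumerate(config.mediator_names):
        table[name] = mediators[:, j]
    return table
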