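"""Synthetic multi-country clustered survey generator.

Each country is generated from a seed derived deterministically from the
master seed and the country index, so single-country and multi-country runs
agree record for record. Births carry a sampling weight (log-normal,
normalised to mean 1 within country), a within-country wealth quintile cut at
weighted 20% points of a latent asset score, categorical covariates whose
distributions depend on poor/non-poor status, and a binary death outcome from

    logit p = alpha + (beta_poor + delta_country) * 1[quintile <= 2]
              + sum_k beta_k[x_k] + u_cluster

with ``u_cluster ~ N(0, cluster_re_sd)`` drawn once per cluster and
``delta_country ~ N(0, country_effect_sd)`` once per country.
"""

from __future__ import annotations

import itertools
import math
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from ._stats import weighted_quantile_groups
from .config import PopulationConfig
from .exceptions import ConfigurationError

#: canonical column order of a generated survey table
CORE_COLUMNS = ["country_id", "cluster_id", "weight", "wealth_quintile", "died"]

POOR_QUINTILES = 2  # quintiles 1..2 are "poor"


def _country_rng(seed: int, country_index: int) -> np.random.Generator:
    if seed < 0 or country_index < 0:
        raise ConfigurationError("seed and country_index must be non-negative")
    return np.random.default_rng(np.random.SeedSequence([seed, country_index]))


def generate_survey(
    config: PopulationConfig, country_index: int, seed: int
) -> pd.DataFrame:
    """Generate one country's births. Deterministic in (config, country_index, seed)."""
    rng = _country_rng(seed, country_index)
    country_dev = rng.normal(0.0, config.country_effect_sd) if config.country_effect_sd > 0 else 0.0

    n_clusters = config.clusters_per_country
    n = n_clusters * config.births_per_cluster
    cluster_idx = np.repeat(np.arange(n_clusters), config.births_per_cluster)
    u_cluster = (
        rng.normal(0.0, config.cluster_re_sd, n_clusters)
        if config.cluster_re_sd > 0
        else np.zeros(n_clusters)
    )

    # sampling weights: log-normal, mean-normalised within country
    if config.weight_sigma > 0:
        weights = rng.lognormal(mean=0.0, sigma=config.weight_sigma, size=n)
    else:
        weights = np.ones(n)
    weights = weights / weights.mean()

    # latent asset score -> weighted within-country quintiles; ties broken by
    # record order after a seeded shuffle
    asset = rng.normal(size=n)
    shuffle = rng.permutation(n)
    quintile = weighted_quantile_groups(asset, weights, n_groups=5, tiebreak=shuffle)
    poor = quintile <= POOR_QUINTILES

    # covariates conditional on poor status
    eta = np.full(n, config.outcome.intercept, dtype=float)
    eta += (config.outcome.poor_effect + country_dev) * poor
    columns: dict[str, np.ndarray] = {}
    for spec in config.covariates:
        u = rng.random(n)
        cum_poor = np.cumsum(spec.p_poor)
        cum_non = np.cumsum(spec.p_non_poor)
        idx = np.where(
            poor,
            np.searchsorted(cum_poor, u, side="right"),
            np.searchsorted(cum_non, u, side="right"),
        )
        idx = np.minimum(idx, len(spec.categories) - 1)  # guard u == 1.0 edge
        cats = np.asarray(spec.categories, dtype=object)
        columns[spec.name] = cats[idx]
        effects = np.array(
            [config.outcome.effect(spec.name, c) for c in spec.categories]
        )
        eta += effects[idx]

    eta += u_cluster[cluster_idx]
    died = rng.random(n) < expit(eta)

    country_id = f"C{country_index:03d}"
    frame = pd.DataFrame(
        {
            "country_id": country_id,
            "cluster_id": [f"{country_id}-{c:04d}" for c in cluster_idx],
            "weight": weights,
            "wealth_quintile": quintile,
            "died": died.astype(int),
            **columns,
        }
    )
    return frame


def generate_multicountry(config: PopulationConfig, seed: int) -> pd.DataFrame:
    """Generate all countries of ``config`` into a single table.

    Country ``i`` is exactly ``generate_survey(config, i, seed)``.
    """
    frames = [generate_survey(config, i, seed) for i in range(config.n_countries)]
    return pd.concat(frames, ignore_index=True)


def _ordering_contributions(
    eta_a: np.ndarray, eta_b: np.ndarray, alpha: float, ordering: np.ndarray
) -> np.ndarray:
    """Per-covariate step changes in mean expit when switching columns of
    ``eta_a`` (group A values) to ``eta_b`` one at a time in ``ordering``."""
    k = eta_a.shape[1]
    eta = alpha + eta_a.sum(axis=1)
    out = np.empty(k)
    prev = expit(eta).mean()
    for j in ordering:
        eta = eta - eta_a[:, j] + eta_b[:, j]
        cur = expit(eta).mean()
        out[j] = prev - cur
        prev = cur
    return out


def true_contributions(
    config: PopulationConfig,
    mc_n: int = 200_000,
    seed: int = 0,
    max_orderings: int = 100,
) -> dict[str, float]:
    """Ground-truth per-covariate compositional contributions by Monte Carlo.

    Draws ``mc_n`` covariate vectors from the poor and non-poor generating
    distributions, evaluates the sequential-substitution step changes in the
    mean logistic response under the *known* coefficients (group effect and
    random effects off), and averages over all covariate orderings (or
    ``max_orderings`` random ones when the factorial is larger). No model is
    fitted.
    """
    if mc_n < 1:
        raise ConfigurationError("mc_n must be >= 1")
    rng = np.random.default_rng(seed)
    k = len(config.covariates)
    eta_poor = np.zeros((mc_n, k))
    eta_non = np.zeros((mc_n, k))
    for j, spec in enumerate(config.covariates):
        effects = np.array([config.outcome.effect(spec.name, c) for c in spec.categories])
        ip = rng.choice(len(spec.categories), size=mc_n, p=spec.p_poor)
        inp = rng.choice(len(spec.categories), size=mc_n, p=spec.p_non_poor)
        eta_poor[:, j] = effects[ip]
        eta_non[:, j] = effects[inp]

    if math.factorial(k) <= max_orderings:
        orderings = [np.array(p) for p in itertools.permutations(range(k))]
    else:
        orderings = [rng.permutation(k) for _ in range(max_orderings)]

    alpha = config.outcome.intercept
    total = np.zeros(k)
    for ordering in orderings:
        total += _ordering_contributions(eta_poor, eta_non, alpha, ordering)
    total /= len(orderings)
    return {spec.name: float(total[j]) for j, spec in enumerate(config.covariates)}


def write_survey_csv(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a generated table as CSV; full float precision so the round-trip
    through :func:`read_survey_csv` is lossless."""
    frame.to_csv(path, index=False)


def read_survey_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(
        path,
        dtype={"country_id": str, "cluster_id": str},
    )
    frame["wealth_quintile"] = frame["wealth_quintile"].astype(int)
    frame["died"] = frame["died"].astype(int)
    return frame


def covariate_columns(frame: pd.DataFrame) -> list[str]:
    """Columns of a survey table that are analysis covariates."""
    return [c for c in frame.columns if c not in CORE_COLUMNS]


def marginal_rates(
    config: PopulationConfig, mc_n: int = 1_000_000, seed: int = 0
) -> Mapping[str, float]:
    """Monte-Carlo marginal death rates of the generating model (per 1), by
    group, integrating over covariates, cluster and country effects.

    A brute-force oracle over the generating process, useful for testing; it
    never touches :func:`generate_survey`'s sampling path.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, float] = {}
    for group, poor in (("poor", True), ("non_poor", False)):
        eta = np.full(mc_n, config.outcome.intercept)
        if poor:
            eta += config.outcome.poor_effect
            if config.country_effect_sd > 0:
                eta += rng.normal(0.0, config.country_effect_sd, mc_n)
        for spec in config.covariates:
            p = spec.p_poor if poor else spec.p_non_poor
            effects = np.array(
                [config.outcome.effect(spec.name, c) for c in spec.categories]
            )
            eta += effects[rng.choice(len(spec.categories), size=mc_n, p=p)]
        if config.cluster_re_sd > 0:
            eta += rng.normal(0.0, config.cluster_re_sd, mc_n)
        out[group] = float(expit(eta).mean())
    return out
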