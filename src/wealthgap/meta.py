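"""Per-country risk differences, DerSimonian-Laird random-effects pooling,
Mantel-Haenszel stratified odds ratios, and the prevalence x inequality
country typology."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import Z95
from .exceptions import EstimationError, ValidationError
from .heat import weighted_prevalence

logger = logging.getLogger(__name__)


@dataclass
class CountryRD:
    """Poor vs non-poor risk difference for one country, per 1000 live births."""

    country_id: str
    rd: float
    se: float
    ci: tuple[float, float]
    rate_poor: float
    rate_non_poor: float
    n_poor: float  # effective counts
    n_non_poor: float
    classification: str  # pro-non-poor | pro-poor | insignificant

    def to_dict(self) -> dict:
        return {
            "country_id": self.country_id,
            "rd": self.rd,
            "se": self.se,
            "ci": list(self.ci),
            "rate_poor": self.rate_poor,
            "rate_non_poor": self.rate_non_poor,
            "n_poor": self.n_poor,
            "n_non_poor": self.n_non_poor,
            "classification": self.classification,
        }


def classify_rd(ci_low: float, ci_high: float) -> str:
    if ci_low > 0:
        return "pro-non-poor"
    if ci_high < 0:
        return "pro-poor"
    return "insignificant"


def country_risk_difference(frame: pd.DataFrame, country_id: str | None = None) -> CountryRD:
    """Weighted poor-minus-non-poor death-rate difference (per 1000) with a
    normal 95% CI. The poor group is wealth quintiles 1-2."""
    if country_id is None:
        ids = frame["country_id"].unique()
        country_id = str(ids[0]) if len(ids) == 1 else "pooled"
    poor = frame["wealth_quintile"].to_numpy(dtype=int) <= 2
    y = frame["died"].to_numpy(dtype=float)
    w = frame["weight"].to_numpy(dtype=float)
    if not poor.any() or poor.all():
        raise EstimationError(
            f"country {country_id}: both poor and non-poor groups must be non-empty"
        )
    r_p, se_p, n_p = weighted_prevalence(y[poor], w[poor])
    r_n, se_n, n_n = weighted_prevalence(y[~poor], w[~poor])
    rd = r_p - r_n
    se = float(np.sqrt(se_p**2 + se_n**2))
    ci = (rd - Z95 * se, rd + Z95 * se)
    return CountryRD(
        country_id=country_id,
        rd=rd,
        se=se,
        ci=ci,
        rate_poor=r_p,
        rate_non_poor=r_n,
        n_poor=n_p,
        n_non_poor=n_n,
        classification=classify_rd(*ci),
    )


def country_risk_differences(frame: pd.DataFrame) -> list[CountryRD]:
    return [
        country_risk_difference(sub, str(country))
        for country, sub in frame.groupby("country_id", sort=True)
    ]


@dataclass
class MetaResult:
    """Fixed- and random-effects (DerSimonian-Laird) pooled estimates."""

    fixed: float
    fixed_ci: tuple[float, float]
    random: float
    random_ci: tuple[float, float]
    tau2: float
    q: float
    df: int
    i2: float  # percent
    fixed_weights: np.ndarray  # percents summing to 100
    random_weights: np.ndarray

    def to_dict(self) -> dict:
        return {
            "fixed": self.fixed,
            "fixed_ci": list(self.fixed_ci),
            "random": self.random,
            "random_ci": list(self.random_ci),
            "tau2": self.tau2,
            "Q": self.q,
            "df": self.df,
            "I2": self.i2,
            "fixed_weights": self.fixed_weights.tolist(),
            "random_weights": self.random_weights.tolist(),
        }


def dl_random_effects(
    estimates: Sequence[float], ses: Sequence[float]
) -> MetaResult:
    """Inverse-variance fixed effect plus DerSimonian-Laird random effects.

    tau2 = max(0, (Q - df) / (sum w - sum w^2 / sum w)) with fixed-effect
    weights w = 1/se^2; I2 = max(0, (Q - df)/Q) * 100.
    """
    y = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    if y.size == 0:
        raise ValidationError("meta-analysis needs at least one study")
    if np.any(se <= 0):
        raise ValidationError("all study standard errors must be positive")
    if y.size == 1:
        warnings.warn("single-study meta-analysis is degenerate", stacklevel=2)
    w = 1.0 / se**2
    fixed = float(np.sum(w * y) / np.sum(w))
    fixed_se = float(np.sqrt(1.0 / np.sum(w)))
    q = float(np.sum(w * (y - fixed) ** 2))
    df = int(y.size - 1)
    if df > 0:
        c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
        tau2 = max(0.0, (q - df) / c) if c > 0 else 0.0
        i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    else:
        tau2, i2 = 0.0, 0.0
    w_re = 1.0 / (se**2 + tau2)
    random = float(np.sum(w_re * y) / np.sum(w_re))
    random_se = float(np.sqrt(1.0 / np.sum(w_re)))
    return MetaResult(
        fixed=fixed,
        fixed_ci=(fixed - Z95 * fixed_se, fixed + Z95 * fixed_se),
        random=random,
        random_ci=(random - Z95 * random_se, random + Z95 * random_se),
        tau2=tau2,
        q=q,
        df=df,
        i2=i2,
        fixed_weights=100.0 * w / w.sum(),
        random_weights=100.0 * w_re / w_re.sum(),
    )


@dataclass
class MHResult:
    """Mantel-Haenszel pooled odds ratio across 2x2 strata."""

    pooled_or: float
    ci: tuple[float, float]
    z: float
    p: float
    homogeneity_x2: float
    df: int
    i2: float
    corrected_strata: int  # strata that needed the 0.5 zero-cell correction

    def to_dict(self) -> dict:
        return {
            "pooled_or": self.pooled_or,
            "ci": list(self.ci),
            "z": self.z,
            "p": self.p,
            "homogeneity_x2": self.homogeneity_x2,
            "df": self.df,
            "I2": self.i2,
            "corrected_strata": self.corrected_strata,
        }


def mh_pooled_or(strata: Iterable[tuple[float, float, float, float]]) -> MHResult:
    """MH pooled OR over strata (a, b, c, d) = (exposed cases, exposed
    non-cases, unexposed cases, unexposed non-cases).

    CI from the Robins-Breslow-Greenland variance; heterogeneity by a
    Woolf-weighted chi-square of stratum log-ORs around the pooled log-OR.
    Strata with a zero cell get a 0.5 continuity correction (logged).
    """
    table = np.asarray(list(strata), dtype=float)
    if table.ndim != 2 or table.shape[1] != 4:
        raise ValidationError("each stratum must be a 2x2 table (a, b, c, d)")
    if np.any(table.sum(axis=1) <= 0):
        raise ValidationError("every stratum must have positive total")
    corrected = int(np.sum(np.any(table == 0, axis=1)))
    if corrected:
        logger.info("applying 0.5 continuity correction to %d strata", corrected)
        zero = np.any(table == 0, axis=1)
        table[zero] += 0.5
    a, b, c, d = table.T
    n = table.sum(axis=1)
    r_i, s_i = a * d / n, b * c / n
    r, s = r_i.sum(), s_i.sum()
    if s == 0:
        raise EstimationError("MH odds ratio undefined: no discordant strata")
    pooled = float(r / s)
    p_i, q_i = (a + d) / n, (b + c) / n
    var_log = float(
        np.sum(p_i * r_i) / (2 * r**2)
        + np.sum(p_i * s_i + q_i * r_i) / (2 * r * s)
        + np.sum(q_i * s_i) / (2 * s**2)
    )
    se_log = np.sqrt(var_log)
    log_or = np.log(pooled)
    ci = (float(np.exp(log_or - Z95 * se_log)), float(np.exp(log_or + Z95 * se_log)))
    z = float(log_or / se_log)
    p = float(2 * stats.norm.sf(abs(z)))

    # Woolf-weighted homogeneity around the pooled log OR
    log_or_i = np.log(a * d / (b * c))
    w_i = 1.0 / (1 / a + 1 / b + 1 / c + 1 / d)
    x2 = float(np.sum(w_i * (log_or_i - log_or) ** 2))
    df = int(len(table) - 1)
    i2 = max(0.0, (x2 - df) / x2) * 100.0 if (df > 0 and x2 > 0) else 0.0
    return MHResult(
        pooled_or=pooled,
        ci=ci,
        z=z,
        p=p,
        homogeneity_x2=x2,
        df=df,
        i2=i2,
        corrected_strata=corrected,
    )


def country_two_by_two(frame: pd.DataFrame) -> list[tuple[str, tuple[int, int, int, int]]]:
    """Per-country (deaths-poor, survivors-poor, deaths-non-poor,
    survivors-non-poor) unweighted count tables."""
    out = []
    for country, sub in frame.groupby("country_id", sort=True):
        poor = sub["wealth_quintile"].to_numpy(dtype=int) <= 2
        died = sub["died"].to_numpy(dtype=bool)
        a = int(np.sum(poor & died))
        b = int(np.sum(poor & ~died))
        c = int(np.sum(~poor & died))
        d = int(np.sum(~poor & ~died))
        out.append((str(country), (a, b, c, d)))
    return out


def quadrant_classify(
    countries: Sequence[tuple[str, float, CountryRD]],
    prevalence_threshold: float = 25.0,
    rd_threshold: float = 0.0,
) -> dict[str, str]:
    """Cross-classify countries by prevalence (per 1000, vs the SDG-style
    threshold) and direction of the risk difference."""
    if not np.isfinite(prevalence_threshold) or not np.isfinite(rd_threshold):
        raise ValidationError("thresholds must be finite")
    out = {}
    for country, prevalence, rd in countries:
        burden = "high-prevalence" if prevalence > prevalence_threshold else "low-prevalence"
        direction = "pro-non-poor" if rd.rd > rd_threshold else "pro-poor"
        out[country] = f"{burden}/{direction}"
    return out


def forest_table(rds: Sequence[CountryRD], meta: MetaResult) -> pd.DataFrame:
    """Forest-plot-ready table: one row per study plus pooled rows."""
    rows = [
        {
            "study": rd.country_id,
            "estimate": rd.rd,
            "ci_low": rd.ci[0],
            "ci_high": rd.ci[1],
            "weight_fixed_pct": meta.fixed_weights[i],
            "weight_random_pct": meta.random_weights[i],
            "classification": rd.classification,
        }
        for i, rd in enumerate(rds)
    ]
    rows.append(
        {
            "study": "FIXED",
            "estimate": meta.fixed,
            "ci_low": meta.fixed_ci[0],
            "ci_high": meta.fixed_ci[1],
            "weight_fixed_pct": 100.0,
            "weight_random_pct": float("nan"),
            "classification": "",
        }
    )
    rows.append(
        {
            "study": "RANDOM",
            "estimate": meta.random,
            "ci_low": meta.random_ci[0],
            "ci_high": meta.random_ci[1],
            "weight_fixed_pct": float("nan"),
            "weight_random_pct": 100.0,
            "classification": "",
        }
    )
    return pd.DataFrame(rows)
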