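"""Weighted subgroup prevalences and the D / R / PAR / PAF summary measures.

Conventions for an adverse indicator (higher rate = worse):

* the most-advantaged subgroup is the highest wealth quintile (Q5);
* D = rate(Q1) - rate(Q5), R = rate(Q1) / rate(Q5);
* PAR = rate(Q5) - mu, truncated to 0 when positive; PAF = PAR / mu * 100,
  truncated alongside PAR.

Prevalences are carried per 1000 live births; D and PAR are reported per 100
by default (``scale="per1000"`` switches them back). Confidence intervals:
normal for D, log-scale delta method for R, correlated-share delta method for
PAR, and an independence (conservative) delta method for PAF. Truncated
measures report a CI centred on the truncated value of 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from ._stats import Z95, weighted_proportion
from .exceptions import EstimationError, ValidationError

IndicatorType = Literal["adverse", "favourable"]


def weighted_prevalence(died, weights) -> tuple[float, float, float]:
    """Weighted death rate per 1000 live births with SE (same scale) and
    effective sample size."""
    p, se, n_eff = weighted_proportion(died, weights)
    return 1000.0 * p, 1000.0 * se, n_eff


@dataclass
class SubgroupEstimates:
    """Per-wealth-quintile weighted rates (per 1000) plus the national
    average mu; index 0 is quintile 1 (poorest)."""

    rates: np.ndarray
    ses: np.ndarray
    n_eff: np.ndarray
    mu: float
    mu_se: float
    weighted: bool = True

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        self.ses = np.asarray(self.ses, dtype=float)
        self.n_eff = np.asarray(self.n_eff, dtype=float)
        if not (len(self.rates) == len(self.ses) == len(self.n_eff) == 5):
            raise ValidationError("five quintile estimates required")
        if np.any(self.rates < 0):
            raise ValidationError("rates must be non-negative")


def subgroup_estimates(frame: pd.DataFrame, weighted: bool = True) -> SubgroupEstimates:
    """Estimate per-quintile rates and the national average from a survey table."""
    w = frame["weight"].to_numpy(dtype=float) if weighted else np.ones(len(frame))
    y = frame["died"].to_numpy(dtype=float)
    q = frame["wealth_quintile"].to_numpy(dtype=int)
    rates, ses, neffs = np.empty(5), np.empty(5), np.empty(5)
    for i, quint in enumerate(range(1, 6)):
        mask = q == quint
        if not mask.any():
            raise EstimationError(f"no records in wealth quintile {quint}")
        rates[i], ses[i], neffs[i] = weighted_prevalence(y[mask], w[mask])
    mu, mu_se, _ = weighted_prevalence(y, w)
    return SubgroupEstimates(rates, ses, neffs, mu, mu_se, weighted=weighted)


@dataclass
class InequalityMeasures:
    """D, R, PAR, PAF with 95% CIs. ``truncated`` marks the WHO convention of
    clamping PAR/PAF to 0 when the reference subgroup does worse than the
    national average. ``r_defined`` is False when the reference rate is 0."""

    d: float
    d_ci: tuple[float, float]
    r: float
    r_ci: tuple[float, float]
    r_defined: bool
    par: float
    par_ci: tuple[float, float]
    paf: float
    paf_ci: tuple[float, float]
    truncated: bool
    reference_quintile: int
    scale: str = "per100"

    def to_dict(self) -> dict:
        return {
            "D": self.d,
            "D_ci": list(self.d_ci),
            "R": None if not self.r_defined else self.r,
            "R_ci": list(self.r_ci) if self.r_defined else None,
            "R_defined": self.r_defined,
            "PAR": self.par,
            "PAR_ci": list(self.par_ci),
            "PAF": self.paf,
            "PAF_ci": list(self.paf_ci),
            "truncated": self.truncated,
            "reference_quintile": self.reference_quintile,
            "scale": self.scale,
        }


def compute_heat(
    estimates: SubgroupEstimates,
    indicator_type: IndicatorType = "adverse",
    scale: Literal["per100", "per1000"] = "per100",
) -> InequalityMeasures:
    """Summary measures of wealth inequality from quintile estimates."""
    if indicator_type not in ("adverse", "favourable"):
        raise ValidationError(f"unknown indicator type {indicator_type!r}")
    rates, ses = estimates.rates, estimates.ses
    mu, mu_se = estimates.mu, estimates.mu_se
    factor = 10.0 if scale == "per100" else 1.0

    if indicator_type == "adverse":
        # most-advantaged = highest quintile; worse-off = poorest
        ref, worse = 4, 0
    else:
        ref, worse = 4, 0  # reference stays Q5; D sign flips below

    sign = 1.0 if indicator_type == "adverse" else -1.0
    d_raw = sign * (rates[worse] - rates[ref])
    d_se = float(np.sqrt(ses[worse] ** 2 + ses[ref] ** 2))
    d = d_raw / factor
    d_ci = ((d_raw - Z95 * d_se) / factor, (d_raw + Z95 * d_se) / factor)

    r_defined = rates[ref] > 0
    if r_defined:
        r = float(rates[worse] / rates[ref])
        if rates[worse] > 0:
            log_se = float(
                np.sqrt(
                    (ses[worse] / rates[worse]) ** 2 + (ses[ref] / rates[ref]) ** 2
                )
            )
            r_ci = (r * np.exp(-Z95 * log_se), r * np.exp(Z95 * log_se))
        else:
            r_ci = (0.0, 0.0)
    else:
        r, r_ci = float("nan"), (float("nan"), float("nan"))

    # PAR: reference rate minus national average; quintiles share the national
    # sample, so Var(rate_ref - mu) uses effective-n shares as mixing weights.
    shares = estimates.n_eff / estimates.n_eff.sum()
    coef = -shares.copy()
    coef[ref] += 1.0
    par_raw = rates[ref] - mu
    par_se = float(np.sqrt(np.sum((coef * ses) ** 2)))
    adverse_excess = par_raw > 0 if indicator_type == "adverse" else par_raw < 0
    truncated = bool(adverse_excess)

    if mu > 0:
        paf_raw = par_raw / mu * 100.0
        # conservative delta method treating (rate_ref - mu) and mu as independent
        paf_se = float(
            np.sqrt(
                (100.0 / mu) ** 2 * par_se**2
                + (100.0 * par_raw / mu**2) ** 2 * mu_se**2
            )
        )
    else:
        paf_raw, paf_se = float("nan"), float("nan")

    if truncated:
        par, paf = 0.0, 0.0
        par_ci = (-Z95 * par_se / factor, Z95 * par_se / factor)
        paf_ci = (-Z95 * paf_se, Z95 * paf_se)
    else:
        par = par_raw / factor
        par_ci = ((par_raw - Z95 * par_se) / factor, (par_raw + Z95 * par_se) / factor)
        paf = paf_raw
        paf_ci = (paf_raw - Z95 * paf_se, paf_raw + Z95 * paf_se)

    return InequalityMeasures(
        d=d,
        d_ci=d_ci,
        r=r,
        r_ci=r_ci,
        r_defined=bool(r_defined),
        par=par,
        par_ci=par_ci,
        paf=paf,
        paf_ci=paf_ci,
        truncated=truncated,
        reference_quintile=ref + 1,
        scale=scale,
    )


def measures_table(
    frame: pd.DataFrame,
    indicator_type: IndicatorType = "adverse",
    scale: Literal["per100", "per1000"] = "per100",
) -> pd.DataFrame:
    """Per-country inequality measures table (one row per country)."""
    rows = []
    for country, sub in frame.groupby("country_id", sort=True):
        est = subgroup_estimates(sub)
        m = compute_heat(est, indicator_type=indicator_type, scale=scale)
        rows.append(
            {
                "country_id": country,
                "mu_per1000": est.mu,
                "D": m.d,
                "D_lo": m.d_ci[0],
                "D_hi": m.d_ci[1],
                "R": m.r,
                "R_lo": m.r_ci[0],
                "R_hi": m.r_ci[1],
                "R_defined": m.r_defined,
                "PAR": m.par,
                "PAR_lo": m.par_ci[0],
                "PAR_hi": m.par_ci[1],
                "PAF": m.paf,
                "PAF_lo": m.paf_ci[0],
                "PAF_hi": m.paf_ci[1],
                "truncated": m.truncated,
            }
        )
    return pd.DataFrame(rows)
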