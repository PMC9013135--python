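"""Recoding of raw survey records into analysis variables.

Covers the poor/non-poor dichotomy, the cluster-level socioeconomic
disadvantage composite (first principal component of three cluster rates,
oriented so higher = more disadvantaged), and iterative VIF screening of the
dummy-coded covariate design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._stats import weighted_quantile_groups
from .exceptions import DegenerateCompositeError, ValidationError

logger = logging.getLogger(__name__)

#: default ingredient map for the neighbourhood SES composite:
#: rate name -> (column, disadvantaged category)
DEFAULT_SES_INDICATORS: dict[str, tuple[str, str]] = {
    "no_education": ("maternal_education", "none"),
    "no_media": ("media_access", "no"),
    "unemployed": ("maternal_employment", "unemployed"),
}

SES_COLUMN = "cluster_ses_quintile"


def dichotomize_wealth(quintile: int) -> bool:
    """True (poor) for quintiles 1-2, False (non-poor) for 3-5."""
    q = int(quintile)
    if q < 1 or q > 5:
        raise ValidationError(f"wealth quintile must be in 1..5, got {quintile}")
    return q <= 2


def add_poor_indicator(frame: pd.DataFrame) -> pd.DataFrame:
    q = frame["wealth_quintile"].to_numpy()
    if q.min() < 1 or q.max() > 5:
        raise ValidationError("wealth_quintile outside 1..5")
    out = frame.copy()
    out["poor"] = q <= 2
    return out


def neighborhood_ses(
    frame: pd.DataFrame,
    indicators: Mapping[str, tuple[str, str]] | None = None,
    weighted: bool = True,
) -> pd.DataFrame:
    """Cluster-level SES disadvantage composite.

    Computes per-cluster (weighted) rates of each disadvantage indicator,
    standardises them, takes the first principal component of their
    correlation matrix, orients it so the loading on the first indicator is
    positive (higher score = more disadvantaged), and cuts cluster scores into
    weighted quintiles.

    Returns a frame indexed by ``cluster_id`` with columns ``score`` and
    ``quintile``.
    """
    indicators = dict(indicators or DEFAULT_SES_INDICATORS)
    if not indicators:
        raise ValidationError("at least one SES indicator required")
    missing = [col for col, _ in indicators.values() if col not in frame.columns]
    if missing:
        raise ValidationError(f"SES ingredient columns missing from data: {missing}")

    w = frame["weight"].to_numpy(dtype=float) if weighted else np.ones(len(frame))
    by_cluster = pd.DataFrame(
        index=pd.Index(sorted(frame["cluster_id"].unique()), name="cluster_id")
    )
    cluster_w = pd.Series(w, index=frame.index).groupby(frame["cluster_id"]).sum()
    for rate_name, (col, bad_cat) in indicators.items():
        ind = (frame[col].astype(str) == bad_cat).to_numpy(dtype=float)
        num = pd.Series(ind * w, index=frame.index).groupby(frame["cluster_id"]).sum()
        den = pd.Series(w, index=frame.index).groupby(frame["cluster_id"]).sum()
        by_cluster[rate_name] = (num / den).reindex(by_cluster.index)

    X = by_cluster.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=0)
    if np.all(sd == 0):
        raise DegenerateCompositeError(
            "all SES ingredients are constant across clusters; composite undefined"
        )
    mean = X.mean(axis=0)
    Z = np.zeros_like(X)
    nonzero = sd > 0
    Z[:, nonzero] = (X[:, nonzero] - mean[nonzero]) / sd[nonzero]
    corr = (Z.T @ Z) / len(Z)
    eigvals, eigvecs = np.linalg.eigh(corr)
    pc1 = eigvecs[:, -1]
    # orient: loading on the first declared (non-degenerate) indicator positive
    anchor_idx = 0 if nonzero[0] else int(np.argmax(nonzero))
    if pc1[anchor_idx] < 0:
        pc1 = -pc1
    scores = Z @ pc1

    cw = cluster_w.reindex(by_cluster.index).to_numpy(dtype=float)
    quintile = weighted_quantile_groups(scores, cw, n_groups=5)
    return pd.DataFrame({"score": scores, "quintile": quintile}, index=by_cluster.index)


def attach_neighborhood_ses(
    frame: pd.DataFrame,
    indicators: Mapping[str, tuple[str, str]] | None = None,
    weighted: bool = True,
) -> pd.DataFrame:
    """Add a ``cluster_ses_quintile`` categorical column to ``frame``."""
    ses = neighborhood_ses(frame, indicators=indicators, weighted=weighted)
    out = frame.copy()
    out[SES_COLUMN] = (
        frame["cluster_id"].map(ses["quintile"]).map(lambda q: f"q{int(q)}")
    )
    return out


@dataclass
class VifReport:
    """Outcome of the iterative VIF screen."""

    vifs: dict[str, float]  # VIF at evaluation time (final for retained,
    # value when dropped for eliminated)
    threshold: float
    eliminated: list[str]
    retained: list[str]

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "vifs": {k: (None if np.isinf(v) else v) for k, v in self.vifs.items()},
            "eliminated": list(self.eliminated),
            "retained": list(self.retained),
        }


def _vif_one(X: np.ndarray, j: int) -> float:
    """VIF of column j: 1/(1-R^2) from regressing it on the other columns
    (with intercept)."""
    y = X[:, j]
    others = np.delete(X, j, axis=1)
    design = np.column_stack([np.ones(len(X)), others])
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        return 1.0
    r2 = 1.0 - float((resid**2).sum()) / sst
    if r2 >= 1.0 - 1e-12:
        return float("inf")
    return 1.0 / (1.0 - r2)


def vif_screen(design: pd.DataFrame, threshold: float = 2.5) -> VifReport:
    """Iteratively drop the worst-VIF column until all VIFs <= threshold.

    Ties on VIF are broken alphabetically (the alphabetically first offender
    is dropped). Perfectly collinear columns get VIF = inf and go first.
    """
    if design.shape[1] < 2:
        raise ValidationError("vif_screen needs at least two columns")
    if design.shape[0] < design.shape[1]:
        raise ValidationError("vif_screen needs at least as many rows as columns")
    cols = list(design.columns)
    X = design.to_numpy(dtype=float)
    vifs: dict[str, float] = {}
    eliminated: list[str] = []
    active = list(range(len(cols)))
    while len(active) >= 2:
        current = {cols[i]: _vif_one(X[:, active], k) for k, i in enumerate(active)}
        worst = max(current.values())
        if worst <= threshold:
            vifs.update(current)
            break
        offenders = sorted(name for name, v in current.items() if v == worst)
        drop = offenders[0]
        vifs[drop] = current[drop]
        eliminated.append(drop)
        active = [i for i in active if cols[i] != drop]
    else:
        # one column left: VIF of a single column (vs intercept only) is 1
        if active:
            vifs[cols[active[0]]] = 1.0
    retained = [cols[i] for i in active]
    return VifReport(vifs=vifs, threshold=threshold, eliminated=eliminated, retained=retained)


def dummy_design(
    frame: pd.DataFrame, covariates: Sequence[str]
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Dummy-code categorical covariates (first category alphabetically is the
    reference). Returns the design and the covariate -> dummy-columns map."""
    blocks: dict[str, list[str]] = {}
    pieces = []
    for cov in covariates:
        if cov not in frame.columns:
            raise ValidationError(f"covariate {cov!r} not in data")
        dummies = pd.get_dummies(frame[cov].astype(str), prefix=cov, dtype=float)
        dummies = dummies[sorted(dummies.columns)]
        dummies = dummies.iloc[:, 1:]  # drop reference level
        blocks[cov] = list(dummies.columns)
        pieces.append(dummies)
    design = pd.concat(pieces, axis=1) if pieces else pd.DataFrame(index=frame.index)
    return design, blocks


@dataclass
class AnalysisFrame:
    """Harmonised analysis dataset: records with a poor indicator and, where
    requested, the neighbourhood SES quintile, plus the VIF-screened covariate
    list."""

    data: pd.DataFrame
    covariates: list[str]
    vif_report: VifReport | None = None
    dropped_rows: int = 0
    blocks: dict[str, list[str]] = field(default_factory=dict)


def build_analysis_frame(
    frame: pd.DataFrame,
    covariates: Sequence[str] | None = None,
    ses_indicators: Mapping[str, tuple[str, str]] | None | bool = None,
    vif_threshold: float = 2.5,
) -> AnalysisFrame:
    """Full harmonisation: poor indicator, optional SES composite, complete-case
    deletion, VIF screen of the dummy-coded design.

    ``ses_indicators``: mapping to build the composite, ``None`` to use the
    default mapping when its ingredient columns exist, ``False`` to skip.
    """
    from .synthetic import covariate_columns

    if covariates is None:
        covariates = covariate_columns(frame)
    covariates = list(covariates)

    out = add_poor_indicator(frame)
    if ses_indicators is not False:
        mapping = dict(ses_indicators or DEFAULT_SES_INDICATORS)
        if all(col in out.columns for col, _ in mapping.values()):
            out = attach_neighborhood_ses(out, indicators=mapping)
            if SES_COLUMN not in covariates:
                covariates.append(SES_COLUMN)

    n0 = len(out)
    out = out.dropna(subset=["weight", "wealth_quintile", "died", *covariates])
    dropped = n0 - len(out)
    if dropped:
        logger.info("complete-case deletion removed %d of %d rows", dropped, n0)

    design, blocks = dummy_design(out, covariates)
    report = None
    retained = covariates
    if design.shape[1] >= 2:
        report = vif_screen(design, threshold=vif_threshold)
        dropped_cols = set(report.eliminated)
        retained = []
        for cov in covariates:
            keep_cols = [c for c in blocks[cov] if c not in dropped_cols]
            if keep_cols:
                blocks[cov] = keep_cols
                retained.append(cov)
            else:
                blocks.pop(cov)
                logger.info("covariate %s fully eliminated by VIF screen", cov)
    blocks = {c: blocks[c] for c in retained}
    return AnalysisFrame(
        data=out.reset_index(drop=True),
        covariates=list(retained),
        vif_report=report,
        dropped_rows=dropped,
        blocks=blocks,
    )
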