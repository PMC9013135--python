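"""Nonlinear decomposition of the poor/non-poor gap in death probability.

The gap in mean outcome between the two groups is split into per-covariate
"compositional" contributions by (i) fitting a pooled weighted logit with a
group indicator, (ii) subsampling the larger group to the smaller group's
size and matching records by rank of predicted probability, and (iii)
switching each covariate block of the poor sample to its matched non-poor
values one at a time, recording the step change in the mean predicted
probability. Because sequential substitution is path dependent, contributions
are averaged over seeded random covariate orderings and subsample draws; the
spread across replications is reported as the replication SD.

For every single replication the contributions telescope exactly to the
explained gap (mean F over poor covariates minus mean F over matched
non-poor covariates under the common coefficients).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

from .exceptions import EstimationError, SeparationError, ValidationError
from .harmonize import AnalysisFrame, dummy_design

GROUP_COLUMN = "_poor"


@dataclass
class LogitModel:
    """Pooled weighted logit: intercept + dummy-column coefficients.

    ``blocks`` maps each covariate to its dummy columns; ``group_col`` names
    the group-indicator column, whose coefficient is excluded from
    decomposition predictions.
    """

    params: pd.Series
    blocks: dict[str, list[str]]
    group_col: str | None = None
    converged: bool = True

    @property
    def intercept(self) -> float:
        return float(self.params["const"])

    def block_eta(self, X: pd.DataFrame, covariate: str) -> np.ndarray:
        cols = self.blocks[covariate]
        return X[cols].to_numpy(dtype=float) @ self.params[cols].to_numpy()

    def predict_prob(self, X: pd.DataFrame, include_group: bool = False) -> np.ndarray:
        eta = np.full(len(X), self.intercept)
        for cov in self.blocks:
            eta += self.block_eta(X, cov)
        if include_group and self.group_col is not None:
            eta += X[self.group_col].to_numpy(dtype=float) * float(
                self.params[self.group_col]
            )
        return expit(eta)


def _diagnose_separation(X: pd.DataFrame, y: np.ndarray) -> str | None:
    """Name a column whose support does not overlap between outcome classes."""
    for col in X.columns:
        x = X[col].to_numpy(dtype=float)
        x0, x1 = x[y == 0], x[y == 1]
        if len(x0) == 0 or len(x1) == 0:
            continue
        if x0.max() <= x1.min() - 1e-12 or x1.max() <= x0.min() - 1e-12:
            return col
    return None


def fit_pooled_logit(
    X: pd.DataFrame,
    y,
    weights=None,
    blocks: Mapping[str, list[str]] | None = None,
    group_col: str | None = None,
) -> LogitModel:
    """Weighted maximum-likelihood logit on a dummy-coded design.

    ``X`` must not contain a constant column; one is added internally.
    """
    y = np.asarray(y, dtype=float)
    if y.min() == y.max():
        raise EstimationError("both outcome classes must be present")
    w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)
    design = sm.add_constant(X.astype(float), has_constant="raise")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            model = sm.GLM(y, design, family=sm.families.Binomial(), freq_weights=w)
            res = model.fit(maxiter=200)
    except Exception as exc:  # separation warnings/errors and numeric failures
        col = _diagnose_separation(X, y)
        raise SeparationError(
            f"logit fit failed{f'; column {col!r} separates the outcome' if col else ''}"
        ) from exc
    params = res.params
    if not np.all(np.isfinite(params)) or np.abs(params).max() > 50:
        col = _diagnose_separation(X, y)
        raise SeparationError(
            "logit fit diverged"
            + (f"; column {col!r} separates the outcome" if col else "")
        )
    if blocks is None:
        blocks = {c: [c] for c in X.columns if c != group_col}
    return LogitModel(
        params=params,
        blocks={k: list(v) for k, v in blocks.items()},
        group_col=group_col,
        converged=bool(res.converged),
    )


def match_samples(
    X_poor: pd.DataFrame,
    X_non_poor: pd.DataFrame,
    model: LogitModel,
    seed: int | np.random.Generator,
    w_poor=None,
    w_non_poor=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank-match the two groups on predicted probability.

    The larger group is subsampled without replacement to the smaller group's
    size (weight-proportionally when weights are given); both samples are then
    sorted by predicted probability under ``model`` (group term excluded) and
    paired by rank. Returns aligned (poor, non-poor) frames of equal length.
    """
    if len(X_poor) == 0 or len(X_non_poor) == 0:
        raise ValidationError("both groups must be non-empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = min(len(X_poor), len(X_non_poor))

    def subsample(X: pd.DataFrame, w) -> pd.DataFrame:
        if len(X) == m:
            return X
        p = None
        if w is not None:
            w = np.asarray(w, dtype=float)
            p = w / w.sum()
        idx = rng.choice(len(X), size=m, replace=False, p=p)
        return X.iloc[idx]

    Xp = subsample(X_poor, w_poor)
    Xn = subsample(X_non_poor, w_non_poor)
    order_p = np.argsort(model.predict_prob(Xp), kind="stable")
    order_n = np.argsort(model.predict_prob(Xn), kind="stable")
    return Xp.iloc[order_p].reset_index(drop=True), Xn.iloc[order_n].reset_index(drop=True)


def sequential_contributions(
    X_poor: pd.DataFrame,
    X_non_poor: pd.DataFrame,
    model: LogitModel,
    ordering: Sequence[str],
) -> tuple[dict[str, float], float]:
    """One sequential-substitution pass over matched pairs.

    Starting from the poor group's covariate values, each covariate block is
    switched (in ``ordering``) to the matched non-poor values; the covariate's
    contribution is the step change in the mean predicted probability. Returns
    ``(contributions, explained)`` with ``sum(contributions) == explained``
    exactly.
    """
    covs = list(model.blocks)
    if sorted(ordering) != sorted(covs):
        raise ValidationError(
            f"ordering must be a permutation of the model covariates {sorted(covs)}"
        )
    if len(X_poor) != len(X_non_poor):
        raise ValidationError("matched samples must have equal length")
    eta_p = {c: model.block_eta(X_poor, c) for c in covs}
    eta_n = {c: model.block_eta(X_non_poor, c) for c in covs}
    eta = model.intercept + np.sum([eta_p[c] for c in covs], axis=0)
    # final (all-switched) state evaluated canonically so the explained gap is
    # bit-identical across orderings
    eta_final = model.intercept + np.sum([eta_n[c] for c in covs], axis=0)
    final = float(expit(eta_final).mean())
    contributions: dict[str, float] = {}
    prev = float(expit(eta).mean())
    start = prev
    for step, c in enumerate(ordering):
        if step == len(ordering) - 1:
            cur = final
        else:
            eta = eta - eta_p[c] + eta_n[c]
            cur = float(expit(eta).mean())
        contributions[c] = prev - cur
        prev = cur
    explained = start - final
    return contributions, explained


@dataclass
class DecompositionResult:
    """Averaged decomposition over random orderings and subsample draws."""

    total_gap: float
    explained: float
    explained_sd: float
    contributions: dict[str, float]
    contribution_sd: dict[str, float]
    percent_of_gap: dict[str, float]
    percent_of_explained: dict[str, float]
    n_replications: int
    seed: int
    covariates: list[str] = field(default_factory=list)
    replications: np.ndarray | None = None  # (n_replications, n_covariates)
    explained_reps: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "total_gap": self.total_gap,
            "explained": self.explained,
            "explained_sd": self.explained_sd,
            "contributions": self.contributions,
            "contribution_sd": self.contribution_sd,
            "percent_of_gap": self.percent_of_gap,
            "percent_of_explained": self.percent_of_explained,
            "n_replications": self.n_replications,
            "seed": self.seed,
            "covariates": self.covariates,
        }


def fairlie_decompose(
    frame: AnalysisFrame | pd.DataFrame,
    covariates: Sequence[str] | None = None,
    n_orderings: int = 100,
    n_subsamples: int = 10,
    seed: int = 0,
    weighted: bool = True,
    keep_replications: bool = True,
) -> DecompositionResult:
    """Full decomposition of the poor/non-poor gap in the death rate.

    Coefficients come from a pooled weighted logit including a group
    indicator that is dropped at prediction time. ``n_subsamples`` seeded
    subsample/match draws are crossed with ``n_orderings`` seeded random
    covariate orderings; contributions are means over all replications with
    their replication SD.
    """
    if n_orderings < 1 or n_subsamples < 1:
        raise ValidationError("n_orderings and n_subsamples must be >= 1")
    if isinstance(frame, AnalysisFrame):
        data = frame.data
        covs = list(covariates) if covariates is not None else list(frame.covariates)
        blocks_hint = {c: frame.blocks[c] for c in covs} if frame.blocks else None
    else:
        data = frame
        if covariates is None:
            raise ValidationError("covariates must be given for a raw DataFrame")
        covs = list(covariates)
        blocks_hint = None

    poor = (
        data["poor"].to_numpy(dtype=bool)
        if "poor" in data.columns
        else data["wealth_quintile"].to_numpy(dtype=int) <= 2
    )
    y = data["died"].to_numpy(dtype=float)
    w = data["weight"].to_numpy(dtype=float) if weighted else np.ones(len(data))

    design, blocks = dummy_design(data, covs)
    if blocks_hint is not None:
        # respect VIF-screened dummy columns
        blocks = {c: [col for col in blocks[c] if col in set(blocks_hint[c])] for c in covs}
        design = design[[col for cols in blocks.values() for col in cols]]
    design = design.copy()
    design[GROUP_COLUMN] = poor.astype(float)

    model = fit_pooled_logit(design, y, w, blocks=blocks, group_col=GROUP_COLUMN)

    wp, wn = w[poor], w[~poor]
    total_gap = float(np.sum(wp * y[poor]) / wp.sum() - np.sum(wn * y[~poor]) / wn.sum())

    X_all = design.drop(columns=[GROUP_COLUMN])
    X_poor, X_non = X_all[poor], X_all[~poor]
    rng = np.random.default_rng(np.random.SeedSequence([seed]))
    match_rng = np.random.default_rng(rng.integers(2**63))
    order_rng = np.random.default_rng(rng.integers(2**63))

    covs = list(model.blocks)
    k = len(covs)
    reps = np.empty((n_subsamples * n_orderings, k))
    exp_reps = np.empty(n_subsamples * n_orderings)
    r = 0
    for _ in range(n_subsamples):
        Xp, Xn = match_samples(
            X_poor, X_non, model, match_rng, w_poor=wp, w_non_poor=wn
        )
        for _ in range(n_orderings):
            ordering = [covs[i] for i in order_rng.permutation(k)]
            contrib, explained = sequential_contributions(Xp, Xn, model, ordering)
            reps[r] = [contrib[c] for c in covs]
            exp_reps[r] = explained
            r += 1

    mean = reps.mean(axis=0)
    sd = reps.std(axis=0, ddof=1) if len(reps) > 1 else np.zeros(k)
    contributions = {c: float(mean[i]) for i, c in enumerate(covs)}
    contribution_sd = {c: float(sd[i]) for i, c in enumerate(covs)}
    explained = float(exp_reps.mean())
    explained_sd = float(exp_reps.std(ddof=1)) if len(exp_reps) > 1 else 0.0
    if total_gap != 0:
        pct_gap = {c: 100.0 * contributions[c] / total_gap for c in covs}
    else:
        pct_gap = {c: float("nan") for c in covs}
    if explained != 0:
        pct_exp = {c: 100.0 * contributions[c] / explained for c in covs}
    else:
        pct_exp = {c: float("nan") for c in covs}
    return DecompositionResult(
        total_gap=total_gap,
        explained=explained,
        explained_sd=explained_sd,
        contributions=contributions,
        contribution_sd=contribution_sd,
        percent_of_gap=pct_gap,
        percent_of_explained=pct_exp,
        n_replications=len(reps),
        seed=seed,
        covariates=covs,
        replications=reps if keep_replications else None,
        explained_reps=exp_reps if keep_replications else None,
    )


def contribution_table(
    results: Mapping[str, DecompositionResult], value: str = "percent_of_gap"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Country x covariate matrix of contributions.

    Returns ``(wide, long)``; percents are NaN where the total gap is zero
    (absolute contributions remain available via ``value="contributions"``).
    """
    if not results:
        raise ValidationError("at least one country result required")
    long_rows = []
    for country, res in results.items():
        values = getattr(res, value)
        for cov in res.covariates:
            long_rows.append(
                {
                    "country_id": country,
                    "covariate": cov,
                    "value": values[cov],
                    "contribution": res.contributions[cov],
                    "replication_sd": res.contribution_sd[cov],
                }
            )
    long = pd.DataFrame(long_rows)
    wide = long.pivot(index="country_id", columns="covariate", values="value")
    return wide, long
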