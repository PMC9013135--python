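"""Configuration objects for the synthetic survey generator and pipeline runs.

All configs round-trip losslessly through plain dicts and therefore through
JSON or YAML files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .exceptions import ConfigurationError


@dataclass(frozen=True)
class CovariateSpec:
    """A categorical covariate whose distribution may differ between poor and
    non-poor households.

    ``p_poor`` / ``p_non_poor`` are category probabilities aligned with
    ``categories``; each must sum to 1.
    """

    name: str
    categories: tuple[str, ...]
    p_poor: tuple[float, ...]
    p_non_poor: tuple[float, ...]

    def __post_init__(self) -> None:
        k = len(self.categories)
        if k < 2:
            raise ConfigurationError(f"covariate {self.name!r} needs >= 2 categories")
        for label, p in (("p_poor", self.p_poor), ("p_non_poor", self.p_non_poor)):
            if len(p) != k:
                raise ConfigurationError(
                    f"covariate {self.name!r}: {label} has {len(p)} entries, expected {k}"
                )
            if any(x < 0 or x > 1 for x in p):
                raise ConfigurationError(
                    f"covariate {self.name!r}: {label} probabilities must be in [0, 1]"
                )
            if not math.isclose(sum(p), 1.0, abs_tol=1e-9):
                raise ConfigurationError(
                    f"covariate {self.name!r}: {label} must sum to 1 (got {sum(p)})"
                )

    def to_dict(self) -> dict[str, Any]:
        return {
            "name": self.name,
            "categories": list(self.categories),
            "p_poor": list(self.p_poor),
            "p_non_poor": list(self.p_non_poor),
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "CovariateSpec":
        return cls(
            name=d["name"],
            categories=tuple(d["categories"]),
            p_poor=tuple(float(x) for x in d["p_poor"]),
            p_non_poor=tuple(float(x) for x in d["p_non_poor"]),
        )


@dataclass(frozen=True)
class OutcomeModel:
    """Logistic generating model for the death outcome.

    ``covariate_effects`` maps covariate name -> {category: log-odds}; a
    category absent from the map has effect 0 (reference level).
    """

    intercept: float
    poor_effect: float = 0.0
    covariate_effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def effect(self, covariate: str, category: str) -> float:
        return float(self.covariate_effects.get(covariate, {}).get(category, 0.0))

    def to_dict(self) -> dict[str, Any]:
        return {
            "intercept": self.intercept,
            "poor_effect": self.poor_effect,
            "covariate_effects": {k: dict(v) for k, v in self.covariate_effects.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "OutcomeModel":
        return cls(
            intercept=float(d["intercept"]),
            poor_effect=float(d.get("poor_effect", 0.0)),
            covariate_effects={
                k: {c: float(b) for c, b in v.items()}
                for k, v in d.get("covariate_effects", {}).items()
            },
        )


@dataclass(frozen=True)
class PopulationConfig:
    """Configuration of the synthetic multi-country survey population."""

    n_countries: int
    clusters_per_country: int
    births_per_cluster: int
    covariates: tuple[CovariateSpec, ...]
    outcome: OutcomeModel
    cluster_re_sd: float = 0.0
    country_effect_sd: float = 0.0
    weight_sigma: float = 0.3  # log-normal sigma of sampling weights
    seed: int = 0

    def __post_init__(self) -> None:
        for name, value in (
            ("n_countries", self.n_countries),
            ("clusters_per_country", self.clusters_per_country),
            ("births_per_cluster", self.births_per_cluster),
        ):
            if int(value) < 1:
                raise ConfigurationError(f"{name} must be >= 1 (got {value})")
        for name, value in (
            ("cluster_re_sd", self.cluster_re_sd),
            ("country_effect_sd", self.country_effect_sd),
            ("weight_sigma", self.weight_sigma),
        ):
            if value < 0:
                raise ConfigurationError(f"{name} must be >= 0 (got {value})")
        if self.seed < 0:
            raise ConfigurationError("seed must be a non-negative integer")
        names = [c.name for c in self.covariates]
        if len(set(names)) != len(names):
            raise ConfigurationError("covariate names must be unique")
        unknown = set(self.outcome.covariate_effects) - set(names)
        if unknown:
            raise ConfigurationError(
                f"outcome coefficients refer to undeclared covariates: {sorted(unknown)}"
            )
        for spec in self.covariates:
            effects = self.outcome.covariate_effects.get(spec.name, {})
            bad = set(effects) - set(spec.categories)
            if bad:
                raise ConfigurationError(
                    f"outcome coefficients for {spec.name!r} refer to unknown "
                    f"categories: {sorted(bad)}"
                )

    @property
    def covariate_names(self) -> list[str]:
        return [c.name for c in self.covariates]

    def to_dict(self) -> dict[str, Any]:
        return {
            "n_countries": self.n_countries,
            "clusters_per_country": self.clusters_per_country,
            "births_per_cluster": self.births_per_cluster,
            "covariates": [c.to_dict() for c in self.covariates],
            "outcome": self.outcome.to_dict(),
            "cluster_re_sd": self.cluster_re_sd,
            "country_effect_sd": self.country_effect_sd,
            "weight_sigma": self.weight_sigma,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PopulationConfig":
        return cls(
            n_countries=int(d["n_countries"]),
            clusters_per_country=int(d["clusters_per_country"]),
            births_per_cluster=int(d["births_per_cluster"]),
            covariates=tuple(CovariateSpec.from_dict(c) for c in d.get("covariates", [])),
            outcome=OutcomeModel.from_dict(d["outcome"]),
            cluster_re_sd=float(d.get("cluster_re_sd", 0.0)),
            country_effect_sd=float(d.get("country_effect_sd", 0.0)),
            weight_sigma=float(d.get("weight_sigma", 0.3)),
            seed=int(d.get("seed", 0)),
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        payload = self.to_dict()
        if path.suffix in {".yaml", ".yml"}:
            path.write_text(yaml.safe_dump(payload, sort_keys=False))
        else:
            path.write_text(json.dumps(payload, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "PopulationConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in {".yaml", ".yml"} else json.loads(text)
        return cls.from_dict(data)


def default_population_config(seed: int = 0, **overrides: Any) -> PopulationConfig:
    """Desk-scale default: 40 countries x 50 clusters x 30 births (60k records)
    with covariates covering the individual- and neighbourhood-level themes of
    the analysis (education, residence, media, employment, water, child sex).
    """
    covariates = (
        CovariateSpec(
            "maternal_education",
            ("none", "primary", "secondary+"),
            p_poor=(0.50, 0.30, 0.20),
            p_non_poor=(0.20, 0.30, 0.50),
        ),
        CovariateSpec(
            "residence", ("rural", "urban"), p_poor=(0.80, 0.20), p_non_poor=(0.45, 0.55)
        ),
        CovariateSpec(
            "media_access", ("no", "yes"), p_poor=(0.55, 0.45), p_non_poor=(0.25, 0.75)
        ),
        CovariateSpec(
            "maternal_employment",
            ("unemployed", "employed"),
            p_poor=(0.50, 0.50),
            p_non_poor=(0.40, 0.60),
        ),
        CovariateSpec(
            "water_source",
            ("unimproved", "improved"),
            p_poor=(0.40, 0.60),
            p_non_poor=(0.15, 0.85),
        ),
        CovariateSpec(
            "sex_child", ("female", "male"), p_poor=(0.49, 0.51), p_non_poor=(0.49, 0.51)
        ),
    )
    outcome = OutcomeModel(
        intercept=-3.4,
        poor_effect=0.20,
        covariate_effects={
            "maternal_education": {"none": 0.45, "primary": 0.20},
            "residence": {"rural": 0.30},
            "media_access": {"no": 0.15},
            "water_source": {"unimproved": 0.20},
            "sex_child": {"male": 0.10},
        },
    )
    params: dict[str, Any] = dict(
        n_countries=40,
        clusters_per_country=50,
        births_per_cluster=30,
        covariates=covariates,
        outcome=outcome,
        cluster_re_sd=0.25,
        country_effect_sd=0.15,
        weight_sigma=0.3,
        seed=seed,
    )
    params.update(overrides)
    return PopulationConfig(**params)
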