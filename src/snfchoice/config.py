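"""Configuration objects for the synthetic generator and the pipeline."""

from __future__ import annotations

from typing import Dict, Optional, Tuple

from pydantic import BaseModel, Field, field_validator, model_validator

#: SNF attributes entering the choice model, in reporting order.
ATTRIBUTES: Tuple[str, ...] = (
    "preferred",
    "star_rating",
    "dist_home_km",
    "dist_hosp_km",
    "for_profit",
    "chain",
    "hospital_affiliated",
    "beds",
    "occupancy_pct",
    "pct_medicaid",
)

#: Attributes treated as continuous (standardised internally by the optimiser).
CONTINUOUS_ATTRIBUTES: Tuple[str, ...] = (
    "star_rating",
    "dist_home_km",
    "dist_hosp_km",
    "beds",
    "occupancy_pct",
    "pct_medicaid",
)


def default_true_beta() -> Dict[str, float]:
    """Main-effect coefficients of the generating choice process.

    Scales are per natural unit (km, star, bed, percentage point).
    Preferred status and proximity dominate placement, quality helps,
    structural attributes matter weakly — the ordering observational
    referral studies report.
    """
    return {
        "preferred": 1.40,
        "star_rating": 0.15,
        "dist_home_km": -0.12,
        "dist_hosp_km": -0.04,
        "for_profit": 0.00,
        "chain": 0.00,
        "hospital_affiliated": 0.20,
        "beds": 0.0010,
        "occupancy_pct": -0.005,
        "pct_medicaid": 0.000,
    }


def default_true_delta() -> Dict[str, float]:
    """OUD x attribute interaction coefficients of the generating process.

    Negative preferred and quality interactions encode the access gap
    under study: facilities' preferred status and star ratings pull
    less (quality: negatively) for patients with opioid use disorder.
    """
    return {
        "preferred": -0.15,
        "star_rating": -0.20,
        "dist_home_km": 0.00,
        "dist_hosp_km": 0.00,
        "for_profit": 0.10,
        "chain": 0.00,
        "hospital_affiliated": 0.00,
        "beds": 0.0,
        "occupancy_pct": 0.0,
        "pct_medicaid": 0.004,
    }


def default_propensity_coefs() -> Dict[str, float]:
    """Log-odds coefficients mapping patient covariates to OUD risk.

    The intercept is calibrated at generation time to hit the target
    prevalence; the slopes fix the confounding directions (younger age
    and dual eligibility predict OUD, consistent with the matched-cohort
    contrast of roughly 70 vs 79 years and 43% vs 24% dual share).
    """
    return {
        "age_per_decade": -0.35,  # centred at 75 years
        "dual_eligible": 0.70,
        "female": -0.05,
        "elixhauser": 0.03,
        "medicare_advantage": 0.05,
    }


class GeneratorConfig(BaseModel):
    """Parameters of the synthetic discharge-cohort generator.

    The defaults emulate the study conditions: ~1.2% OUD prevalence,
    a five-year discharge window preceded by one burn-in year used only
    to seed prior-year referral volumes, and a spatial layout in which
    both the 22 km radius and the 15-nearest rule bind in some markets.
    """

    seed: int = 0
    n_states: int = 4
    n_hospitals: int = 40
    n_snfs: int = 240
    n_discharges: int = 20_000
    oud_prevalence: float = 0.012
    true_beta: Dict[str, float] = Field(default_factory=default_true_beta)
    true_delta: Dict[str, float] = Field(default_factory=default_true_delta)
    propensity_coefs: Dict[str, float] = Field(default_factory=default_propensity_coefs)
    spatial_extent_km: float = 250.0
    snf_scatter_km: float = 12.0
    year_start: int = 2016  # burn-in year: no prior volumes, empty preferred sets
    year_end: int = 2021
    star_missing_rate: float = 0.03
    radius_km: float = 22.0
    k_nearest: int = 15

    @field_validator("n_states", "n_hospitals", "n_snfs", "n_discharges", "k_nearest")
    @classmethod
    def _positive_counts(cls, v: int) -> int:
        if v < 1:
            raise ValueError("counts must be >= 1")
        return v

    @field_validator("oud_prevalence")
    @classmethod
    def _open_unit_interval(cls, v: float) -> float:
        if not 0.0 < v < 1.0:
            raise ValueError("oud_prevalence must lie strictly in (0, 1)")
        return v

    @model_validator(mode="after")
    def _coherent(self) -> "GeneratorConfig":
        if self.year_end < self.year_start:
            raise ValueError("year_end must be >= year_start")
        if self.n_snfs < self.n_states:
            raise ValueError("need at least one SNF per state (choice sets undefined)")
        if self.n_hospitals < self.n_states:
            raise ValueError("need at least one hospital per state")
        missing = set(ATTRIBUTES) - set(self.true_beta)
        if missing:
            raise ValueError(f"true_beta missing attributes: {sorted(missing)}")
        missing = set(ATTRIBUTES) - set(self.true_delta)
        if missing:
            raise ValueError(f"true_delta missing attributes: {sorted(missing)}")
        return self


class PipelineConfig(BaseModel):
    """End-to-end pipeline parameters.

    Defaults are the analysis constants: 50% cumulative-volume preferred
    threshold, 22 km radius, 15 nearest facilities, 1:1 matching within
    +/-2 days, age-spline knot at the 65-year Medicare boundary,
    propensity trimming to [0.01, 0.99], and 4-5 stars as high quality.
    """

    seed: int = 0
    out_dir: str = "runs/default"
    generator: GeneratorConfig = Field(default_factory=GeneratorConfig)
    preferred_threshold: float = 0.50
    sensitivity_grid: Tuple[float, ...] = (0.10, 0.20, 0.30, 0.40, 0.60, 0.70, 0.80)
    radius_km: float = 22.0
    k_nearest: int = 15
    match_ratio: int = 1
    match_window_days: int = 2
    knot_age: float = 65.0
    trim_bounds: Tuple[float, float] = (0.01, 0.99)
    high_quality_stars: Tuple[int, ...] = (4, 5)
    iia_drop_fractions: Tuple[float, ...] = (0.05, 0.10, 0.20)
    min_quintile_choice_sets: int = 50

    @field_validator("preferred_threshold")
    @classmethod
    def _threshold_open(cls, v: float) -> float:
        if not 0.0 < v < 1.0:
            raise ValueError("preferred_threshold must lie in (0, 1)")
        return v

    @field_validator("match_ratio")
    @classmethod
    def _ratio(cls, v: int) -> int:
        if v not in (1, 2, 3):
            raise ValueError("match_ratio must be 1, 2, or 3")
        return v

    @model_validator(mode="after")
    def _sync_geometry(self) -> "PipelineConfig":
        # choice-set geometry is shared between generation and rebuild
        self.generator.radius_km = self.radius_km
        self.generator.k_nearest = self.k_nearest
        return self
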