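"""Synthetic cohort generation for person-centered profiling studies.

The study design this package targets summarizes each latent student
profile by per-variable medians and interquartile ranges (IQRs) on the
variables' native scales.  The generator reproduces that structure: each
variable is drawn independently within profile from a truncated normal
distribution whose parent is parameterized by the profile median (location)
and IQR (scale = IQR / 1.349, the normal IQR-to-sigma factor), truncated to
the variable's admissible interval.  Between-profile separation carries all
of the dependence structure; within a profile variables are independent.

Six built-in profiles (Excellers, Notables, Resilients, Moderates,
Strugglers, Socializers; sizes 29/43/29/35/38/20, total n = 194) encode the
published per-cluster medians/IQRs of the fifteen input variables, the
cognitive outcome distributions, and per-profile girl proportions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VariableDef",
    "ProfileSpec",
    "INPUT_VARIABLES",
    "OUTCOME_VARIABLES",
    "study_profiles",
    "study_outcome_specs",
    "generate_cohort",
    "generate_outcomes",
    "generate_study_cohort",
]

#: Normal-distribution IQR in units of sigma: Phi^-1(.75) - Phi^-1(.25).
IQR_TO_SIGMA = 1.3489795003921634


@dataclass(frozen=True)
class VariableDef:
    """Admissible range and type of one cohort variable."""

    name: str
    lower: float
    upper: float
    integer: bool = False
    likert_step: float | None = None

    def validate_location(self, value: float) -> None:
        if not (self.lower <= value <= self.upper):
            raise ValueError(
                f"location {value} for variable {self.name!r} lies outside "
                f"bounds [{self.lower}, {self.upper}]"
            )


# The fifteen profiling input variables on their native scales.
INPUT_VARIABLES: tuple[VariableDef, ...] = (
    VariableDef("mvpa_min_day", 0.0, math.inf),          # min/day
    VariableDef("cardio_fitness", 0.0, math.inf),        # PACER laps
    VariableDef("actual_motor_comp", 0.0, 28.0),         # CAMSA score
    VariableDef("bmi_percentile", 0.0, 100.0),
    VariableDef("self_reported_pa", 1.0, 5.0, likert_step=0.01),
    VariableDef("perceived_motor_comp", 1.0, 4.0, likert_step=0.01),
    VariableDef("perceived_phys_literacy", 1.0, 4.0, likert_step=0.01),
    VariableDef("intrinsic_motivation", 1.0, 5.0, likert_step=1 / 3),
    VariableDef("identified_motivation", 1.0, 5.0, likert_step=1 / 3),
    VariableDef("bpn_competence", 1.0, 5.0, likert_step=0.2),
    VariableDef("physical_self_concept", 1.0, 4.0, likert_step=0.01),
    VariableDef("bpn_relatedness", 1.0, 5.0, likert_step=0.2),
    VariableDef("school_enjoyment", 1.0, 5.0, likert_step=0.2),
    VariableDef("social_identity", 1.0, 7.0, likert_step=0.01),
    VariableDef("task_climate", 1.0, 5.0, likert_step=0.2),
)

OUTCOME_VARIABLES: tuple[VariableDef, ...] = (
    VariableDef("academic_achievement", 0.0, 5.0),
    VariableDef("perceived_math", 1.0, 5.0, integer=True),
    VariableDef("perceived_language", 1.0, 5.0, integer=True),
    VariableDef("math_fluency", 0.0, 160.0, integer=True),
    VariableDef("digit_span_total", 0.0, 16.0, integer=True),
    VariableDef("stroop_dot_time", 1.0, math.inf),
    VariableDef("stroop_word_time", 1.0, math.inf),
    VariableDef("stroop_color_time", 1.0, math.inf),
    VariableDef("stroop_dot_resp", 0.0, 60.0, integer=True),
    VariableDef("stroop_word_resp", 0.0, 60.0, integer=True),
    VariableDef("stroop_color_resp", 0.0, 60.0, integer=True),
)

INPUT_VARIABLE_NAMES: tuple[str, ...] = tuple(v.name for v in INPUT_VARIABLES)

_INPUT_BY_NAME = {v.name: v for v in INPUT_VARIABLES}
_OUTCOME_BY_NAME = {v.name: v for v in OUTCOME_VARIABLES}


@dataclass
class ProfileSpec:
    """Generative parameters for one latent profile.

    ``locations`` and ``spreads`` map variable names to the profile median
    and interquartile range on the native scale.  ``girl_fraction`` is the
    Bernoulli probability that a generated participant is a girl.
    """

    name: str
    size: int
    girl_fraction: float
    locations: dict[str, float]
    spreads: dict[str, float]
    variables: tuple[VariableDef, ...] = field(default=INPUT_VARIABLES)

    def __post_init__(self) -> None:
        if self.size < 0:
            raise ValueError(f"profile {self.name!r}: size must be >= 0")
        if not 0.0 <= self.girl_fraction <= 1.0:
            raise ValueError(f"profile {self.name!r}: girl_fraction not in [0,1]")
        for var in self.variables:
            if var.name not in self.locations:
                raise ValueError(
                    f"profile {self.name!r}: missing location for {var.name!r}"
                )
            var.validate_location(self.locations[var.name])
            if self.spreads.get(var.name, 0.0) < 0:
                raise ValueError(
                    f"profile {self.name!r}: negative spread for {var.name!r}"
                )

    def scaled(self, iqr_factor: float) -> "ProfileSpec":
        """Copy of the spec with every IQR multiplied by ``iqr_factor``."""
        return ProfileSpec(
            name=self.name,
            size=self.size,
            girl_fraction=self.girl_fraction,
            locations=dict(self.locations),
            spreads={k: v * iqr_factor for k, v in self.spreads.items()},
            variables=self.variables,
        )


def _solve_parent_location(
    median: float, sigma: float, lower: float, upper: float
) -> float:
    """Parent-normal location whose truncation to [lower, upper] has the
    requested median.

    For medians near a bound the exact solution may not exist; the search
    is clamped to median +/- 5 sigma, which places the realized median as
    close to the bound as the truncation geometry allows.
    """
    if not (np.isfinite(lower) or np.isfinite(upper)):
        return median

    def trunc_median(mu: float) -> float:
        a = (lower - mu) / sigma if np.isfinite(lower) else -np.inf
        b = (upper - mu) / sigma if np.isfinite(upper) else np.inf
        return float(stats.truncnorm.ppf(0.5, a, b, loc=mu, scale=sigma))

    lo_mu, hi_mu = median - 5 * sigma, median + 5 * sigma
    # trunc_median is increasing in mu; fall back to the nearer endpoint
    # when the target is unattainable (median at a hard bound).
    if trunc_median(lo_mu) >= median:
        return lo_mu
    if trunc_median(hi_mu) <= median:
        return hi_mu
    from scipy.optimize import brentq

    return float(
        brentq(lambda mu: trunc_median(mu) - median, lo_mu, hi_mu, xtol=1e-9)
    )


def _truncated_normal(
    rng: np.random.Generator,
    median: float,
    iqr: float,
    lower: float,
    upper: float,
    size: int,
) -> np.ndarray:
    """Truncated-normal draws whose median matches ``median``.

    The parent has sigma = IQR / 1.349; its location is solved so that the
    distribution truncated to [lower, upper] has the requested median
    (for unbounded variables this is just the location itself).
    """
    if iqr == 0.0:
        return np.full(size, float(np.clip(median, lower, upper)))
    sigma = iqr / IQR_TO_SIGMA
    mu = _solve_parent_location(median, sigma, lower, upper)
    a = (lower - mu) / sigma if np.isfinite(lower) else -np.inf
    b = (upper - mu) / sigma if np.isfinite(upper) else np.inf
    return stats.truncnorm.rvs(
        a, b, loc=mu, scale=sigma, size=size, random_state=rng
    )


def _draw_profile_block(
    rng: np.random.Generator,
    spec: ProfileSpec,
    variables: tuple[VariableDef, ...],
    snap_likert: bool,
) -> dict[str, np.ndarray]:
    cols: dict[str, np.ndarray] = {}
    for var in variables:
        values = _truncated_normal(
            rng,
            spec.locations[var.name],
            spec.spreads.get(var.name, 0.0),
            var.lower,
            var.upper,
            spec.size,
        )
        if var.integer:
            values = np.clip(np.rint(values), var.lower, var.upper)
        elif snap_likert and var.likert_step:
            step = var.likert_step
            values = var.lower + np.rint((values - var.lower) / step) * step
            values = np.clip(values, var.lower, var.upper)
        cols[var.name] = values
    return cols


def generate_cohort(
    specs: list[ProfileSpec],
    seed: int,
    snap_likert: bool = False,
) -> pd.DataFrame:
    """Generate a participant-level cohort table from profile specs.

    Returns a DataFrame with ``participant_id``, ``true_profile``,
    ``gender`` ('girl'/'boy') and one column per input variable.  The same
    seed always yields the identical table.
    """
    if not specs:
        raise ValueError("at least one ProfileSpec is required")
    if sum(s.size for s in specs) <= 0:
        raise ValueError("profile sizes must sum to a positive count")
    rng = np.random.default_rng(seed)
    frames = []
    offset = 0
    for spec in specs:
        cols = _draw_profile_block(rng, spec, spec.variables, snap_likert)
        gender = np.where(
            rng.random(spec.size) < spec.girl_fraction, "girl", "boy"
        )
        frame = pd.DataFrame(
            {
                "participant_id": [
                    f"P{offset + i + 1:04d}" for i in range(spec.size)
                ],
                "true_profile": spec.name,
                "gender": gender,
                **cols,
            }
        )
        frames.append(frame)
        offset += spec.size
    cohort = pd.concat(frames, ignore_index=True)
    return cohort


def generate_outcomes(
    cohort: pd.DataFrame,
    outcome_specs: dict[str, ProfileSpec],
    seed: int,
) -> pd.DataFrame:
    """Append cognitive outcome columns drawn per true profile.

    ``outcome_specs`` maps profile name to a ProfileSpec whose variables are
    OUTCOME_VARIABLES.  Integer outcomes are rounded to the nearest
    admissible value.  Raises on rows whose ``true_profile`` has no spec.
    """
    if "true_profile" not in cohort.columns:
        raise ValueError("cohort lacks true_profile labels")
    unknown = set(cohort["true_profile"]) - set(outcome_specs)
    if unknown:
        raise ValueError(f"no outcome spec for profiles: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    for var in OUTCOME_VARIABLES:
        out[var.name] = np.nan
    # Draw profile by profile in cohort order for determinism.
    for name in pd.unique(cohort["true_profile"]):
        spec = outcome_specs[name]
        mask = (cohort["true_profile"] == name).to_numpy()
        block_spec = ProfileSpec(
            name=spec.name,
            size=int(mask.sum()),
            girl_fraction=spec.girl_fraction,
            locations=spec.locations,
            spreads=spec.spreads,
            variables=OUTCOME_VARIABLES,
        )
        cols = _draw_profile_block(rng, block_spec, OUTCOME_VARIABLES, False)
        for var in OUTCOME_VARIABLES:
            out.loc[mask, var.name] = cols[var.name]
    for var in OUTCOME_VARIABLES:
        if var.integer:
            out[var.name] = out[var.name].astype(int)
    return out


# ---------------------------------------------------------------------------
# Built-in study parameterization: six profiles, n = 194.
# Per-variable entries are (median, IQR) on the native scale.

_PROFILE_TABLE: dict[str, dict[str, tuple[float, float]]] = {
    "Excellers": {
        "mvpa_min_day": (70.43, 32.0),
        "cardio_fitness": (56.0, 20.0),
        "actual_motor_comp": (22.0, 4.0),
        "bmi_percentile": (37.0, 32.4),
        "self_reported_pa": (3.48, 0.49),
        "perceived_motor_comp": (3.55, 0.3),
        "perceived_phys_literacy": (3.63, 0.23),
        "intrinsic_motivation": (5.0, 0.0),
        "identified_motivation": (5.0, 0.33),
        "bpn_competence": (4.8, 0.4),
        "physical_self_concept": (3.5, 0.5),
        "bpn_relatedness": (4.2, 0.8),
        "school_enjoyment": (3.8, 1.0),
        "social_identity": (4.56, 1.22),
        "task_climate": (4.6, 0.8),
    },
    "Notables": {
        "mvpa_min_day": (34.86, 22.2),
        "cardio_fitness": (26.0, 15.5),
        "actual_motor_comp": (21.0, 5.0),
        "bmi_percentile": (81.5, 22.5),
        "self_reported_pa": (3.42, 0.91),
        "perceived_motor_comp": (3.35, 0.45),
        "perceived_phys_literacy": (3.43, 0.28),
        "intrinsic_motivation": (5.0, 0.33),
        "identified_motivation": (5.0, 0.67),
        "bpn_competence": (4.4, 1.0),
        "physical_self_concept": (3.33, 0.5),
        "bpn_relatedness": (4.6, 0.8),
        "school_enjoyment": (4.0, 0.8),
        "social_identity": (4.56, 0.72),
        "task_climate": (4.6, 0.8),
    },
    "Resilients": {
        "mvpa_min_day": (34.0, 21.1),
        "cardio_fitness": (22.0, 15.0),
        "actual_motor_comp": (20.0, 3.0),
        "bmi_percentile": (79.5, 20.9),
        "self_reported_pa": (2.99, 0.66),
        "perceived_motor_comp": (3.15, 0.4),
        "perceived_phys_literacy": (3.17, 0.37),
        "intrinsic_motivation": (4.67, 0.67),
        "identified_motivation": (4.33, 0.67),
        "bpn_competence": (4.2, 0.6),
        "physical_self_concept": (3.0, 0.33),
        "bpn_relatedness": (3.0, 1.0),
        "school_enjoyment": (3.6, 1.0),
        "social_identity": (3.67, 0.89),
        "task_climate": (3.6, 0.8),
    },
    "Moderates": {
        "mvpa_min_day": (40.57, 22.3),
        "cardio_fitness": (28.0, 15.0),
        "actual_motor_comp": (19.0, 3.5),
        "bmi_percentile": (28.1, 25.7),
        "self_reported_pa": (3.02, 0.57),
        "perceived_motor_comp": (2.7, 0.63),
        "perceived_phys_literacy": (2.97, 0.33),
        "intrinsic_motivation": (4.67, 0.33),
        "identified_motivation": (4.33, 0.67),
        "bpn_competence": (4.0, 0.8),
        "physical_self_concept": (2.67, 0.5),
        "bpn_relatedness": (4.0, 0.6),
        "school_enjoyment": (3.4, 0.9),
        "social_identity": (4.0, 0.72),
        "task_climate": (4.0, 0.4),
    },
    "Strugglers": {
        "mvpa_min_day": (33.57, 21.4),
        "cardio_fitness": (19.0, 11.8),
        "actual_motor_comp": (19.0, 4.0),
        "bmi_percentile": (79.35, 27.2),
        "self_reported_pa": (2.30, 0.89),
        "perceived_motor_comp": (2.58, 0.44),
        "perceived_phys_literacy": (2.6, 0.52),
        "intrinsic_motivation": (3.67, 1.0),
        "identified_motivation": (3.67, 0.33),
        "bpn_competence": (3.2, 0.8),
        "physical_self_concept": (2.25, 0.63),
        "bpn_relatedness": (3.0, 1.0),
        "school_enjoyment": (2.8, 1.0),
        "social_identity": (3.22, 0.64),
        "task_climate": (3.4, 0.6),
    },
    "Socializers": {
        "mvpa_min_day": (33.88, 20.5),
        "cardio_fitness": (11.0, 6.5),
        "actual_motor_comp": (14.5, 3.25),
        "bmi_percentile": (90.6, 8.6),
        "self_reported_pa": (2.89, 0.51),
        "perceived_motor_comp": (2.53, 0.63),
        "perceived_phys_literacy": (2.75, 0.48),
        "intrinsic_motivation": (4.33, 0.75),
        "identified_motivation": (4.33, 0.67),
        "bpn_competence": (3.8, 0.65),
        "physical_self_concept": (2.67, 0.54),
        "bpn_relatedness": (4.1, 1.1),
        "school_enjoyment": (3.8, 1.2),
        "social_identity": (3.89, 0.61),
        "task_climate": (4.4, 0.61),
    },
}

_PROFILE_SIZES = {
    "Excellers": 29,
    "Notables": 43,
    "Resilients": 29,
    "Moderates": 35,
    "Strugglers": 38,
    "Socializers": 20,
}

# Girl proportions per profile.  Clusters 3-6 are reported directly
# (Resilients 69% boys; Moderates 65.7% girls; Strugglers 60.5% girls;
# Socializers 65% girls); cluster 2 is described as balanced (0.49) and
# cluster 1 is chosen so the cohort-wide expectation matches the overall
# 48.96% girl share.
_GIRL_FRACTIONS = {
    "Excellers": 0.21,
    "Notables": 0.49,
    "Resilients": 0.31,
    "Moderates": 0.657,
    "Strugglers": 0.605,
    "Socializers": 0.65,
}

# Cognitive outcomes per profile: (median, IQR).  Math fluency, digit span
# and Stroop rows follow the published per-cluster table; academic
# achievement and perceived performance medians reconstruct the reported
# ordering (profiles 1 and 4 highest achievement, profile 5 lowest;
# perceived performance flat across profiles).
_OUTCOME_TABLE: dict[str, dict[str, tuple[float, float]]] = {
    "Excellers": {
        "academic_achievement": (4.2, 0.9),
        "perceived_math": (4.0, 1.0),
        "perceived_language": (4.0, 1.0),
        "math_fluency": (26.0, 6.0),
        "digit_span_total": (5.0, 1.0),
        "stroop_dot_time": (63.9, 25.0),
        "stroop_word_time": (51.7, 19.8),
        "stroop_color_time": (64.3, 19.6),
        "stroop_dot_resp": (24.0, 1.0),
        "stroop_word_resp": (24.0, 1.0),
        "stroop_color_resp": (25.0, 3.0),
    },
    "Notables": {
        "academic_achievement": (3.9, 1.0),
        "perceived_math": (4.0, 1.0),
        "perceived_language": (4.0, 1.0),
        "math_fluency": (29.0, 8.5),
        "digit_span_total": (5.0, 1.0),
        "stroop_dot_time": (64.5, 32.1),
        "stroop_word_time": (52.1, 21.1),
        "stroop_color_time": (59.5, 28.2),
        "stroop_dot_resp": (25.0, 2.0),
        "stroop_word_resp": (25.0, 2.0),
        "stroop_color_resp": (25.0, 3.0),
    },
    "Resilients": {
        "academic_achievement": (3.9, 1.0),
        "perceived_math": (4.0, 1.0),
        "perceived_language": (4.0, 1.0),
        "math_fluency": (28.0, 7.0),
        "digit_span_total": (5.0, 1.0),
        "stroop_dot_time": (51.6, 36.3),
        "stroop_word_time": (41.5, 13.5),
        "stroop_color_time": (49.3, 26.2),
        "stroop_dot_resp": (25.0, 3.0),
        "stroop_word_resp": (25.0, 4.0),
        "stroop_color_resp": (26.0, 4.0),
    },
    "Moderates": {
        "academic_achievement": (4.1, 0.8),
        "perceived_math": (4.0, 1.0),
        "perceived_language": (4.0, 1.0),
        "math_fluency": (23.0, 9.5),
        "digit_span_total": (5.0, 1.0),
        "stroop_dot_time": (64.3, 25.7),
        "stroop_word_time": (53.5, 30.3),
        "stroop_color_time": (65.8, 31.2),
        "stroop_dot_resp": (25.0, 3.0),
        "stroop_word_resp": (25.0, 2.5),
        "stroop_color_resp": (26.0, 4.0),
    },
    "Strugglers": {
        "academic_achievement": (3.3, 1.2),
        "perceived_math": (4.0, 1.0),
        "perceived_language": (4.0, 1.0),
        "math_fluency": (21.0, 11.0),
        "digit_span_total": (4.0, 1.0),
        "stroop_dot_time": (64.5, 30.9),
        "stroop_word_time": (48.5, 27.0),
        "stroop_color_time": (58.7, 33.1),
        "stroop_dot_resp": (24.0, 2.0),
        "stroop_word_resp": (25.0, 2.0),
        "stroop_color_resp": (25.0, 3.0),
    },
    "Socializers": {
        "academic_achievement": (3.5, 1.0),
        "perceived_math": (4.0, 1.0),
        "perceived_language": (4.0, 1.0),
        "math_fluency": (21.5, 8.0),
        "digit_span_total": (5.0, 1.0),
        "stroop_dot_time": (76.1, 31.2),
        "stroop_word_time": (62.9, 30.2),
        "stroop_color_time": (74.4, 42.8),
        "stroop_dot_resp": (25.5, 1.25),
        "stroop_word_resp": (25.0, 2.0),
        "stroop_color_resp": (26.5, 1.25),
    },
}

PROFILE_NAMES: tuple[str, ...] = tuple(_PROFILE_TABLE)


def study_profiles(iqr_factor: float = 1.0) -> list[ProfileSpec]:
    """The six built-in profile specs (optionally with scaled IQRs).

    ``iqr_factor`` < 1 sharpens the profiles; 0.5 gives the well-separated
    variant used for cluster-recovery validation.
    """
    specs = []
    for name, table in _PROFILE_TABLE.items():
        specs.append(
            ProfileSpec(
                name=name,
                size=_PROFILE_SIZES[name],
                girl_fraction=_GIRL_FRACTIONS[name],
                locations={k: v[0] for k, v in table.items()},
                spreads={k: v[1] * iqr_factor for k, v in table.items()},
            )
        )
    return specs


def study_outcome_specs() -> dict[str, ProfileSpec]:
    """Built-in cognitive-outcome specs keyed by profile name."""
    out = {}
    for name, table in _OUTCOME_TABLE.items():
        out[name] = ProfileSpec(
            name=name,
            size=_PROFILE_SIZES[name],
            girl_fraction=_GIRL_FRACTIONS[name],
            locations={k: v[0] for k, v in table.items()},
            spreads={k: v[1] for k, v in table.items()},
            variables=OUTCOME_VARIABLES,
        )
    return out


def generate_study_cohort(
    seed: int,
    iqr_factor: float = 1.0,
    with_outcomes: bool = True,
    snap_likert: bool = False,
) -> pd.DataFrame:
    """One-call cohort emulating the 194-child study structure."""
    cohort = generate_cohort(study_profiles(iqr_factor), seed, snap_likert)
    if with_outcomes:
        cohort = generate_outcomes(cohort, study_outcome_specs(), seed + 1)
    return cohort
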