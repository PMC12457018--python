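"""Generator and pipeline configuration.

`GeneratorConfig` holds every generating value of the synthetic study:
standardized path coefficients of the causal graph, intraclass-correlation
targets of the repeated measures, the behavioural-syndrome residual
correlation, seasonal birth-date distribution, and the respirometry
hardware settings (flow, chamber volume, alarm schedule) used to synthesise
raw traces.  The defaults are the study conditions: coefficients are the
published standardized slopes of the path analysis and the ICC targets are
the long-term repeatabilities of the six traits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from datetime import date

import numpy as np
import yaml

__all__ = [
    "GeneratorConfig",
    "PipelineConfig",
    "PATH_COEFFICIENT_DEFAULTS",
    "ICC_DEFAULTS",
    "TRANSFORM_OFFSET_STRESS_MAX",
    "TRANSFORM_OFFSET_STRESS_INTEGRAL",
    "BEHAVIOURS",
    "MR_RESPONSES",
]

BEHAVIOURS = ("entry", "distance", "exploration")
MR_RESPONSES = ("rmr", "stress_max", "stress_integral")

# Offsets that positivise the two stress statistics before sqrt/log
# transformation (data-derived constants of the study).
TRANSFORM_OFFSET_STRESS_MAX = 9.76
TRANSFORM_OFFSET_STRESS_INTEGRAL = 25.07

# Standardized generating slopes (latent scale for the binary entry trait).
PATH_COEFFICIENT_DEFAULTS: dict[tuple[str, str], float] = {
    ("birth_date", "exploration"): 0.365,
    ("birth_date", "distance"): 0.267,
    ("birth_date", "entry"): 0.448,
    ("birth_date", "rmr"): 0.240,
    ("birth_date", "stress_max"): -0.274,
    ("birth_date", "stress_integral"): -0.316,
    ("temperature", "rmr"): -0.234,
    ("year", "rmr"): 0.723,
    # null effects: behaviours have no direct metabolic effect, food
    # abundance, age class and body mass have none either
    ("entry", "rmr"): 0.0,
    ("distance", "rmr"): 0.0,
    ("exploration", "rmr"): 0.0,
    ("entry", "stress_max"): 0.0,
    ("distance", "stress_max"): 0.0,
    ("exploration", "stress_max"): 0.0,
    ("entry", "stress_integral"): 0.0,
    ("distance", "stress_integral"): 0.0,
    ("exploration", "stress_integral"): 0.0,
    ("food", "rmr"): 0.0,
    ("food", "stress_max"): 0.0,
    ("food", "stress_integral"): 0.0,
    ("age_class", "rmr"): 0.0,
    ("age_class", "stress_max"): 0.0,
    ("age_class", "stress_integral"): 0.0,
    ("body_mass", "rmr"): 0.0,
    ("body_mass", "stress_max"): 0.0,
    ("body_mass", "stress_integral"): 0.0,
    ("temperature", "stress_max"): 0.0,
    ("temperature", "stress_integral"): 0.0,
    ("year", "stress_max"): 0.0,
    ("year", "stress_integral"): 0.0,
    ("temperature", "entry"): 0.0,
    ("temperature", "distance"): 0.0,
    ("temperature", "exploration"): 0.0,
    ("year", "entry"): 0.0,
    ("year", "distance"): 0.0,
    ("year", "exploration"): 0.0,
    ("age_class", "entry"): 0.0,
    ("age_class", "distance"): 0.0,
    ("age_class", "exploration"): 0.0,
    ("food", "entry"): 0.0,
    ("food", "distance"): 0.0,
    ("food", "exploration"): 0.0,
}

# Long-term intraclass-correlation targets (latent scale for entry).
ICC_DEFAULTS: dict[str, float] = {
    "entry": 0.512,
    "distance": 0.323,
    "exploration": 0.378,
    "rmr": 0.393,
    "stress_max": 0.097,
    "stress_integral": 0.013,
}


def _default_corr() -> np.ndarray:
    r = 0.4
    m = np.full((3, 3), r)
    np.fill_diagonal(m, 1.0)
    return m


@dataclass
class GeneratorConfig:
    """Generating values for one synthetic study.

    Cohort structure
    ----------------
    n_individuals, sessions_per_individual (1-4), survival_prob
        per-session Bernoulli survival after the first test, mirroring
        mortality-driven missingness.
    season_start, birth_mean_day, birth_date_sd, birth_window
        births are truncated-normal over the breeding window expressed in
        days since 1 July (mid-July to late November by default).

    Causal structure
    ----------------
    path_coefficients
        standardized slope per directed edge; the binary entry trait is on
        the latent logit scale.
    icc_targets
        per-trait intraclass correlation of the individual random
        intercept, after fixed effects (latent scale for entry).
    behaviour_residual_correlations
        3x3 correlation applied to the behavioural random intercepts and
        (for the two Gaussian behaviours) the session residuals — the
        behavioural syndrome.
    test_effect_sd
        SD of the shared per-test-session offset (habituation drift).

    Respirometry hardware
    ---------------------
    flow_rate (ml/min), chamber_volume (ml), trace_sampling_rate (Hz),
    baseline_minutes, pre_alarm_minutes, alarm_times (s, from recording
    start), sensor_noise_sd / sensor_offset (fractional O2), incurrent
    fractions, respiratory quotient, barometric and water-vapour pressure.
    """

    n_individuals: int = 75
    sessions_per_individual: int = 4
    survival_prob: float = 0.85
    season_start: date = date(2022, 7, 1)
    birth_mean_day: float = 78.0
    birth_date_sd: float = 30.0
    birth_window: tuple[float, float] = (14.0, 143.0)

    path_coefficients: dict = field(default_factory=lambda: dict(PATH_COEFFICIENT_DEFAULTS))
    icc_targets: dict = field(default_factory=lambda: dict(ICC_DEFAULTS))
    behaviour_residual_correlations: np.ndarray = field(default_factory=_default_corr)
    # session (habituation) drift; default 0 so that the generating process
    # coincides exactly with the causal graph the path analysis assumes — a
    # 2-level session effect is not identifiable alongside the session-aligned
    # body-mass growth trend and would violate the d-separation claims
    test_effect_sd: float = 0.0
    entry_latent_intercept: float = 1.0

    # raw measurement scales (analysis happens on standardized/transformed scales)
    rmr_mean: float = 2.66  # ml O2 / h / g^0.75
    rmr_sd: float = 0.35
    stress_max_t_mean: float = 7.0  # sqrt(% + 9.76) scale
    stress_max_t_sd: float = 1.3
    stress_integral_t_mean: float = 3.55  # log(% + 25.07) scale
    stress_integral_t_sd: float = 0.30
    temperature_mean: float = 25.0
    temperature_sd: float = 4.0
    food_mean: float = 12.0
    food_sd: float = 4.0
    distance_mean: float = 1800.0  # cm in 5 min
    distance_sd: float = 600.0
    exploration_mean: float = 35.0  # % of test time
    exploration_sd: float = 12.0
    mass_noise_sd: float = 1.0  # g, measurement noise on body mass
    size_heterogeneity: float = 0.07  # CV of individual size (growth-curve scale)
    transform_offset_stress_max: float = TRANSFORM_OFFSET_STRESS_MAX
    transform_offset_stress_integral: float = TRANSFORM_OFFSET_STRESS_INTEGRAL

    # respirometry trace settings
    trace_sampling_rate: float = 1.0  # Hz
    flow_rate: float = 700.0  # ml/min, metered wet excurrent
    chamber_volume: float = 1000.0  # ml
    baseline_minutes: float = 5.0
    pre_alarm_minutes: float = 25.0
    alarm_times: tuple[float, ...] = (1800.0, 2460.0)
    post_alarm_seconds: float = 600.0
    sensor_noise_sd: float = 2e-5
    sensor_offset: float = 2e-4
    fio2: float = 0.2095
    fico2: float = 0.0004
    respiratory_quotient: float = 0.85
    barometric_pressure: float = 101.325  # kPa
    water_vapour_pressure: float = 1.2  # kPa
    activity_bout_rate: float = 0.5  # expected bouts per discard window
    response_decay_bounds: tuple[float, float] = (3.0, 150.0)  # s

    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.behaviour_residual_correlations = np.asarray(
            self.behaviour_residual_correlations, dtype=float
        )
        if isinstance(self.season_start, str):
            self.season_start = date.fromisoformat(self.season_start)
        self.validate()

    def validate(self) -> None:
        if not 1 <= self.sessions_per_individual <= 4:
            raise ValueError("sessions_per_individual must be in 1..4")
        if not 0 < self.survival_prob <= 1:
            raise ValueError("survival_prob must be in (0, 1]")
        m = self.behaviour_residual_correlations
        if m.shape != (3, 3) or not np.allclose(m, m.T):
            raise ValueError("behaviour_residual_correlations must be symmetric 3x3")
        if np.linalg.eigvalsh(m).min() <= 1e-10:
            raise ValueError(
                "behaviour_residual_correlations is not positive definite "
                f"(eigenvalues {np.linalg.eigvalsh(m)})"
            )
        for name, icc in self.icc_targets.items():
            if not 0 <= icc < 1:
                raise ValueError(f"icc_target for {name!r} must be in [0, 1), got {icc}")
        for v in (self.birth_date_sd, self.rmr_sd, self.temperature_sd, self.flow_rate,
                  self.chamber_volume, self.trace_sampling_rate):
            if not v > 0:
                raise ValueError("scale/hardware parameters must be positive")
        discard_end = (self.baseline_minutes + 10.0) * 60.0
        for a in self.alarm_times:
            if a <= discard_end:
                raise ValueError(
                    f"alarm at {a} s falls inside the equilibration discard "
                    f"window ending {discard_end:.0f} s"
                )

    def beta(self, frm: str, to: str) -> float:
        return float(self.path_coefficients.get((frm, to), 0.0))

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["behaviour_residual_correlations"] = self.behaviour_residual_correlations.tolist()
        d["season_start"] = self.season_start.isoformat()
        d["path_coefficients"] = {f"{a}->{b}": v for (a, b), v in self.path_coefficients.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "path_coefficients" in d:
            d["path_coefficients"] = {
                tuple(k.split("->")): v for k, v in d["path_coefficients"].items()
            }
        for key in ("birth_window", "alarm_times", "response_decay_bounds"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class PipelineConfig:
    """Orchestration options for a full desk-scale study run."""

    mode: str = "simulate"  # simulate | ingest
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    n_permutations: int = 1000
    n_bootstrap: int = 500
    coarsen_intervals: tuple[int, ...] = (14, 28)
    process_traces: bool = False  # derive MR from synthetic traces vs cohort columns
    use_paper_offsets: bool = True  # fixed 9.76 / 25.07 vs |min|+eps
    input_dir: str | None = None  # ingest mode: directory holding cohort.csv
    output_dir: str = "paceline_out"
    rng_seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "ingest"):
            raise ValueError("mode must be 'simulate' or 'ingest'")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["generator"] = self.generator.to_dict()
        d["coarsen_intervals"] = list(self.coarsen_intervals)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["generator"] = GeneratorConfig.from_dict(d.get("generator", {}))
        if "coarsen_intervals" in d:
            d["coarsen_intervals"] = tuple(d["coarsen_intervals"])
        return cls(**d)
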