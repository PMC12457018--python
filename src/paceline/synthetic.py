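"""Synthetic cohorts and respirometry traces with the study's causal structure.

The generator produces (i) a cohort/session table in which seasonal birth
date drives three correlated behaviours (one through a latent logistic
threshold) and the three metabolic statistics, with individual random
intercepts tuned to intraclass-correlation targets, and (ii) raw pull-mode
respirometry traces whose first-order chamber washout, alarm-locked
peak-decay responses and sensor noise reproduce each session's metabolic
statistics when processed by :mod:`paceline.respirometry`.

Responses are built on the analysis scale (standardized; sqrt/log
transformed for the stress statistics) so that a standardized mixed-model
coefficient estimated downstream is directly comparable to the generating
slope, then back-transformed to raw measurement units for the tables.
Total variance on the analysis scale is budgeted to one:

    1 = beta' Sigma beta + sd_test^2 + sigma2_ind + sigma2_res,
    sigma2_ind / (sigma2_ind + sigma2_res) = ICC target,

with Sigma the analytic covariance of the standardized predictors.  For the
binary entry trait the same budget lives on the latent logit scale with
residual variance pi^2/3.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.signal import lfilter
from scipy.special import expit

from .config import GeneratorConfig, BEHAVIOURS, MR_RESPONSES
from .glmm import LOGIT_LINK_VARIANCE
from .growth import gompertz_mass
from .respirometry import RespTrace

__all__ = ["SyntheticBundle", "generate_cohort", "generate_trace", "generate_dataset"]

_EXOG = ("birth_date", "temperature", "year", "age_class", "food", "body_mass")

# nominal standardization for body mass at testing (adult range)
_MASS_CENTER, _MASS_SCALE = 75.0, 8.0


class VarianceBudgetError(ValueError):
    """Fixed effects and ICC target leave no residual variance."""


def _truncnorm_stats(cfg: GeneratorConfig) -> tuple[float, float]:
    lo, hi = cfg.birth_window
    a = (lo - cfg.birth_mean_day) / cfg.birth_date_sd
    b = (hi - cfg.birth_mean_day) / cfg.birth_date_sd
    mean, var = stats.truncnorm.stats(a, b, loc=cfg.birth_mean_day,
                                      scale=cfg.birth_date_sd, moments="mv")
    return float(mean), float(np.sqrt(var))


def _gaussian_components(cfg: GeneratorConfig, name: str, q_fixed: float) -> tuple[float, float]:
    resid = 1.0 - q_fixed - cfg.test_effect_sd**2
    if resid <= 0.02:
        raise VarianceBudgetError(
            f"{name}: fixed-effect variance {q_fixed:.3f} plus test-session variance "
            f"leaves residual {resid:.3f}; shrink the coefficients or the ICC target"
        )
    icc = cfg.icc_targets[name]
    return icc * resid, (1.0 - icc) * resid  # (sigma2_ind, sigma2_res)


def _predictor_cov(cfg: GeneratorConfig, behaviour_comps: dict) -> tuple[list[str], np.ndarray]:
    """Analytic covariance of the standardized MR-model predictors.

    Exogenous covariates are mutually independent with unit variance; the
    Gaussian behaviours covary with birth date through their generating
    slopes and with each other through slopes plus correlated intercepts
    and residuals.  The binary entry trait enters with unit variance and,
    like all default-null predictors, zero modelled covariance.
    """
    names = list(_EXOG) + list(BEHAVIOURS)
    k = len(names)
    S = np.eye(k)
    R = cfg.behaviour_residual_correlations
    gauss = ("distance", "exploration")
    for bi in gauss:
        i = names.index(bi)
        S[names.index("birth_date"), i] = S[i, names.index("birth_date")] = cfg.beta("birth_date", bi)
    i, j = names.index("distance"), names.index("exploration")
    su_i, se_i = behaviour_comps["distance"]
    su_j, se_j = behaviour_comps["exploration"]
    rho = R[BEHAVIOURS.index("distance"), BEHAVIOURS.index("exploration")]
    S[i, j] = S[j, i] = (
        cfg.beta("birth_date", "distance") * cfg.beta("birth_date", "exploration")
        + rho * np.sqrt(su_i * su_j) + rho * np.sqrt(se_i * se_j)
    )
    return names, S


def generate_cohort(config: GeneratorConfig, rng: np.random.Generator | None = None
                    ) -> tuple[pd.DataFrame, dict]:
    """Simulate a cohort/session table; returns (table, true_parameters)."""
    cfg = config
    cfg.validate()
    rng = rng or np.random.default_rng(cfg.rng_seed)
    n = cfg.n_individuals
    smax = cfg.sessions_per_individual

    b_mean, b_sd = _truncnorm_stats(cfg)
    lo, hi = cfg.birth_window
    a_, b_ = (lo - cfg.birth_mean_day) / cfg.birth_date_sd, (hi - cfg.birth_mean_day) / cfg.birth_date_sd
    birth = stats.truncnorm.rvs(a_, b_, loc=cfg.birth_mean_day, scale=cfg.birth_date_sd,
                                size=n, random_state=rng)
    b_z = (birth - b_mean) / b_sd
    year = np.where(np.arange(n) % 2 == 0, 2022, 2023)
    year_code = np.where(year == 2022, -1.0, 1.0)

    # behaviour variance components (Gaussian pair) and latent entry scale
    beh_exog = [x for x in _EXOG if x != "body_mass"]
    comps = {}
    for beh in ("distance", "exploration"):
        q = sum(cfg.beta(x, beh) ** 2 for x in beh_exog)
        comps[beh] = _gaussian_components(cfg, beh, q)
    q_entry = sum(cfg.beta(x, "entry") ** 2 for x in beh_exog)
    icc_e = cfg.icc_targets["entry"]
    su2_lat = icc_e / (1.0 - icc_e) * LOGIT_LINK_VARIANCE
    denom = 1.0 - q_entry - cfg.test_effect_sd**2
    if denom <= 0.02:
        raise VarianceBudgetError("entry: latent fixed variance leaves no residual")
    T_lat = (su2_lat + LOGIT_LINK_VARIANCE) / denom  # total latent variance
    lat_scale = np.sqrt(T_lat)

    # behavioural random intercepts: correlated across the three traits
    sd_u = np.array([np.sqrt(su2_lat),
                     np.sqrt(comps["distance"][0]),
                     np.sqrt(comps["exploration"][0])])
    S_u = cfg.behaviour_residual_correlations * np.outer(sd_u, sd_u)
    u_beh = rng.multivariate_normal(np.zeros(3), S_u, size=n)
    # session residuals for the Gaussian pair, correlated
    sd_e = np.array([np.sqrt(comps["distance"][1]), np.sqrt(comps["exploration"][1])])
    rho_e = cfg.behaviour_residual_correlations[1, 2]
    S_e = np.array([[1.0, rho_e], [rho_e, 1.0]]) * np.outer(sd_e, sd_e)

    # MR variance components, using the analytic predictor covariance
    mr_names, S_pred = _predictor_cov(cfg, comps)
    mr_comps, mr_beta = {}, {}
    for mr in MR_RESPONSES:
        beta = np.array([cfg.beta(x, mr) for x in mr_names])
        q = float(beta @ S_pred @ beta)
        mr_comps[mr] = _gaussian_components(cfg, mr, q)
        mr_beta[mr] = beta
    u_mr = {mr: rng.normal(0.0, np.sqrt(mr_comps[mr][0]), n) for mr in MR_RESPONSES}

    # shared per-test-session offsets (habituation drift)
    delta = {v: rng.normal(0.0, cfg.test_effect_sd, smax) for v in
             ("distance", "exploration", *MR_RESPONSES)}
    delta["entry"] = rng.normal(0.0, cfg.test_effect_sd * lat_scale, smax)

    # session schedule: first test ~6 weeks, +2 weeks, ~20 weeks, +2 weeks
    base_ages = [42.0, 56.0, 140.0, 154.0][:smax]
    # between-individual size heterogeneity, expressed at testing age only:
    # early juvenile growth is canalized (the shared inverted curve stays
    # valid for ageing), adult size diverges
    size = 1.0 + rng.normal(0.0, cfg.size_heterogeneity, n)
    age_fc = rng.uniform(18.0, 36.0, n)
    mass_fc = np.array([gompertz_mass(a) for a in age_fc])
    mass_fc = np.minimum(mass_fc + rng.normal(0.0, cfg.mass_noise_sd, n), 64.9)

    rows = []
    for i in range(n):
        alive = True
        for s in range(smax):
            if s > 0:
                alive = alive and (rng.random() < cfg.survival_prob)
            if not alive:
                break
            age = base_ages[s] + rng.normal(0.0, 2.0)
            mass = gompertz_mass(age) * size[i] + rng.normal(0.0, 2.0)
            temp = rng.normal(cfg.temperature_mean, cfg.temperature_sd)
            food = max(np.round(rng.normal(cfg.food_mean, cfg.food_sd), 1), 0.0)
            x = {
                "birth_date": b_z[i],
                "temperature": (temp - cfg.temperature_mean) / cfg.temperature_sd,
                "year": year_code[i],
                "age_class": -1.0 if s < 2 else 1.0,
                "food": (food - cfg.food_mean) / cfg.food_sd,
                "body_mass": (mass - _MASS_CENTER) / _MASS_SCALE,
            }
            # behaviours
            eps = rng.multivariate_normal(np.zeros(2), S_e)
            dist_z = (sum(cfg.beta(k, "distance") * x[k] for k in beh_exog)
                      + u_beh[i, 1] + delta["distance"][s] + eps[0])
            expl_z = (sum(cfg.beta(k, "exploration") * x[k] for k in beh_exog)
                      + u_beh[i, 2] + delta["exploration"][s] + eps[1])
            eta = (cfg.entry_latent_intercept
                   + lat_scale * sum(cfg.beta(k, "entry") * x[k] for k in beh_exog)
                   + u_beh[i, 0] + delta["entry"][s])
            entered = float(rng.random() < expit(eta))
            xb = dict(x)
            xb.update({"entry": eta / lat_scale - cfg.entry_latent_intercept / lat_scale,
                       "distance": dist_z, "exploration": expl_z})
            mr_z = {}
            for mr in MR_RESPONSES:
                fixed = sum(mr_beta[mr][j] * xb[nm] for j, nm in enumerate(mr_names))
                mr_z[mr] = (fixed + u_mr[mr][i] + delta[mr][s]
                            + rng.normal(0.0, np.sqrt(mr_comps[mr][1])))
            rmr = cfg.rmr_mean + cfg.rmr_sd * mr_z["rmr"]
            smax_t = max(cfg.stress_max_t_mean + cfg.stress_max_t_sd * mr_z["stress_max"], 0.1)
            sint_t = cfg.stress_integral_t_mean + cfg.stress_integral_t_sd * mr_z["stress_integral"]
            rows.append({
                "individual_id": f"R{i + 1:03d}",
                "year": int(year[i]),
                "session": s + 1,
                "test_number": s,
                "age_class": "young" if s < 2 else "old",
                "age_at_test_days": age,
                "test_day": birth[i] + age,
                "body_mass_g": mass,
                "first_capture_day": birth[i] + age_fc[i],
                "first_capture_mass_g": mass_fc[i],
                "ambient_temp_C": np.round(temp, 1),
                "food_abundance": food,
                "entered_arena": entered,
                "distance_cm": max(cfg.distance_mean + cfg.distance_sd * dist_z, 0.0),
                "exploration_pct": float(np.clip(cfg.exploration_mean + cfg.exploration_sd * expl_z,
                                                 0.0, 100.0)),
                "rmr": rmr,
                "stress_max_pct": smax_t**2 - cfg.transform_offset_stress_max,
                "stress_integral_pct": float(np.exp(sint_t) - cfg.transform_offset_stress_integral),
            })
    table = pd.DataFrame(rows)
    truth = {
        "config": cfg.to_dict(),
        "birth_population_mean": b_mean,
        "birth_population_sd": b_sd,
        "true_birth_day": {f"R{i + 1:03d}": float(birth[i]) for i in range(n)},
        "latent_total_variance_entry": T_lat,
        "variance_components": {
            **{k: {"ind": v[0], "res": v[1]} for k, v in comps.items()},
            **{k: {"ind": mr_comps[k][0], "res": mr_comps[k][1]} for k in MR_RESPONSES},
            "entry": {"ind": su2_lat, "res": LOGIT_LINK_VARIANCE},
        },
    }
    return table, truth


# ---------------------------------------------------------------------------
# respirometry trace synthesis


def _response_shape(tau_d: float, tau_w: float, horizon: float = 60.0) -> tuple[float, float]:
    """Peak and [0, horizon] integral of exp(-t/tau_d) seen through a
    first-order washout with time constant tau_w (unit input amplitude)."""
    if abs(tau_d - tau_w) < 1e-6:
        tau_d = tau_w * (1.0 + 1e-5)
    c = tau_d / (tau_d - tau_w)
    t_peak = np.log(tau_d / tau_w) / (1.0 / tau_w - 1.0 / tau_d)
    peak = c * (np.exp(-t_peak / tau_d) - np.exp(-t_peak / tau_w))
    integ = c * (tau_d * (1.0 - np.exp(-horizon / tau_d)) - tau_w * (1.0 - np.exp(-horizon / tau_w)))
    return peak, integ


def _solve_response(stress_max_pct: float, stress_integral_pct: float, resting_ml_h: float,
                    tau_w: float, bounds: tuple[float, float]) -> tuple[float, float]:
    """Amplitude (ml/h) and decay constant (s) of the alarm-locked VO2 pulse
    whose washed-out image matches the two stress targets (clamped to the
    shape family's feasible range)."""
    m = stress_max_pct / 100.0 * resting_ml_h
    q = stress_integral_pct / 100.0 * resting_ml_h
    lo, hi = bounds
    if stress_max_pct <= 0.5:  # negligible or negative response: flat decay
        tau_d = 25.0
        peak, _ = _response_shape(tau_d, tau_w)
        return m / peak, tau_d
    ratio = np.clip(q / m if m > 0 else 0.5, 1e-3, 0.999)

    def f(tau_d):
        peak, integ = _response_shape(tau_d, tau_w)
        return integ / (60.0 * peak) - ratio

    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        tau_d = lo if abs(flo) < abs(fhi) else hi
    else:
        tau_d = optimize.brentq(f, lo, hi, xtol=1e-3)
    peak, _ = _response_shape(tau_d, tau_w)
    return m / peak, tau_d


def generate_trace(session_params: dict, config: GeneratorConfig,
                   seed: int | np.random.SeedSequence = 0) -> RespTrace:
    """Synthesise one raw respirometry recording.

    ``session_params`` needs ``rmr`` (ml O2/h/g^0.75), ``body_mass_g`` and
    the two stress percentages.  The animal's VO2 profile — resting level,
    optional activity bouts during the equilibration discard, and an
    instantaneous-rise/exponential-decay pulse at each alarm — is passed
    through the chamber's first-order washout (time constant
    chamber_volume/flow); excurrent fractions follow the exact pull-mode
    mass balance with the configured respiratory quotient, plus a constant
    sensor offset and additive Gaussian noise.
    """
    cfg = config
    rng = np.random.default_rng(seed)
    dt = 1.0 / cfg.trace_sampling_rate
    discard_end = (cfg.baseline_minutes + 10.0) * 60.0
    for a in cfg.alarm_times:
        if a <= discard_end:
            raise ValueError(f"alarm at {a:.0f} s inside the discard window (< {discard_end:.0f} s)")
    t_end = max(cfg.alarm_times) + cfg.post_alarm_seconds + 40.0
    t = np.arange(0.0, t_end, dt)

    mass = float(session_params["body_mass_g"])
    resting = float(session_params["rmr"]) * mass**0.75  # ml/h whole animal
    flow_dry = cfg.flow_rate * (cfg.barometric_pressure - cfg.water_vapour_pressure) / cfg.barometric_pressure
    tau_w = cfg.chamber_volume / flow_dry * 60.0  # s

    vo2 = np.full_like(t, resting)
    # activity bouts confined to the equilibration discard
    n_bouts = rng.poisson(cfg.activity_bout_rate)
    base_end = cfg.baseline_minutes * 60.0
    for _ in range(n_bouts):
        start = rng.uniform(base_end, discard_end - 120.0)
        dur = rng.uniform(30.0, 90.0)
        vo2[(t >= start) & (t < start + dur)] += rng.uniform(0.2, 0.6) * resting
    amp, tau_d = _solve_response(
        float(session_params.get("stress_max_pct", 0.0)),
        float(session_params.get("stress_integral_pct", 0.0)),
        resting, tau_w, cfg.response_decay_bounds,
    )
    for a in cfg.alarm_times:
        after = t >= a
        vo2[after] += amp * np.exp(-(t[after] - a) / tau_d)

    # chamber gas dynamics (exact pull-mode mass balance, first-order washout)
    v_min = vo2 / 60.0  # ml/min
    vco2_min = cfg.respiratory_quotient * v_min
    f_in = flow_dry + v_min - vco2_min
    ss_o2 = (f_in * cfg.fio2 - v_min) / flow_dry
    ss_co2 = (f_in * cfg.fico2 + vco2_min) / flow_dry
    alpha = np.exp(-dt / tau_w)

    def washout(ss: np.ndarray, init: float) -> np.ndarray:
        out, _ = lfilter([1.0 - alpha], [1.0, -alpha], ss, zi=[alpha * init])
        return out

    ch_o2 = washout(ss_o2, cfg.fio2)
    ch_co2 = washout(ss_co2, cfg.fico2)

    is_base = t < base_end
    feo2 = np.where(is_base, cfg.fio2, ch_o2) + cfg.sensor_offset
    feco2 = np.where(is_base, cfg.fico2, ch_co2) + cfg.sensor_offset / 10.0
    if cfg.sensor_noise_sd > 0:
        feo2 = feo2 + rng.normal(0.0, cfg.sensor_noise_sd, len(t))
        feco2 = feco2 + rng.normal(0.0, cfg.sensor_noise_sd / 2.0, len(t))
    return RespTrace(
        t=t,
        FeO2=feo2,
        FeCO2=feco2,
        FiO2=cfg.fio2,
        FiCO2=cfg.fico2,
        flow=np.full_like(t, cfg.flow_rate),
        channel=np.where(is_base, "baseline", "test"),
        events=cfg.alarm_times,
        WVP=cfg.water_vapour_pressure,
        BP=cfg.barometric_pressure,
        name=str(session_params.get("name", "synthetic")),
    )


@dataclass
class SyntheticBundle:
    """Cohort table + per-session traces + every generating value."""

    cohort: pd.DataFrame
    traces: dict
    true_parameters: dict

    def save(self, directory) -> None:
        d = Path(directory)
        (d / "traces").mkdir(parents=True, exist_ok=True)
        self.cohort.to_csv(d / "cohort.csv", index=False)
        with open(d / "true_parameters.json", "w") as fh:
            json.dump(self.true_parameters, fh, indent=1, default=float)
        for (ind, session), trace in self.traces.items():
            trace.to_frame().to_csv(d / "traces" / f"{ind}_s{session}.csv", index=False)

    @classmethod
    def load(cls, directory) -> "SyntheticBundle":
        d = Path(directory)
        cohort = pd.read_csv(d / "cohort.csv")
        with open(d / "true_parameters.json") as fh:
            truth = json.load(fh)
        traces = {}
        for f in sorted((d / "traces").glob("*.csv")):
            ind, s = f.stem.rsplit("_s", 1)
            traces[(ind, int(s))] = RespTrace.from_frame(pd.read_csv(f), name=f.stem)
        return cls(cohort=cohort, traces=traces, true_parameters=truth)


def generate_dataset(config: GeneratorConfig, with_traces: bool = True) -> SyntheticBundle:
    """Full reproducible bundle: cohort, traces and true parameters."""
    ss = np.random.SeedSequence(config.rng_seed)
    cohort_seed, trace_root = ss.spawn(2)
    cohort, truth = generate_cohort(config, np.random.default_rng(cohort_seed))
    traces = {}
    if with_traces:
        trace_ss = trace_root.spawn(len(cohort))
        for (idx, row), child in zip(cohort.iterrows(), trace_ss):
            params = {
                "rmr": row["rmr"],
                "body_mass_g": row["body_mass_g"],
                "stress_max_pct": row["stress_max_pct"],
                "stress_integral_pct": row["stress_integral_pct"],
                "name": f"{row['individual_id']}_s{row['session']}",
            }
            traces[(row["individual_id"], int(row["session"]))] = generate_trace(
                params, config, seed=child
            )
    return SyntheticBundle(cohort=cohort, traces=traces, true_parameters=truth)
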