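"""Repeatability, permutation inference and the behaviour-metabolism models.

Repeatability (intraclass correlation) is estimated from mixed-model
variance components after adjusting for the number of prior tests:
R = s2_ind / (s2_ind + s2_res) for Gaussian traits, and the latent-scale
R = s2_ind / (s2_ind + pi^2/3) for the binary entry trait.  Confidence
intervals come from a parametric bootstrap (refit on data simulated from
the fitted model); p-values from Monte Carlo permutation of
individual-identity labels.  Fixed-effect permutation p-values shuffle the
response vector against the fixed design.

`association_models` runs the nine single-predictor mixed models (three
behaviours x three metabolic responses) with an individual random
intercept, standardized slopes and permutation p-values — deliberately
omitting birth date and every other covariate, to expose the marginal
(confounded) behaviour-metabolism association.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (
    BEHAVIOURS,
    MR_RESPONSES,
    TRANSFORM_OFFSET_STRESS_MAX,
    TRANSFORM_OFFSET_STRESS_INTEGRAL,
)
from .glmm import BinomialLogitMixedModel, LOGIT_LINK_VARIANCE, SeparationError
from .lmm import ConvergenceError, LinearMixedModel

__all__ = [
    "ModelSpec",
    "RepeatabilityResult",
    "repeatability",
    "permutation_pvalue_fixed_effect",
    "association_models",
    "prepare_analysis_table",
    "transform_offsets",
]


@dataclass
class ModelSpec:
    """Shape of one mixed model: response, fixed terms, random intercepts."""

    response: str
    fixed_terms: list[str] = field(default_factory=list)
    random_intercept_groups: list[str] = field(default_factory=lambda: ["individual_id"])
    family: str = "gaussian"  # gaussian | binomial-logit
    categorical: tuple[str, ...] = ()

    def build(self, data: pd.DataFrame):
        cls = LinearMixedModel if self.family == "gaussian" else BinomialLogitMixedModel
        return cls.from_dataframe(
            data, self.response, self.fixed_terms, self.random_intercept_groups,
            categorical=self.categorical,
        )


@dataclass
class RepeatabilityResult:
    """Intraclass correlation with bootstrap CI and permutation p."""

    R: float
    ci95: tuple[float, float]
    p_perm: float
    n_permutations: int
    scale: str  # "original" (gaussian) | "latent" (binomial)
    n_individuals: int
    n_observations: int

    def __str__(self) -> str:
        return (f"R = {self.R:.3f} (95% CI {self.ci95[0]:.3f}-{self.ci95[1]:.3f}), "
                f"p = {self.p_perm:.4g} [{self.n_permutations} permutations, "
                f"{self.n_individuals} ind / {self.n_observations} obs, {self.scale} scale]")


def _icc_from_fit(fit, group: str, family: str) -> float:
    s_ind = fit.vc[group]
    if family == "gaussian":
        denom = s_ind + fit.sigma2_resid
    else:
        denom = s_ind + LOGIT_LINK_VARIANCE
    return float(s_ind / denom) if denom > 0 else 0.0


def repeatability(
    spec: ModelSpec,
    data: pd.DataFrame,
    n_perm: int = 10_000,
    n_boot: int = 1000,
    seed: int | np.random.SeedSequence = 0,
) -> RepeatabilityResult:
    """GLMM-based intraclass correlation of ``spec.response``.

    The identity labels are permuted across observations for the p-value
    (a permuted dataset has no true individual signal); the CI refits the
    model on parametric-bootstrap resamples.  Requires repeated measures.
    """
    group = spec.random_intercept_groups[0]
    counts = data[group].value_counts()
    if (counts < 2).all():
        raise ValueError("repeatability undefined: every individual observed once")
    rng = np.random.default_rng(seed)
    model = spec.build(data)
    fit = model.fit()
    r_obs = _icc_from_fit(fit, group, spec.family)

    # parametric bootstrap CI; refits that separate or fail to converge are
    # dropped (finite-sample artifacts of the dummy-coded test factor)
    boots, failed_boot = [], 0
    for _ in range(n_boot):
        y_sim = fit.simulate(rng)
        try:
            sim_fit = type(model)(y_sim, model.exog, _groups_of(model),
                                  model.exog_names).fit()
        except (SeparationError, ConvergenceError):
            failed_boot += 1
            continue
        boots.append(_icc_from_fit(sim_fit, group, spec.family))
    if failed_boot > n_boot // 2:
        raise RuntimeError(f"parametric bootstrap failed in {failed_boot}/{n_boot} refits")
    ci = tuple(np.quantile(boots, [0.025, 0.975]))

    # identity-label permutation p-value
    labels = data[group].to_numpy()
    exceed, n_used = 0, 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        groups = _groups_of(model)
        groups[group] = perm
        try:
            perm_fit = type(model)(model.endog, model.exog, groups, model.exog_names).fit()
        except (SeparationError, ConvergenceError):
            continue
        n_used += 1
        if _icc_from_fit(perm_fit, group, spec.family) >= r_obs:
            exceed += 1
    if n_used < n_perm // 2:
        raise RuntimeError(f"permutation refits failed in {n_perm - n_used}/{n_perm} cases")
    p = (exceed + 1) / (n_used + 1)
    return RepeatabilityResult(
        R=r_obs, ci95=(float(ci[0]), float(ci[1])), p_perm=float(p),
        n_permutations=n_perm, scale="latent" if spec.family != "gaussian" else "original",
        n_individuals=int(data[group].nunique()), n_observations=len(data),
    )


def _groups_of(model) -> dict:
    if isinstance(model, LinearMixedModel):
        return {name: model._levels[k][model._codes[k]] for k, name in enumerate(model.group_names)}
    groups = {model.group_names[0]: model._lev1[model._c1]}
    if model._q2:
        groups[model.group_names[1]] = model._lev2[model._c2]
    return groups


def permutation_pvalue_fixed_effect(
    spec: ModelSpec,
    data: pd.DataFrame,
    term: str,
    n_perm: int = 10_000,
    seed: int | np.random.SeedSequence = 0,
) -> float:
    """Two-sided Monte Carlo permutation p-value for one fixed-effect slope.

    The response vector is shuffled across rows (design and grouping held
    fixed), the model refitted, and |beta| compared with the observed one;
    p = (#{|beta_perm| >= |beta_obs|} + 1) / (n_perm + 1).
    """
    import warnings

    if term not in spec.fixed_terms:
        raise ValueError(f"term {term!r} not among fixed terms {spec.fixed_terms}")
    if n_perm < 100:
        warnings.warn(f"n_perm = {n_perm} is low for a stable permutation p-value",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    model = spec.build(data)
    j = model.exog_names.index(term)
    b_obs = abs(model.fit().params[j])
    groups = _groups_of(model)
    exceed = 0
    for _ in range(n_perm):
        y_perm = rng.permutation(model.endog)
        b = abs(type(model)(y_perm, model.exog, groups, model.exog_names).fit().params[j])
        if b >= b_obs:
            exceed += 1
    return (exceed + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# analysis-scale preparation and the nine association models


def transform_offsets(cohort: pd.DataFrame, use_paper_offsets: bool = True,
                      eps: float = 0.01) -> tuple[float, float]:
    """Offsets positivising the stress statistics before sqrt/log.

    Defaults to the study's fixed constants; otherwise |min| + eps is
    derived from the data at hand.
    """
    if use_paper_offsets:
        return TRANSFORM_OFFSET_STRESS_MAX, TRANSFORM_OFFSET_STRESS_INTEGRAL
    off_max = max(0.0, -float(cohort["stress_max_pct"].min())) + eps
    off_int = max(0.0, -float(cohort["stress_integral_pct"].min())) + eps
    return off_max, off_int


def _zscore(x: pd.Series) -> pd.Series:
    return (x - x.mean()) / x.std(ddof=1)


def prepare_analysis_table(
    cohort: pd.DataFrame,
    birth_column: str = "birth_date_numeric",
    use_paper_offsets: bool = True,
) -> pd.DataFrame:
    """Standardized / transformed session table for all model fitting.

    Continuous variables are z-scored; the two-level factors year and age
    class are coded -1/+1 and left unscaled; the stress statistics are
    positivised and sqrt- (maximum) or log- (integral) transformed before
    scaling.  The binary entry trait is kept 0/1 for binomial modelling and
    additionally provided z-scored for use as a predictor.
    """
    off_max, off_int = transform_offsets(cohort, use_paper_offsets)
    smax = cohort["stress_max_pct"] + off_max
    sint = cohort["stress_integral_pct"] + off_int
    if (smax <= 0).any() or (sint <= 0).any():
        raise ValueError(
            "transform offsets leave non-positive stress values; "
            "use data-derived offsets (use_paper_offsets=False)"
        )
    out = pd.DataFrame({
        "individual_id": cohort["individual_id"],
        "test_number": cohort["test_number"],
        "session": cohort["session"],
        "year_code": np.where(cohort["year"] == cohort["year"].min(), -1.0, 1.0)
        if cohort["year"].nunique() > 1 else 0.0,
        "age_code": np.where(cohort["age_class"] == "young", -1.0, 1.0),
        "entry": cohort["entered_arena"].astype(float),
        "entry_z": _zscore(cohort["entered_arena"].astype(float)),
        "distance_z": _zscore(cohort["distance_cm"]),
        "exploration_z": _zscore(cohort["exploration_pct"]),
        "rmr_z": _zscore(cohort["rmr"]),
        "stress_max_z": _zscore(np.sqrt(smax)),
        "stress_integral_z": _zscore(np.log(sint)),
        "temperature_z": _zscore(cohort["ambient_temp_C"]),
        "food_z": _zscore(cohort["food_abundance"]),
        "mass_z": _zscore(cohort["body_mass_g"]),
        "birth_z": _zscore(cohort[birth_column]),
    })
    return out


_BEHAVIOUR_COLUMNS = {"entry": "entry_z", "distance": "distance_z", "exploration": "exploration_z"}
_MR_COLUMNS = {"rmr": "rmr_z", "stress_max": "stress_max_z", "stress_integral": "stress_integral_z"}


def association_models(
    analysis: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """The nine marginal behaviour-metabolism mixed models.

    One standardized behaviour predictor per model against one metabolic
    response, individual random intercept, no other covariates.  Returns a
    tidy table (behaviour, response, beta, se, p_perm).
    """
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    children = iter(ss.spawn(9))
    rows = []
    for mr in MR_RESPONSES:
        for beh in BEHAVIOURS:
            spec = ModelSpec(
                response=_MR_COLUMNS[mr],
                fixed_terms=[_BEHAVIOUR_COLUMNS[beh]],
                random_intercept_groups=["individual_id"],
            )
            fit = spec.build(analysis).fit()
            j = fit.exog_names.index(_BEHAVIOUR_COLUMNS[beh])
            p = permutation_pvalue_fixed_effect(
                spec, analysis, _BEHAVIOUR_COLUMNS[beh], n_perm=n_perm, seed=next(children)
            )
            rows.append({
                "behaviour": beh,
                "response": mr,
                "beta": float(fit.params[j]),
                "se": float(fit.bse[j]),
                "p_perm": p,
                "n_permutations": n_perm,
            })
    return pd.DataFrame(rows)
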