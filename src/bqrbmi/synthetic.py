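"""EMDHS-like synthetic child-level tables with known quantile-level truth.

The generator emulates the structure of the 2019 Ethiopia Mini DHS child
file: about 5,323 children aged 0-59 months, mothers aged 15-49, fourteen
categorical covariates with the survey's published marginal frequencies, and
a right-skewed BMI outcome whose conditional quantiles depend on the
covariates.  Covariates are drawn independently of each other (the analysis
model conditions on X, so cross-covariate dependence is not needed for
correctness testing); region shares are not published in the survey's
frequency table and use plausible round values instead.

The outcome follows a location-scale model

    y = X beta_loc + (X beta_scale) * z,

with z either standard normal or a centered ALD draw, so the *true*
quantile-level coefficient vector is known exactly: for gaussian noise it is
beta_loc + beta_scale * Phi^{-1}(tau); for ALD noise at level tau (centered
so its tau-quantile is zero) it is beta_loc itself at that tau.  That truth
is what the sampler-recovery tests compare against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .ald import DEFAULT_TAUS, ALDParams, ald_ppf, sample_ald_via_mixture
from .encoding import CategoricalSpec, ContinuousSpec, CovariateSchema, encode_design

EMDHS_SAMPLE_SIZE = 5323

#: Region shares are not printed in the survey's categorical summary table;
#: these are plausible round values for a survey that oversamples small
#: regions (they sum to 1 and are a modeling choice, not survey figures).
_REGION_PROPS = {
    "tigray": 0.09,
    "afar": 0.08,
    "amhara": 0.12,
    "oromia": 0.14,
    "somali": 0.10,
    "benishangul": 0.07,
    "snnpr": 0.13,
    "gambela": 0.06,
    "harari": 0.06,
    "addis_ababa": 0.08,
    "dire_dawa": 0.07,
}


@dataclass(frozen=True)
class OutcomeModel:
    """Location-scale truth for the synthetic BMI outcome.

    ``location_coefs`` and ``scale_coefs`` are aligned with the encoded
    design columns of the schema the covariates were generated from.  The
    scale linear predictor must be positive over the covariate support
    (checked at generation time).
    """

    location_coefs: np.ndarray
    scale_coefs: np.ndarray
    noise_tag: str = "gaussian"  # or "ald"
    tau_for_ald: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "location_coefs", np.asarray(self.location_coefs, dtype=float))
        object.__setattr__(self, "scale_coefs", np.asarray(self.scale_coefs, dtype=float))
        if self.noise_tag not in ("gaussian", "ald"):
            raise ValueError(f"unknown noise tag '{self.noise_tag}'")
        if self.noise_tag == "ald" and self.tau_for_ald is None:
            raise ValueError("ald noise requires tau_for_ald")

    def true_coefficients(self, tau: float) -> np.ndarray:
        """Exact tau-level coefficient vector implied by the model."""
        if self.noise_tag == "gaussian":
            return self.location_coefs + self.scale_coefs * stats.norm.ppf(tau)
        # centered ALD noise: its tau_for_ald-quantile is 0, so at that level
        # the truth is the location vector; other levels shift by the
        # centered-ALD quantile.
        params = ALDParams(location=0.0, scale=1.0, tau=self.tau_for_ald)
        shift = ald_ppf(tau, params)  # already centered: location 0 is the tau_for_ald-quantile
        return self.location_coefs + self.scale_coefs * shift


def default_schema() -> CovariateSchema:
    """The 16-variable schema with the survey's published marginals.

    Reference categories follow the coefficient table's reporting convention
    (male, urban, Tigray, Orthodox, poorest, no formal education, ...);
    child age spans 0-59 months and maternal age 15-49 years.
    """
    cats = [
        CategoricalSpec("sex", ("male", "female"), (0.511, 0.489), "male"),
        CategoricalSpec(
            "household_size", ("le4", "5_9", "ge10"), (0.273, 0.655, 0.072), "le4"
        ),
        CategoricalSpec(
            "n_under_five", ("lt2", "two", "three_plus"), (0.380, 0.447, 0.173), "lt2"
        ),
        CategoricalSpec("birth_type", ("singleton", "multiple"), (0.977, 0.023), "singleton"),
        CategoricalSpec("residence", ("urban", "rural"), (0.231, 0.769), "urban"),
        CategoricalSpec(
            "maternal_education",
            ("no_formal", "primary", "secondary_plus"),
            _normalize((0.547, 0.314, 0.138)),
            "no_formal",
        ),
        CategoricalSpec("marital_status", ("not_married", "married"), (0.068, 0.932), "not_married"),
        CategoricalSpec(
            "wealth_index",
            ("poorest", "poorer", "middle", "richer", "richest"),
            (0.339, 0.174, 0.139, 0.130, 0.218),
            "poorest",
        ),
        CategoricalSpec(
            "region",
            tuple(_REGION_PROPS.keys()),
            tuple(_REGION_PROPS.values()),
            "tigray",
        ),
        CategoricalSpec(
            "religion",
            ("orthodox", "protestant", "muslim", "others"),
            (0.285, 0.185, 0.510, 0.020),
            "orthodox",
        ),
        CategoricalSpec(
            "breastfeeding",
            ("ever_not_current", "never", "still"),
            _normalize((0.543, 0.042, 0.414)),
            "ever_not_current",
        ),
        CategoricalSpec("water_source", ("improved", "unimproved"), (0.615, 0.385), "improved"),
        CategoricalSpec("toilet_facility", ("improved", "unimproved"), (0.201, 0.799), "improved"),
    ]
    conts = [
        ContinuousSpec("child_age_months", 0, 59, "discrete_uniform"),
        ContinuousSpec("maternal_age_years", 15, 49, "discrete_uniform"),
    ]
    return CovariateSchema(categorical_specs=tuple(cats), continuous_specs=tuple(conts))


def small_schema() -> CovariateSchema:
    """Compact schema (child age, sex, residence) for fast recovery fixtures."""
    return CovariateSchema(
        categorical_specs=(
            CategoricalSpec("sex", ("male", "female"), (0.511, 0.489), "male"),
            CategoricalSpec("residence", ("urban", "rural"), (0.231, 0.769), "urban"),
        ),
        continuous_specs=(ContinuousSpec("child_age_months", 0, 59, "discrete_uniform"),),
    )


def _normalize(props: tuple[float, ...]) -> tuple[float, ...]:
    total = sum(props)
    return tuple(p / total for p in props)


def generate_covariates(n: int, schema: CovariateSchema, seed: int):
    """Draw n child-level rows with independent covariates per the schema."""
    import pandas as pd

    if n < 1:
        raise ValueError(f"need n >= 1 rows, got {n}")
    rng = np.random.default_rng(seed)
    data = {}
    for cont in schema.continuous_specs:
        if cont.distribution == "discrete_uniform":
            data[cont.name] = rng.integers(int(cont.low), int(cont.high) + 1, size=n).astype(float)
        else:
            data[cont.name] = rng.uniform(cont.low, cont.high, size=n)
    for cat in schema.categorical_specs:
        data[cat.name] = rng.choice(cat.labels, size=n, p=cat.proportions)
    return pd.DataFrame(data)


def generate_outcome(
    covariates,
    model: OutcomeModel,
    seed: int,
    schema: CovariateSchema | None = None,
) -> np.ndarray:
    """Simulate the BMI vector y = X beta_loc + (X beta_scale) * noise.

    For gaussian noise the implied tau-level truth is
    beta_loc + beta_scale * Phi^{-1}(tau); for ALD noise the draw is centered
    so its tau_for_ald-quantile is exactly zero.
    """
    schema = schema if schema is not None else default_schema()
    table = covariates.copy()
    table["bmi"] = 0.0  # placeholder outcome so the encoder can run
    encoded = encode_design(table, schema)
    design = encoded.design
    p = design.shape[1]
    if model.location_coefs.shape != (p,) or model.scale_coefs.shape != (p,):
        raise ValueError(f"coefficient vectors must have length {p} for this schema")

    location = design @ model.location_coefs
    scale = design @ model.scale_coefs
    bad = np.nonzero(scale <= 0)[0]
    if bad.size:
        raise ValueError(f"non-positive scale linear predictor at row {int(bad[0])}")

    n = len(covariates)
    if model.noise_tag == "gaussian":
        noise = np.random.default_rng(seed).standard_normal(n)
    else:
        params = ALDParams(location=0.0, scale=1.0, tau=model.tau_for_ald)
        noise = sample_ald_via_mixture(n, params, seed)
    return location + scale * noise


def coefficients_from_labels(schema: CovariateSchema, values: dict[str, float]) -> np.ndarray:
    """Build a design-aligned coefficient vector from a {label: value} map."""
    labels = schema.design_labels()
    unknown = set(values) - set(labels)
    if unknown:
        raise ValueError(f"labels not in the design: {sorted(unknown)}")
    return np.array([values.get(lab, 0.0) for lab in labels])


def default_outcome_model(schema: CovariateSchema | None = None) -> OutcomeModel:
    """Default BMI truth: median near 15.3 kg/m^2, age and sex effects, and a
    mild age-dependent spread so true quantile slopes fan out with tau."""
    schema = schema if schema is not None else default_schema()
    labels = set(schema.design_labels())
    loc = {"Intercept": 15.9, "child_age_months": -0.02}
    scl = {"Intercept": 1.0, "child_age_months": 0.004}
    for lab, val in [
        ("maternal_age_years", 0.01),
        ("sex:female", -0.2),
        ("residence:rural", 0.15),
    ]:
        if lab in labels:
            loc[lab] = val
    return OutcomeModel(
        location_coefs=coefficients_from_labels(schema, loc),
        scale_coefs=coefficients_from_labels(schema, scl),
        noise_tag="gaussian",
    )


#: Realistic BMI residual spread (kg/m^2).  The survey-scale percentile
#: table puts the 5th-95th percentile span of under-five BMI near 5.3
#: kg/m^2, i.e. a standard deviation of roughly 1.5.
DEFAULT_RESIDUAL_SD = 1.5


def ald_scale_for_sd(tau: float, sd: float = DEFAULT_RESIDUAL_SD) -> float:
    """ALD scale giving the noise a target standard deviation.

    The mixture eps = gamma*l + h*sqrt(l)*m has variance gamma^2 + h^2, so a
    unit-scale ALD at tail tau is enormously dispersed; fixing the sd keeps
    the synthetic BMI spread realistic across quantile levels.
    """
    from .ald import mixture_constants

    const = mixture_constants(tau)
    return sd / float(np.sqrt(const.gamma**2 + const.h**2))


def ald_outcome_model(schema: CovariateSchema, tau: float,
                      sd: float = DEFAULT_RESIDUAL_SD) -> OutcomeModel:
    """Homoscedastic ALD-noise truth at level tau with realistic BMI spread.

    The noise tau-quantile is zero, so the exact tau-level coefficient
    vector is the location vector itself.
    """
    base = default_outcome_model(schema)
    return OutcomeModel(
        location_coefs=base.location_coefs,
        scale_coefs=coefficients_from_labels(schema, {"Intercept": ald_scale_for_sd(tau, sd)}),
        noise_tag="ald",
        tau_for_ald=tau,
    )


def make_fixture(
    n: int,
    seed: int,
    schema: CovariateSchema | None = None,
    model: OutcomeModel | None = None,
    taus=DEFAULT_TAUS,
):
    """Complete test dataset plus the exact truth map the recovery tests use.

    Returns ``(table, truth, model)`` where ``table`` has the covariates and
    a ``bmi`` column and ``truth`` maps each tau to its exact coefficient
    vector.  Reproducible given the seed.
    """
    schema = schema if schema is not None else default_schema()
    model = model if model is not None else default_outcome_model(schema)
    covariates = generate_covariates(n, schema, seed)
    bmi = generate_outcome(covariates, model, seed + 1, schema)
    table = covariates.copy()
    table["bmi"] = bmi
    truth = {float(t): model.true_coefficients(float(t)) for t in taus}
    return table, truth, model


def write_fixture(table, truth, model: OutcomeModel, seed: int, csv_path, truth_path) -> None:
    """Write the fixture CSV plus a structured-text sidecar naming the truth."""
    import yaml

    table.to_csv(csv_path, index=False)
    payload = {
        "seed": int(seed),
        "noise": model.noise_tag,
        "tau_for_ald": model.tau_for_ald,
        "location_coefs": [float(v) for v in model.location_coefs],
        "scale_coefs": [float(v) for v in model.scale_coefs],
        "true_coefficients": {str(t): [float(v) for v in vec] for t, vec in truth.items()},
    }
    with open(truth_path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
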