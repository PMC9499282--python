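"""Synthetic observer: trial-by-trial simulation of the behavioural experiment.

The experiment presents dynamic CRDS/ACRDS at five eccentricities in
two depth configurations (circle-in-annulus, horizontal edge) and two
durations; in each block each of the three disparities (-28, 0, +28
arcmin) appears 40 times and the participant reports near/far plus a
binary confidence.  The generative model for a non-zero-disparity trial
is a probit-linear psychometric function of eccentricity,

    P(natural-direction response) = Phi(beta0 + beta_ecc * e),

with the eccentricity ``e`` expressed in **arc minutes** (the default
coefficient magnitudes are only dimensionally sensible on that scale;
pass ``eccentricity_unit="deg"`` to interpret slopes per degree).
Zero-disparity trials are near/far coin flips.  Default coefficients per
condition are the fitted values reported for the original experiments,
so the simulator doubles as a parameter-recovery harness for the
analysis pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .stimulus import ARCMIN_PER_DEG, REPLICA_DISPARITIES, REPLICA_ECCENTRICITIES_DEG


@dataclass(frozen=True)
class ExperimentDesign:
    """Factorial structure of one experiment."""

    name: str = "exp1"
    configurations: tuple[str, ...] = ("circle", "edge")
    durations_ms: tuple[float, ...] = (80.0, 700.0)
    eccentricities_deg: tuple[float, ...] = REPLICA_ECCENTRICITIES_DEG
    correlations: tuple[str, ...] = ("correlated", "anticorrelated")
    disparities: tuple[float, ...] = REPLICA_DISPARITIES
    repeats_per_disparity: int = 40
    participants: int = 3
    meridian: str = "horizontal_right"

    @property
    def trials_per_block(self) -> int:
        return len(self.disparities) * self.repeats_per_disparity

    @property
    def blocks_per_condition(self) -> int:
        return len(self.eccentricities_deg) * len(self.correlations)

    @property
    def n_trials(self) -> int:
        return (self.participants * len(self.configurations)
                * len(self.durations_ms) * self.blocks_per_condition
                * self.trials_per_block)


def exp1_design(**overrides) -> ExperimentDesign:
    """Both configurations, both durations, horizontal meridian."""
    return ExperimentDesign(name="exp1", meridian="horizontal_right", **overrides)


def exp2_design(**overrides) -> ExperimentDesign:
    """Short duration only, vertical meridian below fixation."""
    return ExperimentDesign(name="exp2", durations_ms=(80.0,),
                            meridian="vertical_below", **overrides)


@dataclass(frozen=True)
class GeneratingModel:
    """Probit-linear generative model for one condition.

    `beta0` is the probit intercept in natural-direction coding (positive
    = natural depth tendency); `beta_ecc` is the slope per arcmin of
    eccentricity.  `confidence_natural` / `confidence_other` are the
    probabilities of a "confident" response given that the response was
    or was not in the natural direction (zero-disparity trials use the
    latter).
    """

    beta0: float
    beta_ecc: float
    confidence_natural: float = 0.8
    confidence_other: float = 0.3

    def p_natural(self, eccentricity_arcmin: float | np.ndarray) -> np.ndarray:
        return norm.cdf(self.beta0 + self.beta_ecc * np.asarray(eccentricity_arcmin))


#: Fitted (intercept, slope-per-arcmin) coefficients per condition,
#: keyed by (experiment, configuration, duration_ms, correlation).
_PRESET_COEFFICIENTS = {
    ("exp1", "circle", 80.0, "correlated"): (5.12, -0.011),
    ("exp1", "circle", 80.0, "anticorrelated"): (-0.052, 0.0),
    ("exp1", "edge", 80.0, "correlated"): (5.89, -0.014),
    ("exp1", "edge", 80.0, "anticorrelated"): (0.916, -0.0020),
    ("exp1", "circle", 700.0, "correlated"): (4.61, -0.008),
    ("exp1", "circle", 700.0, "anticorrelated"): (-0.391, 0.0004),
    ("exp1", "edge", 700.0, "correlated"): (3.35, -0.0042),
    ("exp1", "edge", 700.0, "anticorrelated"): (1.29, -0.0022),
    ("exp2", "circle", 80.0, "correlated"): (1.50, -0.002),
    ("exp2", "circle", 80.0, "anticorrelated"): (-0.14, -0.0004),
    ("exp2", "edge", 80.0, "correlated"): (1.20, -0.0011),
    ("exp2", "edge", 80.0, "anticorrelated"): (0.89, -0.0022),
}


def condition_presets() -> dict[tuple, GeneratingModel]:
    """Default generating models for every condition of both experiments."""
    return {k: GeneratingModel(beta0=b0, beta_ecc=b1)
            for k, (b0, b1) in _PRESET_COEFFICIENTS.items()}


def get_preset(experiment: str, configuration: str, duration_ms: float,
               correlation: str) -> GeneratingModel:
    key = (experiment, configuration, float(duration_ms), correlation)
    try:
        b0, b1 = _PRESET_COEFFICIENTS[key]
    except KeyError:
        raise KeyError(f"no preset coefficients for condition {key}") from None
    return GeneratingModel(beta0=b0, beta_ecc=b1)


def simulate_trials(
    design: ExperimentDesign,
    model: GeneratingModel | dict | None = None,
    rng: int | np.random.Generator | None = None,
    eccentricity_unit: str = "arcmin",
    participant_sd: float = 0.0,
) -> pd.DataFrame:
    """Simulate every trial of a design.

    `model` may be a single :class:`GeneratingModel` (applied to every
    condition), a mapping from ``(configuration, duration_ms,
    correlation)`` to models, or ``None`` to use the experiment's preset
    coefficients.  `participant_sd` adds an optional Gaussian intercept
    jitter per participant (off by default).  Returns one row per trial
    with a nullable-boolean ``natural`` column (NA at zero disparity).
    """
    if eccentricity_unit not in ("arcmin", "deg"):
        raise ValueError("eccentricity_unit must be 'arcmin' or 'deg'")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    def model_for(cfg, dur, corr) -> GeneratingModel:
        if model is None:
            return get_preset(design.name, cfg, dur, corr)
        if isinstance(model, GeneratingModel):
            return model
        return model[(cfg, float(dur), corr)]

    rows = []
    for p in range(1, design.participants + 1):
        jitter = rng.normal(0.0, participant_sd) if participant_sd > 0 else 0.0
        for cfg in design.configurations:
            for dur in design.durations_ms:
                for ecc_deg in design.eccentricities_deg:
                    ecc_arcmin = ecc_deg * ARCMIN_PER_DEG
                    for corr in design.correlations:
                        m = model_for(cfg, dur, corr)
                        ecc = ecc_arcmin if eccentricity_unit == "arcmin" else ecc_deg
                        p_nat = float(norm.cdf(m.beta0 + jitter + m.beta_ecc * ecc))
                        for d in design.disparities:
                            for _ in range(design.repeats_per_disparity):
                                if d == 0:
                                    near = rng.random() < 0.5
                                    natural = pd.NA
                                    p_conf = m.confidence_other
                                else:
                                    natural = rng.random() < p_nat
                                    near = natural == (d > 0)
                                    p_conf = (m.confidence_natural if natural
                                              else m.confidence_other)
                                rows.append((
                                    p, cfg, dur, ecc_deg, ecc_arcmin, corr, d,
                                    "near" if near else "far",
                                    bool(rng.random() < p_conf), natural,
                                ))
    df = pd.DataFrame(rows, columns=[
        "participant", "configuration", "duration_ms", "eccentricity_deg",
        "eccentricity_arcmin", "correlation", "disparity_arcmin",
        "response", "confident", "natural",
    ])
    df["natural"] = df["natural"].astype("boolean")
    return df
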