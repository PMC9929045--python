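"""Synthetic welfare-readout cohorts with known ground truth.

The generator emulates the longitudinal structure the severity analysis
assumes: a latent per-animal distress trajectory drives four correlated
readouts — body weight (% of baseline), burrowing activity (% of baseline),
nest quality (ordinal 1–6) and a clinical distress score (ordinal, 0 = no
distress).  Two trajectory shapes are supported:

* ``acute`` — surgery-like insult: distress peaks at the nadir day (day 0,
  the first day after the intervention) and decays exponentially back to
  baseline.  The reference cohort (transmitter implantation) uses this shape.
* ``progressive`` — disease that worsens continuously (cholestasis-like):
  distress rises saturating towards its asymptote over the horizon.

Cross-variable correlation comes from a single shared per-animal random
effect on the latent scale; observation noise is additive Gaussian per
readout, with rounding and clamping for the ordinal scales.  The latent
scale is calibrated so that a latent level of 1 corresponds to the reference
cohort's peak distress — a cohort with severity S therefore lands near S on
the composite severity scale, which makes ground-truth recovery checks
direct.

Default disease profiles follow the severity ordering established for the
four gastrointestinal models (CCl4 < PDA ≈ Pancreatitis < BDL), with the
latent severities set to the published pooled composite-severity medians
(0.40, 0.61, 0.70, 1.10).  The BDL profile includes rare extreme
individuals that cross the humane endpoint (> 20% body-weight loss).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .data_model import AnimalSeries, Cohort, VariableSpec

__all__ = [
    "ModelProfile",
    "GroundTruth",
    "default_variable_specs",
    "default_profiles",
    "INTENDED_ORDERING",
    "latent_distress",
    "emit_readouts",
    "simulate_reference_cohort",
    "simulate_model_cohort",
]

#: severity ordering the default profiles are calibrated to
INTENDED_ORDERING: tuple[str, ...] = ("CCl4", "PDA", "Pancreatitis", "BDL")

#: latent-unit gains per readout: effect of one latent unit on the raw scale
DEFAULT_GAINS: dict[str, float] = {
    "body_weight": 12.0,   # percentage points lost per latent unit
    "burrowing": 60.0,     # percentage points lost per latent unit
    "nesting": 3.0,        # score points lost per latent unit
    "distress_score": 5.0, # score points gained per latent unit
}

DEFAULT_NOISE_SD: dict[str, float] = {
    "body_weight": 1.5,
    "burrowing": 8.0,
    "nesting": 0.4,
    "distress_score": 0.6,
}

REFERENCE_DAYS: tuple[int, ...] = (-2, -1, 0, 1, 2, 3, 5, 7)
DISEASE_DAYS: tuple[int, ...] = (-1, 0, 1, 2, 3, 5, 7, 10, 14, 21, 28)


def default_variable_specs(distress_max: int = 20) -> dict[str, VariableSpec]:
    """Specs for the four standard readouts.

    The distress-score range is scoresheet-specific and therefore
    configurable; 0–20 is the default.
    """
    return {
        "body_weight": VariableSpec("body_weight", "down", "percent_of_baseline", (0.0, 200.0)),
        "burrowing": VariableSpec("burrowing", "down", "percent_of_baseline", (0.0, 200.0)),
        "nesting": VariableSpec("nesting", "down", "native_ordinal", (1.0, 6.0), max_score=6),
        "distress_score": VariableSpec(
            "distress_score", "up", "native_ordinal", (0.0, float(distress_max)), max_score=distress_max
        ),
    }


@dataclass(frozen=True)
class ModelProfile:
    """Parameters of one simulated disease (or reference) model.

    severity
        Latent scale S >= 0; 1 equals the reference cohort's peak distress.
    nadir_day
        Day of peak distress for acute onset (day 0 = first post-intervention
        day).
    recovery_rate
        Exponential rate lambda > 0 per day: decay back to baseline (acute)
        or approach to the asymptote (progressive).
    onset
        ``"acute"`` or ``"progressive"``.
    noise_sd
        Per-readout additive observation noise (raw readout units).
    endpoint_fraction
        Probability that an animal is an extreme individual whose body-weight
        loss exceeds the humane endpoint (> 20%).
    days
        Measurement-day grid (irregular grids are fine).
    animal_effect_sd
        SD of the shared per-animal random effect on the latent scale.
    """

    name: str
    severity: float
    nadir_day: int = 0
    recovery_rate: float = 0.6
    onset: str = "acute"
    noise_sd: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    endpoint_fraction: float = 0.0
    days: tuple[int, ...] = DISEASE_DAYS
    animal_effect_sd: float = 0.12
    gains: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_GAINS))

    def __post_init__(self) -> None:
        if self.severity < 0:
            raise ValueError("severity must be >= 0")
        if self.recovery_rate <= 0:
            raise ValueError("recovery_rate must be > 0")
        if not 0.0 <= self.endpoint_fraction <= 1.0:
            raise ValueError("endpoint_fraction must be a probability")
        if self.onset not in ("acute", "progressive"):
            raise ValueError(f"unknown onset {self.onset!r}")
        if any(sd < 0 for sd in self.noise_sd.values()):
            raise ValueError("noise_sd must be non-negative")


@dataclass
class GroundTruth:
    """What the generator knows: per-animal latent trajectories and the
    configured severity, for recovery testing."""

    model: str
    severity: float
    latent: dict[str, np.ndarray]  # animal_id -> latent level per measurement day
    latent_peak: dict[str, float]
    endpoint_animals: list[str]


def latent_distress(day: int, profile: ModelProfile, animal_effect: float = 0.0) -> float:
    """Latent distress level on one day; never negative, zero before the
    intervention (day < 0)."""
    amplitude = max(0.0, profile.severity + animal_effect)
    if day < 0:
        return 0.0
    if profile.onset == "acute":
        return amplitude * math.exp(-profile.recovery_rate * max(0, day - profile.nadir_day))
    return amplitude * (1.0 - math.exp(-profile.recovery_rate * day))


def emit_readouts(
    latent: float,
    specs: Mapping[str, VariableSpec],
    rng: np.random.Generator,
    gains: Mapping[str, float] = DEFAULT_GAINS,
    noise_sd: Mapping[str, float] = DEFAULT_NOISE_SD,
) -> dict[str, float]:
    """Map one latent level to noisy readout values for the given specs.

    Percent readouts are emitted directly on the percent-of-baseline scale
    (noise-free latent 0 gives exactly 100); ordinal readouts are rounded and
    clamped to their valid range.
    """
    out: dict[str, float] = {}
    for name, spec in specs.items():
        g = gains[name]
        eps = rng.normal(0.0, noise_sd.get(name, 0.0)) if noise_sd.get(name, 0.0) > 0 else 0.0
        if spec.is_percent:
            lo, hi = spec.valid_range
            out[name] = float(np.clip(100.0 - g * latent + eps, lo, hi))
        elif spec.adverse_direction == "down":
            lo, hi = spec.valid_range
            out[name] = float(np.clip(round(hi - g * latent + eps), lo, hi))
        else:
            lo, hi = spec.valid_range
            out[name] = float(np.clip(round(lo + g * latent + eps), lo, hi))
    return out


def _simulate_cohort(
    profile: ModelProfile,
    n: int,
    seed: int,
    specs: Mapping[str, VariableSpec],
    provenance: str,
    subgroups: Sequence[str],
) -> tuple[Cohort, GroundTruth]:
    rng = np.random.default_rng(seed)
    days = np.asarray(profile.days, dtype=int)
    animals: list[AnimalSeries] = []
    latent_by_animal: dict[str, np.ndarray] = {}
    latent_peak: dict[str, float] = {}
    endpoint_animals: list[str] = []
    g_bw = profile.gains.get("body_weight", DEFAULT_GAINS["body_weight"])
    for i in range(n):
        animal_id = f"{profile.name}_{i + 1:03d}"
        subgroup = subgroups[i % len(subgroups)]
        effect = rng.normal(0.0, profile.animal_effect_sd)
        is_endpoint = rng.random() < profile.endpoint_fraction
        if is_endpoint:
            # extreme individual: peak body-weight loss beyond the >20% humane
            # endpoint (peak latent > 20 / gain_bw)
            peak = rng.uniform(22.0, 32.0) / g_bw
            effect = peak - profile.severity
            endpoint_animals.append(animal_id)
        latent = np.array([latent_distress(int(d), profile, effect) for d in days])
        values: dict[str, np.ndarray] = {v: np.empty(days.size) for v in specs}
        for j in range(days.size):
            row = emit_readouts(latent[j], specs, rng, profile.gains, profile.noise_sd)
            for v in specs:
                values[v][j] = row[v]
        animals.append(AnimalSeries(animal_id, profile.name, subgroup, days, values))
        latent_by_animal[animal_id] = latent
        latent_peak[animal_id] = float(latent.max())
    cohort = Cohort(animals, dict(specs), provenance=provenance, baseline_day=-1)
    truth = GroundTruth(profile.name, profile.severity, latent_by_animal, latent_peak, endpoint_animals)
    return cohort, truth


def simulate_reference_cohort(
    n: int = 10,
    variables: Sequence[str] = ("body_weight", "burrowing", "distress_score"),
    seed: int = 0,
    provenance: str = "laboratory A",
    distress_max: int = 20,
) -> tuple[Cohort, GroundTruth]:
    """Transmitter-implantation-like reference cohort.

    Acute profile with unit severity (defining the composite scale), nadir on
    day 0, recovery within about a week; baseline days −2 and −1 included.
    The 3-variable flavor (body weight, burrowing, distress score) emulates
    laboratory A; pass the 2-variable subset (body weight, burrowing) for the
    laboratory-B flavor.
    """
    if n < 2:
        raise ValueError("reference cohort needs n >= 2")
    specs = {k: v for k, v in default_variable_specs(distress_max).items() if k in variables}
    profile = ModelProfile(
        name="Reference",
        severity=1.0,
        nadir_day=0,
        recovery_rate=0.6,
        onset="acute",
        days=REFERENCE_DAYS,
    )
    return _simulate_cohort(profile, n, seed, specs, provenance, subgroups=("reference",))


def simulate_model_cohort(
    profile: ModelProfile,
    n: int,
    seed: int,
    subgroups: Sequence[str] = ("vehicle", "treated"),
    distress_max: int = 20,
) -> tuple[Cohort, GroundTruth]:
    """Disease cohort with per-animal random effects and optional extreme
    (humane-endpoint) individuals; ground truth returned alongside."""
    if n < 1:
        raise ValueError("n must be >= 1")
    specs = default_variable_specs(distress_max)
    return _simulate_cohort(profile, n, seed, specs, profile.name, subgroups)


def default_profiles() -> dict[str, ModelProfile]:
    """The four gastrointestinal disease profiles, in intended severity order.

    Latent severities equal the published pooled composite-severity medians;
    the cholestasis (BDL) profile is progressive and carries the extreme-
    individual fraction (about 2 in 30 animals reach the humane endpoint).
    """
    return {
        "CCl4": ModelProfile("CCl4", severity=0.40, recovery_rate=0.35),
        "PDA": ModelProfile("PDA", severity=0.61, recovery_rate=0.30),
        "Pancreatitis": ModelProfile("Pancreatitis", severity=0.70, recovery_rate=0.40),
        "BDL": ModelProfile(
            "BDL", severity=1.10, onset="progressive", recovery_rate=0.35, endpoint_fraction=0.067
        ),
    }
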