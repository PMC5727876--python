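"""Synthetic UGIB cohort generator.

No per-patient data is deposited with the study, so pipeline stages are
exercised on simulated cohorts built around the minimal latent structure
the published results imply: two weakly related axes of patient state.

* **Bleeding severity** drives the haemodynamic and laboratory variables
  (pulse up, systolic BP down, BUN up, haemoglobin down), the presenting
  symptoms, and the need-of-intervention outcome — so the Blatchford
  scores discriminate intervention.
* **Frailty** (age / comorbidity) drives the age distribution, cardiac and
  severe comorbidity, and 30-day death — so the pre-endoscopy Rockall
  score discriminates mortality.

Flags and outcomes follow logistic models on their axis; intercepts are
calibrated by Gauss-Hermite quadrature so large-cohort marginals hit the
published cohort frequencies (female 36.4%, melena 48.8%, syncope 3.4%,
liver disease 6.9%, heart disease 57.1%, death 4.2%, intervention
280/590). A single integer seed governs all draws; no global RNG state is
touched.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd
from scipy import optimize, special

from .fixtures import cohort_marginals

__all__ = ["VitalMap", "LogitModel", "CohortSpec", "default_spec", "generate_cohort"]

Axis = Literal["severity", "frailty"]


@dataclass(frozen=True)
class VitalMap:
    """Monotone link from latent severity to one continuous variable.

    ``value = intercept + slope * severity + Normal(0, noise_sd)``, then
    exponentiated when ``log`` is set, then truncated to ``[lo, hi]`` (the
    physiologic range keeping record invariants satisfiable).
    """

    intercept: float
    slope: float
    noise_sd: float
    lo: float
    hi: float
    log: bool = False

    def draw(self, latent: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        x = self.intercept + self.slope * latent + rng.normal(0.0, self.noise_sd, latent.size)
        if self.log:
            x = np.exp(x)
        return np.clip(x, self.lo, self.hi)


@dataclass(frozen=True)
class LogitModel:
    """Bernoulli model ``logit p = intercept + slope * axis-latent``."""

    intercept: float
    slope: float
    axis: Axis

    def prob(self, latent: np.ndarray) -> np.ndarray:
        return special.expit(self.intercept + self.slope * latent)


def _calibrated_intercept(target: float, slope: float) -> float:
    """Intercept making E[expit(a + b*X)] = target for X ~ N(0, 1)."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(80)
    weights = weights / weights.sum()

    def marginal(a: float) -> float:
        return float(weights @ special.expit(a + slope * nodes)) - target

    return float(optimize.brentq(marginal, -30.0, 30.0))


@dataclass(frozen=True)
class CohortSpec:
    """Full parameterization of the synthetic cohort model.

    ``vital_maps`` keys the four continuous variables; ``flag_logits`` and
    ``outcome_logits`` hold logistic models tied to one latent axis each;
    ``marginal_targets`` records the frequencies the defaults were
    calibrated to (used by validation, not by generation).
    """

    n: int = 590
    severity_sd: float = 1.0
    frailty_sd: float = 1.0
    female_fraction: float = 0.364
    age_band_fractions: tuple[float, float, float] = (0.281, 0.225, 0.493)
    vital_maps: dict = field(default_factory=dict)
    flag_logits: dict = field(default_factory=dict)
    outcome_logits: dict = field(default_factory=dict)
    marginal_targets: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("cohort size must be at least 2")
        if not (self.severity_sd > 0 and self.frailty_sd > 0):
            raise ValueError("latent scales must be positive")
        for name, vm in self.vital_maps.items():
            if not vm.noise_sd > 0:
                raise ValueError(f"{name}: noise_sd must be positive")
        if not 0 < self.female_fraction < 1:
            raise ValueError("female_fraction must be in (0, 1)")
        if abs(sum(self.age_band_fractions) - 1.0) > 1e-9:
            raise ValueError("age band fractions must sum to 1")

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["vital_maps"] = {k: asdict(v) for k, v in self.vital_maps.items()}
        payload["flag_logits"] = {k: asdict(v) for k, v in self.flag_logits.items()}
        payload["outcome_logits"] = {k: asdict(v) for k, v in self.outcome_logits.items()}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CohortSpec":
        with open(path) as fh:
            payload = json.load(fh)
        payload["age_band_fractions"] = tuple(payload["age_band_fractions"])
        payload["vital_maps"] = {k: VitalMap(**v) for k, v in payload["vital_maps"].items()}
        payload["flag_logits"] = {k: LogitModel(**v) for k, v in payload["flag_logits"].items()}
        payload["outcome_logits"] = {
            k: LogitModel(**v) for k, v in payload["outcome_logits"].items()
        }
        return cls(**payload)


def default_spec(n: int = 590) -> CohortSpec:
    """Package-default cohort model calibrated to the published marginals.

    Slopes are invented package defaults encoding the qualitative
    structure (intervention on the severity axis, death on the frailty
    axis); intercepts are solved so the large-n marginals equal the
    published cohort frequencies.
    """
    targets = cohort_marginals()
    flag_slopes = {
        "melena": ("severity", 0.5),
        "syncope": ("severity", 0.8),
        "hepatic_disease": ("severity", 0.4),
        "cardiac_failure": ("frailty", 0.8),
        "severe_comorbidity": ("frailty", 0.8),
    }
    target_keys = {"cardiac_failure": "cardiac_disease"}
    flag_logits = {}
    for name, (axis, slope) in flag_slopes.items():
        p = targets[target_keys.get(name, name)]
        flag_logits[name] = LogitModel(_calibrated_intercept(p, slope), slope, axis)
    outcome_logits = {
        "intervention": LogitModel(
            _calibrated_intercept(targets["intervention"], 1.6), 1.6, "severity"
        ),
        "death30": LogitModel(_calibrated_intercept(targets["death30"], 2.5), 2.5, "frailty"),
    }
    vital_maps = {
        "pulse": VitalMap(86.0, 16.0, 10.0, 40.0, 180.0),
        "sbp": VitalMap(118.0, -15.0, 12.0, 60.0, 220.0),
        "bun_mg_dl": VitalMap(3.30, 0.50, 0.35, 5.0, 150.0, log=True),
        "hb_g_dl": VitalMap(9.5, -2.0, 1.3, 4.0, 18.0),
    }
    return CohortSpec(
        n=n,
        vital_maps=vital_maps,
        flag_logits=flag_logits,
        outcome_logits=outcome_logits,
        marginal_targets=targets,
        female_fraction=targets["female"],
        age_band_fractions=(targets["age_lt60"], targets["age_60_79"], targets["age_ge80"]),
    )


def _ages_from_frailty(frailty: np.ndarray, bands: tuple[float, float, float]) -> np.ndarray:
    """Deterministic monotone map from frailty percentile to age in years.

    The percentile is split at the published age-band frequencies and
    interpolated linearly within bands 19-59, 60-79, 80-95, so age is a
    monotone function of frailty with the published band marginals.
    """
    u = special.ndtr(frailty)
    p1, p2, _ = bands
    age = np.empty(u.size)
    low = u < p1
    mid = (~low) & (u < p1 + p2)
    high = ~(low | mid)
    age[low] = 19 + (u[low] / p1) * (60 - 19)
    age[mid] = 60 + ((u[mid] - p1) / p2) * (80 - 60)
    age[high] = 80 + ((u[high] - p1 - p2) / (1 - p1 - p2)) * (96 - 80)
    return np.clip(np.floor(age).astype(int), 19, 95)


def generate_cohort(
    spec: Optional[CohortSpec] = None,
    seed: int = 0,
    *,
    keep_latent: bool = False,
) -> pd.DataFrame:
    """Draw a synthetic cohort in the patient CSV schema.

    Deterministic given ``(spec, seed)``. With ``keep_latent`` the hidden
    severity/frailty axes are appended as ``latent_severity`` /
    ``latent_frailty`` columns (used for parameter-recovery checks; never
    written by the simulate command).
    """
    if spec is None:
        spec = default_spec()
    rng = np.random.default_rng(seed)
    n = spec.n
    severity = rng.normal(0.0, spec.severity_sd, n)
    frailty = rng.normal(0.0, spec.frailty_sd, n)

    female = rng.random(n) < spec.female_fraction
    age = _ages_from_frailty(frailty, spec.age_band_fractions)

    cols: dict[str, np.ndarray] = {}
    for name, vm in spec.vital_maps.items():
        cols[name] = vm.draw(severity, rng)
    cols["hb_g_dl"] = np.clip(
        cols["hb_g_dl"] - 0.5 * female, spec.vital_maps["hb_g_dl"].lo, None
    )  # women run slightly lower haemoglobin

    latents = {"severity": severity, "frailty": frailty}
    flags = {}
    for name, model in spec.flag_logits.items():
        flags[name] = (rng.random(n) < model.prob(latents[model.axis])).astype(int)
    comorbidity = np.where(
        flags["severe_comorbidity"] == 1,
        "severe",
        np.where(flags["cardiac_failure"] == 1, "major", "none"),
    )
    outcomes = {}
    for name, model in spec.outcome_logits.items():
        outcomes[name] = (rng.random(n) < model.prob(latents[model.axis])).astype(int)

    frame = pd.DataFrame(
        {
            "age": age,
            "sex": np.where(female, "female", "male"),
            "pulse": np.round(cols["pulse"], 0),
            "sbp": np.round(cols["sbp"], 0),
            "bun_mg_dl": np.round(cols["bun_mg_dl"], 1),
            "hb_g_dl": np.round(cols["hb_g_dl"], 1),
            "melena": flags["melena"],
            "syncope": flags["syncope"],
            "hepatic_disease": flags["hepatic_disease"],
            "cardiac_failure": flags["cardiac_failure"],
            "rockall_comorbidity": comorbidity,
            "endoscopy_delay_h": np.round(rng.lognormal(2.48, 0.8, n), 1),
            "intervention": outcomes["intervention"],
            "death30": outcomes["death30"],
        }
    )
    if keep_latent:
        frame["latent_severity"] = severity
        frame["latent_frailty"] = frailty
    return frame
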