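"""Synthetic survey-like cohort generator.

Emulates the inputs of a prevalence-based healthy-longevity study of older
Europeans: a Gompertz mortality schedule over ages 50-90 (calculations
truncated at 90, so the last class is certainly fatal), a logistically
declining prevalence of freedom from limitations in activities of daily
living (ADL), and grip-strength moments with an age-linear declining mean,
constant coefficient of variation and mild negative skew.

The schedules themselves are deterministic parametric curves; the seed
drives only the grip-strength microdata sample.  What the generator does
NOT emulate: survey weighting, nonresponse, cohort effects, or any
correlation between an individual's health state in successive years —
exactly the independence assumptions of the prevalence-based model itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .chain import MortalitySchedule
from .rewards import OutcomeMomentSchedule, PrevalenceSchedule

__all__ = ["SyntheticCohortSpec", "SyntheticCohort", "generate_synthetic"]


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Parameters of the synthetic cohort.

    Mortality is Gompertz: q(x) = level * exp(slope * (x - age_start)),
    capped below 1; the last class (the truncation age) is certainly
    fatal.  The ADL-free prevalence declines logistically from ~0.98
    towards the midpoint age.  Grip strength (kg) has an age-linear mean,
    constant CV and constant (negative) skewness.  Defaults describe a
    male cohort aged 50-90.
    """

    age_start: int = 50
    age_stop: int = 90  # truncation age, inclusive
    gompertz_level: float = 0.004
    gompertz_slope: float = 0.088
    prevalence_max: float = 0.98
    prevalence_midpoint: float = 92.0
    prevalence_width: float = 7.0
    grip_mean_at_start: float = 46.0
    grip_mean_slope: float = -0.40  # kg per year of age
    grip_cv: float = 0.21
    grip_skewness: float = -0.10
    n_per_age: int = 80  # microdata sample size per age class
    sex: str = "male"
    seed: int = 20180607

    def __post_init__(self):
        if self.age_stop <= self.age_start:
            raise ValueError("age_stop must exceed age_start")
        if not 0 < self.prevalence_max <= 1:
            raise ValueError("prevalence_max must lie in (0, 1]")
        if self.grip_cv <= 0 or abs(self.grip_skewness) >= 0.99:
            raise ValueError("grip CV must be positive and |skew| < 0.99")

    @property
    def ages(self) -> np.ndarray:
        return np.arange(self.age_start, self.age_stop + 1)


@dataclass(frozen=True)
class SyntheticCohort:
    """Generated schedules plus the grip-strength microdata table."""

    mortality: MortalitySchedule
    prevalence: PrevalenceSchedule
    grip_moments: OutcomeMomentSchedule
    microdata: pd.DataFrame
    spec: SyntheticCohortSpec


def _skewnorm_params(mean, sd, skew):
    """scipy skewnorm (a, loc, scale) matching a mean/SD/skewness triple."""
    g = abs(skew)
    if g >= 0.9952:
        raise ValueError("skewnorm cannot reach |skewness| >= 0.9952")
    g23 = g ** (2.0 / 3.0)
    delta2 = (np.pi / 2.0) * g23 / (g23 + ((4.0 - np.pi) / 2.0) ** (2.0 / 3.0))
    delta = np.sign(skew) * np.sqrt(delta2)
    a = delta / np.sqrt(1.0 - delta2) if delta2 < 1 else np.inf
    scale = sd / np.sqrt(1.0 - 2.0 * delta2 / np.pi)
    loc = mean - scale * delta * np.sqrt(2.0 / np.pi)
    return a, loc, scale


def generate_synthetic(
    spec: SyntheticCohortSpec | None = None,
    outdir=None,
) -> SyntheticCohort:
    """Generate the synthetic cohort; optionally write its CSV files.

    Deterministic for a fixed spec (the seed drives the microdata draws).
    With ``outdir`` set, writes ``mortality.csv``, ``prevalence.csv``,
    ``grip_moments.csv`` and ``grip_microdata.csv`` there.
    """
    spec = spec or SyntheticCohortSpec()
    ages = spec.ages
    rel = ages - spec.age_start

    qx = np.minimum(spec.gompertz_level * np.exp(spec.gompertz_slope * rel), 0.999)
    p = 1.0 - qx
    p[-1] = 0.0  # truncation at age_stop: last class is certainly fatal
    if np.any((p[:-1] <= 0) | (p[:-1] >= 1)):
        raise ValueError("Gompertz parameters push survival out of (0, 1)")
    mortality = MortalitySchedule(tuple(int(a) for a in ages), p, open_ended=False)

    v = spec.prevalence_max / (
        1.0 + np.exp((ages - spec.prevalence_midpoint) / spec.prevalence_width)
    )
    if np.any((v < 0) | (v > 1)):
        raise ValueError("prevalence parameters leave [0, 1]")
    prevalence = PrevalenceSchedule(v)

    mean = spec.grip_mean_at_start + spec.grip_mean_slope * rel
    if np.any(mean <= 0):
        raise ValueError("grip mean must stay positive over the age range")
    sd = spec.grip_cv * mean
    m1 = mean
    m2 = mean ** 2 + sd ** 2
    m3 = mean ** 3 + 3 * mean * sd ** 2 + spec.grip_skewness * sd ** 3
    grip_moments = OutcomeMomentSchedule(m1, m2, m3)

    rng = np.random.default_rng(spec.seed)
    records = []
    for j, age in enumerate(ages):
        a, loc, scale = _skewnorm_params(mean[j], sd[j], spec.grip_skewness)
        draws = stats.skewnorm.rvs(
            a, loc=loc, scale=scale, size=spec.n_per_age, random_state=rng
        )
        draws = np.maximum(draws, 0.1)  # grip strength is positive
        records.append(pd.DataFrame({"age": int(age), "value": draws}))
    microdata = pd.concat(records, ignore_index=True)

    cohort = SyntheticCohort(mortality, prevalence, grip_moments, microdata, spec)
    if outdir is not None:
        _write_cohort(cohort, Path(outdir))
    return cohort


def _write_cohort(cohort: SyntheticCohort, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    ages = list(cohort.mortality.ages)
    pd.DataFrame({"age": ages, "qx": cohort.mortality.death}).to_csv(
        outdir / "mortality.csv", index=False, float_format="%.12g"
    )
    pd.DataFrame({"age": ages, "prevalence": cohort.prevalence.values}).to_csv(
        outdir / "prevalence.csv", index=False, float_format="%.12g"
    )
    pd.DataFrame(
        {
            "age": ages,
            "m1": cohort.grip_moments.m1,
            "m2": cohort.grip_moments.m2,
            "m3": cohort.grip_moments.m3,
        }
    ).to_csv(outdir / "grip_moments.csv", index=False, float_format="%.12g")
    cohort.microdata.to_csv(
        outdir / "grip_microdata.csv", index=False, float_format="%.12g"
    )
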