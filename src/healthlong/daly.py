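"""Disability-adjusted life years (DALYs) as a Markov chain with rewards.

DALYs combine two losses attributable to a focal cause: years of life lost
to mortality (YLL — the remaining longevity, under a reference "standard"
mortality schedule, forgone by dying of the cause) and years lost to
disability (YLD — prevalence times a severity weight in [0, 1], accumulated
over years lived).  The chain has two absorbing states: death from the
focal cause (state 1) and death from all other causes (state 2).

Reward placement:

* survival transition out of class j: Bernoulli reward, value s_j with
  probability v_j (k-th raw moment s_j**k * v_j);
* transition from class j to absorbing state 1: the k-th raw moment of
  remaining longevity under the standard schedule at class j;
* transitions to absorbing state 2, and all absorbing-origin columns: zero.

A larger mean DALY means a greater burden of the cause.  No age-weighting
or time-discounting is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chain import (
    FullTransition,
    LongevityMoments,
    MortalitySchedule,
    TransientMatrix,
    build_age_U,
    build_M,
    assemble_P,
    fundamental_matrix,
    longevity_moments,
)
from .moments import HealthStatistics, accumulate_moments, analyze
from .rewards import PrevalenceSchedule, RewardMomentSet

__all__ = [
    "SeveritySchedule",
    "DalySpec",
    "standard_longevity",
    "daly_rewards",
    "daly_chain",
    "compute_daly",
    "component_means",
]


@dataclass(frozen=True)
class SeveritySchedule:
    """Disability (severity) weight per age class, in [0, 1].

    A weight of 1 means a year with the condition is equivalent to a year
    lost to death; a weight near 0 means a negligible loss.
    """

    values: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", s)
        if s.ndim != 1 or s.size < 1:
            raise ValueError("severity must be a non-empty 1-d vector")
        if np.any(s < 0) or np.any(s > 1):
            raise ValueError("severity weights must lie in [0, 1]")

    @property
    def n_classes(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class DalySpec:
    """Inputs for a DALY calculation.

    Parameters
    ----------
    mortality
        Focal population's all-cause mortality schedule.
    cause1_death
        Per-age probability of death from the focal cause (q_j); the
        remainder 1 - p_j - q_j goes to all other causes.
    prevalence
        Prevalence of disability due to the focal cause, per age class.
    severity
        Disability weight per age class.
    standard
        Reference mortality schedule defining the years-of-life-lost
        baseline; the choice of reference is the investigator's.  Ages are
        matched class-by-class with the focal schedule (identical grids).
    """

    mortality: MortalitySchedule
    cause1_death: np.ndarray
    prevalence: PrevalenceSchedule
    severity: SeveritySchedule
    standard: MortalitySchedule

    def __post_init__(self):
        q = np.asarray(self.cause1_death, dtype=float)
        object.__setattr__(self, "cause1_death", q)
        w = self.mortality.n_classes
        if q.shape != (w,):
            raise ValueError("cause1_death must have one entry per age class")
        if np.any(q < 0):
            raise ValueError("cause-specific death probabilities must be >= 0")
        total_death = self.mortality.death
        if np.any(q > total_death + 1e-9):
            raise ValueError(
                "cause-1 death probability exceeds total death probability"
            )
        for name, n in (
            ("prevalence", self.prevalence.n_classes),
            ("severity", self.severity.n_classes),
            ("standard", self.standard.n_classes),
        ):
            if n != w:
                raise ValueError(
                    f"{name} has {n} classes but mortality has {w}; "
                    "focal and standard grids must match"
                )

    @property
    def n_classes(self) -> int:
        return self.mortality.n_classes

    @property
    def cause2_death(self) -> np.ndarray:
        return np.clip(self.mortality.death - self.cause1_death, 0.0, None)


def standard_longevity(standard: MortalitySchedule) -> LongevityMoments:
    """Moments of remaining longevity under the reference schedule."""
    U_s = build_age_U(standard)
    N_s = fundamental_matrix(U_s)
    return longevity_moments(N_s)


def daly_chain(spec: DalySpec) -> FullTransition:
    """Two-cause absorbing chain: U plus M with rows (focal, other)."""
    U = build_age_U(spec.mortality)
    q = spec.cause1_death
    total = spec.mortality.death
    # fractions of deaths by cause; degenerate classes with no deaths get 0/1
    with np.errstate(divide="ignore", invalid="ignore"):
        frac1 = np.where(total > 0, q / np.where(total > 0, total, 1.0), 0.0)
    split = np.vstack([frac1, 1.0 - frac1])
    M = build_M(spec.mortality, cause_split=split, cause_labels=("focal", "other"))
    return assemble_P(U, M)


def daly_rewards(
    spec: DalySpec,
    eta: LongevityMoments | None = None,
    max_order: int = 3,
    include_yll: bool = True,
    include_yld: bool = True,
) -> RewardMomentSet:
    """Reward moment matrices combining YLL and YLD.

    Each transition carries exactly one reward type: survival transitions
    the Bernoulli disability loss (moments s_j**k * v_j), the focal-cause
    death transition the standard-schedule longevity moments, everything
    else zero.  No disability credit is given in the step of death.  The
    ``include_*`` switches isolate one component (for reporting YLL and
    YLD separately).
    """
    if max_order > 3:
        raise ValueError("standard longevity moments are available to order 3")
    if eta is None:
        eta = standard_longevity(spec.standard)
    w = spec.n_classes
    s = w + 2
    v = spec.prevalence.values
    sev = spec.severity.values
    eta_k = (eta.eta1, eta.eta2, eta.eta3)
    mats = []
    for k in range(1, max_order + 1):
        R = np.zeros((s, s))
        if include_yld:
            R[:w, :w] = np.tile(sev ** k * v, (w, 1))  # YLD, living transitions
        if include_yll:
            # YLL on focal-cause death; impossible transitions carry none
            R[w, :w] = np.where(spec.cause1_death > 0, eta_k[k - 1], 0.0)
        mats.append(R)
    return RewardMomentSet(
        tuple(mats), n_transient=w, mode="daly", death_credit=0.0
    )


def compute_daly(spec: DalySpec, max_order: int = 3) -> HealthStatistics:
    """Statistics of lifetime DALYs for every starting age class."""
    P = daly_chain(spec)
    eta = standard_longevity(spec.standard)
    R = daly_rewards(spec, eta=eta, max_order=max_order)
    return analyze(P, R, max_order=max_order, meta={"model": "daly"})


def component_means(spec: DalySpec) -> tuple[np.ndarray, np.ndarray]:
    """Mean YLL and mean YLD per starting class.

    Obtained by zeroing the other component's rewards; the first moment is
    additive, so yll + yld equals the combined mean DALY.
    """
    P = daly_chain(spec)
    eta = standard_longevity(spec.standard)
    R_yll = daly_rewards(spec, eta=eta, max_order=1, include_yld=False)
    R_yld = daly_rewards(spec, eta=eta, max_order=1, include_yll=False)
    yll = accumulate_moments(P, R_yll, max_order=1).moment(1)
    yld = accumulate_moments(P, R_yld, max_order=1).moment(1)
    return yll, yld
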