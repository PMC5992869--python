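"""Reward moment matrices for health outcomes.

A "reward" is the health value collected on each transition of the life
course chain: a Bernoulli year of disability-free life, a severity-weighted
fraction of a year, or a quantitative measure such as grip strength in kg.
The k-th raw moments of the per-transition rewards are stored in matrices
R_k whose (i, j) entry refers to the transition from state j to state i.

Conventions (all configurable where noted):

* Rewards attach to the origin class j: every transition out of class j,
  survival and death alike, draws on the class-j prevalence or moments.
* Individuals who die during a step are credited with a fraction
  ``death_credit`` (default 1/2) of that step's reward.
* Columns whose origin is an absorbing state are zero: the dead collect
  nothing.

Two constructions of the higher binary-reward moments are offered.  The
``paper_literal`` mode sets R_3 = R_2 = R_1, treating the half-credit death
reward value as if it also were its own square and cube.  The
``moment_consistent`` mode uses strict Bernoulli raw moments, so the k-th
moment of the death-row reward is v * death_credit**k.  The two agree
everywhere except on death transitions for k >= 2; the mode in force is
recorded in every output.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np

__all__ = [
    "PrevalenceSchedule",
    "OutcomeMomentSchedule",
    "RewardMomentSet",
    "binary_rewards",
    "combine_prevalence",
    "count_groupings",
    "ordinal_binary_splits",
    "interval_rewards",
    "fixed_rewards",
    "unit_rewards",
    "MODES",
]

MODES = ("paper_literal", "moment_consistent")


@dataclass(frozen=True)
class PrevalenceSchedule:
    """Per-age-class prevalence of a binary health state, in [0, 1]."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size < 1:
            raise ValueError("prevalence must be a non-empty 1-d vector")
        if np.any(v < 0) or np.any(v > 1):
            raise ValueError("prevalences must lie in [0, 1]")

    @property
    def n_classes(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class OutcomeMomentSchedule:
    """First three empirical raw moments of a quantitative health outcome.

    ``m1[j]``, ``m2[j]``, ``m3[j]`` are the raw moments (about zero) of the
    outcome among individuals in age class j, in outcome units, units^2 and
    units^3 (e.g. kg, kg^2, kg^3 for grip strength).
    """

    m1: np.ndarray
    m2: np.ndarray
    m3: np.ndarray

    def __post_init__(self):
        for name in ("m1", "m2", "m3"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        if not (self.m1.shape == self.m2.shape == self.m3.shape):
            raise ValueError("moment vectors must have equal length")
        if self.m1.ndim != 1 or self.m1.size < 1:
            raise ValueError("moments must be non-empty 1-d vectors")
        if np.any(self.m2 < 0):
            raise ValueError("second raw moments must be nonnegative")
        if np.any(self.m2 - self.m1**2 < -1e-9):
            raise ValueError("m2 < m1^2: implied outcome variance is negative")

    @property
    def n_classes(self) -> int:
        return self.m1.size

    @classmethod
    def from_samples(cls, samples_by_class: list[np.ndarray]) -> "OutcomeMomentSchedule":
        """Raw moments computed from per-class microdata samples."""
        m = np.empty((3, len(samples_by_class)))
        for j, x in enumerate(samples_by_class):
            x = np.asarray(x, dtype=float)
            if x.size < 1:
                raise ValueError(f"age class index {j}: no observations")
            for k in range(3):
                m[k, j] = np.mean(x ** (k + 1))
        return cls(m[0], m[1], m[2])


@dataclass(frozen=True)
class RewardMomentSet:
    """Matrices R_1..R_m of raw moments of per-transition rewards.

    Entry (i, j) of ``matrices[k-1]`` is the k-th raw moment of the reward
    collected on the transition from state j to state i.  Columns whose
    origin is absorbing are zero.
    """

    matrices: tuple
    n_transient: int
    mode: str = "paper_literal"
    death_credit: float = 0.5

    def __post_init__(self):
        mats = tuple(np.asarray(R, dtype=float) for R in self.matrices)
        object.__setattr__(self, "matrices", mats)
        if not mats:
            raise ValueError("need at least one moment matrix")
        s = mats[0].shape[0]
        for R in mats:
            if R.shape != (s, s):
                raise ValueError("all R_k must be square with equal dimension")
        if not (0 < self.n_transient <= s):
            raise ValueError("n_transient out of range")
        w = self.n_transient
        for k, R in enumerate(mats, start=1):
            if np.any(R[:, w:] != 0):
                raise ValueError(
                    f"R_{k}: columns with absorbing origin must be zero"
                )

    @property
    def max_order(self) -> int:
        return len(self.matrices)

    @property
    def n_states(self) -> int:
        return self.matrices[0].shape[0]

    def R(self, k: int) -> np.ndarray:
        """The k-th moment matrix (1-based)."""
        return self.matrices[k - 1]

    def transient_block(self, k: int) -> np.ndarray:
        """R-tilde_k: the omega x omega submatrix over transient states."""
        w = self.n_transient
        return self.matrices[k - 1][:w, :w]

    def scaled(self, c: float) -> "RewardMomentSet":
        """Reward scaled by c: R_k -> c**k R_k."""
        return RewardMomentSet(
            tuple(c ** k * R for k, R in enumerate(self.matrices, start=1)),
            self.n_transient,
            mode=self.mode,
            death_credit=self.death_credit,
        )


def _reward_matrices_from_schedules(
    living: np.ndarray,
    death: np.ndarray,
    alpha: int,
    max_order: int,
) -> tuple:
    """Assemble dense R_k matrices from per-origin-class moment schedules.

    ``living[k-1, j]`` is placed in every transient row of column j,
    ``death[k-1, j]`` in every absorbing row; absorbing-origin columns are
    zero.  Density is harmless: rewards only ever enter the analysis through
    Hadamard products with P or U, which vanish on impossible transitions.
    """
    w = living.shape[1]
    s = w + alpha
    mats = []
    for k in range(max_order):
        R = np.zeros((s, s))
        R[:w, :w] = np.tile(living[k], (w, 1))
        R[w:, :w] = np.tile(death[k], (alpha, 1))
        mats.append(R)
    return tuple(mats)


def binary_rewards(
    v: PrevalenceSchedule,
    alpha: int = 1,
    mode: str = "paper_literal",
    death_credit: float = 0.5,
    max_order: int = 3,
) -> RewardMomentSet:
    """Reward matrices for a binary (Bernoulli) health outcome.

    The reward for a year lived in class j is 1 with probability v_j and 0
    otherwise; a death during the step credits ``death_credit`` (default a
    half year) of the condition.  In ``paper_literal`` mode R_2 = R_3 = R_1;
    in ``moment_consistent`` mode death-transition k-th moments are
    v_j * death_credit**k (strict Bernoulli moments of the scaled reward).
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if not 0 <= death_credit <= 1:
        raise ValueError("death_credit must lie in [0, 1]")
    vj = v.values
    w = v.n_classes
    living = np.tile(vj, (max_order, 1))  # kth moment of Bernoulli(v) is v
    if mode == "paper_literal":
        death = np.tile(vj * death_credit, (max_order, 1))
    else:
        death = np.stack(
            [vj * death_credit ** k for k in range(1, max_order + 1)]
        )
    mats = _reward_matrices_from_schedules(living, death, alpha, max_order)
    return RewardMomentSet(mats, n_transient=w, mode=mode, death_credit=death_credit)


def unit_rewards(
    omega: int,
    alpha: int = 1,
    death_credit: float = 0.5,
    mode: str = "paper_literal",
    max_order: int = 3,
) -> RewardMomentSet:
    """Total-longevity rewards: prevalence 1 in every class.

    With ``death_credit=1`` the accumulated reward equals the time to
    absorption exactly, so its moments reproduce the longevity moments.
    """
    return binary_rewards(
        PrevalenceSchedule(np.ones(omega)),
        alpha=alpha,
        mode=mode,
        death_credit=death_credit,
        max_order=max_order,
    )


def combine_prevalence(
    outcome_prevalences: list[PrevalenceSchedule],
    subset: set[int] | frozenset[int],
) -> PrevalenceSchedule:
    """Group polychotomous outcomes into a binary condition.

    The prevalence of a combination of mutually exclusive outcomes is the
    sum of the component prevalences.  The subset must be a nonempty proper
    subset of the outcomes (its complement defines the opposing condition).
    """
    n = len(outcome_prevalences)
    subset = frozenset(subset)
    if not subset or subset == frozenset(range(n)):
        raise ValueError(
            "subset must be a nonempty proper subset of the outcomes"
        )
    if not subset <= frozenset(range(n)):
        raise ValueError("subset indices out of range")
    total = np.sum([s.values for s in outcome_prevalences], axis=0)
    if np.any(total > 1 + 1e-9):
        raise ValueError("component prevalences sum to more than 1 at some age")
    combined = np.sum([outcome_prevalences[i].values for i in subset], axis=0)
    return PrevalenceSchedule(np.clip(combined, 0.0, 1.0))


def count_groupings(n: int) -> int:
    """Number of binary conditions formable from n exclusive outcomes.

    Each nonempty proper subset of the outcomes defines one condition:
    sum_{k=1}^{n-1} C(n, k) = 2**n - 2.
    """
    if n < 2:
        raise ValueError("need at least two outcomes to form a grouping")
    return 2 ** n - 2


def ordinal_binary_splits(n: int) -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
    """The n-1 order-preserving binary cuts of n ordered levels.

    Levels are indexed 0..n-1 from low to high; each cut c returns
    (levels <= c, levels > c), e.g. for n=3: (L | M+H) and (L+M | H).
    """
    if n < 2:
        raise ValueError("need at least two ordered levels")
    return [
        (tuple(range(c + 1)), tuple(range(c + 1, n)))
        for c in range(n - 1)
    ]


def all_groupings(n: int) -> list[frozenset[int]]:
    """Every nonempty proper subset of n outcomes (2**n - 2 of them)."""
    out = []
    for k in range(1, n):
        out.extend(frozenset(c) for c in combinations(range(n), k))
    return out


def interval_rewards(
    moments: OutcomeMomentSchedule,
    alpha: int = 1,
    death_credit: float = 0.5,
    mode: str = "paper_literal",
) -> RewardMomentSet:
    """Reward matrices for an interval-scale (quantitative) outcome.

    Living transitions out of class j carry the empirical raw moments
    m_k[j]; death transitions carry the death-credit-scaled versions,
    following the same convention as the binary case (``paper_literal``:
    m_k * death_credit for every k; ``moment_consistent``:
    m_k * death_credit**k).
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if not 0 <= death_credit <= 1:
        raise ValueError("death_credit must lie in [0, 1]")
    living = np.stack([moments.m1, moments.m2, moments.m3])
    if mode == "paper_literal":
        death = living * death_credit
    else:
        scale = np.array([death_credit, death_credit ** 2, death_credit ** 3])
        death = living * scale[:, np.newaxis]
    mats = _reward_matrices_from_schedules(living, death, alpha, 3)
    return RewardMomentSet(
        mats, n_transient=moments.n_classes, mode=mode, death_credit=death_credit
    )


def fixed_rewards(rewards: RewardMomentSet) -> RewardMomentSet:
    """Degenerate rewards fixed at their mean values.

    R_1 is unchanged; R_k = R_1 elementwise to the k-th power, so every
    per-transition reward has zero variance.  Used to isolate the
    among-trajectory component of the variance of lifetime rewards.
    """
    R1 = rewards.R(1)
    mats = tuple(R1 ** k for k in range(1, rewards.max_order + 1))
    return RewardMomentSet(
        mats,
        rewards.n_transient,
        mode="fixed",
        death_credit=rewards.death_credit,
    )


def binomial(m: int, k: int) -> int:
    return comb(m, k)
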