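"""Moments and statistics of lifetime accumulated health rewards.

Given the chain P (with transient block U and fundamental matrix N) and the
reward moment matrices R_k, the raw moments of the reward accumulated over
a remaining lifetime, by starting class, satisfy the recursion

    rho_m = N' Z (P o R_m)' 1  +  sum_{k=1}^{m-1} C(m,k) N' (U o Rt_{m-k})' rho_k

where Z = [I | 0] selects the transient states, Rt_k = Z R_k Z' and "o" is
the Hadamard product.  The first moment is the health expectancy (the
Sullivan quantity when rewards are prevalence-based); the higher moments
yield the variance, SD, CV and skewness of healthy longevity among
individuals subject to identical probabilities — individual stochasticity,
not parameter uncertainty.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from math import comb

import numpy as np

from .chain import FullTransition, TransientMatrix, fundamental_matrix
from .rewards import RewardMomentSet, fixed_rewards

__all__ = [
    "MomentVectorSet",
    "HealthStatistics",
    "transient_selector",
    "accumulate_moments",
    "lifetime_statistics",
    "decompose_variance",
    "sullivan_expectancy",
    "occupancy_person_years",
    "analyze",
]

logger = logging.getLogger(__name__)

#: variances in (-NEG_VARIANCE_TOL, 0) are clamped to zero; below is an error
NEG_VARIANCE_TOL = 1e-9


class InconsistentMomentsError(ValueError):
    """Moment vectors imply a variance more negative than round-off allows."""


@dataclass(frozen=True)
class MomentVectorSet:
    """Raw moments of remaining lifetime accumulated reward by start class.

    ``rho[k-1][j]`` is the k-th raw moment for an individual starting in
    transient class j.
    """

    rho: tuple

    def __post_init__(self):
        vecs = tuple(np.asarray(r, dtype=float) for r in self.rho)
        object.__setattr__(self, "rho", vecs)
        if not vecs:
            raise ValueError("need at least the first moment vector")
        n = vecs[0].size
        for r in vecs:
            if r.ndim != 1 or r.size != n:
                raise ValueError("moment vectors must share one length")

    @property
    def max_order(self) -> int:
        return len(self.rho)

    @property
    def n_classes(self) -> int:
        return self.rho[0].size

    def moment(self, k: int) -> np.ndarray:
        return self.rho[k - 1]


@dataclass(frozen=True)
class HealthStatistics:
    """Mean, variance, SD, CV and skewness of healthy longevity by class.

    Mean and SD are in reward units (years, severity-weighted years,
    grip-years, ...); variance in units squared; CV and skewness are
    dimensionless.  CV is NaN where the mean is zero, skewness NaN where
    the variance is zero.
    """

    mean: np.ndarray
    variance: np.ndarray
    sd: np.ndarray
    cv: np.ndarray
    skewness: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("mean", "variance", "sd", "cv", "skewness"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))

    @property
    def n_classes(self) -> int:
        return self.mean.size


def transient_selector(omega: int, alpha: int) -> np.ndarray:
    """The omega x (omega+alpha) 0-1 matrix Z = [I | 0] selecting living states."""
    return np.hstack([np.eye(omega), np.zeros((omega, alpha))])


def accumulate_moments(
    P: FullTransition,
    R: RewardMomentSet,
    max_order: int = 3,
    N: np.ndarray | None = None,
) -> MomentVectorSet:
    """Raw moments of lifetime accumulated reward, all starting classes.

    Implements the general moment recursion for every order up to
    ``max_order`` (default 3, enough for skewness; arbitrary orders are
    supported when R provides them).

    Parameters
    ----------
    P
        Full transition matrix (transient block U, absorbing identity).
    R
        Reward moment matrices up to at least ``max_order``.
    max_order
        Highest moment to compute.
    N
        Optional precomputed fundamental matrix (I - U)^{-1}.
    """
    if R.n_states != P.n_states or R.n_transient != P.n_transient:
        raise ValueError("reward matrices do not conform to the chain")
    if max_order > R.max_order:
        raise ValueError(
            f"max_order={max_order} exceeds available reward moments "
            f"({R.max_order})"
        )
    w = P.n_transient
    a = P.n_absorbing
    U = P.U
    if N is None:
        N = fundamental_matrix(TransientMatrix(U))
    Z = transient_selector(w, a)
    ones = np.ones(P.n_states)
    Nt = N.T

    rho: list[np.ndarray] = []
    for m in range(1, max_order + 1):
        vec = Z @ ((P.entries * R.R(m)).T @ ones)
        for k in range(1, m):
            Rt = R.transient_block(m - k)
            vec = vec + comb(m, k) * ((U * Rt).T @ rho[k - 1])
        rho.append(Nt @ vec)
    return MomentVectorSet(tuple(rho))


def _clamped_variance(rho1: np.ndarray, rho2: np.ndarray) -> np.ndarray:
    var = rho2 - rho1 ** 2
    bad = var < -NEG_VARIANCE_TOL
    if np.any(bad):
        raise InconsistentMomentsError(
            f"negative variance beyond tolerance at classes {np.where(bad)[0]}: "
            f"min {var.min():.3g}"
        )
    small = (var < 0) & ~bad
    if np.any(small):
        logger.warning(
            "clamping %d tiny negative variance(s) (min %.3g) to zero",
            int(small.sum()), float(var.min()),
        )
        var = np.where(small, 0.0, var)
    return var


def lifetime_statistics(
    rho: MomentVectorSet, meta: dict | None = None
) -> HealthStatistics:
    """Summary statistics of healthy longevity from its raw moments.

    variance = rho2 - rho1^2;  sd = sqrt(variance);  cv = sd / mean;
    skewness = (rho3 - 3 rho1 rho2 + 2 rho1^3) / variance^{3/2}.
    Skewness requires the third moment; with only two orders it is NaN.
    """
    r1 = rho.moment(1)
    if rho.max_order < 2:
        raise ValueError("statistics require at least the first two moments")
    var = _clamped_variance(r1, rho.moment(2))
    sd = np.sqrt(var)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        cv = np.where(r1 != 0, sd / np.where(r1 != 0, r1, 1.0), np.nan)
        if rho.max_order >= 3:
            r2, r3 = rho.moment(2), rho.moment(3)
            third_central = r3 - 3 * r1 * r2 + 2 * r1 ** 3
            skew = np.where(var > 0, third_central / np.where(var > 0, var, 1.0) ** 1.5, np.nan)
        else:
            skew = np.full_like(r1, np.nan)
    return HealthStatistics(r1, var, sd, cv, skew, meta=dict(meta or {}))


def decompose_variance(
    P: FullTransition,
    R_stochastic: RewardMomentSet,
    N: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split the variance of lifetime reward within vs. among trajectories.

    The among-trajectory component is the variance under rewards fixed at
    their mean values (R_k = R_1 elementwise to the k); the within component
    is obtained by subtraction.  Returns (total, among, within) per
    starting class; among + within = total exactly by construction.
    """
    if R_stochastic.max_order < 2:
        raise ValueError("variance decomposition needs moments up to order 2")
    if N is None:
        N = fundamental_matrix(TransientMatrix(P.U))
    rho_tot = accumulate_moments(P, R_stochastic, max_order=2, N=N)
    total = _clamped_variance(rho_tot.moment(1), rho_tot.moment(2))
    rho_fix = accumulate_moments(P, fixed_rewards(R_stochastic), max_order=2, N=N)
    among = _clamped_variance(rho_fix.moment(1), rho_fix.moment(2))
    within = total - among
    bad = within < -NEG_VARIANCE_TOL
    if np.any(bad):
        raise InconsistentMomentsError(
            f"within-trajectory variance negative beyond tolerance: "
            f"min {within.min():.3g}"
        )
    within = np.where(within < 0, 0.0, within)
    return total, among, within


def sullivan_expectancy(L: np.ndarray, v, x: int = 0) -> float:
    """Prevalence-weighted health expectancy HE(x) = sum_{j>=x} L_j v_j.

    Parameters
    ----------
    L
        Person-years lived in each age class (nonnegative).
    v
        Prevalence of the healthy condition per age class
        (:class:`~healthlong.rewards.PrevalenceSchedule` or array).
    x
        Starting class index (0-based); the sum runs from x onward.
    """
    L = np.asarray(L, dtype=float)
    vvals = np.asarray(getattr(v, "values", v), dtype=float)
    if L.shape != vvals.shape:
        raise ValueError("L and v must have equal length")
    if np.any(L < 0):
        raise ValueError("person-years must be nonnegative")
    if not 0 <= x < L.size:
        raise IndexError(f"starting class {x} out of range 0..{L.size - 1}")
    return float(np.sum(L[x:] * vvals[x:]))


def occupancy_person_years(
    P: FullTransition,
    start: int,
    death_credit: float = 0.5,
    N: np.ndarray | None = None,
) -> np.ndarray:
    """Expected person-years lived per age class from a starting class.

    L_j = N_{j,start} * (p_j + (1 - p_j) * death_credit), the expected
    occupancy of class j weighted by the expected fraction of the step
    lived there (a full step when surviving it, ``death_credit`` of a step
    when dying during it).  With this construction the Sullivan sum
    ``sum_j L_j v_j`` equals the first moment of the binary-reward lifetime
    accumulation exactly.
    """
    if N is None:
        N = fundamental_matrix(TransientMatrix(P.U))
    w = P.n_transient
    if not 0 <= start < w:
        raise IndexError(f"starting class {start} out of range 0..{w - 1}")
    p_surv = P.U.sum(axis=0)  # probability of surviving the step, per class
    q = 1.0 - p_surv
    return N[:, start] * (p_surv + q * death_credit)


def analyze(
    P: FullTransition,
    R: RewardMomentSet,
    max_order: int = 3,
    meta: dict | None = None,
) -> HealthStatistics:
    """Full pipeline: moments of lifetime reward, then summary statistics."""
    N = fundamental_matrix(TransientMatrix(P.U))
    rho = accumulate_moments(P, R, max_order=max_order, N=N)
    info = {"reward_mode": R.mode, "death_credit": R.death_credit}
    info.update(meta or {})
    return lifetime_statistics(rho, meta=info)
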