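"""Absorbing Markov chain construction for age- or stage-classified life courses.

The life course is a discrete-time absorbing Markov chain.  Transient states
1..omega are living age classes (or stages); absorbing states 1..alpha are
death states, possibly classified by cause.  Transition matrices are
column-stochastic (column-to-row orientation): entry (i, j) is the
probability of moving from state j to state i in one time step.

The full transition matrix has the block form::

    P = [ U  0 ]
        [ M  I ]

where U (omega x omega) holds transitions among living states, M
(alpha x omega) holds probabilities of death by cause, and the identity
block keeps the dead dead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

__all__ = [
    "MortalitySchedule",
    "TransientMatrix",
    "MortalityMatrix",
    "FullTransition",
    "LongevityMoments",
    "NonAbsorbingError",
    "ConservationError",
    "build_age_U",
    "build_M",
    "assemble_P",
    "fundamental_matrix",
    "longevity_moments",
]

_CONSERVATION_TOL = 1e-12


class NonAbsorbingError(ValueError):
    """The chain cannot reach an absorbing state with probability 1."""


class ConservationError(ValueError):
    """Column sums of the assembled transition matrix do not equal 1."""


@dataclass(frozen=True)
class MortalitySchedule:
    """Per-age-class survival probabilities defining the life course.

    Parameters
    ----------
    ages
        Ordered labels for the age classes (integer years, or stage names).
    survival
        Vector of per-class survival probabilities ``p_j`` in [0, 1].
    open_ended
        If True, the last class retains an age-invariant survival
        probability ``p_omega`` (a self-loop), giving a geometric tail to
        the lifespan distribution.  Requires ``p_omega < 1`` so that
        absorption is certain.
    """

    ages: tuple
    survival: np.ndarray
    open_ended: bool = False

    def __post_init__(self):
        p = np.asarray(self.survival, dtype=float)
        object.__setattr__(self, "survival", p)
        object.__setattr__(self, "ages", tuple(self.ages))
        if p.ndim != 1 or p.size < 1:
            raise ValueError("survival must be a non-empty 1-d vector")
        if len(self.ages) != p.size:
            raise ValueError(
                f"ages has length {len(self.ages)} but survival has {p.size}"
            )
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("survival probabilities must lie in [0, 1]")
        if self.open_ended and p[-1] >= 1.0:
            raise NonAbsorbingError(
                "open-ended last class needs survival < 1 for certain absorption"
            )

    @property
    def n_classes(self) -> int:
        return self.survival.size

    @property
    def death(self) -> np.ndarray:
        """Per-class death probabilities ``q_j = 1 - p_j``."""
        return 1.0 - self.survival


@dataclass(frozen=True)
class TransientMatrix:
    """omega x omega matrix U of transitions among living states."""

    entries: np.ndarray

    def __post_init__(self):
        U = np.asarray(self.entries, dtype=float)
        object.__setattr__(self, "entries", U)
        if U.ndim != 2 or U.shape[0] != U.shape[1]:
            raise ValueError("U must be square")
        if np.any(U < 0) or np.any(U > 1):
            raise ValueError("entries of U must lie in [0, 1]")
        if np.any(U.sum(axis=0) > 1 + _CONSERVATION_TOL):
            raise ValueError("column sums of U must not exceed 1")
        if spectral_radius(U) >= 1 - 1e-12:
            raise NonAbsorbingError("spectral radius of U must be < 1")

    @property
    def n_transient(self) -> int:
        return self.entries.shape[0]


@dataclass(frozen=True)
class MortalityMatrix:
    """alpha x omega matrix M; row c holds death probabilities into cause c."""

    entries: np.ndarray
    cause_labels: tuple = field(default=())

    def __post_init__(self):
        M = np.atleast_2d(np.asarray(self.entries, dtype=float))
        object.__setattr__(self, "entries", M)
        if not self.cause_labels:
            object.__setattr__(
                self, "cause_labels", tuple(f"cause_{c + 1}" for c in range(M.shape[0]))
            )
        else:
            object.__setattr__(self, "cause_labels", tuple(self.cause_labels))
        if len(self.cause_labels) != M.shape[0]:
            raise ValueError("one cause label per row of M required")
        if np.any(M < 0) or np.any(M > 1):
            raise ValueError("entries of M must lie in [0, 1]")

    @property
    def n_absorbing(self) -> int:
        return self.entries.shape[0]


@dataclass(frozen=True)
class FullTransition:
    """(omega+alpha) square column-stochastic matrix P = [[U, 0], [M, I]]."""

    entries: np.ndarray
    n_transient: int

    def __post_init__(self):
        P = np.asarray(self.entries, dtype=float)
        object.__setattr__(self, "entries", P)
        s = P.shape[0]
        if P.ndim != 2 or P.shape[1] != s:
            raise ValueError("P must be square")
        if not (0 < self.n_transient <= s):
            raise ValueError("n_transient out of range")
        colsums = P.sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > 1e-9):
            raise ConservationError(
                f"columns of P must sum to 1; worst deviation "
                f"{np.max(np.abs(colsums - 1.0)):.3g}"
            )

    @property
    def n_states(self) -> int:
        return self.entries.shape[0]

    @property
    def n_absorbing(self) -> int:
        return self.n_states - self.n_transient

    @property
    def U(self) -> np.ndarray:
        w = self.n_transient
        return self.entries[:w, :w]

    @property
    def M(self) -> np.ndarray:
        w = self.n_transient
        return self.entries[w:, :w]


@dataclass(frozen=True)
class LongevityMoments:
    """First three raw moments of remaining longevity per starting class.

    ``eta1[j]`` is the expected remaining lifetime (in time steps, counting
    the step in which death occurs) of an individual currently in class j;
    ``eta2`` and ``eta3`` are the second and third raw moments.
    """

    eta1: np.ndarray
    eta2: np.ndarray
    eta3: np.ndarray

    def __post_init__(self):
        for name in ("eta1", "eta2", "eta3"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        if not (self.eta1.shape == self.eta2.shape == self.eta3.shape):
            raise ValueError("moment vectors must have equal length")
        if np.any(self.eta1 < 1 - 1e-9):
            raise ValueError("mean remaining longevity is at least one step")
        if np.any(self.eta2 - self.eta1**2 < -1e-9):
            raise ValueError("implied variance of longevity is negative")

    @property
    def variance(self) -> np.ndarray:
        return self.eta2 - self.eta1**2


def spectral_radius(U: np.ndarray) -> float:
    U = np.asarray(U, dtype=float)
    if U.size == 1:
        return abs(float(U.ravel()[0]))
    return float(np.max(np.abs(np.linalg.eigvals(U))))


def build_age_U(schedule: MortalitySchedule) -> TransientMatrix:
    """Build the age-classified transient matrix U from a mortality schedule.

    Survival probabilities ``p_1 .. p_{omega-1}`` sit on the subdiagonal; if
    the schedule is open-ended the (omega, omega) corner holds ``p_omega``,
    making the last class a self-loop with age-invariant survival.
    """
    p = schedule.survival
    w = schedule.n_classes
    U = np.zeros((w, w))
    if w > 1:
        U[np.arange(1, w), np.arange(w - 1)] = p[:-1]
    if schedule.open_ended:
        U[w - 1, w - 1] = p[-1]
    return TransientMatrix(U)


def build_M(
    schedule: MortalitySchedule,
    cause_split: np.ndarray | None = None,
    cause_labels: tuple = (),
) -> MortalityMatrix:
    """Build the mortality matrix M, optionally split by cause of death.

    Parameters
    ----------
    schedule
        The mortality schedule; death probability in class j is ``1 - p_j``.
    cause_split
        Optional (alpha, omega) array of per-age cause fractions; column j
        must sum to 1.  Row c of M is then ``fraction_cj * (1 - p_j)``.
        With no split, M has the single row ``1 - p``.
    """
    q = schedule.death
    if cause_split is None:
        return MortalityMatrix(q[np.newaxis, :], cause_labels=cause_labels or ("dead",))
    F = np.atleast_2d(np.asarray(cause_split, dtype=float))
    if F.shape[1] != schedule.n_classes:
        raise ValueError(
            f"cause_split has {F.shape[1]} age columns, schedule has "
            f"{schedule.n_classes}"
        )
    if np.any(F < 0):
        raise ValueError("cause fractions must be nonnegative")
    colsums = F.sum(axis=0)
    if np.any(np.abs(colsums - 1.0) > 1e-9):
        raise ValueError(
            f"cause fractions must sum to 1 per age; got sums {colsums}"
        )
    return MortalityMatrix(F * q[np.newaxis, :], cause_labels=cause_labels)


def assemble_P(U: TransientMatrix, M: MortalityMatrix) -> FullTransition:
    """Assemble the full transition matrix P = [[U, 0], [M, I_alpha]]."""
    w = U.n_transient
    if M.entries.shape[1] != w:
        raise ValueError(
            f"M has {M.entries.shape[1]} columns but U is {w} x {w}"
        )
    a = M.n_absorbing
    P = np.zeros((w + a, w + a))
    P[:w, :w] = U.entries
    P[w:, :w] = M.entries
    P[w:, w:] = np.eye(a)
    return FullTransition(P, n_transient=w)


def chain_from_schedule(
    schedule: MortalitySchedule,
    cause_split: np.ndarray | None = None,
    cause_labels: tuple = (),
) -> FullTransition:
    """Convenience: schedule -> assembled P in one call."""
    U = build_age_U(schedule)
    M = build_M(schedule, cause_split=cause_split, cause_labels=cause_labels)
    return assemble_P(U, M)


def fundamental_matrix(U: TransientMatrix | np.ndarray) -> np.ndarray:
    """Fundamental matrix N = (I - U)^{-1} of the absorbing chain.

    Entry (i, j) is the expected number of time steps spent in transient
    state i by an individual starting in state j, before absorption.
    Computed by a linear solve; the relative residual of (I - U) N = I is
    checked against 1e-10.
    """
    Umat = U.entries if isinstance(U, TransientMatrix) else np.asarray(U, float)
    w = Umat.shape[0]
    A = np.eye(w) - Umat
    try:
        N = scipy.linalg.solve(A, np.eye(w))
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise NonAbsorbingError("I - U is singular; chain is not absorbing") from exc
    residual = np.linalg.norm(A @ N - np.eye(w)) / max(np.linalg.norm(N), 1.0)
    if not np.isfinite(residual) or residual > 1e-10:
        raise NonAbsorbingError(
            f"ill-conditioned I - U (relative residual {residual:.3g}); "
            "chain is not (numerically) absorbing"
        )
    return N


def longevity_moments(N: np.ndarray) -> LongevityMoments:
    """First three raw moments of remaining longevity from N.

    eta1' = 1'N;  eta2' = eta1'(2N - I);  eta3' = eta1'(6N^2 - 6N + I),
    where longevity counts the time step in which death occurs.
    """
    N = np.asarray(N, dtype=float)
    w = N.shape[0]
    I = np.eye(w)
    eta1 = N.T @ np.ones(w)
    eta2 = (2 * N - I).T @ eta1
    eta3 = (6 * N @ N - 6 * N + I).T @ eta1
    return LongevityMoments(eta1, eta2, eta3)
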