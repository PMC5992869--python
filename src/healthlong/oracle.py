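"""Reference implementations: simulation and exact enumeration.

These validate the analytic moment recursion by brute force.  A
:class:`RewardSampler` realizes the random per-transition rewards as
explicit discrete distributions; :func:`simulate_rewards` samples whole
lifetimes, and :func:`enumerate_exact` walks the entire
(path x reward-realization) space of a tiny bounded chain with exact
probabilities.  The analytic engine never calls into this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chain import FullTransition
from .rewards import RewardMomentSet

__all__ = [
    "RewardSampler",
    "SimulationResult",
    "simulate_rewards",
    "enumerate_exact",
    "lifetime_distribution",
    "sampler_for_binary",
    "sampler_for_daly",
    "fixed_mean_sampler",
]


def _normalize_dist(values, probs) -> tuple[np.ndarray, np.ndarray]:
    v = np.atleast_1d(np.asarray(values, dtype=float))
    p = np.atleast_1d(np.asarray(probs, dtype=float))
    if v.shape != p.shape:
        raise ValueError("values and probs must have equal length")
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("probabilities must be nonnegative and sum to 1")
    return v, p


@dataclass
class RewardSampler:
    """Discrete reward distribution for each transition (i, j) of the chain.

    ``dists[(i, j)]`` is a pair (values, probs).  Transitions without an
    entry default to a deterministic zero reward.  Raw moments of each
    distribution can be checked against a :class:`RewardMomentSet` with
    :meth:`check_moments`.
    """

    dists: dict = field(default_factory=dict)

    def __post_init__(self):
        self.dists = {
            key: _normalize_dist(*vp) for key, vp in self.dists.items()
        }

    def set(self, i: int, j: int, values, probs) -> "RewardSampler":
        self.dists[(i, j)] = _normalize_dist(values, probs)
        return self

    def set_fixed(self, i: int, j: int, value: float) -> "RewardSampler":
        return self.set(i, j, [value], [1.0])

    def set_bernoulli(self, i: int, j: int, value: float, prob: float) -> "RewardSampler":
        return self.set(i, j, [value, 0.0], [prob, 1.0 - prob])

    def dist(self, i: int, j: int) -> tuple[np.ndarray, np.ndarray]:
        return self.dists.get((i, j), (np.array([0.0]), np.array([1.0])))

    def raw_moment(self, i: int, j: int, k: int) -> float:
        v, p = self.dist(i, j)
        return float(np.sum(p * v ** k))

    def check_moments(
        self, R: RewardMomentSet, P: FullTransition, tol: float = 1e-12
    ) -> None:
        """Verify sampler raw moments match R on every possible transition."""
        w = P.n_transient
        rows, cols = np.nonzero(P.entries)
        for i, j in zip(rows, cols):
            if j >= w:
                continue  # absorbing origin: no reward by construction
            for k in range(1, R.max_order + 1):
                want = R.R(k)[i, j]
                got = self.raw_moment(i, j, k)
                if abs(got - want) > tol:
                    raise AssertionError(
                        f"sampler moment {k} on transition ({i},{j}) is "
                        f"{got}, reward matrix says {want}"
                    )


@dataclass
class SimulationResult:
    """Accumulated lifetime rewards of ``n`` simulated individuals."""

    rewards: np.ndarray
    start: int
    seed: int

    @property
    def n(self) -> int:
        return self.rewards.size

    def raw_moment(self, k: int) -> float:
        return float(np.mean(self.rewards ** k))

    @property
    def mean(self) -> float:
        return float(np.mean(self.rewards))

    @property
    def sd(self) -> float:
        return float(np.std(self.rewards, ddof=1))

    @property
    def se_mean(self) -> float:
        return self.sd / np.sqrt(self.n)

    @property
    def se_sd(self) -> float:
        """Delta-method standard error of the sample SD."""
        x = self.rewards
        m = x.mean()
        s2 = x.var(ddof=1)
        if s2 == 0:
            return 0.0
        m4 = np.mean((x - m) ** 4)
        var_s2 = (m4 - s2 ** 2 * (self.n - 3) / (self.n - 1)) / self.n
        return float(np.sqrt(max(var_s2, 0.0)) / (2 * np.sqrt(s2)))

    def summary(self) -> dict:
        return {
            "n": self.n,
            "seed": self.seed,
            "start": self.start,
            "mean": self.mean,
            "sd": self.sd,
            "se_mean": self.se_mean,
            "se_sd": self.se_sd,
            "raw_moments": [self.raw_moment(k) for k in (1, 2, 3)],
        }


def _step_cap(P: FullTransition) -> int:
    """Generous absorption-time cap: ~10x the longest mean lifetime."""
    from .chain import TransientMatrix, fundamental_matrix, longevity_moments

    eta1 = longevity_moments(fundamental_matrix(TransientMatrix(P.U))).eta1
    return max(100, int(np.ceil(10 * float(eta1.max()))))


def simulate_rewards(
    P: FullTransition,
    sampler: RewardSampler,
    start: int,
    n: int,
    seed: int,
) -> SimulationResult:
    """Simulate n independent lifetimes, summing rewards until absorption.

    A single seeded generator drives both the transitions and the reward
    draws, so results are exactly reproducible for a given seed.
    """
    rng = np.random.default_rng(seed)
    w = P.n_transient
    s = P.n_states
    if not 0 <= start < w:
        raise IndexError(f"start must be a transient state 0..{w - 1}")
    cap = _step_cap(P)
    state = np.full(n, start, dtype=np.int64)
    total = np.zeros(n)
    alive = np.ones(n, dtype=bool)
    cols = [np.cumsum(P.entries[:, j]) for j in range(w)]
    for _ in range(cap):
        if not alive.any():
            break
        idx = np.flatnonzero(alive)
        cur = state[idx]
        for j in np.unique(cur):
            sel = idx[cur == j]
            u = rng.random(sel.size)
            dest = np.searchsorted(cols[j], u)
            dest = np.minimum(dest, s - 1)
            for i in np.unique(dest):
                members = sel[dest == i]
                vals, probs = sampler.dist(int(i), int(j))
                if vals.size == 1:
                    total[members] += vals[0]
                else:
                    total[members] += rng.choice(
                        vals, size=members.size, p=probs
                    )
                if i >= w:
                    alive[members] = False
                else:
                    state[members] = i
    if alive.any():
        raise RuntimeError(
            f"{int(alive.sum())} individuals not absorbed after {cap} steps; "
            "chain may be non-absorbing"
        )
    return SimulationResult(rewards=total, start=start, seed=seed)


def enumerate_exact(
    P: FullTransition,
    sampler: RewardSampler,
    start: int,
    max_outcomes: int = 10 ** 6,
) -> tuple[float, float, float]:
    """Exact raw moments 1-3 of lifetime reward by full enumeration.

    Walks every path from ``start`` to absorption and every combination of
    per-transition reward realizations, with exact probabilities.  Requires
    a bounded chain (no open-ended class) and finite reward supports.
    """
    w = P.n_transient
    Pm = P.entries
    s = P.n_states
    outcomes: list[tuple[float, float]] = []  # (probability, total reward)
    max_depth = 4 * s + 4  # bounded chains absorb within omega steps

    def expand(j: int, prob: float, total: float, depth: int) -> None:
        if depth > max_depth:
            raise RuntimeError(
                "path longer than any bounded chain allows; "
                "open-ended chains cannot be enumerated"
            )
        for i in range(s):
            pij = Pm[i, j]
            if pij == 0.0:
                continue
            vals, probs = sampler.dist(i, j)
            for val, pv in zip(vals, probs):
                if pv == 0.0:
                    continue
                p_branch = prob * pij * pv
                if i >= w:
                    outcomes.append((p_branch, total + val))
                    if len(outcomes) > max_outcomes:
                        raise RuntimeError(
                            f"outcome space exceeds {max_outcomes}"
                        )
                else:
                    expand(i, p_branch, total + val, depth + 1)

    if not 0 <= start < w:
        raise IndexError(f"start must be a transient state 0..{w - 1}")
    expand(start, 1.0, 0.0, 0)
    probs = np.array([p for p, _ in outcomes])
    vals = np.array([r for _, r in outcomes])
    if abs(probs.sum() - 1.0) > 1e-9:
        raise RuntimeError(
            f"enumerated probabilities sum to {probs.sum()}, not 1"
        )
    return tuple(float(np.sum(probs * vals ** k)) for k in (1, 2, 3))


def lifetime_distribution(P: FullTransition, start: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of time to absorption for a bounded chain.

    Returns (values, probs) of the number of steps until absorption,
    counting the step in which death occurs.  Used to realize
    years-of-life-lost rewards as an explicit discrete distribution.
    """
    w = P.n_transient
    Pm = P.entries
    s = P.n_states
    acc: dict[int, float] = {}
    max_depth = 4 * s + 4

    def expand(j: int, prob: float, t: int) -> None:
        if t > max_depth:
            raise RuntimeError("open-ended chains have unbounded lifetimes")
        for i in range(s):
            pij = Pm[i, j]
            if pij == 0.0:
                continue
            if i >= w:
                acc[t + 1] = acc.get(t + 1, 0.0) + prob * pij
            else:
                expand(i, prob * pij, t + 1)

    expand(start, 1.0, 0)
    ts = np.array(sorted(acc), dtype=float)
    ps = np.array([acc[int(t)] for t in ts])
    return ts, ps


def sampler_for_binary(
    P: FullTransition,
    v: np.ndarray,
    death_credit: float = 0.5,
    mode: str = "paper_literal",
) -> RewardSampler:
    """Sampler realizing the binary-outcome reward matrices.

    Living transitions out of class j: reward 1 with probability v_j.
    Death transitions: in ``moment_consistent`` mode the reward is
    ``death_credit`` with probability v_j (strict Bernoulli moments
    v_j * death_credit**k); in ``paper_literal`` mode it is 1 with
    probability v_j * death_credit, whose raw moments are all
    v_j * death_credit — exactly the literal construction R_3 = R_2 = R_1.
    """
    w = P.n_transient
    sampler = RewardSampler()
    rows, cols = np.nonzero(P.entries)
    for i, j in zip(rows, cols):
        if j >= w:
            continue
        if i < w:
            sampler.set_bernoulli(i, j, 1.0, float(v[j]))
        elif mode == "paper_literal":
            sampler.set_bernoulli(i, j, 1.0, float(v[j]) * death_credit)
        else:
            sampler.set_bernoulli(i, j, death_credit, float(v[j]))
    return sampler


def sampler_for_daly(P: FullTransition, spec, standard_P: FullTransition) -> RewardSampler:
    """Sampler realizing the DALY rewards on a bounded chain.

    Survival transitions out of class j: severity s_j with probability v_j.
    Focal-cause death from class j: the exact remaining-lifetime
    distribution of the standard chain started in class j (so its raw
    moments equal the standard longevity moments).  Other-cause deaths: 0.
    """
    w = P.n_transient
    sampler = RewardSampler()
    rows, cols = np.nonzero(P.entries)
    lifedists = {}
    for i, j in zip(rows, cols):
        if j >= w:
            continue
        if i < w:
            sampler.set_bernoulli(
                i, j, float(spec.severity.values[j]), float(spec.prevalence.values[j])
            )
        elif i == w:  # focal cause
            if j not in lifedists:
                lifedists[j] = lifetime_distribution(standard_P, j)
            ts, ps = lifedists[j]
            sampler.set(i, j, ts, ps)
        else:
            sampler.set_fixed(i, j, 0.0)
    return sampler


def fixed_mean_sampler(sampler: RewardSampler) -> RewardSampler:
    """Replace every reward distribution by its mean (zero-variance rewards)."""
    out = RewardSampler()
    for (i, j), (vals, probs) in sampler.dists.items():
        out.set_fixed(i, j, float(np.sum(vals * probs)))
    return out
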