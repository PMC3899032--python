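"""Synthetic RR-interval generators for the three exemplar dynamics.

Three generative models reproduce the statistical structure that drives the
method's landmark pictures:

* :func:`gen_bistable` — a hidden two-state Markov chain (slow/fast heart
  rate, e.g. sleep-stage switching) with short-range-correlated (AR(1))
  fluctuations around each state mean.  Its density delay map shows two
  on-diagonal maxima.
* :func:`gen_iid` — independent, identically distributed intervals, the
  uncorrelated ("circular map") dynamics typical of atrial fibrillation.
* :func:`gen_cluster_switching` — persistent alternation between two RR
  levels with a minimum run length, producing four delay-map clusters: two
  on-diagonal (dwelling) and two off-diagonal (the level changes).

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import signal, stats

from .rr_io import RRSeries

__all__ = [
    "BistableSpec",
    "ClusterSwitchSpec",
    "gen_bistable",
    "gen_iid",
    "gen_cluster_switching",
]

# physiologic positivity floor for RR intervals, seconds
_RR_FLOOR = 0.2


@dataclasses.dataclass(frozen=True)
class BistableSpec:
    """Parameters of the two-state switching generator.

    ``mean_rr`` holds the two state-mean RR intervals in seconds (defaults
    0.65 and 1.0 s — heart rates of about 92 and 60 beats/min).  The hidden
    state stays put each beat with probability ``stay_prob``; within-state
    fluctuations follow an AR(1) process with lag-1 coefficient ``ar_coeff``
    and stationary standard deviation ``sd_rr``.
    """

    mean_rr: tuple[float, float] = (0.65, 1.0)
    sd_rr: float = 0.03
    stay_prob: float = 0.998
    ar_coeff: float = 0.9
    n_beats: int = 30000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.stay_prob < 1.0) and self.stay_prob != 1.0:
            raise ValueError(f"stay_prob must be in (0, 1]: {self.stay_prob}")
        if not (0.0 <= self.ar_coeff < 1.0):
            raise ValueError(f"ar_coeff must be in [0, 1): {self.ar_coeff}")
        if len(self.mean_rr) != 2 or self.mean_rr[0] == self.mean_rr[1]:
            raise ValueError(f"mean_rr must be two distinct values: {self.mean_rr}")
        if self.sd_rr <= 0:
            raise ValueError(f"sd_rr must be positive: {self.sd_rr}")
        if self.n_beats < 2:
            raise ValueError(f"n_beats must be at least 2: {self.n_beats}")


@dataclasses.dataclass(frozen=True)
class ClusterSwitchSpec:
    """Parameters of the persistent level-alternation generator.

    The series dwells at each of two RR ``levels`` for at least ``min_run``
    beats; after the minimum run each further beat switches level with
    probability ``switch_prob``.  Gaussian noise of sd ``sd_rr`` rides on
    each level.
    """

    levels: tuple[float, float] = (0.4, 0.8)
    min_run: int = 3
    switch_prob: float = 0.3
    sd_rr: float = 0.02
    n_beats: int = 20000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_run < 1:
            raise ValueError(f"min_run must be >= 1: {self.min_run}")
        if len(self.levels) != 2 or self.levels[0] == self.levels[1]:
            raise ValueError(f"levels must be two distinct values: {self.levels}")
        if not (0.0 < self.switch_prob <= 1.0):
            raise ValueError(f"switch_prob must be in (0, 1]: {self.switch_prob}")
        if self.sd_rr <= 0:
            raise ValueError(f"sd_rr must be positive: {self.sd_rr}")
        if self.n_beats < 2:
            raise ValueError(f"n_beats must be at least 2: {self.n_beats}")


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    """Independent child generators so state path and noise are decoupled."""
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(n)]


def gen_bistable(spec: BistableSpec) -> RRSeries:
    """Simulate the two-state (bistable) RR dynamics.

    The hidden state s(n) is a symmetric two-state Markov chain; the output
    is ``RR(n) = mean_rr[s(n)] + e(n)`` where e is a stationary AR(1)
    process, ``e(n) = phi * e(n-1) + sd * sqrt(1 - phi^2) * w(n)``, clipped
    at the 0.2 s positivity floor.  The state path and the noise draw from
    independent sub-streams of the seed, so changing noise parameters leaves
    the state path unchanged.
    """
    rng_state, rng_noise = _substreams(spec.seed, 2)
    n = spec.n_beats

    states = np.empty(n, dtype=np.intp)
    states[0] = rng_state.integers(2)
    if spec.stay_prob >= 1.0:
        states[:] = states[0]
    else:
        flips = rng_state.random(n - 1) >= spec.stay_prob
        states[1:] = (states[0] + np.cumsum(flips)) % 2

    phi = spec.ar_coeff
    w = rng_noise.standard_normal(n)
    innov = spec.sd_rr * np.sqrt(1.0 - phi**2) * w
    innov[0] = spec.sd_rr * w[0]  # start the AR(1) at its stationary sd
    e = signal.lfilter([1.0], [1.0, -phi], innov)

    means = np.asarray(spec.mean_rr, dtype=float)
    rr = np.maximum(means[states] + e, _RR_FLOOR)
    return RRSeries.from_intervals(rr, label=f"bistable(seed={spec.seed})")


def gen_iid(
    mean_rr: float = 0.6,
    sd_rr: float = 0.1,
    n_beats: int = 20000,
    seed: int = 0,
) -> RRSeries:
    """Simulate uncorrelated RR dynamics (typical atrial fibrillation).

    Draws are i.i.d. from a Gaussian truncated below at the 0.2 s floor,
    so every interval is positive by construction.
    """
    if sd_rr <= 0:
        raise ValueError(f"sd_rr must be positive: {sd_rr}")
    if n_beats < 2:
        raise ValueError(f"n_beats must be at least 2: {n_beats}")
    rng = np.random.default_rng(seed)
    a = (_RR_FLOOR - mean_rr) / sd_rr
    rr = stats.truncnorm.rvs(a, np.inf, loc=mean_rr, scale=sd_rr, size=n_beats, random_state=rng)
    return RRSeries.from_intervals(rr, label=f"iid(seed={seed})")


def gen_cluster_switching(spec: ClusterSwitchSpec) -> RRSeries:
    """Simulate persistent alternation between two RR levels.

    Run lengths are ``min_run + G`` with G geometric(switch_prob) counting
    post-minimum beats, so ``switch_prob=1`` forces runs of exactly
    ``min_run``.  Each level change contributes one off-diagonal delay pair,
    so the lag-1 map carries four clusters: both (level, level) dwelling
    loci and both (level_i, level_j) transition loci.
    """
    rng_runs, rng_noise, rng_init = _substreams(spec.seed, 3)
    n = spec.n_beats

    level_idx = np.empty(n, dtype=np.intp)
    cur = int(rng_init.integers(2))
    pos = 0
    while pos < n:
        # geometric number of failures before the first switch success
        extra = rng_runs.geometric(spec.switch_prob) - 1
        run = spec.min_run + int(extra)
        level_idx[pos : pos + run] = cur
        pos += run
        cur = 1 - cur

    levels = np.asarray(spec.levels, dtype=float)
    rr = levels[level_idx] + spec.sd_rr * rng_noise.standard_normal(n)
    rr = np.maximum(rr, _RR_FLOOR)
    return RRSeries.from_intervals(rr, label=f"cluster(seed={spec.seed})")
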