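"""Closed-form linear ballistic accumulator (LBA) distributions and simulator.

The LBA models a two-choice decision as a race between two independent
accumulators. Each accumulator starts at a point drawn uniformly from
``[0, A]``, accumulates evidence linearly at a rate drawn (once per trial)
from ``Normal(v, s)``, and triggers its response on reaching the threshold
``b``. The observed response time is the winner's hit time plus a
non-decision time ``t0`` for stimulus encoding and motor execution.

All times are in seconds internally. The single-accumulator CDF/PDF are the
standard closed forms; the joint density of (choice, RT) is the *defective*
density ``f_choice(t - t0) * (1 - F_other(t - t0))``, which integrates to
the probability of that choice (< 1), not to 1. Accumulators whose drift
draw is negative never finish, so the two defective densities jointly
integrate to ``1 - P(both drifts <= 0)``; at the parameter scales typical of
flanker data that deficit is < 1e-5 and no renormalization is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

__all__ = [
    "Accumulator",
    "AccumulatorSet",
    "accumulator_cdf",
    "accumulator_pdf",
    "defective_density",
    "response_probability",
    "log_likelihood",
    "simulate_trial",
    "simulate_trials",
    "DENSITY_FLOOR",
]

# floor applied to the defective density before taking logs, keeping the
# likelihood finite everywhere inside the optimizer's box bounds
DENSITY_FLOOR = 1e-10

# guard on the t*s scale terms against division by ~0
_TS_MIN = 1e-10

# below this A the start-point spread is numerically invisible; use the A->0 limit
_A_LIMIT = 1e-8


def _phi(x):
    """Standard normal PDF."""
    return np.exp(-0.5 * np.square(x)) / np.sqrt(2.0 * np.pi)


@dataclass(frozen=True)
class Accumulator:
    """One racing accumulator.

    Parameters
    ----------
    b : float
        Response threshold (evidence units).
    A : float
        Upper end of the uniform start-point distribution; ``0 <= A <= b``.
    v : float
        Mean drift rate (evidence units / s).
    s : float
        Across-trial SD of the drift rate; ``s > 0``.
    """

    b: float
    A: float
    v: float
    s: float

    def validate(self) -> None:
        if not (self.b >= self.A >= 0.0):
            raise ValueError(f"require b >= A >= 0, got b={self.b}, A={self.A}")
        if not self.s > 0.0:
            raise ValueError(f"require s > 0, got s={self.s}")


@dataclass(frozen=True)
class AccumulatorSet:
    """The pair of accumulators racing on one trial, plus non-decision time.

    ``correct`` is the accumulator for the response matching the target,
    ``error`` the other response. Both share ``b``, ``A`` and ``s`` (no
    response bias); only the drift means differ.
    """

    correct: Accumulator
    error: Accumulator
    t0: float

    def validate(self) -> None:
        self.correct.validate()
        self.error.validate()
        if self.t0 < 0.0:
            raise ValueError(f"require t0 >= 0, got t0={self.t0}")


def accumulator_cdf(t, acc: Accumulator):
    """P(single accumulator reaches threshold by decision time ``t``).

    Vectorized over ``t``; returns 0 for ``t <= 0``. As ``t -> inf`` the
    value tends to ``1 - Phi(-v/s)``, the probability of a positive drift
    draw. For ``A`` below ~1e-8 the closed form is replaced by its A->0
    limit ``Phi((v - b/t)/s)``.
    """
    acc.validate()
    t = np.asarray(t, dtype=float)
    b, A, v, s = acc.b, acc.A, acc.v, acc.s

    tpos = np.where(t > 0.0, t, 1.0)  # placeholder; masked below
    ts = np.maximum(tpos * s, _TS_MIN)

    if A < _A_LIMIT:
        F = ndtr((tpos * v - b) / ts)
    else:
        z1 = (b - A - tpos * v) / ts
        z2 = (b - tpos * v) / ts
        F = (
            1.0
            + (b - A - tpos * v) / A * ndtr(z1)
            - (b - tpos * v) / A * ndtr(z2)
            + ts / A * (_phi(z1) - _phi(z2))
        )
    F = np.clip(F, 0.0, 1.0)
    return np.where(t > 0.0, F, 0.0)[()]


def accumulator_pdf(t, acc: Accumulator):
    """Density of a single accumulator's threshold-hitting time at ``t``."""
    acc.validate()
    t = np.asarray(t, dtype=float)
    b, A, v, s = acc.b, acc.A, acc.v, acc.s

    tpos = np.where(t > 0.0, t, 1.0)
    ts = np.maximum(tpos * s, _TS_MIN)

    if A < _A_LIMIT:
        # hit time b / drift; change of variables from the drift's normal law
        f = b / np.square(tpos) * _phi((b - tpos * v) / ts) * tpos / ts
    else:
        z1 = (b - A - tpos * v) / ts
        z2 = (b - tpos * v) / ts
        f = (-v * ndtr(z1) + s * _phi(z1) + v * ndtr(z2) - s * _phi(z2)) / A
    f = np.maximum(f, 0.0)
    return np.where(t > 0.0, f, 0.0)[()]


def defective_density(rt, choice: str, accs: AccumulatorSet):
    """Joint density of giving ``choice`` ('correct' or 'error') at time ``rt``.

    The race rule: the density of the chosen accumulator finishing at the
    decision time ``rt - t0`` times the probability the other has not yet
    finished. Zero for ``rt <= t0``.
    """
    if choice == "correct":
        winner, loser = accs.correct, accs.error
    elif choice == "error":
        winner, loser = accs.error, accs.correct
    else:
        raise ValueError(f"choice must be 'correct' or 'error', got {choice!r}")
    rt = np.asarray(rt, dtype=float)
    t = rt - accs.t0
    dens = accumulator_pdf(t, winner) * (1.0 - accumulator_cdf(t, loser))
    return np.where(t > 0.0, dens, 0.0)[()]


def response_probability(choice: str, accs: AccumulatorSet, t_max: float = 20.0, n_grid: int = 4000) -> float:
    """Probability of ``choice``, by trapezoid quadrature of the defective density."""
    t = np.linspace(1e-6, t_max, n_grid) + accs.t0
    return float(np.trapezoid(defective_density(t, choice, accs), t))


def _trial_loglik(rt_s: np.ndarray, correct: np.ndarray, accs: AccumulatorSet) -> np.ndarray:
    """Per-trial log defective density, floored; vectorized over trials.

    Both accumulators share b, A, s within a condition, so the winner/loser
    densities differ only in the drift mean.
    """
    b, A, s = accs.correct.b, accs.correct.A, accs.correct.s
    v_win = np.where(correct, accs.correct.v, accs.error.v)
    v_lose = np.where(correct, accs.error.v, accs.correct.v)
    t = rt_s - accs.t0

    # inline vectorized forms (drift varies per trial, so call with arrays)
    tpos = np.where(t > 0.0, t, 1.0)
    ts = np.maximum(tpos * s, _TS_MIN)
    if A < _A_LIMIT:
        f = b / np.square(tpos) * _phi((b - tpos * v_win) / ts) * tpos / ts
        F = ndtr((tpos * v_lose - b) / ts)
    else:
        z1w = (b - A - tpos * v_win) / ts
        z2w = (b - tpos * v_win) / ts
        f = (-v_win * ndtr(z1w) + s * _phi(z1w) + v_win * ndtr(z2w) - s * _phi(z2w)) / A
        z1l = (b - A - tpos * v_lose) / ts
        z2l = (b - tpos * v_lose) / ts
        F = (
            1.0
            + (b - A - tpos * v_lose) / A * ndtr(z1l)
            - (b - tpos * v_lose) / A * ndtr(z2l)
            + ts / A * (_phi(z1l) - _phi(z2l))
        )
    f = np.maximum(f, 0.0)
    F = np.clip(F, 0.0, 1.0)
    dens = np.where(t > 0.0, f * (1.0 - F), 0.0)
    return np.log(np.maximum(dens, DENSITY_FLOOR))


def log_likelihood(data, mapping) -> float:
    """Summed log defective density of a participant's trials.

    Parameters
    ----------
    data :
        Either a ``ParticipantData`` (``.trials`` DataFrame with columns
        ``context``, ``congruency``, ``correct``, ``rt_ms``) or a dict
        ``condition -> (rt_seconds array, correct bool array)``.
    mapping :
        ``condition -> AccumulatorSet`` for every condition present.

    Densities are floored at ``DENSITY_FLOOR`` before the log, so the value
    is finite for any parameter vector. Empty data gives 0.
    """
    grouped = data if isinstance(data, dict) else group_trials(data)
    total = 0.0
    for cond, (rt_s, correct) in grouped.items():
        if cond not in mapping:
            raise KeyError(f"no AccumulatorSet mapped for condition {cond!r}")
        if len(rt_s):
            total += float(np.sum(_trial_loglik(rt_s, correct, mapping[cond])))
    return total


def group_trials(data) -> dict:
    """Group a ParticipantData's trials into condition -> (rt_s, correct) arrays."""
    trials = data.trials
    out = {}
    for (ctx, cong), sub in trials.groupby(["context", "congruency"], observed=True):
        out[(str(ctx), str(cong))] = (
            sub["rt_ms"].to_numpy(dtype=float) / 1000.0,
            sub["correct"].to_numpy(dtype=bool),
        )
    return out


def simulate_trials(accs: AccumulatorSet, n: int, rng: np.random.Generator):
    """Simulate ``n`` race trials; returns (correct bool array, rt seconds array).

    Trials on which both drift draws are <= 0 (no accumulator ever finishes)
    are redrawn.
    """
    accs.validate()
    correct = np.empty(n, dtype=bool)
    rt = np.empty(n, dtype=float)
    todo = np.arange(n)
    while todo.size:
        m = todo.size
        start_c = rng.uniform(0.0, max(accs.correct.A, 1e-300), m)
        start_e = rng.uniform(0.0, max(accs.error.A, 1e-300), m)
        drift_c = rng.normal(accs.correct.v, accs.correct.s, m)
        drift_e = rng.normal(accs.error.v, accs.error.s, m)
        with np.errstate(divide="ignore"):
            t_c = np.where(drift_c > 0, (accs.correct.b - start_c) / drift_c, np.inf)
            t_e = np.where(drift_e > 0, (accs.error.b - start_e) / drift_e, np.inf)
        ok = np.isfinite(t_c) | np.isfinite(t_e)
        win_c = t_c <= t_e
        correct[todo[ok]] = win_c[ok]
        rt[todo[ok]] = np.minimum(t_c, t_e)[ok] + accs.t0
        todo = todo[~ok]
    return correct, rt


def simulate_trial(accs: AccumulatorSet, rng: np.random.Generator):
    """Simulate a single trial; returns ('correct'|'error', rt seconds)."""
    correct, rt = simulate_trials(accs, 1, rng)
    return ("correct" if correct[0] else "error"), float(rt[0])
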