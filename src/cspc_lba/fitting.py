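"""Per-participant maximum-likelihood estimation by particle swarm search.

Each model is fit to one participant's choice/RT data by maximizing the
summed log defective density over the model's free parameters inside box
bounds. The search is a standard constriction-type particle swarm
(inertia 0.72, cognitive = social = 1.49) with seeded restarts, followed by
a bounded Nelder-Mead polish of the swarm's best point. The likelihood
surface is multimodal enough that restarts plus an informed start particle
matter more than long single runs.

The objective is finite everywhere inside the bounds (density floor in
``lba.log_likelihood``), and every random draw comes from a Generator
seeded from the config, so a refit with the same seed reproduces the
result bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from dataclasses import fields as dataclasses_fields
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from . import lba, model_space
from .lba import log_likelihood
from .model_space import ModelTheta, default_bounds, free_parameter_count, theta_from_vector
from .selection import information_criteria

__all__ = ["FitConfig", "FitResult", "ParticipantData", "prepare_fit_data", "fit_participant"]


@dataclass(frozen=True)
class ParticipantData:
    """One participant's trial sequence.

    ``trials`` columns: ``context`` (low/high), ``congruency``
    (congruent/incongruent), ``correct`` (bool), ``rt_ms``; an ``omission``
    bool column marks trials without a response.
    """

    participant: str
    trials: pd.DataFrame

    @property
    def n_trials(self) -> int:
        return len(self.trials)


@dataclass(frozen=True)
class FitConfig:
    """Particle swarm settings. Defaults favor speed over exhaustiveness;
    raise ``n_particles``/``n_iter``/``n_restarts`` for production fits."""

    n_particles: int = 30
    n_iter: int = 150
    inertia: float = 0.72
    cognitive: float = 1.49
    social: float = 1.49
    n_restarts: int = 2
    seed: int = 0
    polish: bool = True
    polish_maxiter: int = 500

    @classmethod
    def from_file(cls, path) -> "FitConfig":
        """Read settings from a plain-text ``key = value`` file.

        Lines starting with '#' and blank lines are ignored; unknown keys
        raise. Example::

            n_particles = 40
            n_iter = 300
            seed = 7
        """
        fields = {f.name: f.type for f in dataclasses_fields(cls)}
        values: dict = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
            key, _, raw = (s.strip() for s in line.partition("="))
            if key not in fields:
                raise ValueError(f"{path}:{lineno}: unknown setting {key!r}")
            if key == "polish":
                values[key] = raw.lower() in ("1", "true", "yes")
            elif key in ("inertia", "cognitive", "social"):
                values[key] = float(raw)
            else:
                values[key] = int(raw)
        return cls(**values)


@dataclass(frozen=True)
class FitResult:
    model_id: str
    theta: ModelTheta
    loglik: float
    k: int
    n_trials: int
    aic: float
    bic: float
    seed: int
    n_evals: int
    restart_logliks: tuple = field(default_factory=tuple)

    def to_row(self) -> dict:
        row = {
            "model": self.model_id,
            "loglik": self.loglik,
            "k": self.k,
            "n_trials": self.n_trials,
            "aic": self.aic,
            "bic": self.bic,
            "seed": self.seed,
        }
        row.update({f"par_{k}": v for k, v in self.theta.values.items()})
        return row


def prepare_fit_data(raw: ParticipantData) -> ParticipantData:
    """Drop response omissions; keep everything else.

    Model fitting uses all responded trials (no RT-window trimming), which
    is a different accounting than the conventional behavioral statistics.
    """
    trials = raw.trials
    if "omission" in trials.columns:
        trials = trials.loc[~trials["omission"].astype(bool)]
    trials = trials.loc[trials["rt_ms"].notna()]
    if len(trials) == 0:
        raise ValueError(f"participant {raw.participant}: no valid trials after omission removal")
    return replace(raw, trials=trials.reset_index(drop=True))


def _objective(model_id: str, grouped: dict, b2_literal: bool):
    def negloglik(x) -> float:
        try:
            theta = theta_from_vector(model_id, x)
            mapping = model_space.build_condition_params(theta, b2_literal=b2_literal)
        except ValueError:
            return 1e12
        return -log_likelihood(grouped, mapping)

    return negloglik


def _heuristic_start(model_id: str, grouped: dict, bounds) -> np.ndarray:
    """A plausible starting particle from coarse data moments."""
    all_rt = np.concatenate([rt for rt, _ in grouped.values()])
    min_rt = float(all_rt.min())
    mean_rt = float(all_rt.mean())
    t0 = 0.85 * min_rt
    d = max(0.7 * (mean_rt - t0) * 0.7, 0.05)  # d ~ v * mean decision time
    start = {
        "s": 0.15,
        "A": 0.5 * d,
        "t0": t0,
        "dv": 0.0,
        "db": 0.0,
        "dt0": 0.0,
    }
    x = []
    for name, (lo, hi) in zip(model_space.parameter_names(model_id), bounds):
        if name in start:
            val = start[name]
        elif name.startswith("t0"):
            val = t0
        elif name == "d" or name.startswith("d_"):
            val = d
        elif name.startswith("v"):
            val = 0.72
        else:  # pragma: no cover
            val = 0.5 * (lo + hi)
        x.append(np.clip(val, lo, hi))
    return np.asarray(x)


def _pso(negloglik, bounds, config: FitConfig, rng: np.random.Generator, x_hint=None):
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    span = hi - lo
    npart, dim = config.n_particles, len(bounds)

    x = lo + span * rng.random((npart, dim))
    if x_hint is not None:
        x[0] = np.clip(x_hint, lo, hi)
    vel = 0.2 * span * (rng.random((npart, dim)) - 0.5)

    fx = np.array([negloglik(xi) for xi in x])
    pbest_x, pbest_f = x.copy(), fx.copy()
    g = int(np.argmin(fx))
    gbest_x, gbest_f = x[g].copy(), float(fx[g])
    n_evals = npart

    vmax = 0.5 * span
    for _ in range(config.n_iter):
        r1 = rng.random((npart, dim))
        r2 = rng.random((npart, dim))
        vel = (
            config.inertia * vel
            + config.cognitive * r1 * (pbest_x - x)
            + config.social * r2 * (gbest_x - x)
        )
        vel = np.clip(vel, -vmax, vmax)
        x = np.clip(x + vel, lo, hi)
        fx = np.array([negloglik(xi) for xi in x])
        n_evals += npart
        better = fx < pbest_f
        pbest_x[better] = x[better]
        pbest_f[better] = fx[better]
        g = int(np.argmin(pbest_f))
        if pbest_f[g] < gbest_f:
            gbest_f = float(pbest_f[g])
            gbest_x = pbest_x[g].copy()
    return gbest_x, gbest_f, n_evals


def fit_participant(
    data: ParticipantData,
    model_id: str,
    config: FitConfig | None = None,
    b2_literal: bool = False,
) -> FitResult:
    """Maximum-likelihood fit of one model to one participant.

    Runs ``n_restarts`` independent swarms (the first seeded with a
    moment-based start particle), keeps the best, optionally polishes with
    bounded Nelder-Mead, and reports AIC/BIC at the returned optimum.
    """
    config = config or FitConfig()
    if model_id not in model_space.MODEL_IDS:
        raise ValueError(f"unknown model id {model_id!r}")
    grouped = lba.group_trials(data)
    n = sum(len(rt) for rt, _ in grouped.values())
    if n == 0:
        raise ValueError("no trials to fit")
    min_rt = min(float(rt.min()) for rt, _ in grouped.values() if len(rt))

    bounds = default_bounds(model_id, min_rt)
    negloglik = _objective(model_id, grouped, b2_literal)
    rng = np.random.default_rng(config.seed)

    best_x, best_f, total_evals = None, np.inf, 0
    restart_logliks = []
    hint = _heuristic_start(model_id, grouped, bounds)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    for r in range(config.n_restarts):
        x, f, ne = _pso(negloglik, bounds, config, rng, x_hint=hint if r == 0 else None)
        total_evals += ne
        if config.polish:
            # polishing every restart, not just the best, guards against a
            # swarm that stalls far from its basin's optimum
            res = optimize.minimize(
                negloglik,
                x,
                method="Nelder-Mead",
                bounds=bounds,
                options={"maxiter": config.polish_maxiter, "xatol": 1e-6, "fatol": 1e-8},
            )
            total_evals += res.nfev
            if res.fun < f:
                x, f = np.clip(res.x, lo, hi), float(res.fun)
        restart_logliks.append(-f)
        if f < best_f:
            best_x, best_f = x, f
    if not np.isfinite(best_f):
        raise RuntimeError("optimization failed: non-finite objective at all particles")

    theta = theta_from_vector(model_id, best_x)
    mapping = model_space.build_condition_params(theta, b2_literal=b2_literal)
    loglik = log_likelihood(grouped, mapping)  # re-evaluate at returned theta
    k = free_parameter_count(model_id)
    aic, bic = information_criteria(loglik, k, n)
    return FitResult(
        model_id=model_id,
        theta=theta,
        loglik=loglik,
        k=k,
        n_trials=n,
        aic=aic,
        bic=bic,
        seed=config.seed,
        n_evals=total_evals,
        restart_logliks=tuple(restart_logliks),
    )
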