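"""Synthetic flanker-task cohorts with the study's statistical structure.

The task design: 448 trials per participant (4 blocks of 112 or 7 blocks of
64), each stimulus shown left or right of fixation. One side is the
high-conflict context (75% incongruent trials), the other the low-conflict
context (75% congruent); half of all trials are congruent overall and the
two sides get equal trial counts. Congruency proportions are realized
exactly by counterbalanced allocation followed by a seeded shuffle, not
just in expectation.

Choices and RTs are simulated from an LBA parameterization (defaults: the
published group-average Model B2 values per data set), with a small
omission rate (0.7%, matching a mean of ~445 valid trials out of 448).
Randomness flows from one master seed through per-participant spawned
streams, so any single participant is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import reference
from .fitting import ParticipantData
from .lba import simulate_trials
from .model_space import ModelTheta, build_condition_params

__all__ = [
    "DesignSpec",
    "GeneratingModel",
    "generate_design",
    "simulate_participant",
    "simulate_participants",
    "recovery_report",
    "TRIAL_COLUMNS",
]

TRIAL_COLUMNS = [
    "participant",
    "dataset",
    "block",
    "trial",
    "location",
    "context",
    "congruency",
    "compatibility",
    "response",
    "omission",
    "correct",
    "rt_ms",
]


@dataclass(frozen=True)
class DesignSpec:
    """Trial-structure settings for one participant's session."""

    n_blocks: int = 4
    trials_per_block: int = 112
    high_conflict_side: str = "left"
    p_incongruent_high: float = 0.75
    omission_rate: float = 0.007
    seed: int = 0

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block


@dataclass(frozen=True)
class GeneratingModel:
    """The parameterization a synthetic participant is simulated from."""

    model_id: str
    theta: ModelTheta

    @classmethod
    def from_reference(cls, model_id: str = "B2", dataset: str = "I") -> "GeneratingModel":
        return cls(model_id, reference.reference_theta(model_id, dataset))


def generate_design(spec: DesignSpec) -> pd.DataFrame:
    """Trial sequence (block, trial, location, context, congruency).

    Exact counts: equal trials per side; on the high-conflict side a
    fraction ``p_incongruent_high`` of trials is incongruent, mirrored
    (congruent) on the low-conflict side. Raises if the proportions do not
    resolve to whole trials.
    """
    if spec.high_conflict_side not in ("left", "right"):
        raise ValueError("high_conflict_side must be 'left' or 'right'")
    n = spec.n_trials
    if n % 2:
        raise ValueError("total trial count must be even (equal trials per side)")
    per_side = n // 2
    n_inc_high = spec.p_incongruent_high * per_side
    if abs(n_inc_high - round(n_inc_high)) > 1e-9:
        raise ValueError(
            f"p_incongruent_high={spec.p_incongruent_high} not realizable over {per_side} trials"
        )
    n_inc_high = int(round(n_inc_high))

    low_side = "right" if spec.high_conflict_side == "left" else "left"
    rows = []
    for side, ctx, n_inc in (
        (spec.high_conflict_side, "high", n_inc_high),
        (low_side, "low", per_side - n_inc_high),
    ):
        rows += [(side, ctx, "incongruent")] * n_inc
        rows += [(side, ctx, "congruent")] * (per_side - n_inc)
    design = pd.DataFrame(rows, columns=["location", "context", "congruency"])

    rng = np.random.default_rng(spec.seed)
    design = design.sample(frac=1.0, random_state=rng).reset_index(drop=True)
    design["block"] = np.repeat(np.arange(1, spec.n_blocks + 1), spec.trials_per_block)
    design["trial"] = np.tile(np.arange(1, spec.trials_per_block + 1), spec.n_blocks)
    # target viewpoint direction, balanced at random: defines the correct
    # response and the spatial S-R compatibility label
    design["target_direction"] = rng.permutation(
        np.array(["left", "right"]).repeat(n // 2)
    )
    design["compatibility"] = np.where(
        design["target_direction"] == design["location"], "compatible", "incompatible"
    )
    return design[
        ["block", "trial", "location", "context", "congruency", "target_direction", "compatibility"]
    ]


def simulate_participant(
    design: pd.DataFrame,
    gen: GeneratingModel,
    rng: np.random.Generator,
    participant: str = "sim_001",
    dataset: str = "I",
    omission_rate: float = 0.007,
    b2_literal: bool = False,
) -> ParticipantData:
    """Simulate one participant's choices and RTs over a design."""
    mapping = build_condition_params(gen.theta, b2_literal=b2_literal)
    df = design.copy()
    df["correct"] = False
    df["rt_ms"] = np.nan
    for cond, sub in df.groupby(["context", "congruency"], observed=True):
        correct, rt = simulate_trials(mapping[(cond[0], cond[1])], len(sub), rng)
        df.loc[sub.index, "correct"] = correct
        df.loc[sub.index, "rt_ms"] = 1000.0 * rt
    other = {"left": "right", "right": "left"}
    df["response"] = np.where(
        df["correct"], df["target_direction"], df["target_direction"].map(other)
    )
    df["omission"] = rng.random(len(df)) < omission_rate
    df.loc[df["omission"], ["response", "rt_ms"]] = [None, np.nan]
    df.loc[df["omission"], "correct"] = False
    df["participant"] = participant
    df["dataset"] = dataset
    return ParticipantData(participant, df[TRIAL_COLUMNS])


def simulate_participants(
    design_spec: DesignSpec,
    gen: GeneratingModel,
    n_participants: int,
    seed: int = 0,
    dataset: str = "I",
) -> tuple:
    """Simulate a cohort; returns (list of ParticipantData, truth sidecar).

    Each participant gets an independent design shuffle and an independent
    RNG stream spawned from the master seed. The truth DataFrame records the
    generating model and parameters for recovery scoring.
    """
    streams = np.random.SeedSequence(seed).spawn(n_participants)
    cohort, truth_rows = [], []
    for i, ss in enumerate(streams):
        pid = f"sim_{i + 1:03d}"
        child = np.random.default_rng(ss)
        dspec = DesignSpec(
            n_blocks=design_spec.n_blocks,
            trials_per_block=design_spec.trials_per_block,
            high_conflict_side=design_spec.high_conflict_side,
            p_incongruent_high=design_spec.p_incongruent_high,
            omission_rate=design_spec.omission_rate,
            seed=int(child.integers(2**31)),
        )
        design = generate_design(dspec)
        pdata = simulate_participant(
            design, gen, child, participant=pid, dataset=dataset,
            omission_rate=design_spec.omission_rate,
        )
        cohort.append(pdata)
        truth_rows.append(
            {"participant": pid, "dataset": dataset, "model": gen.model_id}
            | {f"par_{k}": v for k, v in gen.theta.values.items()}
        )
    return cohort, pd.DataFrame(truth_rows)


def recovery_report(fits: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """Score fitted parameters and model selection against generating truth.

    ``fits`` holds one row per participant × model (columns from
    ``FitResult.to_row`` plus ``participant``); ``truth`` is the sidecar
    from :func:`simulate_participants`. Returns per-parameter bias/RMSE for
    fits of the generating model, sign-recovery rates for the CSPC shift
    parameters (db/dv), and a best-model tally by BIC and AIC.
    """
    gen_model = truth["model"].iloc[0]
    merged = fits.loc[fits["model"] == gen_model].merge(
        truth, on="participant", suffixes=("_fit", "_true")
    )
    if len(merged) != len(truth):
        raise ValueError("fits and truth participants do not align")
    params = {}
    for col in truth.columns:
        if not col.startswith("par_"):
            continue
        err = merged[f"{col}_fit"] - merged[f"{col}_true"]
        entry = {
            "bias": float(err.mean()),
            "rmse": float(np.sqrt(np.mean(np.square(err)))),
            "mae_median": float(err.abs().median()),
        }
        if col in ("par_db", "par_dv", "par_dt0"):
            true_sign = np.sign(merged[f"{col}_true"])
            entry["sign_rate"] = float(np.mean(np.sign(merged[f"{col}_fit"]) == true_sign))
        params[col.removeprefix("par_")] = entry

    tally = {}
    for crit in ("aic", "bic"):
        best = fits.loc[fits.groupby("participant")[crit].idxmin(), ["participant", "model"]]
        counts = best["model"].value_counts().to_dict()
        b_class = sum(v for m, v in counts.items() if m.startswith("B"))
        v_class = sum(v for m, v in counts.items() if m.startswith("V"))
        tally[crit.upper()] = {
            "counts": counts,
            "b_class": int(b_class),
            "v_class": int(v_class),
        }
    return {"generating_model": gen_model, "parameters": params, "best_model": tally}
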