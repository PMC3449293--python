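"""Model parameterizations: drift (V) vs threshold (B) accounts of CSPC effects.

The flanker design crosses two conditions: stimulus *context* (the screen
side, associated with a high or low proportion of incongruent trials) and
flanker *congruency*. Competing LBA parameterizations attribute the
context-specific proportion congruent (CSPC) effect — a smaller congruency
effect in the high-conflict context — either to context-dependent drift
rates (processing selectivity) or to context-dependent response thresholds
(response caution):

====== ==  =======================================================
model   k  free parameters (besides the shared s, A, t0)
====== ==  =======================================================
V1      8  one threshold distance d = b − A; v per condition (4)
V2      7  d; v_CL, v_IL and a symmetric context shift Δv
B1      9  d per condition (4); v per congruency (2)
B2      8  d_CL, d_IL and a symmetric context shift Δb; v_C, v_I
VB     11  d per condition (4) and v per condition (4)
T0      8  d; v_C, v_I; t0_CL, t0_IL and a symmetric shift Δt0
====== ==  =======================================================

Positive Δv / Δb / Δt0 produce the standard CSPC direction. Thresholds are
parameterized internally as distances ``d = b − A > 0`` so that box bounds
guarantee ``b >= A``; reported thresholds are ``b = A + d``. The error
accumulator's drift mean is ``1 − v`` (sum-to-one convention), which makes
the single per-condition drift identifiable.

VB and T0 are extension models used for recovery completeness; the headline
comparison is V1/V2 vs B1/B2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lba import Accumulator, AccumulatorSet

__all__ = [
    "CONDITIONS",
    "MODEL_IDS",
    "HEADLINE_MODELS",
    "ModelTheta",
    "free_parameter_count",
    "parameter_names",
    "build_condition_params",
    "theta_from_vector",
    "theta_to_vector",
    "default_bounds",
]

# (context, congruency): low/high conflict x congruent/incongruent
CONDITIONS = (
    ("low", "congruent"),
    ("low", "incongruent"),
    ("high", "congruent"),
    ("high", "incongruent"),
)

HEADLINE_MODELS = ("V1", "V2", "B1", "B2")
MODEL_IDS = HEADLINE_MODELS + ("VB", "T0")

_COND_SUFFIX = {c: f"{c[1][0].upper()}{c[0][0].upper()}" for c in CONDITIONS}
# e.g. ("low","congruent") -> "CL"

_PARAM_NAMES = {
    "V1": ("s", "A", "t0", "d", "v_CL", "v_IL", "v_CH", "v_IH"),
    "V2": ("s", "A", "t0", "d", "v_CL", "v_IL", "dv"),
    "B1": ("s", "A", "t0", "d_CL", "d_IL", "d_CH", "d_IH", "v_C", "v_I"),
    "B2": ("s", "A", "t0", "d_CL", "d_IL", "db", "v_C", "v_I"),
    "VB": ("s", "A", "t0", "d_CL", "d_IL", "d_CH", "d_IH", "v_CL", "v_IL", "v_CH", "v_IH"),
    "T0": ("s", "A", "t0_CL", "t0_IL", "dt0", "d", "v_C", "v_I"),
}


@dataclass(frozen=True)
class ModelTheta:
    """A named parameterization with its free-parameter values."""

    model_id: str
    values: dict = field(default_factory=dict)

    def __post_init__(self):
        names = parameter_names(self.model_id)
        missing = set(names) - set(self.values)
        extra = set(self.values) - set(names)
        if missing or extra:
            raise ValueError(
                f"model {self.model_id}: missing={sorted(missing)}, extra={sorted(extra)}"
            )

    def __getitem__(self, key: str) -> float:
        return self.values[key]


def parameter_names(model_id: str) -> tuple:
    try:
        return _PARAM_NAMES[model_id]
    except KeyError:
        raise ValueError(f"unknown model id {model_id!r}") from None


def free_parameter_count(model_id: str) -> int:
    """Number of free parameters k (V1=8, V2=7, B1=9, B2=8, VB=11, T0=8)."""
    return len(parameter_names(model_id))


def _cond_values(theta: ModelTheta, b2_literal: bool = False):
    """Per-condition (d, v_correct, t0) under the model's constraints."""
    m, v = theta.model_id, theta.values
    out = {}
    for cond in CONDITIONS:
        ctx, cong = cond
        suf = _COND_SUFFIX[cond]  # CL / IL / CH / IH
        if m == "V1":
            d, drift, t0 = v["d"], v[f"v_{suf}"], v["t0"]
        elif m == "V2":
            d, t0 = v["d"], v["t0"]
            if ctx == "low":
                drift = v[f"v_{suf}"]
            else:
                drift = v["v_IL"] + v["dv"] if cong == "incongruent" else v["v_CL"] - v["dv"]
        elif m == "B1":
            d, drift, t0 = v[f"d_{suf}"], v[f"v_{cong[0].upper()}"], v["t0"]
        elif m == "B2":
            drift, t0 = v[f"v_{cong[0].upper()}"], v["t0"]
            if ctx == "low":
                d = v[f"d_{suf}"]
            elif b2_literal:
                # literal reading: both high-conflict distances from d_IL
                d = v["d_IL"] + v["db"] if cong == "incongruent" else v["d_IL"] - v["db"]
            else:
                d = v["d_IL"] - v["db"] if cong == "incongruent" else v["d_CL"] + v["db"]
        elif m == "VB":
            d, drift, t0 = v[f"d_{suf}"], v[f"v_{suf}"], v["t0"]
        elif m == "T0":
            d, drift = v["d"], v[f"v_{cong[0].upper()}"]
            if ctx == "low":
                t0 = v[f"t0_{suf}"]
            else:
                t0 = v["t0_IL"] - v["dt0"] if cong == "incongruent" else v["t0_CL"] + v["dt0"]
        else:  # pragma: no cover - guarded by parameter_names
            raise ValueError(m)
        out[cond] = (d, drift, t0)
    return out


def build_condition_params(theta: ModelTheta, b2_literal: bool = False) -> dict:
    """Map a ModelTheta to a per-condition ``AccumulatorSet`` dict.

    The error accumulator's drift mean is ``1 - v_correct``; both
    accumulators share b = A + d, A and s within a condition.
    """
    s, A = theta["s"], theta["A"]
    mapping = {}
    for cond, (d, drift, t0) in _cond_values(theta, b2_literal=b2_literal).items():
        if d <= 0:
            raise ValueError(f"threshold distance must be positive, got {d} for {cond}")
        if t0 < 0:
            raise ValueError(f"t0 must be nonnegative, got {t0} for {cond}")
        b = A + d
        mapping[cond] = AccumulatorSet(
            correct=Accumulator(b=b, A=A, v=drift, s=s),
            error=Accumulator(b=b, A=A, v=1.0 - drift, s=s),
            t0=t0,
        )
    return mapping


def theta_to_vector(theta: ModelTheta) -> np.ndarray:
    return np.array([theta[name] for name in parameter_names(theta.model_id)])


def theta_from_vector(model_id: str, x) -> ModelTheta:
    names = parameter_names(model_id)
    x = np.asarray(x, dtype=float)
    if x.shape != (len(names),):
        raise ValueError(f"model {model_id} expects {len(names)} values, got {x.shape}")
    return ModelTheta(model_id, dict(zip(names, x)))


def default_bounds(model_id: str, min_rt_s: float) -> list:
    """Box bounds per parameter, generously bracketing typical flanker fits.

    ``t0`` is bounded above by the participant's minimum RT (a response
    cannot precede the non-decision time).
    """
    t0_hi = max(min_rt_s - 0.005, 0.011)
    bounds = []
    for name in parameter_names(model_id):
        if name == "s" or name == "A" or name.startswith("d_") or name == "d":
            bounds.append((0.001, 2.0))
        elif name.startswith("v"):
            bounds.append((0.0, 2.0))
        elif name in ("dv", "db"):
            bounds.append((-1.0, 1.0))
        elif name.startswith("t0"):
            bounds.append((0.01, t0_hi))
        elif name == "dt0":
            lim = min(0.2, t0_hi / 2)
            bounds.append((-lim, lim))
        else:  # pragma: no cover
            raise ValueError(name)
    return bounds
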