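"""Published group-average reference values for the four flanker data sets.

These tables come from a published LBA analysis of context-specific
proportion congruent (CSPC) effects in a face-viewpoint flanker task with
four independent samples (data sets I–IV, pooled n = 87):

* ``PARAMS``: per data set and model, participant-averaged parameter
  estimates (thresholds ``b`` on the evidence scale, drifts ``v`` in
  evidence/s, ``t0`` in seconds). They are the default generating values for
  the synthetic cohorts, so simulations run at an empirically realistic
  operating point.
* ``IC_WEIGHTS`` / ``BEST_COUNTS``: per data set, the mean AIC/BIC model
  weights across participants and the number of participants best fit by
  each model. ``N_PARTICIPANTS`` gives each sample's size.

The selection module reconstructs the derived quantities (threshold-vs-drift
evidence ratios, pooled best-fit percentages) from these inputs; the
published values of those derived quantities are kept alongside for
cross-checking (``PUBLISHED_B_VS_V``, ``PUBLISHED_POOLED_PCT``).
"""

from __future__ import annotations

DATASETS = ("I", "II", "III", "IV")
N_PARTICIPANTS = {"I": 25, "II": 19, "III": 25, "IV": 18}

# Participant-averaged parameter estimates per (model, data set).
# Keys follow model_space.parameter_names; thresholds stored as b (not d).
PARAMS = {
    ("V1", "I"): {"s": 0.18, "A": 0.14, "b": 0.48, "t0": 0.14,
                  "v_CL": 0.79, "v_IL": 0.64, "v_CH": 0.77, "v_IH": 0.66},
    ("V1", "II"): {"s": 0.15, "A": 0.09, "b": 0.36, "t0": 0.13,
                   "v_CL": 0.78, "v_IL": 0.63, "v_CH": 0.75, "v_IH": 0.65},
    ("V1", "III"): {"s": 0.13, "A": 0.09, "b": 0.37, "t0": 0.08,
                    "v_CL": 0.73, "v_IL": 0.58, "v_CH": 0.71, "v_IH": 0.60},
    ("V1", "IV"): {"s": 0.17, "A": 0.15, "b": 0.46, "t0": 0.08,
                   "v_CL": 0.77, "v_IL": 0.62, "v_CH": 0.75, "v_IH": 0.64},
    ("V2", "I"): {"s": 0.18, "A": 0.14, "b": 0.48, "t0": 0.14,
                  "v_CL": 0.79, "v_IL": 0.64, "dv": 0.02},
    ("V2", "II"): {"s": 0.15, "A": 0.09, "b": 0.36, "t0": 0.13,
                   "v_CL": 0.78, "v_IL": 0.63, "dv": 0.02},
    ("V2", "III"): {"s": 0.13, "A": 0.10, "b": 0.37, "t0": 0.08,
                    "v_CL": 0.73, "v_IL": 0.59, "dv": 0.02},
    ("V2", "IV"): {"s": 0.17, "A": 0.15, "b": 0.46, "t0": 0.08,
                   "v_CL": 0.77, "v_IL": 0.62, "dv": 0.02},
    ("B1", "I"): {"s": 0.19, "A": 0.16, "b_CL": 0.43, "b_IL": 0.48,
                  "b_CH": 0.41, "b_IH": 0.47, "t0": 0.19, "v_C": 0.77, "v_I": 0.70},
    ("B1", "II"): {"s": 0.17, "A": 0.10, "b_CL": 0.32, "b_IL": 0.36,
                   "b_CH": 0.33, "b_IH": 0.35, "t0": 0.17, "v_C": 0.76, "v_I": 0.70},
    ("B1", "III"): {"s": 0.14, "A": 0.10, "b_CL": 0.36, "b_IL": 0.37,
                    "b_CH": 0.37, "b_IH": 0.37, "t0": 0.11, "v_C": 0.73, "v_I": 0.61},
    ("B1", "IV"): {"s": 0.19, "A": 0.18, "b_CL": 0.42, "b_IL": 0.47,
                   "b_CH": 0.43, "b_IH": 0.47, "t0": 0.13, "v_C": 0.77, "v_I": 0.69},
    ("B2", "I"): {"s": 0.19, "A": 0.17, "b_CL": 0.43, "b_IL": 0.48, "db": 0.01,
                  "t0": 0.20, "v_C": 0.78, "v_I": 0.70},
    ("B2", "II"): {"s": 0.17, "A": 0.10, "b_CL": 0.32, "b_IL": 0.37, "db": 0.01,
                   "t0": 0.17, "v_C": 0.76, "v_I": 0.69},
    ("B2", "III"): {"s": 0.14, "A": 0.11, "b_CL": 0.36, "b_IL": 0.37, "db": 0.01,
                    "t0": 0.12, "v_C": 0.75, "v_I": 0.62},
    ("B2", "IV"): {"s": 0.18, "A": 0.20, "b_CL": 0.43, "b_IL": 0.47, "db": 0.01,
                   "t0": 0.14, "v_C": 0.79, "v_I": 0.70},
}

# Mean IC weights per (criterion, data set), in model order V1, V2, B1, B2.
IC_WEIGHTS = {
    ("AIC", "I"): {"V1": 0.059, "V2": 0.106, "B1": 0.412, "B2": 0.422},
    ("AIC", "II"): {"V1": 0.050, "V2": 0.094, "B1": 0.498, "B2": 0.358},
    ("AIC", "III"): {"V1": 0.185, "V2": 0.119, "B1": 0.468, "B2": 0.228},
    ("AIC", "IV"): {"V1": 0.152, "V2": 0.116, "B1": 0.419, "B2": 0.313},
    ("BIC", "I"): {"V1": 0.027, "V2": 0.313, "B1": 0.123, "B2": 0.537},
    ("BIC", "II"): {"V1": 0.015, "V2": 0.221, "B1": 0.255, "B2": 0.509},
    ("BIC", "III"): {"V1": 0.129, "V2": 0.389, "B1": 0.216, "B2": 0.267},
    ("BIC", "IV"): {"V1": 0.085, "V2": 0.337, "B1": 0.153, "B2": 0.425},
}

# Number of participants best fit by each model (same keying).
BEST_COUNTS = {
    ("AIC", "I"): {"V1": 0, "V2": 4, "B1": 8, "B2": 13},
    ("AIC", "II"): {"V1": 0, "V2": 2, "B1": 9, "B2": 8},
    ("AIC", "III"): {"V1": 4, "V2": 3, "B1": 12, "B2": 6},
    ("AIC", "IV"): {"V1": 2, "V2": 2, "B1": 8, "B2": 6},
    ("BIC", "I"): {"V1": 0, "V2": 8, "B1": 3, "B2": 14},
    ("BIC", "II"): {"V1": 0, "V2": 5, "B1": 4, "B2": 10},
    ("BIC", "III"): {"V1": 3, "V2": 10, "B1": 4, "B2": 8},
    ("BIC", "IV"): {"V1": 1, "V2": 7, "B1": 1, "B2": 9},
}

# Published derived quantities, for cross-checks of the reconstruction.
PUBLISHED_B_VS_V = {
    ("AIC", "I"): 5.06, ("AIC", "II"): 5.94, ("AIC", "III"): 2.29, ("AIC", "IV"): 2.73,
    ("BIC", "I"): 1.94, ("BIC", "II"): 3.24, ("BIC", "III"): 0.934, ("BIC", "IV"): 1.37,
}
PUBLISHED_B_VS_V_MEAN = {"AIC": 4.0, "BIC": 1.87}
PUBLISHED_POOLED_PCT = {
    "AIC": {"V1": 6.9, "V2": 12.6, "B1": 42.5, "B2": 38.0},
    "BIC": {"V1": 4.6, "V2": 34.5, "B1": 13.8, "B2": 47.1},
}

# Behavioral anchors from the pooled sample (n = 87).
BEHAVIOR_ANCHORS = {
    "accuracy_pct": 93.5,
    "mean_rt_incongruent_ms": 700.0,
    "mean_rt_congruent_ms": 596.0,
    "interference_low_ms": 121.0,
    "interference_high_ms": 88.0,
    "cspc_rt_ms": 33.0,
    "cspc_error_pct": 2.1,
}


def reference_theta(model_id: str, dataset: str):
    """ModelTheta at the published averages for one model and data set.

    Thresholds are converted from the published ``b`` to internal distances
    ``d = b − A``.
    """
    from .model_space import ModelTheta, parameter_names

    raw = dict(PARAMS[(model_id, dataset)])
    A = raw["A"]
    values = {}
    for name in parameter_names(model_id):
        if name == "d":
            values[name] = raw["b"] - A
        elif name.startswith("d_"):
            values[name] = raw["b" + name[1:]] - A
        else:
            values[name] = raw[name]
    return ModelTheta(model_id, values)
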