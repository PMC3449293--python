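"""Conventional behavioral statistics: trimming, cell means, CSPC contrasts.

The descriptive pipeline mirrors standard conflict-task practice: drop the
first trial of each block and responses faster than 150 ms or slower than
2000 ms, then summarize mean correct RT (excluding post-error correct
trials) and error rate per context × congruency cell. The CSPC statistic is
the interference (incongruent − congruent) difference between contexts:

    CSPC = (I − C)_low-conflict − (I − C)_high-conflict

positive under the standard effect (interference shrinks where conflict is
frequent). Context-transition labels (repetition vs switch relative to the
previous retained trial) support the transition-split analysis. Inferential
F-tests are deliberately out of scope; this module exposes the cell means
and contrasts those tests are built on.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "trim_trials",
    "label_transitions",
    "cell_means",
    "cspc_statistic",
    "RT_MIN_MS",
    "RT_MAX_MS",
]

RT_MIN_MS = 150.0
RT_MAX_MS = 2000.0


def trim_trials(df: pd.DataFrame) -> pd.DataFrame:
    """Apply the conventional-analysis exclusions.

    Removes the first trial of each block (per participant) and trials with
    RT outside [150, 2000] ms (omissions, which have no RT, are also
    dropped). Adds a ``post_error`` flag: the previous retained trial in the
    same block was an error. Post-error correct trials stay in the data —
    they are excluded from RT means only, not from accuracy. Idempotent.
    """
    df = df.copy()
    keys = [k for k in ("participant", "dataset") if k in df.columns] + ["block"]
    # presence of post_error marks already-trimmed data: the first retained
    # trial per block must not be removed again
    if "post_error" in df.columns:
        keep = pd.Series(True, index=df.index)
    else:
        first_idx = df.groupby(keys)["trial"].transform("min")
        keep = df["trial"] > first_idx
    rt_ok = df["rt_ms"].between(RT_MIN_MS, RT_MAX_MS)
    if "omission" in df.columns:
        rt_ok &= ~df["omission"].astype(bool)
    out = df.loc[keep & rt_ok].copy()
    prev_correct = out.groupby(keys)["correct"].shift(1)
    out["post_error"] = prev_correct.eq(False).fillna(False).astype(bool)
    return out.reset_index(drop=True)


def label_transitions(df: pd.DataFrame) -> pd.DataFrame:
    """Label each retained trial repetition/switch vs the previous retained trial.

    The first analyzed trial of each block gets no label (NaN). Trials are
    compared in their stored (temporal) order within block.
    """
    df = df.copy()
    keys = [k for k in ("participant", "dataset") if k in df.columns] + ["block"]
    prev_ctx = df.groupby(keys)["context"].shift(1)
    df["transition"] = np.where(
        prev_ctx.isna(), None, np.where(df["context"].eq(prev_ctx), "repetition", "switch")
    )
    return df


def cell_means(df: pd.DataFrame, by=("context", "congruency")) -> pd.DataFrame:
    """Mean correct RT, error rate (%) and count per cell.

    RT means use correct trials excluding post-error correct trials (when
    the ``post_error`` flag from :func:`trim_trials` is present); error
    rates use all retained trials in the cell.
    """
    by = list(by)
    rows = []
    for cell, sub in df.groupby(by, dropna=True):
        cell = cell if isinstance(cell, tuple) else (cell,)
        correct = sub["correct"].astype(bool)
        rt_mask = correct & ~sub.get("post_error", pd.Series(False, index=sub.index)).astype(bool)
        rows.append(
            dict(zip(by, cell))
            | {
                "mean_rt_ms": float(sub.loc[rt_mask, "rt_ms"].mean()),
                "error_rate_pct": float(100.0 * (1.0 - correct.mean())),
                "n_trials": int(len(sub)),
            }
        )
    return pd.DataFrame(rows)


def _cell(cells: pd.DataFrame, context: str, congruency: str, col: str) -> float:
    m = cells.loc[(cells["context"] == context) & (cells["congruency"] == congruency), col]
    if len(m) != 1:
        raise ValueError(f"missing or duplicated cell ({context}, {congruency})")
    return float(m.iloc[0])


def cspc_statistic(cells: pd.DataFrame, col: str = "mean_rt_ms") -> float:
    """Interference in the low-conflict context minus in the high-conflict one.

    ``col`` selects RT (``mean_rt_ms``) or error rate (``error_rate_pct``).
    """
    int_low = _cell(cells, "low", "incongruent", col) - _cell(cells, "low", "congruent", col)
    int_high = _cell(cells, "high", "incongruent", col) - _cell(cells, "high", "congruent", col)
    return int_low - int_high
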