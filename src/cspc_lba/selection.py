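"""Model selection: information criteria, weights, tallies, and predictions.

AIC = 2k − 2 ln L and BIC = k ln N − 2 ln L, with L̂ the maximized
likelihood, k the free-parameter count and N the number of trials entering
the likelihood. Per participant, ΔIC = IC − min(IC) and the weights

    w_i = exp(−Δ_i/2) / Σ_k exp(−Δ_k/2)

are interpreted as model probabilities. The threshold-vs-drift evidence
ratio is (w_B1 + w_B2) / (w_V1 + w_V2): how much more probable a
response-caution account is than a processing-selectivity account.

Also provides the distributional summaries used to display model fit:
defective quantile tables (within-class RT quantiles with cumulative
heights scaled by the class's response proportion) and quadrature-based
predicted mean RT / accuracy per condition.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .lba import AccumulatorSet, defective_density

__all__ = [
    "information_criteria",
    "ic_weights",
    "b_vs_v_ratio",
    "selection_records",
    "aggregate_best_fit",
    "quantile_summary",
    "predicted_quantiles",
    "predicted_moments",
]

_B_MODELS = ("B1", "B2")
_V_MODELS = ("V1", "V2")

DEFAULT_QUANTILES = (0.1, 0.3, 0.5, 0.7, 0.9)


def information_criteria(loglik: float, k: int, n: int) -> tuple:
    """(AIC, BIC) from a maximized log-likelihood. BIC − AIC = k(ln N − 2)."""
    if n < 1:
        raise ValueError(f"need n >= 1 trials, got {n}")
    if k < 0:
        raise ValueError(f"need k >= 0, got {k}")
    aic = 2.0 * k - 2.0 * loglik
    bic = k * math.log(n) - 2.0 * loglik
    return aic, bic


def ic_weights(ics) -> np.ndarray:
    """Normalized exp(−ΔIC/2) weights; invariant to adding a constant."""
    ics = np.asarray(ics, dtype=float)
    if ics.size < 2:
        raise ValueError("need at least two models to compare")
    delta = ics - ics.min()
    w = np.exp(-0.5 * delta)
    return w / w.sum()


def b_vs_v_ratio(weights: dict) -> float:
    """Summed threshold-model weight over summed drift-model weight.

    ``weights`` maps model id -> weight for V1, V2, B1, B2. Returns NaN when
    the drift-class weight is zero.
    """
    num = sum(weights[m] for m in _B_MODELS)
    den = sum(weights[m] for m in _V_MODELS)
    return num / den if den > 0 else float("nan")


def selection_records(fits: pd.DataFrame) -> pd.DataFrame:
    """Per-participant ΔIC, weights and best model for each criterion.

    ``fits`` has one row per participant × model with columns
    ``participant``, ``model``, ``aic``, ``bic`` (``dataset`` carried
    through if present). Ties at ΔIC = 0 are split equally in downstream
    counts; here the best-model label lists all tied models joined by '/'.
    """
    out = []
    carry = [c for c in ("dataset",) if c in fits.columns]
    # participant ids may repeat across datasets, so group on both
    for key, sub in fits.groupby(carry + ["participant"]):
        key = key if isinstance(key, tuple) else (key,)
        rec = dict(zip(carry + ["participant"], key))
        for crit in ("aic", "bic"):
            ics = sub[crit].to_numpy(dtype=float)
            w = ic_weights(ics)
            delta = ics - ics.min()
            best = sub["model"].to_numpy()[np.isclose(delta, 0.0)]
            for m, d_, w_ in zip(sub["model"], delta, w):
                rec[f"d{crit}_{m}"] = d_
                rec[f"w{crit}_{m}"] = w_
            rec[f"best_{crit}"] = "/".join(best)
        out.append(rec)
    return pd.DataFrame(out)


def _best_count_frame(records: pd.DataFrame, crit: str, models) -> pd.DataFrame:
    """Per-dataset best-fit counts; ties split equally across tied models."""
    counts = {}
    for _, row in records.iterrows():
        ds = row.get("dataset", "all")
        tied = row[f"best_{crit}"].split("/")
        for m in models:
            counts.setdefault(ds, {m_: 0.0 for m_ in models})
        for m in tied:
            counts[ds][m] += 1.0 / len(tied)
    return pd.DataFrame(counts).T[list(models)]


def aggregate_best_fit(records: pd.DataFrame, models=("V1", "V2", "B1", "B2")) -> dict:
    """Summarize selection records into the published table's layout.

    Returns, per criterion: per-dataset mean weights, per-dataset best-fit
    counts, pooled best-fit percentages over all participants, the
    per-dataset threshold-vs-drift ratios (from mean weights) and their
    unweighted mean across data sets.
    """
    summary = {}
    for crit in ("aic", "bic"):
        wcols = {m: f"w{crit}_{m}" for m in models}
        group = records.groupby("dataset") if "dataset" in records.columns else [("all", records)]
        mean_w = {}
        for ds, sub in group:
            mean_w[ds] = {m: float(sub[col].mean()) for m, col in wcols.items()}
        counts = _best_count_frame(records, crit, models)
        pooled = counts.sum(axis=0)
        pooled_pct = (100.0 * pooled / pooled.sum()).to_dict()
        ratios = {
            ds: b_vs_v_ratio(w) for ds, w in mean_w.items()
        } if set(models) >= set(_B_MODELS + _V_MODELS) else {}
        summary[crit.upper()] = {
            "mean_weights": mean_w,
            "best_counts": counts,
            "pooled_pct": pooled_pct,
            "b_vs_v": ratios,
            "b_vs_v_mean": float(np.mean(list(ratios.values()))) if ratios else float("nan"),
        }
    return summary


def quantile_summary(rt_ms, correct, probs=DEFAULT_QUANTILES, min_count: int = 5) -> pd.DataFrame:
    """Defective quantile table for one condition cell.

    For each response class (correct/error), the within-class RT quantiles
    at ``probs`` and their cumulative heights ``p * class_proportion`` — the
    absolute cumulative proportion of all responses lying below the
    quantile. Classes with fewer than ``min_count`` responses are flagged
    unreliable but still tabulated; empty classes are omitted.
    """
    rt_ms = np.asarray(rt_ms, dtype=float)
    correct = np.asarray(correct, dtype=bool)
    if rt_ms.size == 0:
        raise ValueError("empty condition cell")
    rows = []
    n_total = rt_ms.size
    for label, mask in (("correct", correct), ("error", ~correct)):
        n = int(mask.sum())
        if n == 0:
            continue
        prop = n / n_total
        qs = np.quantile(rt_ms[mask], probs)
        for p, q in zip(probs, qs):
            rows.append(
                {
                    "class": label,
                    "quantile_p": p,
                    "rt_ms": float(q),
                    "cumulative_height": p * prop,
                    "n_class": n,
                    "reliable": n >= min_count,
                }
            )
    return pd.DataFrame(rows)


def _decision_grid(accs: AccumulatorSet, t_max: float = 8.0, n_grid: int = 4096):
    t = np.linspace(1e-6, t_max, n_grid)
    return t + accs.t0, t


def predicted_quantiles(accs: AccumulatorSet, probs=DEFAULT_QUANTILES) -> pd.DataFrame:
    """Model-implied defective quantile table for one condition.

    Within-class quantiles solve F_class(t)/p_class = p on a dense grid of
    the defective CDF.
    """
    rows = []
    rt, _ = _decision_grid(accs)
    for label in ("correct", "error"):
        dens = defective_density(rt, label, accs)
        cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2 * np.diff(rt))])
        p_class = cdf[-1]
        if p_class <= 0:
            continue
        for p in probs:
            q = float(np.interp(p * p_class, cdf, rt))
            rows.append(
                {
                    "class": label,
                    "quantile_p": p,
                    "rt_ms": 1000.0 * q,
                    "cumulative_height": p * p_class,
                    "p_class": p_class,
                }
            )
    return pd.DataFrame(rows)


def predicted_moments(mapping: dict, t_max: float = 8.0, n_grid: int = 4096) -> pd.DataFrame:
    """Quadrature mean RT (ms) and accuracy per condition.

    Means are over all responses (defective densities of both classes
    combined); ``mean_rt_correct_ms`` conditions on a correct response.
    """
    rows = []
    for cond, accs in mapping.items():
        rt, _ = _decision_grid(accs, t_max=t_max, n_grid=n_grid)
        f_c = defective_density(rt, "correct", accs)
        f_e = defective_density(rt, "error", accs)
        p_c = np.trapezoid(f_c, rt)
        p_e = np.trapezoid(f_e, rt)
        m_c = np.trapezoid(rt * f_c, rt) / p_c if p_c > 0 else float("nan")
        m_all = np.trapezoid(rt * (f_c + f_e), rt) / (p_c + p_e)
        rows.append(
            {
                "context": cond[0],
                "congruency": cond[1],
                "accuracy": p_c / (p_c + p_e),
                "mean_rt_ms": 1000.0 * m_all,
                "mean_rt_correct_ms": 1000.0 * m_c,
            }
        )
    return pd.DataFrame(rows)
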