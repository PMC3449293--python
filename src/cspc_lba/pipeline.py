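"""End-to-end pipeline: simulate (or load) → behavior → fit → select → recover.

``run_pipeline`` chains the stages over a cohort and writes every table as
delimited text plus a run manifest (seed, config echo, versions) so a rerun
with the same config reproduces every output byte for byte. Per-participant
fit failures are logged and tallied without aborting the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, selection, synth
from .fitting import FitConfig, ParticipantData, fit_participant, prepare_fit_data
from .model_space import MODEL_IDS
from .synth import DesignSpec, GeneratingModel

__all__ = ["RunConfig", "run_pipeline", "load_trials", "write_table"]

log = logging.getLogger("cspc_lba")


@dataclass(frozen=True)
class RunConfig:
    """Settings for one pipeline run.

    Either ``input_path`` (a trial table in the documented delimited
    format) or a synthetic cohort spec (``n_participants`` with
    ``design``/``generating_model``) must be provided.
    """

    out_dir: str
    seed: int = 0
    models: tuple = ("V1", "V2", "B1", "B2")
    input_path: str | None = None
    n_participants: int = 2
    design: DesignSpec = field(default_factory=DesignSpec)
    generating_model_id: str = "B2"
    generating_dataset: str = "I"
    fit_config: FitConfig = field(default_factory=FitConfig)

    def validate(self) -> None:
        unknown = set(self.models) - set(MODEL_IDS)
        if unknown:
            raise ValueError(f"unknown model ids: {sorted(unknown)}")
        if self.input_path is not None and not Path(self.input_path).exists():
            raise FileNotFoundError(self.input_path)


def write_table(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def load_trials(path) -> list:
    """Read a delimited trial table into per-participant data objects."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = {"participant", "block", "trial", "context", "congruency", "correct", "rt_ms"} - set(
        df.columns
    )
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    return [
        ParticipantData(str(pid), sub.reset_index(drop=True))
        for pid, sub in df.groupby("participant")
    ]


def run_pipeline(config: RunConfig) -> Path:
    """Run all stages and write artifacts under ``config.out_dir``.

    Returns the artifact directory. Emits: the trial table (if synthetic),
    behavioral cell means and CSPC contrasts, per-participant fit rows,
    selection records and summary, per-condition quantile summaries, and
    ``manifest.json``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()

    truth = None
    if config.input_path is not None:
        cohort = load_trials(config.input_path)
    else:
        gen = GeneratingModel.from_reference(config.generating_model_id, config.generating_dataset)
        cohort, truth = synth.simulate_participants(
            config.design, gen, config.n_participants,
            seed=config.seed, dataset=config.generating_dataset,
        )
        write_table(pd.concat([p.trials for p in cohort]), out / "trials.tsv")
        write_table(truth, out / "generating_truth.tsv")

    # behavioral descriptives on the pooled, trimmed data
    pooled = pd.concat([p.trials for p in cohort], ignore_index=True)
    trimmed = behavior.label_transitions(behavior.trim_trials(pooled))
    cells = behavior.cell_means(trimmed)
    write_table(cells, out / "behavior_cells.tsv")
    contrasts = pd.DataFrame(
        [
            {"statistic": "cspc_rt_ms", "value": behavior.cspc_statistic(cells)},
            {"statistic": "cspc_error_pct", "value": behavior.cspc_statistic(cells, "error_rate_pct")},
        ]
    )
    write_table(contrasts, out / "behavior_contrasts.tsv")
    trans_cells = behavior.cell_means(
        trimmed.dropna(subset=["transition"]), by=("transition", "context", "congruency")
    )
    write_table(trans_cells, out / "behavior_transition_cells.tsv")

    # quantile summaries per condition (pooled)
    qrows = []
    for (ctx, cong), sub in trimmed.groupby(["context", "congruency"], observed=True):
        q = selection.quantile_summary(sub["rt_ms"].to_numpy(), sub["correct"].to_numpy(bool))
        q.insert(0, "congruency", cong)
        q.insert(0, "context", ctx)
        qrows.append(q)
    write_table(pd.concat(qrows, ignore_index=True), out / "quantiles.tsv")

    # per-participant maximum-likelihood fits
    fit_rows, failures = [], []
    for pdata in cohort:
        try:
            prepared = prepare_fit_data(pdata)
        except ValueError as exc:
            log.warning("skipping %s: %s", pdata.participant, exc)
            failures.append({"participant": pdata.participant, "error": str(exc)})
            continue
        ds = str(prepared.trials["dataset"].iloc[0]) if "dataset" in prepared.trials else "all"
        for model_id in config.models:
            t0 = time.time()
            try:
                res = fit_participant(prepared, model_id, config.fit_config)
            except Exception as exc:  # noqa: BLE001 - continue over participants
                log.warning("fit failed for %s/%s: %s", pdata.participant, model_id, exc)
                failures.append(
                    {"participant": pdata.participant, "model": model_id, "error": str(exc)}
                )
                continue
            row = {"participant": pdata.participant, "dataset": ds} | res.to_row()
            fit_rows.append(row)
            log.info("fit %s %s: loglik=%.2f (%.1fs)", pdata.participant, model_id,
                     res.loglik, time.time() - t0)
    fits = pd.DataFrame(fit_rows)
    write_table(fits, out / "fits.tsv")

    # model selection
    if len(fits):
        records = selection.selection_records(fits)
        write_table(records, out / "selection_records.tsv")
        summary = selection.aggregate_best_fit(records, models=list(config.models))
        summary_rows = []
        for crit, s in summary.items():
            for ds, w in s["mean_weights"].items():
                for m, wt in w.items():
                    summary_rows.append(
                        {
                            "criterion": crit,
                            "dataset": ds,
                            "model": m,
                            "mean_weight": wt,
                            "best_count": s["best_counts"].loc[ds, m],
                            "pooled_pct": s["pooled_pct"][m],
                        }
                    )
            for ds, r in s["b_vs_v"].items():
                summary_rows.append(
                    {"criterion": crit, "dataset": ds, "model": "B_vs_V", "mean_weight": r}
                )
        write_table(pd.DataFrame(summary_rows), out / "selection_summary.tsv")

    # recovery scoring when generating truth is known
    if truth is not None and len(fits) and config.generating_model_id in set(fits["model"]):
        report = synth.recovery_report(fits, truth)
        (out / "recovery.json").write_text(json.dumps(report, indent=2, default=float))

    manifest = {
        "seed": config.seed,
        "models": list(config.models),
        "n_participants": len(cohort),
        "failures": failures,
        "config": _as_jsonable(config),
        "versions": {
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "elapsed_s": round(time.time() - t_start, 2),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    return obj
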