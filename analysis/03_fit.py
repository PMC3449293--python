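"""Fit the four LBA parameterizations to every simulated participant.

Maximum likelihood via particle swarm, per participant x model; writes one
row per fit (parameters, log-likelihood, AIC, BIC) to results/fits.tsv.
"""

import argparse
import time
from pathlib import Path

import pandas as pd

from cspc_lba.fitting import FitConfig, fit_participant, prepare_fit_data
from cspc_lba.pipeline import load_trials, write_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--results-dir", default="results")
    ap.add_argument("--models", nargs="+", default=["V1", "V2", "B1", "B2"])
    ap.add_argument("--particles", type=int, default=24)
    ap.add_argument("--iterations", type=int, default=120)
    ap.add_argument("--restarts", type=int, default=2)
    args = ap.parse_args()
    out = Path(args.results_dir)
    cfg = FitConfig(
        n_particles=args.particles, n_iter=args.iterations,
        n_restarts=args.restarts, seed=args.seed,
    )

    rows = []
    for path in sorted(out.glob("trials_*.tsv")):
        ds = path.stem.split("_")[1]
        for pdata in load_trials(path):
            prep = prepare_fit_data(pdata)
            for model_id in args.models:
                t0 = time.time()
                res = fit_participant(prep, model_id, cfg)
                rows.append({"participant": pdata.participant, "dataset": ds} | res.to_row())
                print(
                    f"{ds}/{pdata.participant} {model_id}: loglik={res.loglik:.1f} "
                    f"BIC={res.bic:.1f} ({time.time() - t0:.1f}s)"
                )
    write_table(pd.DataFrame(rows), out / "fits.tsv")


if __name__ == "__main__":
    main()
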