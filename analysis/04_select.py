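"""Model selection over the fitted cohorts, plus the published-table arithmetic.

Part 1 turns results/fits.tsv into per-participant AIC/BIC weights, best-model
tallies and threshold-vs-drift ("B vs V") evidence ratios for the simulated
cohorts. Part 2 reconstructs the derived cells of the published selection
table from its printed per-model weights and best-fit counts: the eight
B-vs-V ratios, their means across data sets, and the pooled best-fit
percentages over the 87 participants.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from cspc_lba import reference
from cspc_lba.pipeline import write_table
from cspc_lba.selection import aggregate_best_fit, b_vs_v_ratio, selection_records


def published_reconstruction() -> pd.DataFrame:
    rows = []
    n_total = sum(reference.N_PARTICIPANTS.values())
    for crit in ("AIC", "BIC"):
        ratios = []
        for ds in reference.DATASETS:
            r = b_vs_v_ratio(reference.IC_WEIGHTS[(crit, ds)])
            ratios.append(r)
            rows.append({"criterion": crit, "dataset": ds, "quantity": "b_vs_v",
                         "reconstructed": r,
                         "published": reference.PUBLISHED_B_VS_V[(crit, ds)]})
        rows.append({"criterion": crit, "dataset": "mean", "quantity": "b_vs_v",
                     "reconstructed": float(np.mean(ratios)),
                     "published": reference.PUBLISHED_B_VS_V_MEAN[crit]})
        for m in ("V1", "V2", "B1", "B2"):
            count = sum(reference.BEST_COUNTS[(crit, ds)][m] for ds in reference.DATASETS)
            rows.append({"criterion": crit, "dataset": "pooled", "quantity": f"pct_{m}",
                         "reconstructed": 100.0 * count / n_total,
                         "published": reference.PUBLISHED_POOLED_PCT[crit][m]})
    return pd.DataFrame(rows)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results-dir", default="results")
    args = ap.parse_args()
    out = Path(args.results_dir)

    fits_path = out / "fits.tsv"
    if fits_path.exists():
        fits = pd.read_csv(fits_path, sep="\t")
        records = selection_records(fits)
        write_table(records, out / "selection_records.tsv")
        summary = aggregate_best_fit(records, models=sorted(set(fits["model"])))
        for crit, s in summary.items():
            print(f"{crit}: pooled best-fit %:",
                  {m: round(p, 1) for m, p in s["pooled_pct"].items()},
                  f"mean B vs V = {s['b_vs_v_mean']:.2f}")
    else:
        print("no fits.tsv found; run 03_fit.py first (published part still written)")

    recon = published_reconstruction()
    write_table(recon, out / "published_reconstruction.tsv")
    worst = (recon["reconstructed"] - recon["published"]).abs().max()
    print(f"published-table reconstruction: {len(recon)} cells, "
          f"max |reconstructed - published| = {worst:.3f}")


if __name__ == "__main__":
    main()
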