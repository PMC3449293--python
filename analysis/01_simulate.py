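"""Simulate synthetic flanker cohorts for the four study designs.

Writes one trial table and one generating-truth sidecar per data set under
results/. Data set I uses the 4x112 scanner design; II-IV the 7x64
behavioral design. Generating parameters are the published group-average
threshold-model (B2) values for each data set, so the cohorts land in the
empirically observed accuracy/RT regime.
"""

import argparse
from pathlib import Path

import pandas as pd

from cspc_lba.pipeline import write_table
from cspc_lba.synth import DesignSpec, GeneratingModel, simulate_participants


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-participants", type=int, default=4, help="per data set")
    ap.add_argument("--out-dir", default="results")
    args = ap.parse_args()

    out = Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    designs = {
        "I": DesignSpec(n_blocks=4, trials_per_block=112),
        "II": DesignSpec(n_blocks=7, trials_per_block=64),
        "III": DesignSpec(n_blocks=7, trials_per_block=64),
        "IV": DesignSpec(n_blocks=7, trials_per_block=64),
    }
    for i, (ds, spec) in enumerate(designs.items()):
        gen = GeneratingModel.from_reference("B2", ds)
        cohort, truth = simulate_participants(
            spec, gen, args.n_participants, seed=args.seed + i, dataset=ds
        )
        trials = pd.concat([p.trials for p in cohort], ignore_index=True)
        write_table(trials, out / f"trials_{ds}.tsv")
        write_table(truth, out / f"truth_{ds}.tsv")
        resp = trials[~trials["omission"]]
        print(
            f"data set {ds}: {len(cohort)} participants x {cohort[0].n_trials} trials, "
            f"accuracy {100 * resp['correct'].mean():.1f}%, "
            f"mean RT {resp['rt_ms'].mean():.0f} ms"
        )


if __name__ == "__main__":
    main()
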