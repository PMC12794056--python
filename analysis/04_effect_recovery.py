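"""Power and accuracy of enrichment recovery.

Generates cohorts with a known distal fibrosis enrichment (p0 = 0.25,
delta = 0.08, enrichment disks covering each distal tile), runs the
pipeline, and compares the measured distal-minus-proximal mean metric with
the analytic expectation from the generator's ground truth, recording how
often both tests detect the enrichment at the 1% level.

Run:  python analysis/04_effect_recovery.py [--reps 20]
"""

import argparse
import time
from pathlib import Path

import pandas as pd

from afm.imaging import FibrosisParams
from afm.metrics import compute_tile_metrics, records_to_frame
from afm.stats import compare_groups
from afm.synthetic import effect_spec, generate_slide


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--reps", type=int, default=20)
    ap.add_argument("--seed", type=int, default=60_000)
    ap.add_argument("--out", type=Path, default=Path("results/effect_recovery.csv"))
    args = ap.parse_args()

    params = FibrosisParams()
    rows = []
    t0 = time.time()
    for i in range(args.reps):
        slide = generate_slide(effect_spec(seed=args.seed + i))
        frame = records_to_frame(
            compute_tile_metrics(slide.image, slide.annotations, params, nominal_size=64)
        )
        by = frame.groupby("tubule_class")["fibrotic_fraction"].mean()
        gby = slide.ground_truth.groupby("tubule_class")["expected_fraction"].mean()
        res = compare_groups(frame)
        rows.append(
            {
                "seed": args.seed + i,
                "observed_diff": by["distal"] - by["proximal"],
                "expected_diff": gby["distal"] - gby["proximal"],
                "p_t": res.p_t,
                "p_u": res.p_u,
            }
        )
    table = pd.DataFrame(rows)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out, index=False)

    err = (table["observed_diff"] - table["expected_diff"]).abs()
    power = ((table["p_t"] < 0.01) & (table["p_u"] < 0.01)).mean()
    print(
        f"{args.reps} enriched cohorts in {time.time() - t0:.0f}s: "
        f"mean observed diff {table['observed_diff'].mean():.4f} vs analytic "
        f"{table['expected_diff'].mean():.4f} (mean |error| {err.mean():.4f}); "
        f"both tests significant at 1% in {power:.0%} of replicates"
    )


if __name__ == "__main__":
    main()
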