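#!/usr/bin/env python
"""Per-synapse K-means cluster analysis of reconstructed gold positions.

For every reconstructed synapse: SSD curve over k = 1..N, knee-point
cluster number, and a 50-map randomization null (same particle count placed
uniformly over the reconstructed PSD).  Regresses SSD on PSD area for data
and null.  Cluster numbers should be modally 2 for the AMPA-like and 1 for
the NMDA-like condition, with data SSD below the randomized null.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from nanosyn.annotations_io import group_reconstructions, read_annotations
from nanosyn.clustering import cluster_analysis, cohort_table, regress_ssd_vs_size

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    out = ROOT / "tables"
    out.mkdir(parents=True, exist_ok=True)
    for name in ("AMPA_like", "NMDA_like"):
        ds = read_annotations(ROOT / "data" / f"{name}.json")
        rng = np.random.default_rng(4)
        results = [
            cluster_analysis(syn, n_maps=50, seed=rng.integers(2**31))
            for syn in group_reconstructions(ds)
        ]
        cohort = cohort_table(results)
        cohort.to_csv(out / f"clusters_{name}.csv", index=False)
        analyzed = cohort[cohort.n_gold >= 4]
        frac_below = float(
            (analyzed.ssd_nm2 < analyzed.randomized_mean_ssd_nm2).mean()
        )
        print(f"{name}: {len(analyzed)} analyzed synapses, "
              f"median k={analyzed.k_opt.median():.0f}, "
              f"median gold/synapse={cohort.n_gold.median():.0f}, "
              f"data SSD < null in {frac_below:.0%}")
        try:
            for which in ("data", "randomized"):
                fit = regress_ssd_vs_size(results, which)
                print(f"  SSD ~ area ({which}): R^2={fit['r_squared']:.2f} "
                      f"slope p={fit['p_value']:.2g}")
        except ValueError as e:
            print(f"  regression skipped: {e}")


if __name__ == "__main__":
    main()
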