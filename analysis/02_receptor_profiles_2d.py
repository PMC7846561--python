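#!/usr/bin/env python
"""Receptor positions within single 2D profiles.

Measures each gold particle's normalized lateral distance from the PSD
center (0 = center, 1 = edge) in every profile, pools per receptor type,
and tests each pool against the theoretical uniform median of 0.5 with
one-sample two-tailed Wilcoxon signed-rank tests.  Edge-biased AMPA-like
placement should pool above 0.5; the centrally clustered NMDA-like
placement below it.
"""

from pathlib import Path

import pandas as pd

from nanosyn.annotations_io import read_annotations
from nanosyn.inferential_stats import results_table, wilcoxon_one_sample
from nanosyn.spatial_metrics import normalized_distance_2d, pool_distributions

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    groups = {}
    for name in ("AMPA_like", "NMDA_like"):
        ds = read_annotations(ROOT / "data" / f"{name}.json")
        groups[name.split("_")[0]] = [
            normalized_distance_2d(g, p.psd_trace)
            for p in ds.profiles
            for g in p.gold
        ]
    summary, ecdfs = pool_distributions(groups, seed=1)
    out = ROOT / "tables"
    out.mkdir(parents=True, exist_ok=True)
    summary.to_csv(out / "receptor_2d_summary.csv", index=False)
    rows = []
    for label, locs in groups.items():
        res = wilcoxon_one_sample([l.normalized for l in locs], 0.5)
        rows.append({"comparison": f"{label} vs uniform 0.5", "n": res.n[0],
                     "statistic": res.statistic, "p": res.p_value,
                     "p_corrected": min(1.0, 2 * res.p_value),
                     "method": res.method})
        ecdfs[label].to_csv(out / f"receptor_2d_ecdf_{label}.csv", index=False)
    results_table(rows).to_csv(out / "receptor_2d_wilcoxon.csv", index=False)
    for _, r in summary.iterrows():
        print(f"{r.group}: n={r.n} median={r['median']:.3f} "
              f"[{r.ci_lo:.3f}, {r.ci_hi:.3f}]")
    for row in rows:
        print(f"{row['comparison']}: W={row['statistic']:.0f} p={row['p']:.2e}")


if __name__ == "__main__":
    main()
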