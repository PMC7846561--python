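#!/usr/bin/env python
"""Generate the synthetic study datasets for all downstream analyses.

Emulates the study's conditions: receptor-labeled synapses imaged as 20-nm
block-face stacks (AMPA-like edge clusters, NMDA-like central cluster) and
40-nm TEM profiles frozen at rest / 5 ms / 11 ms after stimulation (docked
vesicles uniform, pits progressively center-biased).  Writes annotation JSON
plus ground-truth sidecars under results/data/.
"""

import json
from pathlib import Path

from nanosyn.annotations_io import write_annotations
from nanosyn.synthetic_data import generate_dataset, preset

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = 2000
SIZES = {
    "AMPA_like": 40,
    "NMDA_like": 40,
    "pits_5ms": 150,
    "pits_11ms": 150,
    "docked": 150,
}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for i, (name, n) in enumerate(SIZES.items()):
        cfg = preset(name, n_synapses=n, seed=SEED + i)
        ds, sidecar = generate_dataset(cfg)
        write_annotations(ds, OUT / f"{name}.json")
        (OUT / f"{name}.truth.json").write_text(json.dumps(sidecar))
        n_gold = sum(len(p.gold) for p in ds.profiles)
        n_pits = sum(len(p.pits) for p in ds.profiles)
        print(f"{name}: {len(ds)} profiles, {n_gold} gold, {n_pits} pits")


if __name__ == "__main__":
    main()
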