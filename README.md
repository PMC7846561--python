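# nanosyn

Spatial statistics of synaptic nano-organization, and a desk-scale model of
AMPA/NMDA receptor activation by spatiotemporally patterned glutamate
release.

At excitatory synapses, glutamate receptors are not spread evenly under the
postsynaptic density (PSD): AMPA receptors cluster toward its edge, NMDA
receptors near its center, and vesicle fusion sites mirror this arrangement
— synchronous fusion near AMPA clusters, late (asynchronous) fusion near the
center.  `nanosyn` implements the quantitative toolchain needed to measure
and interpret that organization from immunogold electron-microscopy
annotations, plus a receptor-kinetics simulator that asks what the
arrangement does to signaling:

- **annotations_io** — a JSON data model for per-section point annotations
  (gold particles, docked vesicles, exocytic pits; AZ/PSD membrane
  polylines in nm), with validation, blinding, and flat CSV export.
- **synthetic_data** — a forward model of the experiment: placement laws on
  a disc-shaped PSD parameterized on the fractional-area coordinate
  u = (r/R)², ~50% gold-labeling with background, and random 20/40-nm
  sectioning.  Ground truth ships in a sidecar, so every downstream stage
  is tested by parameter recovery.
- **spatial_metrics** — normalized lateral distance in 2D profiles
  (0 = PSD center, 1 = edge, arc-length convention), serial-section 3D
  distance (√(d_lat² + Δz²), normalized by the equivalent-circle radius),
  the fractional-area correction (normalized², which maps a uniform surface
  distribution to U[0, 1]), nearest-gold distances, densities, and
  bootstrap-pooled summaries.
- **clustering** — per-synapse K-means (Lloyd's algorithm) over k = 1..N,
  knee-point selection of the cluster number on the SSD curve, a 50-map
  uniform-within-PSD randomization null, and SSD-vs-area regression.
- **inferential_stats** — one-sample Wilcoxon signed-rank vs. the uniform
  median 0.5 (exact at small n), Mann–Whitney U, two-sample KS D,
  Kruskal–Wallis + Dunn, Bonferroni, D'Agostino–Pearson.
- **receptor_sim** — 2D slab diffusion transient for ~2000 released
  glutamate molecules, Markov schemes for AMPA (with desensitization) and
  NMDA receptors (with voltage-dependent trapping Mg²⁺ block), an EPSP
  voltage template peaking at +25 mV, mean-field (RK4, 1-µs steps) and
  per-receptor stochastic integration, and a scenario grid over release
  patterns × delays × voltage protocols.
- **pipeline / CLI** — `nanosyn run --config cfg.yaml` orchestrates
  generate → metrics → cluster → stats → simulate with one master seed and
  manifested, cached outputs.

The `analysis/` directory holds the numbered study scripts
(01_generate_datasets … 06_receptor_activation); each writes tidy CSV
tables under `results/tables/`.

## Worked example

Generate a synthetic cohort and run the numbered analyses:

```bash
python analysis/01_generate_datasets.py
python analysis/02_receptor_profiles_2d.py
python analysis/04_cluster_analysis.py
python analysis/06_receptor_activation.py
```

prints (abridged):

```
AMPA: n=641 median=0.545 [0.521, 0.569]
NMDA: n=384 median=0.154 [0.135, 0.168]
AMPA vs uniform 0.5: W=122473 p=2.95e-05
AMPA_like: 40 analyzed synapses, median k=2, median gold/synapse=16, data SSD < null in 100%
NMDA_like: 39 analyzed synapses, median k=1, median gold/synapse=10, data SSD < null in 100%
NMDA AUC at 5 ms delay (EPSP-coupled):
  A-N: 14.91   N-A: 15.73   N-N: 12.12   A-A: 18.94
  N-N vs A-N: 19% lower
Mg-free NMDA AUC by delay: 0 ms: 130.2, 5 ms: 161.0, 10 ms: 178.5, 20 ms: 200.8, 50 ms: 223.1
```

Reading: pooled 2D normalized distances put the edge-biased receptor above
the uniform median of 0.5 and the centrally clustered one far below it
(one-sample Wilcoxon); knee-point K-means recovers 2 clusters per synapse
for the peripheral receptor and 1 for the central one, always tighter than
the randomized null.  In the simulator, NMDA activation is insensitive to
the order of the two release events (A-N ≈ N-A), drops by ~19% when both
releases occur at the NMDA cluster (weaker AMPA-mediated depolarization),
and — without Mg²⁺ block — grows monotonically as the second release is
delayed out to 50 ms (long-lived singly-bound receptors).

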