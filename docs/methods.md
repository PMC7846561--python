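# Methods

This note documents the models, conventions, parameters and numerical
choices behind `nanosyn`, and what the synthetic-data tests do and do not
establish about real electron-microscopy data.

## Coordinate and distance conventions

Annotations are Cartesian nanometre coordinates with an arbitrary
per-profile origin; y increases upward; the section z-coordinate is always
derived as `section_index × section_thickness_nm`, never stored.

**2D normalized distance.** A particle is projected to the nearest point on
the membrane polyline; its raw distance is the *arc length* from that
projection to the trace center (the point at half the total arc length),
and the normalized distance divides by the trace half-width.  0 is exactly
the center, 1 exactly the edge.  We use arc rather than chord distance
because the traces are curved membranes and the normalizing half-width is
itself an arc quantity; a `mode="chord"` switch exists for sensitivity
analysis.  Projections beyond a trace terminus extend the terminal segment
linearly, so such points keep normalized > 1 and are flagged rather than
clamped; pooling includes them by default (out-of-AZ pits are excluded
upstream at annotation time).

**3D distance.** Serial sections are assumed laterally pre-aligned (an
explicit per-profile (dx, dy) offset defaults to zero).  The lateral offset
within a particle's own section and the section offset
`|section − middle| × thickness` combine by the Pythagorean theorem.  The
"size" of a reconstructed PSD is not directly observable; we normalize by
the equivalent-circle radius `R = √(area/π)` with
`area = Σ trace length × thickness` (the maximum-extent alternative is not
used).

**Fractional-area correction.** For a circular PSD, squaring the normalized
radial distance gives the fraction of disc area inside that radius, so a
uniform surface distribution becomes uniform on [0, 1].  The identity
`fractional_area = normalized²` holds exactly by construction.

## Synthetic-data forward model

Each synapse is a disc PSD (default radius 150 nm) with a congruent AZ (a
flag allows unequal radii).  Placement laws are parameterized on the
fractional-area coordinate so the uniform law is exactly Beta(1, 1):
edge bias draws u ~ Beta(a, 1) (a > 1), center bias u ~ Beta(1, b) (b > 1),
and the clustered law scatters Gaussian clouds around centroids drawn
uniformly (by area) on an annulus of the disc.  Gold labeling keeps each
receptor with probability 0.5 (the estimated labeling efficiency) and adds
Poisson off-PSD background at 0.03 per profile.  Docked vesicles (1.9 per
profile) and pits (0.28 per profile) are additional point sets on the AZ.
Total per-synapse counts are Poisson with expectation rate × expected
profile count, so per-profile expectations match the configured rates.

Sectioning slices the disc into parallel slabs of 20 nm (block-face) or
40 nm (TEM) at a random orientation and phase; each slab whose center lies
inside the disc becomes a profile whose PSD trace is the straight chord at
the slab-center offset, and particle in-plane positions are signed
distances along the chord.  Particle counts arise from this 3D
placement-plus-slab geometry, not from independent 2D draws.  Monte-Carlo
verification shows the pooled 2D normalized distance of uniformly placed
particles has median 0.500–0.503 under this construction (the small
positive bias at 40 nm thickness comes from the chord being evaluated at
the slab center), which is the premise that pooled random profiles estimate
the surface distribution.

Preset conditions (frozen defaults):

| preset      | placement                                            | thickness |
|-------------|------------------------------------------------------|-----------|
| AMPA_like   | 2 clusters, σ = 15 nm, centroids at 0.55–0.85 R      | 20 nm     |
| NMDA_like   | 1 cluster, σ = 25 nm, centroid within 0.25 R         | 20 nm     |
| pits_5ms    | center-biased Beta(1, 1.5) → pooled 2D median ≈ 0.4  | 40 nm     |
| pits_11ms   | center-biased Beta(1, 14) → pooled 2D median ≈ 0.13  | 40 nm     |
| docked      | uniform, 1.9 per profile                             | 40 nm     |

The pit beta parameters were calibrated numerically to the target pooled
medians and are conveniences, not empirical claims.  Cluster widths are at
the physiological nanodomain scale (~70–80 nm domains); the per-synapse
receptor means (32 AMPA-like, 20 NMDA-like true receptors, i.e. ~16 and
~10 gold at 50% labeling) reproduce realistic per-synapse gold counts.
Randomness flows from one master seed through `numpy.random.SeedSequence`
spawning, so datasets are bit-reproducible and parallel-safe.

What the generator does *not* emulate: electron-optics, staining artifacts,
segmentation error, curved (non-disc) PSDs, or per-synapse size
variability — synthetic PSDs share one radius, so the SSD-vs-area
regression, while implemented and unit-tested on constructed data, is
uninformative on synthetic cohorts.  Passing recovery tests show the
*estimators* are consistent under the stated model, not that real synapses
satisfy the model.

## Cluster analysis

Per synapse, gold particles are mapped to planar surface coordinates
(signed lateral arc offset, section offset) and Lloyd's k-means is run for
k = 1..N with 10 uniform-random point seedings plus a warm start that
splits the k−1 solution at its worst-fit point — this makes SSD(k)
structurally non-increasing.  Small instances (C(N, k) ≤ 60) are seeded
from every distinct point subset, which makes the optimizer provably reach
the exhaustive-partition optimum on the tested instance sizes.  Empty
clusters re-seed to the farthest point that is not a sole cluster member.

The cluster number is the knee of the SSD curve: both axes are min–max
normalized and the perpendicular distance to the chord from (1, SSD(1)) to
(N, SSD(N)) is maximized.  Two constants make this a decision rule rather
than a bare argmax, and both are deliberate design choices: a knee must be
*pronounced* (maximum normalized chord distance ≥ 0.45, else the curve is
treated as featureless decay and one cluster is reported — a bare argmax
can never return k = 1 on a convex curve), and near-ties within 90% of the
maximum break to the smallest k (conservative).  Synapses with fewer than
4 particles skip knee selection and report one cluster, matching the
smallest observed cluster size.

The randomization null draws the same number of particles uniformly over
the reconstructed PSD surface (sections weighted by trace length ×
thickness, uniform along each trace, z at the slice center) 50 times; each
null map is scored at its *own* knee-selected k, which keeps the null
self-consistent (a flag switches to the data's k).  On planted-cluster
fixtures the data SSD falls below the null mean in 100% of synapses.

## Statistical tests

Wrappers over scipy.stats pin conventions: the Wilcoxon statistic is W⁺
(sum of positive ranks) with zero differences dropped and an exact null for
n ≤ 25 without ties (normal approximation with continuity and tie
correction otherwise); Mann–Whitney reports U₁ with an exact null for
min(n, m) ≤ 8; KS uses the asymptotic Kolmogorov distribution; Dunn's
post-hoc z tests on pooled mid-ranks are Bonferroni-scaled.  Type-I error
for both location tests is verified to lie in [0.035, 0.065] at α = 0.05
over 1000 null replicates.

## Receptor activation model

**Geometry.** The cleft is an analytic 20-nm slab over a 150-nm-radius PSD
disc.  Receptor clusters are placed deterministically: ~20 AMPA receptors
at (+50, 0) nm and ~15 NMDA receptors at (−50, 0) nm — centroids 100 nm
apart.  Each population sees the glutamate concentration at its centroid.

**Glutamate transient.** A fusion event releases 2000 molecules that
spread by 2D diffusion (D = 0.3 µm²/ms) in the slab with first-order
clearance (τ = 1 ms, standing in for astrocytic transporter uptake and
cleft escape): C(r, t) = n/(h·4πDt) · exp(−r²/4Dt) · exp(−t/τ), evaluated
from t₀ = 1 µs.  Mass is conserved to 0.1% when clearance is disabled and
the peak time at distance r matches the analytic t* = r²/4D.

**Kinetic schemes.** Both receptors bind two glutamate molecules
sequentially (statistical factors 2kon / kon).  All rate constants are
configuration entries with representative defaults shipped in a versioned
YAML (`nanosyn/data/receptor_rates.yaml`); the scheme topology is fixed in
code.  AMPA: association 10⁷ M⁻¹s⁻¹, fast gating (β = 4.2, α = 0.9 ms⁻¹),
desensitization from the doubly-bound closed state (1 ms⁻¹) with slow
recovery (67 ms), giving paired-pulse depression for same-site releases
closer than ~15 ms and a 52% peak-open reduction when release moves 100 nm
away (within the expected 20–70% band).  NMDA: association
1.5 × 10⁷ M⁻¹s⁻¹ with *decoupled* unbinding — the singly-bound state lives
~67 ms while the doubly-bound state unbinds at 0.15 ms⁻¹ — so the open
burst stays inside the depolarization window while a singly-bound
"primed" pool persists for tens of milliseconds.  These two time scales
are what express the package's qualitative contracts: without Mg²⁺ the
NMDA response to a second release grows monotonically with its delay out
to 50 ms (+71% here), because the saturating first response must decay
before the second release can add charge and the primed pool keeps late
re-activation efficient.

**Mg²⁺ block.** Woodhull-form voltage dependence: block slows e-fold per
28 mV and unblock speeds e-fold per 38 mV of depolarization (combined
e-fold ≈ 16 mV, ~95% block at −70 mV in 1 mM Mg²⁺).  Block is *trapping*
by default — a blocked channel can close and release glutamate behind the
blocker through a mirrored chain of blocked-closed states, as the
physiological blocker does.  This choice matters: with a purely
open-state (non-trapping) block the entire bound pool is kinetically stuck
behind the blocker at rest and trickles out over ~90 ms, which buries
every release-timing effect; the non-trapping variant remains available
behind a flag.

**Voltage.** Clamped modes hold −70 mV or a fixed depolarization; the
EPSP-coupled mode triggers one template per release event — a
monotone-segment piecewise cubic through (0, 0), (4, 25), (8, 50/3),
(10, 2), (15, 0) ms/mV, so the peak is exactly +25 mV and the value at
8 ms exactly 2/3 of peak — summed linearly and capped at rest + 45 mV.
Because the depolarization is AMPA-receptor-mediated, each event's
amplitude is attenuated by exp(−d/λ) with d the release site's distance to
the AMPA cluster and λ = 100/ln 2 nm; λ was chosen so the attenuation at
100 nm (0.5) matches the measured distance fall-off of simulated AMPA
charge (AUC ratio 0.504 at 100 nm), and it is this attenuation that
reproduces the ~19% NMDA deficit when both releases occur at the NMDA
cluster.

**Integration.** Mean-field occupancies follow dp/dt = p·Q(glu(t), V(t))
under classic RK4 with a 1-µs default step (occupancies are renormalized
each step; drift beyond 10⁻⁶ aborts with advice to reduce dt).  The
glutamate spike at a release site is stiff: scenarios with release at the
NMDA cluster need the 1-µs step, while 100-nm-distant release tolerates
2 µs.  The scenario grid batches all cells into one vectorized integration
per receptor kind, which is numerically identical to cell-by-cell
simulation (verified) and makes the full grid run in minutes.  Stochastic
mode simulates `trials` (default 48) independent per-receptor Markov
chains by fixed-step thinning, automatically subcycling while the
transient makes first-order probabilities invalid; its mean agrees with
mean-field within sampling error.  AUC is the trapezoidal time-integral of
the open-receptor count on a 0.1-ms recording grid.

**Problem sizes.** Test and analysis runs use 150-ms (orderings) and
250-ms (Mg-free series) horizons and 15–40-ms horizons for single-pulse
properties; the uniform-placement calibration pools ≥ 10⁴ particles over
three seeds.  These sizes put every check within minutes on one core while
leaving the measured quantities' sampling error well inside the asserted
tolerances.

## Known limitations

- The cleft model has no 3D escape geometry, no explicit transporters and
  no receptor-level spatial heterogeneity within a cluster; distance
  effects enter only through the centroid concentration.
- EPSP coupling is template-triggered, not conductance-computed; amplitude
  attenuation with release distance is a modeling choice (calibrated to
  the simulated AMPA charge fall-off), not derived from a cable model.
- Exact receptor rate constants are representative defaults calibrated to
  the package's qualitative property suite, not fits to recordings;
  quantitative AUC values are therefore not comparable across parameter
  sets, only orderings and ratios within one set.
- Synthetic PSDs are fixed-radius discs; analyses that depend on
  between-synapse size variance (SSD-vs-area regression) run but carry no
  information on synthetic cohorts.
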