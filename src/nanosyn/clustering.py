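"""Per-synapse K-means cluster analysis of reconstructed gold positions.

For each reconstructed synapse the gold particles are mapped to planar
surface coordinates (signed arc position within their own section, section
offset from the middle section x thickness), Lloyd's algorithm is run for
k = 1..N, the cluster number is chosen at the knee of the within-cluster
sum-of-squared-distances (SSD) curve, and the observed SSD is compared
against a null of 50 maps with the same particle count placed uniformly over
the reconstructed PSD surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotations_io import SynapseReconstruction
from .spatial_metrics import (
    SynapseGeometry3D,
    lateral_offset_nm,
    synapse_geometry_3d,
    _vertices,
    _cumlen,
)

__all__ = [
    "ClusterResult",
    "kmeans_lloyd",
    "ssd_curve",
    "knee_point",
    "reconstruct_coordinates",
    "randomize_within_psd",
    "cluster_analysis",
    "regress_ssd_vs_size",
]

#: below this many gold particles no knee is selected (observed cluster sizes
#: start at 4), the synapse reports a single cluster
MIN_PARTICLES_FOR_KNEE = 4


@dataclass
class ClusterResult:
    synapse_id: str
    n_particles: int
    k_opt: int
    centroids: np.ndarray
    assignments: np.ndarray
    ssd_curve: np.ndarray
    ssd_at_kopt: float
    randomized_mean_ssd: float | None
    cluster_sizes: list[int]
    area_um2: float | None = None


def _ssd(points: np.ndarray, assign: np.ndarray, cents: np.ndarray) -> float:
    return float(np.sum((points - cents[assign]) ** 2))


def _lloyd_once(points: np.ndarray, cents: np.ndarray, max_iter: int = 200):
    n, k = len(points), len(cents)
    assign = np.full(n, -1)
    for _ in range(max_iter):
        d2 = ((points[:, None, :] - cents[None, :, :]) ** 2).sum(axis=2)
        new_assign = np.argmin(d2, axis=1)
        # re-seed empty clusters to the worst-fit points (distinct, and never
        # a point that is its current cluster's sole member)
        empties = [j for j in range(k) if not np.any(new_assign == j)]
        if empties:
            order = np.argsort(-d2[np.arange(n), new_assign])
            taken: set[int] = set()
            for j in empties:
                for cand in order:
                    cand = int(cand)
                    if cand in taken:
                        continue
                    if np.sum(new_assign == new_assign[cand]) <= 1:
                        continue
                    cents[j] = points[cand]
                    new_assign[cand] = j
                    taken.add(cand)
                    break
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for j in range(k):
            members = assign == j
            if np.any(members):
                cents[j] = points[members].mean(axis=0)
    return assign, cents


def kmeans_lloyd(
    points,
    k: int,
    n_init: int = 10,
    seed=0,
    init_centroids: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Lloyd's algorithm, best of ``n_init`` uniform-random point seedings.

    Initial centroids are drawn uniformly without replacement from the points
    themselves (no k-means++ weighting); an optional explicit seeding is run
    as one extra restart (used to warm-start from the k-1 solution).  Empty
    clusters are re-seeded to the farthest point from its current centroid.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    n = len(points)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range 1..{n}")
    rng = np.random.default_rng(seed)
    best = None
    inits: list[np.ndarray] = []
    from math import comb
    from itertools import combinations

    if comb(n, k) <= max(n_init, 60):
        # small instance: seed from every distinct point subset
        for idx in combinations(range(n), k):
            inits.append(points[list(idx)].copy())
    else:
        for _ in range(n_init):
            idx = rng.choice(n, size=k, replace=False)
            inits.append(points[idx].copy())
    if init_centroids is not None:
        inits.append(np.asarray(init_centroids, dtype=float).copy())
    for cents0 in inits:
        assign, cents = _lloyd_once(points, cents0.copy())
        ssd = _ssd(points, assign, cents)
        if best is None or ssd < best[2] - 1e-12:
            best = (assign, cents, ssd)
    return best


def ssd_curve(points, k_max: int | None = None, n_init: int = 10, seed=0) -> np.ndarray:
    """SSD(k) for k = 1..k_max (default N), monotone non-increasing.

    Monotonicity is enforced structurally: the best solution at k-1, with one
    centroid split onto the farthest point, is supplied as a warm-start
    restart at k, so the optimizer can never do worse by adding a cluster.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    n = len(points)
    if n < 1:
        raise ValueError("need at least one point")
    k_max = n if k_max is None else min(k_max, n)
    rng = np.random.default_rng(seed)
    curve = np.empty(k_max)
    prev_cents = None
    for k in range(1, k_max + 1):
        warm = None
        if prev_cents is not None:
            d2 = ((points[:, None, :] - prev_cents[None, :, :]) ** 2).sum(axis=2)
            far = int(np.argmax(d2.min(axis=1)))
            warm = np.vstack([prev_cents, points[far]])
        assign, cents, ssd = kmeans_lloyd(
            points, k, n_init=n_init, seed=rng, init_centroids=warm
        )
        if k > 1 and ssd > curve[k - 2]:
            ssd = curve[k - 2]  # numerical guard; warm start makes this rare
        curve[k - 1] = ssd
        prev_cents = cents
    return curve


#: minimum normalized chord distance for a knee to count as pronounced; a
#: smoothly decaying SSD curve (one diffuse cluster) stays below this and
#: reports a single cluster
KNEE_SENSITIVITY = 0.45
#: plateau tie-break: the smallest k within this fraction of the maximum
#: chord distance is taken, keeping the conservative small-k convention
KNEE_PLATEAU_FRAC = 0.90


def knee_point(
    ssd: np.ndarray,
    sensitivity: float = KNEE_SENSITIVITY,
    plateau_frac: float = KNEE_PLATEAU_FRAC,
) -> int:
    """Cluster number at the knee of the SSD curve (kneedle-style).

    Both axes are min-max normalized and the perpendicular distance from
    (k, SSD(k)) to the chord joining (1, SSD(1)) and (N, SSD(N)) is
    computed.  A knee must be pronounced: if the maximum distance is below
    ``sensitivity`` the curve is treated as featureless decay and one
    cluster is reported.  Near-tied distances (within ``plateau_frac`` of
    the maximum) break to the smallest k; curves of length <= 2 report 1.
    """
    ssd = np.asarray(ssd, dtype=float)
    n = len(ssd)
    if n == 0:
        raise ValueError("empty SSD curve")
    if n <= 2:
        return 1
    span = ssd[0] - ssd[-1]
    if span <= 0:
        return 1
    x = np.linspace(0.0, 1.0, n)
    y = (ssd - ssd[-1]) / span
    # signed distance from (x, y) to the chord from (0, 1) to (1, 0)
    d = (1.0 - x - y) / np.sqrt(2.0)
    d_max = float(d.max())
    if d_max < sensitivity:
        return 1
    return int(np.argmax(d >= plateau_frac * d_max)) + 1


def reconstruct_coordinates(syn: SynapseReconstruction, kind: str = "gold") -> np.ndarray:
    """Planar PSD-surface coordinates (lateral arc offset, section offset) in nm."""
    coords = []
    for p in syn.profiles:
        dz = (p.section_index - syn.middle_index) * syn.thickness_nm
        for pt in getattr(p, kind):
            coords.append([lateral_offset_nm(p, pt), dz])
    return np.asarray(coords, dtype=float).reshape(-1, 2)


def randomize_within_psd(
    syn: SynapseReconstruction, n_points: int, n_maps: int = 50, seed=0
) -> list[np.ndarray]:
    """Null maps: ``n_points`` placed uniformly over the reconstructed PSD.

    Sections are weighted by trace length x thickness, positions are uniform
    along each section's trace, and the section offset is taken at the slice
    center — global area-weighted uniformity over the reconstructed surface.
    """
    if n_points < 1:
        raise ValueError("need at least one point")
    lengths = []
    for p in syn.profiles:
        lengths.append(_cumlen(_vertices(p.psd_trace))[-1])
    lengths = np.asarray(lengths)
    w = lengths / lengths.sum()
    ss = np.random.SeedSequence(
        seed.integers(2**31) if isinstance(seed, np.random.Generator) else seed
    )
    maps = []
    for child in ss.spawn(n_maps):
        rng = np.random.default_rng(child)
        secs = rng.choice(len(syn.profiles), size=n_points, p=w)
        pts = np.empty((n_points, 2))
        for i, si in enumerate(secs):
            p = syn.profiles[si]
            half = lengths[si] / 2.0
            pts[i, 0] = rng.uniform(-half, half)
            pts[i, 1] = (p.section_index - syn.middle_index) * syn.thickness_nm
        maps.append(pts)
    return maps


def cluster_analysis(
    syn: SynapseReconstruction,
    n_maps: int = 50,
    n_init: int = 10,
    seed=0,
    null_k: str = "knee",
) -> ClusterResult:
    """Full per-synapse cluster analysis with randomization null.

    The randomized-null mean SSD evaluates each null map at its own
    knee-selected k (``null_k="knee"``, self-consistent default) or at the
    data's k (``null_k="data"``).  Synapses with fewer than
    :data:`MIN_PARTICLES_FOR_KNEE` particles skip knee selection and report a
    single cluster with no null.
    """
    points = reconstruct_coordinates(syn, "gold")
    geom = synapse_geometry_3d(syn)
    n = len(points)
    sid = syn.synapse_id
    if n == 0:
        return ClusterResult(sid, 0, 0, np.empty((0, 2)), np.empty(0, int),
                             np.empty(0), 0.0, None, [], geom.area_um2)
    rng = np.random.default_rng(seed)
    if n < MIN_PARTICLES_FOR_KNEE:
        assign, cents, ssd = kmeans_lloyd(points, 1, n_init=1, seed=rng)
        return ClusterResult(sid, n, 1, cents, assign, np.array([ssd]), ssd,
                             None, [n], geom.area_um2)
    curve = ssd_curve(points, n_init=n_init, seed=rng)
    k_opt = knee_point(curve)
    assign, cents, ssd = kmeans_lloyd(points, k_opt, n_init=n_init, seed=rng)
    sizes = [int(np.sum(assign == j)) for j in range(k_opt)]
    null_ssds = []
    for m in randomize_within_psd(syn, n, n_maps=n_maps, seed=rng):
        mcurve = ssd_curve(m, n_init=n_init, seed=rng)
        mk = knee_point(mcurve) if null_k == "knee" else k_opt
        null_ssds.append(mcurve[mk - 1])
    return ClusterResult(
        sid, n, k_opt, cents, assign, curve, ssd,
        float(np.mean(null_ssds)), sizes, geom.area_um2,
    )


def regress_ssd_vs_size(
    results: list[ClusterResult], which: str = "data"
) -> dict:
    """OLS of per-synapse SSD on reconstructed PSD area.

    ``which`` selects the observed SSD (``"data"``) or the randomized-null
    mean (``"randomized"``).  Returns slope, intercept, R^2 and the two-sided
    slope p-value.
    """
    pairs = []
    for r in results:
        y = r.ssd_at_kopt if which == "data" else r.randomized_mean_ssd
        if r.n_particles >= 1 and y is not None and r.area_um2 is not None:
            pairs.append((r.area_um2, y))
    if len(pairs) < 3:
        raise ValueError("need >= 3 synapses with usable SSD")
    x, y = np.array(pairs).T
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: all areas equal")
    fit = sps.linregress(x, y)
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r_squared": float(fit.rvalue**2),
        "p_value": float(fit.pvalue),
        "n": len(pairs),
    }


def cohort_table(results: list[ClusterResult]) -> pd.DataFrame:
    rows = [
        {
            "synapse_id": r.synapse_id,
            "n_gold": r.n_particles,
            "k_opt": r.k_opt,
            "ssd_nm2": r.ssd_at_kopt,
            "randomized_mean_ssd_nm2": r.randomized_mean_ssd,
            "area_um2": r.area_um2,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
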