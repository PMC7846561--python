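"""Distance measures for synaptic point annotations.

2D: a particle's lateral position within a membrane trace is measured as the
arc distance from its projection onto the trace to the trace center, divided
by the trace half-width, so 0 is exactly at the center and 1 exactly at the
edge.  For serial-section reconstructions the lateral offset and the
inter-section offset combine by the Pythagorean theorem, the result is
normalized by the equivalent-circle radius of the reconstructed PSD, and the
normalized distance is squared ("fractional area" of a circular PSD) so that
a uniform surface distribution maps to a uniform distribution on [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotations_io import ProfileAnnotation, SynapseReconstruction

__all__ = [
    "NormalizedLocation",
    "SynapseGeometry3D",
    "trace_center_halfwidth",
    "normalized_distance_2d",
    "synapse_geometry_3d",
    "distance_3d",
    "nearest_gold_nm",
    "receptor_density",
    "pool_distributions",
    "ecdf_table",
]


@dataclass(frozen=True)
class NormalizedLocation:
    """One particle's location: raw nm, center-normalized, and fractional-area."""

    raw_nm: float
    normalized: float
    fractional_area: float
    beyond_edge: bool = False

    @classmethod
    def from_normalized(cls, raw_nm: float, normalized: float) -> "NormalizedLocation":
        return cls(
            raw_nm=float(raw_nm),
            normalized=float(normalized),
            fractional_area=float(normalized) ** 2,
            beyond_edge=bool(normalized > 1.0),
        )


@dataclass(frozen=True)
class SynapseGeometry3D:
    """Reconstructed-PSD geometry: middle-section center and equivalent radius."""

    center_section: int
    area_um2: float
    R_equiv_nm: float


class DegenerateTraceError(ValueError):
    """A polyline with zero arc length cannot define center or half-width."""


def _vertices(trace: Sequence[Sequence[float]]) -> np.ndarray:
    a = np.asarray(trace, dtype=float)
    if a.ndim != 2 or a.shape[0] < 2 or a.shape[1] != 2:
        raise DegenerateTraceError("trace needs >= 2 two-dimensional vertices")
    return a


def _cumlen(a: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(a, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def trace_center_halfwidth(
    trace: Sequence[Sequence[float]],
) -> tuple[np.ndarray, float]:
    """Center point (at half the arc length) and half-width of a membrane trace."""
    a = _vertices(trace)
    s = _cumlen(a)
    total = s[-1]
    if total <= 0:
        raise DegenerateTraceError("trace has zero arc length")
    half = total / 2.0
    i = int(np.searchsorted(s, half, side="right") - 1)
    i = min(i, len(s) - 2)
    seg_len = s[i + 1] - s[i]
    frac = 0.0 if seg_len == 0 else (half - s[i]) / seg_len
    center = a[i] + frac * (a[i + 1] - a[i])
    return center, half


def _project_arc_position(p: np.ndarray, a: np.ndarray, s: np.ndarray) -> float:
    """Arc-length coordinate of the nearest point on the polyline to ``p``.

    The first and last segments extend linearly beyond the termini, so a
    point lying past the end of the trace gets an arc coordinate < 0 or
    > total length (and hence a normalized distance > 1) rather than being
    clamped onto the terminus.
    """
    n_seg = len(a) - 1
    best_d2 = np.inf
    best_s = 0.0
    for i in range(n_seg):
        v = a[i + 1] - a[i]
        L2 = float(v @ v)
        if L2 == 0:
            t = 0.0
        else:
            t = float((p - a[i]) @ v / L2)
            lo = -np.inf if i == 0 else 0.0
            hi = np.inf if i == n_seg - 1 else 1.0
            t = float(np.clip(t, lo, hi))
        q = a[i] + t * v
        d2 = float(np.sum((p - q) ** 2))
        if d2 < best_d2:
            best_d2 = d2
            best_s = s[i] + t * np.sqrt(L2)
    return best_s


def normalized_distance_2d(
    p: Sequence[float],
    trace: Sequence[Sequence[float]],
    mode: str = "arc",
) -> NormalizedLocation:
    """Lateral distance of a point from a membrane trace's center, normalized.

    The point is projected to the nearest point on the trace; ``raw_nm`` is the
    arc distance (default) or straight-line chord distance (``mode="chord"``,
    for sensitivity analysis) from that projection to the trace center, and
    ``normalized`` divides by the half-width.  Projections beyond the trace
    termini yield normalized > 1 and are flagged, never clamped.
    """
    a = _vertices(trace)
    s = _cumlen(a)
    if s[-1] <= 0:
        raise DegenerateTraceError("trace has zero arc length")
    center, half = trace_center_halfwidth(trace)
    pt = np.asarray(p, dtype=float)
    if mode == "arc":
        s_proj = _project_arc_position(pt, a, s)
        raw = abs(s_proj - s[-1] / 2.0)
    elif mode == "chord":
        s_proj = _project_arc_position(pt, a, s)
        i = int(np.searchsorted(s, s_proj, side="right") - 1)
        i = min(i, len(s) - 2)
        seg = a[i + 1] - a[i]
        seg_len = np.linalg.norm(seg)
        frac = 0.0 if seg_len == 0 else (s_proj - s[i]) / seg_len
        proj = a[i] + frac * seg
        raw = float(np.linalg.norm(proj - center))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return NormalizedLocation.from_normalized(raw, raw / half)


def synapse_geometry_3d(
    syn: SynapseReconstruction, surface: str = "psd"
) -> SynapseGeometry3D:
    """Equivalent-circle geometry of a reconstructed PSD (or AZ).

    Surface area is the sum over sections of trace arc length x section
    thickness; the equivalent radius is that of the circle with the same area.
    """
    attr = "psd_trace" if surface == "psd" else "az_trace"
    t = syn.thickness_nm
    area_nm2 = 0.0
    for p in syn.profiles:
        a = _vertices(getattr(p, attr))
        area_nm2 += _cumlen(a)[-1] * t
    if area_nm2 <= 0:
        raise DegenerateTraceError(f"{syn.synapse_id}: zero reconstructed area")
    return SynapseGeometry3D(
        center_section=syn.middle_index,
        area_um2=area_nm2 * 1e-6,
        R_equiv_nm=float(np.sqrt(area_nm2 / np.pi)),
    )


def lateral_offset_nm(
    profile: ProfileAnnotation, p: Sequence[float], surface: str = "psd"
) -> float:
    """Signed arc coordinate of a particle relative to its section's trace center.

    Per-profile alignment offsets (dx) shift the coordinate; serial sections
    are assumed laterally pre-aligned so each section's trace center sits on
    the middle-section center line.
    """
    trace = profile.psd_trace if surface == "psd" else profile.az_trace
    a = _vertices(trace)
    s = _cumlen(a)
    s_proj = _project_arc_position(np.asarray(p, dtype=float), a, s)
    return float(s_proj - s[-1] / 2.0 + profile.offset[0])


def distance_3d(
    syn: SynapseReconstruction,
    p: Sequence[float],
    section_index: int,
    surface: str = "psd",
    geometry: SynapseGeometry3D | None = None,
) -> NormalizedLocation:
    """3D distance from a particle to the middle-section center, normalized.

    The lateral (in-section) offset and the section offset
    |section - middle| x thickness combine by the Pythagorean theorem; the
    result is divided by the equivalent-circle radius of the reconstruction,
    and squared to give the fractional-area coordinate.
    """
    profile = syn.profile_at(section_index)
    geom = geometry if geometry is not None else synapse_geometry_3d(syn, surface)
    d_lat = abs(lateral_offset_nm(profile, p, surface))
    dz = abs(section_index - syn.middle_index) * syn.thickness_nm
    raw = float(np.hypot(d_lat, dz))
    return NormalizedLocation.from_normalized(raw, raw / geom.R_equiv_nm)


def nearest_gold_nm(
    profile: ProfileAnnotation, feature: Sequence[float]
) -> float | None:
    """Distance (nm) from a feature to the nearest gold particle in its profile.

    Returns ``None`` when the profile has no gold — an "absent" result to be
    excluded from pooling, never coerced to zero.
    """
    if not profile.gold:
        return None
    g = np.asarray(profile.gold, dtype=float)
    f = np.asarray(feature, dtype=float)
    return float(np.min(np.linalg.norm(g - f, axis=1)))


def receptor_density(count: int, area_um2: float) -> float:
    """Particles per square micron."""
    if area_um2 <= 0:
        raise ValueError("area must be positive")
    return count / area_um2


def ecdf_table(values: Iterable[float]) -> pd.DataFrame:
    x = np.sort(np.asarray(list(values), dtype=float))
    if x.size == 0:
        return pd.DataFrame(columns=["x", "F"])
    return pd.DataFrame({"x": x, "F": np.arange(1, x.size + 1) / x.size})


def pool_distributions(
    locations: dict[str, Sequence[NormalizedLocation | float]],
    value: str = "normalized",
    n_boot: int = 10_000,
    seed: int = 0,
    include_beyond_edge: bool = True,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Per-group medians with percentile-bootstrap 95% CIs, plus ECDF tables.

    ``locations`` maps group keys to sequences of :class:`NormalizedLocation`
    (from which ``value`` in {"normalized", "fractional_area", "raw_nm"} is
    taken) or plain floats.  Empty groups are dropped with a warning column.
    """
    rng = np.random.default_rng(seed)
    rows = []
    ecdfs: dict[str, pd.DataFrame] = {}
    for group, locs in locations.items():
        vals = []
        for loc in locs:
            if isinstance(loc, NormalizedLocation):
                if not include_beyond_edge and loc.beyond_edge:
                    continue
                vals.append(getattr(loc, value))
            else:
                vals.append(float(loc))
        v = np.asarray(vals, dtype=float)
        if v.size == 0:
            continue
        med = float(np.median(v))
        if v.size == 1:
            lo = hi = med
        else:
            idx = rng.integers(0, v.size, size=(n_boot, v.size))
            boot = np.median(v[idx], axis=1)
            lo, hi = np.percentile(boot, [2.5, 97.5])
        rows.append(
            {"group": group, "n": int(v.size), "median": med,
             "ci_lo": float(lo), "ci_hi": float(hi)}
        )
        ecdfs[group] = ecdf_table(v)
    return pd.DataFrame(rows, columns=["group", "n", "median", "ci_lo", "ci_hi"]), ecdfs
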