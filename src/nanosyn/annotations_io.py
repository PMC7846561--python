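"""Annotation data model and on-disk schema for synaptic EM point annotations.

One :class:`ProfileAnnotation` holds everything traced in a single EM section:
the active-zone and PSD membrane polylines, and the point annotations (gold
particles marking receptors, docked vesicles, exocytic pits), all in
nanometres with a per-profile Cartesian origin.  Profiles that share a
``synapse_id`` and ascend in ``section_index`` form a serial-section
reconstruction of one synapse.

The canonical on-disk format is JSON (polylines need nesting); a flat CSV
export with one annotated point per row is provided for statistics tools.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CONDITIONS = ("rest", "stim_5ms", "stim_11ms")
LABELS = ("AMPA", "NMDA", "control")

__all__ = [
    "AnnotationError",
    "ProfileAnnotation",
    "Dataset",
    "SynapseReconstruction",
    "read_annotations",
    "write_annotations",
    "blind_shuffle",
    "export_feature_table",
    "group_reconstructions",
]


class AnnotationError(ValueError):
    """Raised when an annotation record violates the schema or an invariant."""


def _as_points(obj, name: str, record: str) -> list[list[float]]:
    pts = []
    for i, p in enumerate(obj):
        if len(p) != 2:
            raise AnnotationError(f"{record}: {name}[{i}] is not a 2D point")
        x, y = float(p[0]), float(p[1])
        if not (math.isfinite(x) and math.isfinite(y)):
            raise AnnotationError(f"{record}: {name}[{i}] has non-finite coordinate")
        pts.append([x, y])
    return pts


def _polyline_arc_length(pts: Sequence[Sequence[float]]) -> float:
    a = np.asarray(pts, dtype=float)
    if a.ndim != 2 or a.shape[0] < 2:
        return 0.0
    return float(np.sum(np.linalg.norm(np.diff(a, axis=0), axis=1)))


@dataclass
class ProfileAnnotation:
    """Point and polyline annotations of one EM section of one synapse."""

    synapse_id: str
    section_index: int
    section_thickness_nm: float
    condition: str
    label: str
    az_trace: list[list[float]]
    psd_trace: list[list[float]]
    docked_vesicles: list[list[float]] = field(default_factory=list)
    pits: list[list[float]] = field(default_factory=list)
    gold: list[list[float]] = field(default_factory=list)
    offset: tuple[float, float] = (0.0, 0.0)

    def validate(self) -> None:
        rec = f"profile ({self.synapse_id}, {self.section_index})"
        if self.section_thickness_nm <= 0:
            raise AnnotationError(f"{rec}: section_thickness_nm must be > 0")
        if self.condition not in CONDITIONS:
            raise AnnotationError(
                f"{rec}: condition {self.condition!r} not in {CONDITIONS}"
            )
        if self.label not in LABELS:
            raise AnnotationError(f"{rec}: label {self.label!r} not in {LABELS}")
        for name in ("az_trace", "psd_trace"):
            trace = getattr(self, name)
            setattr(self, name, _as_points(trace, name, rec))
            if len(trace) < 2:
                raise AnnotationError(f"{rec}: {name} needs >= 2 vertices")
            if _polyline_arc_length(trace) <= 0:
                raise AnnotationError(f"{rec}: {name} has zero arc length")
        for name in ("docked_vesicles", "pits", "gold"):
            setattr(self, name, _as_points(getattr(self, name), name, rec))
        dx, dy = float(self.offset[0]), float(self.offset[1])
        if not (math.isfinite(dx) and math.isfinite(dy)):
            raise AnnotationError(f"{rec}: non-finite offset")
        self.offset = (dx, dy)

    def to_json_obj(self) -> dict:
        return {
            "synapse_id": self.synapse_id,
            "section_index": int(self.section_index),
            "section_thickness_nm": float(self.section_thickness_nm),
            "condition": self.condition,
            "label": self.label,
            "az_trace": self.az_trace,
            "psd_trace": self.psd_trace,
            "docked_vesicles": self.docked_vesicles,
            "pits": self.pits,
            "gold": self.gold,
            "offset": list(self.offset),
        }

    @classmethod
    def from_json_obj(cls, obj: dict) -> "ProfileAnnotation":
        required = {
            "synapse_id",
            "section_index",
            "section_thickness_nm",
            "condition",
            "label",
            "az_trace",
            "psd_trace",
        }
        missing = required - set(obj)
        if missing:
            raise AnnotationError(
                f"profile record missing fields {sorted(missing)}: {obj.get('synapse_id', '?')}"
            )
        prof = cls(
            synapse_id=str(obj["synapse_id"]),
            section_index=int(obj["section_index"]),
            section_thickness_nm=float(obj["section_thickness_nm"]),
            condition=obj["condition"],
            label=obj["label"],
            az_trace=[list(map(float, p)) for p in obj["az_trace"]],
            psd_trace=[list(map(float, p)) for p in obj["psd_trace"]],
            docked_vesicles=[list(map(float, p)) for p in obj.get("docked_vesicles", [])],
            pits=[list(map(float, p)) for p in obj.get("pits", [])],
            gold=[list(map(float, p)) for p in obj.get("gold", [])],
            offset=tuple(obj.get("offset", (0.0, 0.0))),
        )
        prof.validate()
        return prof


@dataclass
class Dataset:
    """A pool of profiles plus free-text provenance (generator config, source)."""

    profiles: list[ProfileAnnotation] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def validate(self) -> None:
        seen: set[tuple[str, int]] = set()
        for p in self.profiles:
            p.validate()
            key = (p.synapse_id, p.section_index)
            if key in seen:
                raise AnnotationError(
                    f"duplicate (synapse_id, section_index) = {key}"
                )
            seen.add(key)

    def __len__(self) -> int:
        return len(self.profiles)


@dataclass
class SynapseReconstruction:
    """Ordered serial sections of one synapse; the middle section anchors 3D."""

    synapse_id: str
    profiles: list[ProfileAnnotation]

    def __post_init__(self) -> None:
        if not self.profiles:
            raise AnnotationError(f"{self.synapse_id}: reconstruction needs >= 1 profile")
        self.profiles = sorted(self.profiles, key=lambda p: p.section_index)
        idx = [p.section_index for p in self.profiles]
        if idx != list(range(idx[0], idx[0] + len(idx))):
            raise AnnotationError(f"{self.synapse_id}: section indices not contiguous")
        thick = {p.section_thickness_nm for p in self.profiles}
        if len(thick) > 1:
            raise AnnotationError(f"{self.synapse_id}: mixed section thicknesses")

    @property
    def thickness_nm(self) -> float:
        return self.profiles[0].section_thickness_nm

    @property
    def middle_index(self) -> int:
        idx = [p.section_index for p in self.profiles]
        return idx[(len(idx) - 1) // 2]

    def profile_at(self, section_index: int) -> ProfileAnnotation:
        for p in self.profiles:
            if p.section_index == section_index:
                return p
        raise AnnotationError(
            f"{self.synapse_id}: no section {section_index} in reconstruction"
        )


def group_reconstructions(ds: Dataset) -> list[SynapseReconstruction]:
    """Group a dataset's profiles into per-synapse serial reconstructions."""
    by_id: dict[str, list[ProfileAnnotation]] = {}
    for p in ds.profiles:
        by_id.setdefault(p.synapse_id, []).append(p)
    return [SynapseReconstruction(sid, profs) for sid, profs in by_id.items()]


def read_annotations(path: str | Path) -> Dataset:
    """Read and validate an annotation JSON file.

    Raises :class:`AnnotationError` naming the offending record on any schema
    violation, including duplicate (synapse_id, section_index) pairs.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise AnnotationError(f"{path}: empty annotation file")
    try:
        obj = json.loads(text)
    except json.JSONDecodeError as e:
        raise AnnotationError(f"{path}: not valid JSON ({e})") from e
    if not isinstance(obj, dict) or "profiles" not in obj:
        raise AnnotationError(f"{path}: top level must be an object with 'profiles'")
    ds = Dataset(
        profiles=[ProfileAnnotation.from_json_obj(rec) for rec in obj["profiles"]],
        provenance=dict(obj.get("provenance", {})),
    )
    ds.validate()
    return ds


def write_annotations(ds: Dataset, path: str | Path) -> None:
    """Write a dataset to JSON; round-trips bit-stably through repr floats."""
    ds.validate()
    obj = {
        "provenance": ds.provenance,
        "profiles": [p.to_json_obj() for p in ds.profiles],
    }
    Path(path).write_text(json.dumps(obj, indent=1))


def blind_shuffle(ds: Dataset, seed: int) -> tuple[Dataset, pd.DataFrame]:
    """Shuffle profile order and replace synapse ids with opaque codes.

    Mirrors blinded pooling of micrographs during analysis: the analyst sees
    profiles in random order under codes like ``blind_0007``; the returned key
    table inverts the mapping.  Profiles of the same synapse share a code so
    reconstructions survive blinding.
    """
    if not ds.profiles:
        raise AnnotationError("cannot blind an empty dataset")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ds.profiles))
    ids = sorted({p.synapse_id for p in ds.profiles})
    id_perm = rng.permutation(len(ids))
    code = {sid: f"blind_{id_perm[i]:04d}" for i, sid in enumerate(ids)}
    blinded = Dataset(provenance={"blinded": True, "seed": int(seed)})
    for j in order:
        p = ds.profiles[j]
        blinded.profiles.append(replace(p, synapse_id=code[p.synapse_id]))
    key = pd.DataFrame(
        {"blind_id": [code[s] for s in ids], "synapse_id": ids}
    ).sort_values("blind_id", ignore_index=True)
    return blinded, key


def export_feature_table(ds: Dataset) -> pd.DataFrame:
    """Flatten all annotated points to one row per point (CSV-friendly)."""
    rows = []
    for p in ds.profiles:
        for kind, pts in (
            ("gold", p.gold),
            ("vesicle", p.docked_vesicles),
            ("pit", p.pits),
        ):
            for x, y in pts:
                rows.append(
                    {
                        "synapse_id": p.synapse_id,
                        "section_index": p.section_index,
                        "kind": kind,
                        "x": x,
                        "y": y,
                        "condition": p.condition,
                        "label": p.label,
                    }
                )
    cols = ["synapse_id", "section_index", "kind", "x", "y", "condition", "label"]
    return pd.DataFrame(rows, columns=cols)
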