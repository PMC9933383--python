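"""The 1D core model of the gut.

The small and large intestines are modelled as two linear paths of anatomical
landmarks joined by regions.  Every landmark carries a centreline distance
``s_mm`` from the path's reference point — the anus for the large intestine
and the ileocaecal valve (ileum side, ICVi) for the small intestine — so
``s`` increases away from the reference, toward the mouth.  "Proximal" means
larger ``s`` (toward the mouth), "distal" smaller ``s`` (toward the anus).

A location on a path is expressed canonically as a :class:`GcaLocation`: the
pair of adjacent landmarks bracketing it plus the proportional distance
(fraction in [0, 1]) from the distal landmark toward the proximal one.  This
proportional representation is the unit of interoperability: it transfers
unchanged between models that share the landmark vocabulary, even when the
absolute distances differ (e.g. between a consensus model and a
patient-specific rescaling).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "Landmark",
    "Region",
    "GutPath",
    "GutModel1D",
    "GcaLocation",
    "RoiInterval",
    "ModelError",
    "ModelValidationError",
    "MappingError",
    "load_model",
    "model_from_dict",
    "model_to_dict",
    "save_model",
    "path_length",
    "abs_to_location",
    "location_to_abs",
    "offset_location",
    "proportion_location",
    "rescale_model",
]

#: tolerance (mm) for length-consistency checks
LENGTH_TOL_MM = 1e-6

SCHEMA_VERSION = "1.0"


class ModelError(ValueError):
    """Base class for model errors."""


class ModelValidationError(ModelError):
    """Raised when a model violates its invariants.

    Carries *all* detected inconsistencies, not just the first.
    """

    def __init__(self, errors: Iterable[str]):
        self.errors = list(errors)
        super().__init__("model validation failed:\n  - " + "\n  - ".join(self.errors))


class MappingError(ModelError):
    """Raised when a location cannot be expressed against a given model."""


@dataclass(frozen=True)
class Landmark:
    """A recognizable anatomical point on a path's centreline."""

    id: str
    name: str
    s_mm: float
    #: interior to a region (e.g. APR inside the rectum, ICVc inside the caecum)
    intermediate: bool = False
    term_ref: str | None = None


@dataclass(frozen=True)
class Region:
    """A gut segment between two landmarks (distal start, proximal end)."""

    id: str
    name: str
    start_landmark: str
    end_landmark: str
    length_mm: float
    term_ref: str | None = None


@dataclass
class GutPath:
    """One linear path (large or small intestine) of a 1D model."""

    path_id: str
    reference_landmark: str
    landmarks: list[Landmark]
    regions: list[Region]

    def __post_init__(self) -> None:
        self._by_id = {lm.id: lm for lm in self.landmarks}

    def landmark(self, landmark_id: str) -> Landmark:
        try:
            return self._by_id[landmark_id]
        except KeyError:
            raise MappingError(
                f"unknown landmark {landmark_id!r} on path {self.path_id!r}"
            ) from None

    def has_landmark(self, landmark_id: str) -> bool:
        return landmark_id in self._by_id

    def s_of(self, landmark_id: str) -> float:
        return self.landmark(landmark_id).s_mm

    def index_of(self, landmark_id: str) -> int:
        self.landmark(landmark_id)
        return next(i for i, lm in enumerate(self.landmarks) if lm.id == landmark_id)

    @property
    def s_values(self) -> np.ndarray:
        return np.asarray([lm.s_mm for lm in self.landmarks], dtype=float)

    @property
    def length_mm(self) -> float:
        if not self.landmarks:
            raise ModelError(f"path {self.path_id!r} has no landmarks")
        return float(self.s_values.max())

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty if valid)."""
        errs: list[str] = []
        pid = self.path_id
        if not self.landmarks:
            return [f"path {pid!r}: no landmarks"]
        s = self.s_values
        if np.any(s < 0):
            errs.append(f"path {pid!r}: negative s_mm values")
        if len(set(np.round(s, 9))) != len(s):
            errs.append(f"path {pid!r}: duplicate landmark s_mm values")
        if not np.all(np.diff(s) > 0):
            errs.append(f"path {pid!r}: landmark list is not ordered by increasing s_mm")
        zeros = [lm.id for lm in self.landmarks if lm.s_mm == 0]
        if len(zeros) != 1:
            errs.append(
                f"path {pid!r}: expected exactly one landmark at s_mm=0, found {zeros!r}"
            )
        elif zeros[0] != self.reference_landmark:
            errs.append(
                f"path {pid!r}: reference landmark {self.reference_landmark!r} "
                f"is not the landmark at s_mm=0 ({zeros[0]!r})"
            )
        ids = [lm.id for lm in self.landmarks]
        if len(set(ids)) != len(ids):
            errs.append(f"path {pid!r}: duplicate landmark ids")

        for reg in self.regions:
            for lm_id in (reg.start_landmark, reg.end_landmark):
                if lm_id not in self._by_id:
                    errs.append(
                        f"region {reg.id!r}: unknown landmark {lm_id!r} on path {pid!r}"
                    )
        regs_ok = [
            r
            for r in self.regions
            if r.start_landmark in self._by_id and r.end_landmark in self._by_id
        ]
        for reg in regs_ok:
            gap = self.s_of(reg.end_landmark) - self.s_of(reg.start_landmark)
            if gap <= 0:
                errs.append(
                    f"region {reg.id!r}: end landmark {reg.end_landmark!r} is not "
                    f"proximal to start landmark {reg.start_landmark!r}"
                )
            elif abs(gap - reg.length_mm) > LENGTH_TOL_MM:
                errs.append(
                    f"region {reg.id!r}: length mismatch — declared length_mm="
                    f"{reg.length_mm} but landmark gap is {gap}"
                )
            if reg.length_mm <= 0:
                errs.append(f"region {reg.id!r}: length_mm must be > 0")
        if regs_ok and len(regs_ok) == len(self.regions):
            if self.regions[0].start_landmark != self.reference_landmark:
                errs.append(
                    f"path {pid!r}: first region must start at the reference "
                    f"landmark {self.reference_landmark!r}"
                )
            for a, b in zip(self.regions, self.regions[1:]):
                if a.end_landmark != b.start_landmark:
                    errs.append(
                        f"path {pid!r}: regions {a.id!r} and {b.id!r} are not "
                        f"contiguous ({a.end_landmark!r} != {b.start_landmark!r})"
                    )
            terminal = self.landmarks[-1].id
            if self.regions[-1].end_landmark != terminal:
                errs.append(
                    f"path {pid!r}: last region must end at the terminal landmark "
                    f"{terminal!r}"
                )
        return errs


@dataclass
class GutModel1D:
    """A validated 1D gut model: ordered paths of landmarks and regions."""

    model_id: str
    species: str = "human"
    provenance: str = ""
    paths: dict[str, GutPath] = field(default_factory=dict)

    def path(self, path_id: str) -> GutPath:
        try:
            return self.paths[path_id]
        except KeyError:
            raise ModelError(
                f"model {self.model_id!r} has no path {path_id!r} "
                f"(available: {sorted(self.paths)})"
            ) from None

    def validate(self) -> list[str]:
        errs: list[str] = []
        if not self.paths:
            errs.append("model has no paths")
        for p in self.paths.values():
            errs.extend(p.validate())
        return errs

    def check_valid(self) -> "GutModel1D":
        errs = self.validate()
        if errs:
            raise ModelValidationError(errs)
        return self


@dataclass(frozen=True)
class GcaLocation:
    """A canonical gut location: bracketing landmark pair plus fraction.

    ``fraction`` is measured from the distal landmark (smaller ``s``) toward
    the proximal landmark; 0 means exactly at the distal landmark.
    """

    model_id: str
    path_id: str
    distal_landmark: str
    proximal_landmark: str
    fraction: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction <= 1.0):
            raise ModelError(f"fraction {self.fraction} outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "path_id": self.path_id,
            "distal_landmark": self.distal_landmark,
            "proximal_landmark": self.proximal_landmark,
            "fraction": self.fraction,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GcaLocation":
        return cls(
            model_id=d["model_id"],
            path_id=d["path_id"],
            distal_landmark=d["distal_landmark"],
            proximal_landmark=d["proximal_landmark"],
            fraction=float(d["fraction"]),
        )


@dataclass(frozen=True)
class RoiInterval:
    """A 1D range of centreline distances on one path of one model."""

    model_id: str
    path_id: str
    s_start_mm: float
    s_end_mm: float

    def __post_init__(self) -> None:
        if self.s_start_mm > self.s_end_mm:
            raise ModelError(
                f"ROI start {self.s_start_mm} exceeds end {self.s_end_mm}"
            )
        if self.s_start_mm < 0:
            raise ModelError("ROI start must be >= 0")

    @property
    def length_mm(self) -> float:
        return self.s_end_mm - self.s_start_mm

    def to_locations(self, model: GutModel1D) -> tuple[GcaLocation, GcaLocation]:
        return (
            abs_to_location(model, self.path_id, self.s_start_mm),
            abs_to_location(model, self.path_id, self.s_end_mm),
        )

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "path_id": self.path_id,
            "s_start_mm": self.s_start_mm,
            "s_end_mm": self.s_end_mm,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RoiInterval":
        return cls(
            model_id=d["model_id"],
            path_id=d["path_id"],
            s_start_mm=float(d["s_start_mm"]),
            s_end_mm=float(d["s_end_mm"]),
        )


# ---------------------------------------------------------------------------
# config (de)serialisation


def _parse_path(doc: Mapping, errs: list[str]) -> GutPath | None:
    for key in ("path_id", "reference_landmark", "landmarks", "regions"):
        if key not in doc:
            errs.append(f"path document missing required field {key!r}")
            return None
    landmarks = []
    for i, lm in enumerate(doc["landmarks"]):
        for key in ("id", "s_mm"):
            if key not in lm:
                errs.append(
                    f"path {doc['path_id']!r} landmark #{i}: missing field {key!r}"
                )
                return None
        landmarks.append(
            Landmark(
                id=lm["id"],
                name=lm.get("name", lm["id"]),
                s_mm=float(lm["s_mm"]),
                intermediate=bool(lm.get("intermediate", False)),
                term_ref=lm.get("term_ref"),
            )
        )
    regions = []
    for i, reg in enumerate(doc["regions"]):
        for key in ("id", "start_landmark", "end_landmark", "length_mm"):
            if key not in reg:
                errs.append(
                    f"path {doc['path_id']!r} region #{i}: missing field {key!r}"
                )
                return None
        regions.append(
            Region(
                id=reg["id"],
                name=reg.get("name", reg["id"]),
                start_landmark=reg["start_landmark"],
                end_landmark=reg["end_landmark"],
                length_mm=float(reg["length_mm"]),
                term_ref=reg.get("term_ref"),
            )
        )
    return GutPath(
        path_id=doc["path_id"],
        reference_landmark=doc["reference_landmark"],
        landmarks=landmarks,
        regions=regions,
    )


def model_from_dict(doc: Mapping) -> GutModel1D:
    """Build and validate a :class:`GutModel1D` from a config document."""
    errs: list[str] = []
    for key in ("model_id", "paths"):
        if key not in doc:
            errs.append(f"config missing required field {key!r}")
    if errs:
        raise ModelValidationError(errs)
    paths: dict[str, GutPath] = {}
    for pdoc in doc["paths"]:
        p = _parse_path(pdoc, errs)
        if p is not None:
            if p.path_id in paths:
                errs.append(f"duplicate path_id {p.path_id!r}")
            paths[p.path_id] = p
    if errs:
        raise ModelValidationError(errs)
    model = GutModel1D(
        model_id=doc["model_id"],
        species=doc.get("species", "human"),
        provenance=doc.get("provenance", ""),
        paths=paths,
    )
    return model.check_valid()


def load_model(source: str | Path | Mapping) -> GutModel1D:
    """Load a 1D model from a JSON config file (or an already-parsed dict)."""
    if isinstance(source, Mapping):
        return model_from_dict(source)
    with open(source) as fh:
        doc = json.load(fh)
    return model_from_dict(doc)


def model_to_dict(model: GutModel1D) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "model_id": model.model_id,
        "model_kind": "1d",
        "species": model.species,
        "provenance": model.provenance,
        "paths": [
            {
                "path_id": p.path_id,
                "reference_landmark": p.reference_landmark,
                "landmarks": [
                    {
                        "id": lm.id,
                        "name": lm.name,
                        "s_mm": lm.s_mm,
                        "intermediate": lm.intermediate,
                        "term_ref": lm.term_ref,
                    }
                    for lm in p.landmarks
                ],
                "regions": [
                    {
                        "id": r.id,
                        "name": r.name,
                        "start_landmark": r.start_landmark,
                        "end_landmark": r.end_landmark,
                        "length_mm": r.length_mm,
                        "term_ref": r.term_ref,
                    }
                    for r in p.regions
                ],
            }
            for p in model.paths.values()
        ],
    }


def save_model(model: GutModel1D, path: str | Path) -> None:
    from .jsonio import dump_json

    dump_json(model_to_dict(model), path)


# ---------------------------------------------------------------------------
# coordinate operations


def path_length(model: GutModel1D, path_id: str) -> float:
    """Total centreline length (mm) of a path: the maximum landmark s_mm."""
    return model.path(path_id).length_mm


def abs_to_location(model: GutModel1D, path_id: str, s_mm: float) -> GcaLocation:
    """Express an absolute centreline distance as a canonical location.

    At an interior landmark the proximal-side interval is chosen (fraction 0);
    at the path's proximal terminus the last interval is used with fraction 1.
    """
    p = model.path(path_id)
    s = p.s_values
    total = s[-1]
    if not (0.0 <= s_mm <= total):
        raise ModelError(
            f"s={s_mm} mm outside [0, {total}] on path {path_id!r}"
        )
    if s_mm == total:
        i = len(s) - 2
        frac = 1.0
    else:
        i = int(np.searchsorted(s, s_mm, side="right")) - 1
        frac = (s_mm - s[i]) / (s[i + 1] - s[i])
    return GcaLocation(
        model_id=model.model_id,
        path_id=path_id,
        distal_landmark=p.landmarks[i].id,
        proximal_landmark=p.landmarks[i + 1].id,
        fraction=float(frac),
    )


def location_to_abs(model: GutModel1D, loc: GcaLocation) -> float:
    """Absolute centreline distance (mm) of a canonical location."""
    p = model.path(loc.path_id)
    i_d = p.index_of(loc.distal_landmark)
    i_p = p.index_of(loc.proximal_landmark)
    if i_p != i_d + 1:
        raise MappingError(
            f"landmarks {loc.distal_landmark!r} and {loc.proximal_landmark!r} "
            f"are not adjacent on path {loc.path_id!r} of model {model.model_id!r}"
        )
    s_d = p.landmarks[i_d].s_mm
    s_p = p.landmarks[i_p].s_mm
    return float(s_d + loc.fraction * (s_p - s_d))


def offset_location(
    model: GutModel1D,
    landmark_id: str,
    offset_mm: float,
    direction: str,
) -> GcaLocation:
    """Location a given distance proximal or distal of a landmark.

    Implements clinical expressions such as "a lesion located 110 mm distal
    from the ileocaecal valve": the offset walks along the centreline (it may
    cross intervening landmarks).
    """
    if direction not in ("proximal", "distal"):
        raise ModelError(f"direction must be 'proximal' or 'distal', got {direction!r}")
    if offset_mm < 0:
        raise ModelError("offset_mm must be >= 0")
    path = _path_of_landmark(model, landmark_id)
    s0 = path.s_of(landmark_id)
    s = s0 + offset_mm if direction == "proximal" else s0 - offset_mm
    total = path.length_mm
    if s < 0:
        raise ModelError(
            f"offset runs {-s:g} mm past the distal end of path {path.path_id!r}"
        )
    if s > total:
        raise ModelError(
            f"offset runs {s - total:g} mm past the proximal end of path "
            f"{path.path_id!r}"
        )
    return abs_to_location(model, path.path_id, s)


def proportion_location(
    model: GutModel1D,
    from_landmark: str,
    to_landmark: str,
    fraction_f: float,
) -> GcaLocation:
    """Location a proportional distance between two (not necessarily adjacent)
    landmarks, e.g. "two-thirds of the distance between the ileocaecal valve
    and the hepatic flexure".

    The result is canonicalized against the adjacent bracketing landmark pair.
    """
    if not (0.0 <= fraction_f <= 1.0):
        raise ModelError(f"fraction {fraction_f} outside [0, 1]")
    p_from = _path_of_landmark(model, from_landmark)
    p_to = _path_of_landmark(model, to_landmark)
    if p_from.path_id != p_to.path_id:
        raise ModelError(
            f"landmarks {from_landmark!r} and {to_landmark!r} lie on different "
            f"paths ({p_from.path_id!r} vs {p_to.path_id!r})"
        )
    s_from = p_from.s_of(from_landmark)
    s_to = p_from.s_of(to_landmark)
    s = s_from + fraction_f * (s_to - s_from)
    return abs_to_location(model, p_from.path_id, s)


def _path_of_landmark(model: GutModel1D, landmark_id: str) -> GutPath:
    hits = [p for p in model.paths.values() if p.has_landmark(landmark_id)]
    if not hits:
        raise MappingError(
            f"landmark {landmark_id!r} not found in model {model.model_id!r}"
        )
    return hits[0]


def rescale_model(
    model: GutModel1D,
    measured: Mapping[str, Mapping[str, float] | float],
    model_id: str | None = None,
) -> GutModel1D:
    """Derive a patient-specific model from measured landmark distances.

    ``measured`` maps landmark id to its measured s_mm (landmark ids must be
    unique across paths, as in the shipped models; a per-path nested mapping
    ``{path_id: {landmark_id: s_mm}}`` is also accepted).  Unmeasured
    landmarks between two measured anchors are interpolated piecewise-linearly
    (proportions within each span preserved); unmeasured landmarks beyond the
    last measured anchor keep their original distance, and an error names the
    first landmark pair whose order a measurement would violate.  The
    reference landmark is always an anchor at 0.
    """
    nested = measured and all(isinstance(v, Mapping) for v in measured.values())
    new_paths: dict[str, GutPath] = {}
    for pid, p in model.paths.items():
        pm: Mapping[str, float]
        if nested:
            pm = measured.get(pid, {})  # type: ignore[assignment]
        else:
            pm = {k: float(v) for k, v in measured.items() if p.has_landmark(k)}  # type: ignore[arg-type]
        new_paths[pid] = _rescale_path(p, pm)
    out = GutModel1D(
        model_id=model_id or f"{model.model_id}_rescaled",
        species=model.species,
        provenance=f"patient-specific rescale of {model.model_id!r}",
        paths=new_paths,
    )
    return out.check_valid()


def _rescale_path(p: GutPath, measured: Mapping[str, float]) -> GutPath:
    for lm_id in measured:
        p.landmark(lm_id)  # raises on unknown id
    if measured.get(p.reference_landmark, 0.0) != 0.0:
        raise ModelError(
            f"reference landmark {p.reference_landmark!r} must stay at 0 mm"
        )
    anchors: dict[int, float] = {0: 0.0}
    for lm_id, val in measured.items():
        anchors[p.index_of(lm_id)] = float(val)
    idx = sorted(anchors)
    # measured anchors must preserve landmark order among themselves
    for a, b in zip(idx, idx[1:]):
        if anchors[b] <= anchors[a]:
            raise ModelError(
                f"measured distances violate landmark order: "
                f"{p.landmarks[a].id!r} ({anchors[a]} mm) must precede "
                f"{p.landmarks[b].id!r} ({anchors[b]} mm)"
            )
    old = p.s_values
    new = np.empty_like(old)
    for i in range(len(old)):
        if i in anchors:
            new[i] = anchors[i]
            continue
        lo = max((j for j in idx if j < i), default=None)
        hi = min((j for j in idx if j > i), default=None)
        if hi is None:
            # beyond the last measured anchor there is nothing to
            # interpolate against: the original distance stands
            new[i] = old[i]
        else:
            t = (old[i] - old[lo]) / (old[hi] - old[lo])
            new[i] = anchors[lo] + t * (anchors[hi] - anchors[lo])
    bad = np.flatnonzero(np.diff(new) <= 0)
    if bad.size:
        i = int(bad[0])
        raise ModelError(
            f"rescaled distances violate landmark order between "
            f"{p.landmarks[i].id!r} ({new[i]} mm) and "
            f"{p.landmarks[i + 1].id!r} ({new[i + 1]} mm)"
        )
    landmarks = [replace(lm, s_mm=float(s)) for lm, s in zip(p.landmarks, new)]
    by_id = {lm.id: lm.s_mm for lm in landmarks}
    regions = [
        replace(r, length_mm=by_id[r.end_landmark] - by_id[r.start_landmark])
        for r in p.regions
    ]
    return GutPath(
        path_id=p.path_id,
        reference_landmark=p.reference_landmark,
        landmarks=landmarks,
        regions=regions,
    )
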