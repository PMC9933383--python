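"""Smooth midline curves and model embeddings.

A discrete midline path is turned into a cubic B-spline in physical (mm)
coordinates with an arc-length lookup table, giving the continuous
"natural coordinate" axis of a 2D/3D gut domain.  An embedding then anchors
a 1D model's landmarks to arc-length positions on that curve, either at the
boundary crossings between region sub-domains or by manual override, which
is what makes locations transferable between the 1D model and the image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate

from .domains import DomainError, LabelledDomain
from .model import GutModel1D, ModelError
from .pathfind import DiscretePath

__all__ = ["MidlineCurve", "ModelEmbedding", "fit_midline_curve", "place_landmarks"]

#: default arc-length table resolution, mm
ARC_RESAMPLE_MM = 0.1


@dataclass
class MidlineCurve:
    """A B-spline curve in physical coordinates with an arc-length table."""

    knots: np.ndarray
    coefficients: np.ndarray  # (ndim, ncoef)
    degree: int
    arc_u: np.ndarray = field(repr=False, default=None)  # spline parameter
    arc_s: np.ndarray = field(repr=False, default=None)  # cumulative mm
    domain_ref: str = ""

    @property
    def tck(self):
        return (self.knots, list(self.coefficients), self.degree)

    @property
    def ndim(self) -> int:
        return len(self.coefficients)

    @property
    def total_length_mm(self) -> float:
        return float(self.arc_s[-1])

    @property
    def resample_step_mm(self) -> float:
        return float(np.max(np.diff(self.arc_s)))

    def eval_u(self, u) -> np.ndarray:
        return np.asarray(interpolate.splev(u, self.tck)).T

    def point_at_arclength(self, s_mm) -> np.ndarray:
        u = np.interp(s_mm, self.arc_s, self.arc_u)
        return self.eval_u(u)

    def sample_points(self) -> np.ndarray:
        """Curve points at every arc-table entry."""
        return self.eval_u(self.arc_u)

    def reversed(self) -> "MidlineCurve":
        """Same geometry, arc length measured from the other end."""
        t, c, k = self.tck
        tr = (t[-1] + t[0]) - t[::-1]
        cr = np.asarray([ci[::-1] for ci in c])
        out = MidlineCurve(
            knots=tr, coefficients=cr, degree=k, domain_ref=self.domain_ref
        )
        out.build_arc_table(step_mm=float(np.max(np.diff(self.arc_s))))
        return out

    def build_arc_table(self, step_mm: float = ARC_RESAMPLE_MM) -> None:
        t, _, k = self.tck
        u0, u1 = float(t[k]), float(t[-k - 1])
        coarse = np.linspace(u0, u1, 512)
        pts = self.eval_u(coarse)
        rough = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
        n = max(int(np.ceil(rough / step_mm)) + 1, 16)
        u = np.linspace(u0, u1, n)
        pts = self.eval_u(u)
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        self.arc_u = u
        self.arc_s = np.concatenate([[0.0], np.cumsum(seg)])

    def to_dict(self) -> dict:
        return {
            "degree": int(self.degree),
            "knots": [float(v) for v in self.knots],
            "control_points": [[float(v) for v in ci] for ci in self.coefficients],
            "total_length_mm": self.total_length_mm,
            "arc_resample_mm": self.resample_step_mm,
            "domain_ref": self.domain_ref,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MidlineCurve":
        out = cls(
            knots=np.asarray(d["knots"], float),
            coefficients=np.asarray(d["control_points"], float),
            degree=int(d["degree"]),
            domain_ref=d.get("domain_ref", ""),
        )
        out.build_arc_table(step_mm=float(d.get("arc_resample_mm", ARC_RESAMPLE_MM)))
        return out


def fit_midline_curve(
    path: DiscretePath | np.ndarray,
    spacing: tuple[float, ...] | None = None,
    smoothing: float | None = None,
    step_mm: float = ARC_RESAMPLE_MM,
    domain_ref: str = "",
) -> MidlineCurve:
    """Fit a cubic B-spline to a discrete midline path.

    ``smoothing`` is the maximum allowed deviation (mm) of the spline from
    the input points; 0 requests exact interpolation.  Default is
    2 * max(spacing).
    """
    if isinstance(path, DiscretePath):
        pts = path.points_mm
        if not domain_ref:
            domain_ref = path.domain_id
        spacing = path.spacing
    else:
        if spacing is None:
            raise ValueError("spacing is required for a bare point array")
        pts = np.asarray(path, float) * np.asarray(spacing, float)
    # splprep rejects zero-length chords
    keep = np.concatenate(
        [[True], np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-12]
    )
    pts = pts[keep]
    k = 3
    if len(pts) < k + 1:
        raise ModelError(
            f"need at least {k + 1} distinct points for a degree-{k} spline, "
            f"got {len(pts)}"
        )
    if smoothing is None:
        smoothing = 2.0 * float(np.max(spacing))

    if smoothing == 0:
        tck, _ = interpolate.splprep(pts.T, s=0, k=k)
    else:
        s_try = len(pts) * smoothing**2
        for _ in range(40):
            tck, u = interpolate.splprep(pts.T, s=s_try, k=k)
            fitted = np.asarray(interpolate.splev(u, tck)).T
            dev = float(np.linalg.norm(fitted - pts, axis=1).max())
            if dev <= smoothing or s_try < 1e-12:
                break
            s_try /= 4.0
    curve = MidlineCurve(
        knots=np.asarray(tck[0]),
        coefficients=np.asarray(tck[1]),
        degree=int(tck[2]),
        domain_ref=domain_ref,
    )
    curve.build_arc_table(step_mm=step_mm)
    return curve


@dataclass
class ModelEmbedding:
    """Anchors of a 1D model's landmarks on a midline curve.

    ``landmark_arclengths`` maps landmark id to arc-length position (mm) on
    the curve, in the 1D model's landmark order (arc length increases
    proximally).  Landmarks absent from the map (e.g. unplaced intermediates)
    are interpolated proportionally by the mapping layer.
    """

    model_id: str
    path_id: str
    curve: MidlineCurve
    landmark_arclengths: dict[str, float]

    def anchors(self, model: GutModel1D) -> tuple[np.ndarray, np.ndarray]:
        """(model s_mm, curve arc mm) anchor arrays, ordered by s."""
        p = model.path(self.path_id)
        s, a = [], []
        for lm in p.landmarks:
            if lm.id in self.landmark_arclengths:
                s.append(lm.s_mm)
                a.append(self.landmark_arclengths[lm.id])
        return np.asarray(s), np.asarray(a)

    def validate_against(self, model: GutModel1D) -> list[str]:
        errs = []
        p = model.path(self.path_id)
        for lm_id in self.landmark_arclengths:
            if not p.has_landmark(lm_id):
                errs.append(f"embedded landmark {lm_id!r} not in model path")
        _, arcs = self.anchors(model)
        if len(arcs) < 2:
            errs.append("embedding needs at least two placed landmarks")
        elif np.any(np.diff(arcs) <= 0):
            errs.append(
                "landmark arc lengths do not increase in the model's landmark order"
            )
        return errs

    def to_dict(self) -> dict:
        d = self.curve.to_dict()
        return {
            "model_id": self.model_id,
            "path_id": self.path_id,
            "control_points": d["control_points"],
            "knots": d["knots"],
            "degree": d["degree"],
            "arc_resample_mm": d["arc_resample_mm"],
            "landmark_arclengths": {
                k: float(v) for k, v in self.landmark_arclengths.items()
            },
            "total_length_mm": self.curve.total_length_mm,
            "domain_ref": d["domain_ref"],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelEmbedding":
        curve = MidlineCurve.from_dict(d)
        return cls(
            model_id=d["model_id"],
            path_id=d["path_id"],
            curve=curve,
            landmark_arclengths={
                k: float(v) for k, v in d["landmark_arclengths"].items()
            },
        )


def _region_runs(curve: MidlineCurve, domain: LabelledDomain):
    """Collapse the curve's arc samples into runs of region ids."""
    pts = curve.sample_points()
    spacing = np.asarray(domain.spacing, float)
    idx = np.round(pts / spacing).astype(int)
    idx = np.clip(idx, 0, np.asarray(domain.label_grid.shape) - 1)
    labels = domain.label_grid[tuple(idx.T)]
    # a smoothed curve may clip a background corner; carry the last region
    for i in range(1, len(labels)):
        if labels[i] == 0:
            labels[i] = labels[i - 1]
    if labels[0] == 0:
        nz = np.flatnonzero(labels)
        if not nz.size:
            raise DomainError("curve never enters the foreground")
        labels[: nz[0]] = labels[nz[0]]
    runs = []  # (region_id, first_sample, last_sample)
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append((domain.region_label_map[int(labels[start])], start, i - 1))
            start = i
    return runs


def place_landmarks(
    curve: MidlineCurve,
    domain: LabelledDomain,
    model: GutModel1D,
    path_id: str,
    overrides: dict[str, float] | None = None,
) -> ModelEmbedding:
    """Place a 1D model's landmarks on a midline curve.

    Each landmark shared by two consecutive regions is placed at the curve
    arc length where the path crosses between the corresponding sub-domains
    (midpoint of the crossing interval for thick boundaries).  The curve is
    reoriented if its region sequence runs opposite to the model's.  Manual
    overrides (landmark id -> arc mm) replace or add positions, which is how
    intermediate landmarks with no sub-domain boundary are embedded.
    """
    p = model.path(path_id)
    model_order = [r.id for r in p.regions]
    runs = _region_runs(curve, domain)
    seq = [r[0] for r in runs]
    if seq == model_order[::-1] and seq != model_order:
        curve = curve.reversed()
        runs = _region_runs(curve, domain)
        seq = [r[0] for r in runs]
    if seq != model_order:
        raise ModelError(
            f"region order along curve {seq!r} does not match the model's "
            f"region order {model_order!r} for path {path_id!r}"
        )
    arcs: dict[str, float] = {}
    arcs[p.regions[0].start_landmark] = 0.0
    for reg_a, reg_b, run_a, run_b in zip(
        p.regions, p.regions[1:], runs, runs[1:]
    ):
        a_last = curve.arc_s[run_a[2]]
        b_first = curve.arc_s[run_b[1]]
        arcs[reg_a.end_landmark] = float(0.5 * (a_last + b_first))
    arcs[p.regions[-1].end_landmark] = curve.total_length_mm
    if overrides:
        for lm_id, arc in overrides.items():
            p.landmark(lm_id)  # raises on unknown id
            arcs[lm_id] = float(arc)
    emb = ModelEmbedding(
        model_id=model.model_id,
        path_id=path_id,
        curve=curve,
        landmark_arclengths={
            lm.id: arcs[lm.id] for lm in p.landmarks if lm.id in arcs
        },
    )
    errs = emb.validate_against(model)
    if errs:
        raise ModelError("; ".join(errs))
    return emb
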