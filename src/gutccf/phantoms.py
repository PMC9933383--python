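"""Synthetic tube phantoms with analytic ground truth.

The gut is, geometrically, a long tube, so every image-side operation in this
package (distance fields, midline extraction, spline fitting, landmark
placement, midline projection) can be exercised on generated tube masks whose
true centreline, arc length and landmark positions are known analytically.
Four centreline families are provided: straight, sinusoid, U-bend and a 3D
helix.  Region sub-domains are produced by splitting the tube at given
fractions of its arc length, which also yields the true landmark arc lengths.

Everything is deterministic; optional boundary noise is seeded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .domains import LabelledDomain
from .model import GutModel1D, model_from_dict

__all__ = ["TubeSpec", "TubePhantom", "make_tube", "make_toy_model", "toy_model_dict"]


@dataclass(frozen=True)
class TubeSpec:
    """Specification of a synthetic labelled tube domain.

    half_width is in cells (index space); spacing converts indices to mm.
    splits are region arc-length fractions and must sum to 1.
    """

    kind: str  # straight | sinusoid | ubend | helix
    shape: tuple[int, ...]
    half_width: float = 8.0
    spacing: tuple[float, ...] | None = None
    splits: tuple[float, ...] = (1.0,)
    amplitude: float = 10.0
    period: float = 100.0
    radius: float = 20.0
    pitch: float = 12.0
    turns: float = 2.0
    noise: float = 0.0
    seed: int = 0
    domain_id: str = "phantom"
    region_prefix: str = "seg"

    def __post_init__(self):
        if abs(sum(self.splits) - 1.0) > 1e-9:
            raise ValueError("region split fractions must sum to 1")
        if self.spacing is None:
            object.__setattr__(self, "spacing", (1.0,) * len(self.shape))
        if len(self.spacing) != len(self.shape):
            raise ValueError("spacing length must match shape")


@dataclass
class TubePhantom:
    """A generated tube domain together with its analytic ground truth."""

    domain: LabelledDomain
    centreline_idx: np.ndarray  # (N, ndim) dense samples, index coordinates
    centreline_mm: np.ndarray  # (N, ndim) same samples in physical mm
    arclength_mm: np.ndarray  # (N,) cumulative physical arc length
    landmark_arclengths_mm: list[float]  # interior split positions, mm
    start_index: tuple[int, ...]
    end_index: tuple[int, ...]
    spec: TubeSpec = field(repr=False, default=None)

    @property
    def total_length_mm(self) -> float:
        return float(self.arclength_mm[-1])


def _centreline_samples(spec: TubeSpec, step: float = 0.25) -> np.ndarray:
    """Dense analytic centreline in index coordinates, ~`step` cells apart."""
    kind = spec.kind
    if kind == "straight":
        ny, nx = spec.shape
        y0 = (ny - 1) / 2.0
        n = int(np.ceil((nx - 1) / step)) + 1
        x = np.linspace(0, nx - 1, n)
        return np.column_stack([np.full_like(x, y0), x])
    if kind == "sinusoid":
        ny, nx = spec.shape
        y0 = (ny - 1) / 2.0
        n = int(np.ceil(4 * (nx - 1) / step))
        x = np.linspace(0, nx - 1, n)
        y = y0 + spec.amplitude * np.sin(2 * np.pi * x / spec.period)
        return np.column_stack([y, x])
    if kind == "ubend":
        ny, nx = spec.shape
        R = spec.radius
        m = spec.half_width + 3.0
        cx = (nx - 1) / 2.0
        cy = ny - 1 - m - R  # bend centre; arc dips toward large y
        y_top = m
        pts = []
        n_arm = max(int(np.ceil((cy - y_top) / step)), 2)
        ys = np.linspace(y_top, cy, n_arm)
        pts.append(np.column_stack([ys, np.full_like(ys, cx - R)]))
        n_arc = max(int(np.ceil(np.pi * R / step)), 8)
        th = np.linspace(np.pi, 0.0, n_arc)  # from left arm around to right arm
        pts.append(np.column_stack([cy + R * np.sin(th), cx + R * np.cos(th)]))
        pts.append(np.column_stack([ys[::-1], np.full_like(ys, cx + R)]))
        return np.vstack(pts)
    if kind == "helix":
        nz, ny, nx = spec.shape
        cz0 = spec.half_width + 3.0
        cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
        t_max = 2 * np.pi * spec.turns
        total = np.hypot(spec.radius * t_max, spec.pitch * spec.turns)
        n = int(np.ceil(total / step))
        t = np.linspace(0.0, t_max, n)
        z = cz0 + spec.pitch * t / (2 * np.pi)
        y = cy + spec.radius * np.sin(t)
        x = cx + spec.radius * np.cos(t)
        return np.column_stack([z, y, x])
    raise ValueError(f"unknown tube kind {spec.kind!r}")


def _check_no_self_intersection(samples: np.ndarray, arc: np.ndarray, hw: float):
    tree = cKDTree(samples)
    pairs = tree.query_pairs(r=2.0 * hw, output_type="ndarray")
    if len(pairs):
        sep = np.abs(arc[pairs[:, 0]] - arc[pairs[:, 1]])
        if np.any(sep > 4.0 * hw):
            raise ValueError(
                f"tube self-intersects at half-width {hw}: distinct centreline "
                "stretches come closer than one tube diameter"
            )


def make_tube(spec: TubeSpec) -> TubePhantom:
    """Generate a labelled tube domain and its analytic ground truth.

    The mask contains every cell whose centre lies within ``half_width`` cells
    of the analytic centreline; labels k=1..len(splits) partition the tube by
    cumulative arc-length fraction.
    """
    samples = _centreline_samples(spec)
    steps = np.linalg.norm(np.diff(samples, axis=0), axis=1)
    arc_idx = np.concatenate([[0.0], np.cumsum(steps)])
    _check_no_self_intersection(samples, arc_idx, spec.half_width)

    # physical-space ground truth
    spacing = np.asarray(spec.spacing, float)
    samples_mm = samples * spacing
    steps_mm = np.linalg.norm(np.diff(samples_mm, axis=0), axis=1)
    arc_mm = np.concatenate([[0.0], np.cumsum(steps_mm)])

    coords = np.indices(spec.shape).reshape(len(spec.shape), -1).T.astype(float)
    tree = cKDTree(samples)
    dist, nearest = tree.query(coords, workers=-1)
    hw = np.full(len(coords), float(spec.half_width))
    if spec.noise > 0:
        rng = np.random.default_rng(spec.seed)
        hw = hw + rng.normal(0.0, spec.noise, size=len(coords))
    inside = dist <= hw

    frac = arc_idx[nearest] / arc_idx[-1]
    edges = np.concatenate([[0.0], np.cumsum(spec.splits)])
    labels = np.clip(np.searchsorted(edges, frac, side="right"), 1, len(spec.splits))
    grid = np.where(inside, labels, 0).reshape(spec.shape).astype(np.int32)

    region_map = {
        k + 1: f"{spec.region_prefix}{k + 1}" for k in range(len(spec.splits))
    }
    domain = LabelledDomain(
        domain_id=spec.domain_id,
        label_grid=grid,
        spacing=tuple(spec.spacing),
        region_label_map=region_map,
    ).check_valid()

    landmark_arcs = [
        float(np.interp(e, arc_idx / arc_idx[-1], arc_mm)) for e in edges[1:-1]
    ]
    start = tuple(int(round(v)) for v in samples[0])
    end = tuple(int(round(v)) for v in samples[-1])
    return TubePhantom(
        domain=domain,
        centreline_idx=samples,
        centreline_mm=samples_mm,
        arclength_mm=arc_mm,
        landmark_arclengths_mm=landmark_arcs,
        start_index=start,
        end_index=end,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# toy 1D model configs


def toy_model_dict(
    landmarks,
    path_id: str = "large_intestine",
    model_id: str = "toy",
    intermediates: set[str] | frozenset[str] = frozenset(),
    species: str = "human",
) -> dict:
    """Build a schema-valid 1D model config from an ordered landmark spec.

    ``landmarks`` is an ordered mapping or list of (id, s_mm) pairs with
    strictly increasing distances starting at 0.  Regions are created between
    consecutive non-intermediate landmarks; landmarks listed in
    ``intermediates`` sit inside a region (like the APR inside the rectum).
    """
    items = list(landmarks.items()) if hasattr(landmarks, "items") else list(landmarks)
    if not items:
        raise ValueError("at least one landmark is required")
    s_vals = [float(s) for _, s in items]
    if any(b <= a for a, b in zip(s_vals, s_vals[1:])):
        raise ValueError("landmark distances must be strictly increasing")
    if s_vals[0] != 0.0:
        raise ValueError("the first landmark is the reference and must be at 0 mm")
    delimiters = [(lid, s) for (lid, s) in items if lid not in intermediates]
    regions = [
        {
            "id": f"r_{a}_{b}",
            "name": f"{a}-{b}",
            "start_landmark": a,
            "end_landmark": b,
            "length_mm": float(sb) - float(sa),
        }
        for (a, sa), (b, sb) in zip(delimiters, delimiters[1:])
    ]
    return {
        "schema_version": "1.0",
        "model_id": model_id,
        "model_kind": "1d",
        "species": species,
        "provenance": "synthetic toy model",
        "paths": [
            {
                "path_id": path_id,
                "reference_landmark": items[0][0],
                "landmarks": [
                    {
                        "id": lid,
                        "name": lid,
                        "s_mm": float(s),
                        "intermediate": lid in intermediates,
                    }
                    for lid, s in items
                ],
                "regions": regions,
            }
        ],
    }


def make_toy_model(landmarks, **kwargs) -> GutModel1D:
    """Build and validate a toy :class:`GutModel1D` (see :func:`toy_model_dict`)."""
    return model_from_dict(toy_model_dict(landmarks, **kwargs))
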