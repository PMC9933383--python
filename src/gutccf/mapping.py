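"""Base-level piecewise-linear mapping between gut models.

A location expressed as (landmark pair, fraction) transfers directly between
any two models that share the landmark vocabulary: the pair and fraction are
preserved and only the absolute millimetre positions change.  When the
landmark sets differ — a patient model with extra intermediate landmarks, or
a sparser abstract model used as the cross-species intermediate — the
location is re-bracketed: it is converted to its proportional position
across the minimal span bounded by landmarks shared by both models and
re-expressed against the target's own adjacent pair.  Because shared
landmarks are fixed points of this rule it is symmetric and reversible.

Mapping between a 1D model and a 2D/3D image domain goes through a
:class:`~gutccf.curve.ModelEmbedding`: model distance and curve arc length
are interpolated piecewise-linearly between the embedded landmark anchors.
Points off the midline are projected to the nearest midline point *of the
same region* — plain 3D proximity is deliberately not used, because the
looping of the gut makes points of far-apart regions spuriously close.
"""

from __future__ import annotations

import numpy as np

from .curve import ModelEmbedding
from .domains import DomainError, LabelledDomain
from .model import (
    GcaLocation,
    GutModel1D,
    MappingError,
    RoiInterval,
    abs_to_location,
    location_to_abs,
)

__all__ = [
    "map_location",
    "map_roi",
    "cross_species_map",
    "location_to_point",
    "point_to_location",
    "MidlineProjectionIndex",
]


def map_location(
    loc: GcaLocation, source: GutModel1D, target: GutModel1D
) -> GcaLocation:
    """Map a canonical location from one model to another.

    If the location's landmark pair is adjacent in the target the pair and
    fraction are preserved exactly; otherwise the location is re-bracketed
    across the minimal shared bounding span (see module docstring).
    """
    sp = source.path(loc.path_id)
    tp = target.path(loc.path_id)
    if (
        tp.has_landmark(loc.distal_landmark)
        and tp.has_landmark(loc.proximal_landmark)
        and tp.index_of(loc.proximal_landmark) == tp.index_of(loc.distal_landmark) + 1
    ):
        return GcaLocation(
            model_id=target.model_id,
            path_id=loc.path_id,
            distal_landmark=loc.distal_landmark,
            proximal_landmark=loc.proximal_landmark,
            fraction=loc.fraction,
        )
    shared = [lm.id for lm in sp.landmarks if tp.has_landmark(lm.id)]
    if len(shared) < 2:
        missing = [
            lm_id
            for lm_id in (loc.distal_landmark, loc.proximal_landmark)
            if not tp.has_landmark(lm_id)
        ]
        raise MappingError(
            f"cannot map to model {target.model_id!r}: landmark(s) {missing!r} "
            f"missing and no shared span exists on path {loc.path_id!r}"
        )
    t_order = sorted(shared, key=tp.index_of)
    if t_order != shared:
        raise MappingError(
            f"models {source.model_id!r} and {target.model_id!r} disagree on "
            f"the order of shared landmarks on path {loc.path_id!r}"
        )
    s_src = location_to_abs(source, loc)
    s_shared = np.asarray([sp.s_of(lm) for lm in shared])
    if not (s_shared[0] <= s_src <= s_shared[-1]):
        raise MappingError(
            f"location at s={s_src} mm lies outside the span covered by "
            f"landmarks shared with model {target.model_id!r}"
        )
    if s_src == s_shared[-1]:
        i = len(shared) - 2
        q = 1.0
    else:
        i = int(np.searchsorted(s_shared, s_src, side="right")) - 1
        q = (s_src - s_shared[i]) / (s_shared[i + 1] - s_shared[i])
    su_t = tp.s_of(shared[i])
    sv_t = tp.s_of(shared[i + 1])
    return abs_to_location(target, loc.path_id, su_t + q * (sv_t - su_t))


def map_roi(
    roi: RoiInterval, source: GutModel1D, target: GutModel1D
) -> RoiInterval:
    """Map both endpoints of an ROI; the result is ordered."""
    a, b = roi.to_locations(source)
    sa = location_to_abs(target, map_location(a, source, target))
    sb = location_to_abs(target, map_location(b, source, target))
    lo, hi = (sa, sb) if sa <= sb else (sb, sa)
    return RoiInterval(
        model_id=target.model_id, path_id=roi.path_id, s_start_mm=lo, s_end_mm=hi
    )


def cross_species_map(
    loc: GcaLocation,
    source: GutModel1D,
    abstract: GutModel1D,
    target: GutModel1D,
) -> GcaLocation:
    """Map between species via an abstract intermediate model.

    The abstract model may carry a sparser landmark set; re-bracketing is
    proportional within the shared spans, so source→abstract→target→
    abstract→source round-trips are identities.
    """
    return map_location(map_location(loc, source, abstract), abstract, target)


# ---------------------------------------------------------------------------
# location <-> physical point, via an embedding


def _arc_of_model_s(emb: ModelEmbedding, model: GutModel1D, s_mm: float) -> float:
    s_anchor, arc_anchor = emb.anchors(model)
    if not (s_anchor[0] <= s_mm <= s_anchor[-1]):
        raise MappingError(
            f"s={s_mm} mm lies outside the embedded span "
            f"[{s_anchor[0]}, {s_anchor[-1]}] mm"
        )
    return float(np.interp(s_mm, s_anchor, arc_anchor))


def _model_s_of_arc(emb: ModelEmbedding, model: GutModel1D, arc_mm: float) -> float:
    s_anchor, arc_anchor = emb.anchors(model)
    arc_mm = float(np.clip(arc_mm, arc_anchor[0], arc_anchor[-1]))
    return float(np.interp(arc_mm, arc_anchor, s_anchor))


def location_to_point(
    loc: GcaLocation, embedding: ModelEmbedding, model: GutModel1D
) -> np.ndarray:
    """Physical point (mm) on the embedded midline curve for a location."""
    s = location_to_abs(model, loc)
    arc = _arc_of_model_s(embedding, model, s)
    return embedding.curve.point_at_arclength(arc)


def _sample_regions(emb: ModelEmbedding, domain: LabelledDomain) -> np.ndarray:
    pts = emb.curve.sample_points()
    spacing = np.asarray(domain.spacing, float)
    idx = np.clip(
        np.round(pts / spacing).astype(int),
        0,
        np.asarray(domain.label_grid.shape) - 1,
    )
    return domain.label_grid[tuple(idx.T)]


def point_to_location(
    point,
    embedding: ModelEmbedding,
    domain: LabelledDomain,
    model: GutModel1D,
    _sample_labels: np.ndarray | None = None,
) -> GcaLocation:
    """Project a physical point to the midline and return its location.

    The projection is region-restricted: only curve samples whose arc length
    falls in the point's own region sub-domain are candidates.
    """
    point = np.asarray(point, float)
    idx = domain.world_to_index(point)
    label = int(domain.label_grid[idx])
    if label == 0:
        raise DomainError(f"point {tuple(point)} mm lies in the background")
    labels = (
        _sample_labels if _sample_labels is not None else _sample_regions(embedding, domain)
    )
    cand = np.flatnonzero(labels == label)
    if not cand.size:
        region = domain.region_label_map[label]
        raise MappingError(
            f"region {region!r} is not traversed by the embedded curve"
        )
    pts = embedding.curve.sample_points()[cand]
    d = np.linalg.norm(pts - point, axis=1)
    arc = float(embedding.curve.arc_s[cand[int(np.argmin(d))]])
    s = _model_s_of_arc(embedding, model, arc)
    return abs_to_location(model, embedding.path_id, s)


class MidlineProjectionIndex:
    """Precomputed nearest-midline arc length for every foreground cell.

    Serves :func:`point_to_location` lookups in O(1) after an upfront
    region-restricted nearest-curve-sample search over the whole grid.
    """

    def __init__(
        self,
        embedding: ModelEmbedding,
        domain: LabelledDomain,
        model: GutModel1D,
        chunk: int = 65536,
    ):
        self.embedding = embedding
        self.domain = domain
        self.model = model
        labels = _sample_regions(embedding, domain)
        pts = embedding.curve.sample_points()
        arc = embedding.curve.arc_s
        spacing = np.asarray(domain.spacing, float)
        self.arc_grid = np.full(domain.label_grid.shape, np.nan)
        for label in domain.region_label_map:
            cand = np.flatnonzero(labels == label)
            cells = np.argwhere(domain.label_grid == label)
            if not cells.size:
                continue
            if not cand.size:
                continue  # region not traversed; lookups there raise
            cpts = pts[cand]
            world = cells * spacing
            best = np.empty(len(world), dtype=np.int64)
            for lo in range(0, len(world), chunk):
                blk = world[lo : lo + chunk]
                d = np.linalg.norm(blk[:, None, :] - cpts[None, :, :], axis=2)
                best[lo : lo + chunk] = np.argmin(d, axis=1)
            self.arc_grid[tuple(cells.T)] = arc[cand[best]]

    def lookup(self, point) -> GcaLocation:
        idx = self.domain.world_to_index(np.asarray(point, float))
        if self.domain.label_grid[idx] == 0:
            raise DomainError(f"point {tuple(point)} mm lies in the background")
        arc = self.arc_grid[idx]
        if np.isnan(arc):
            region = self.domain.region_of_index(idx)
            raise MappingError(
                f"region {region!r} is not traversed by the embedded curve"
            )
        s = _model_s_of_arc(self.embedding, self.model, float(arc))
        return abs_to_location(self.model, self.embedding.path_id, s)
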