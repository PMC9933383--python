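"""Location cards and ROI queries.

A *location card* is the serializable annotation record pairing a 1D region
of interest (where along the gut a sample was taken, with its uncertainty)
with semantic terms and free-form sample metadata.  Stores of cards are
queried spatially: a query ROI is compared with every card's ROI by 1D
interval Jaccard index and matches are returned ranked by overlap.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .jsonio import _round_floats
from .mapping import map_roi
from .model import GutModel1D, ModelError, RoiInterval

__all__ = [
    "LocationCard",
    "AnnotationStore",
    "interval_jaccard",
    "query_store",
    "make_location_card",
]

log = logging.getLogger(__name__)

CARD_SCHEMA_VERSION = "1.0"

#: dilation (mm) applied to zero-length ROIs so point samples can still rank
POINT_EPSILON_MM = 0.5


@dataclass(frozen=True)
class LocationCard:
    card_id: str
    roi: RoiInterval
    terms: tuple[str, ...] = ()
    metadata: Mapping[str, str] = field(default_factory=dict)
    created: str = ""

    def to_dict(self) -> dict:
        return {
            "schema_version": CARD_SCHEMA_VERSION,
            "card_id": self.card_id,
            "roi": self.roi.to_dict(),
            "terms": list(self.terms),
            "metadata": dict(self.metadata),
            "created": self.created,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "LocationCard":
        return cls(
            card_id=d["card_id"],
            roi=RoiInterval.from_dict(d["roi"]),
            terms=tuple(d.get("terms", ())),
            metadata=dict(d.get("metadata", {})),
            created=d.get("created", ""),
        )


def make_location_card(
    roi: RoiInterval,
    terms: Iterable[str] = (),
    metadata: Mapping[str, str] | None = None,
    registry=None,
    card_id: str | None = None,
    created: str = "",
) -> LocationCard:
    """Build a location card, resolving term refs against a registry if given."""
    terms = tuple(terms)
    if registry is not None:
        for t in terms:
            registry.get(t)  # raises naming the unresolvable term
    if card_id is None:
        card_id = f"card_{roi.path_id}_{roi.s_start_mm:g}_{roi.s_end_mm:g}"
    return LocationCard(
        card_id=card_id,
        roi=roi,
        terms=terms,
        metadata=dict(metadata or {}),
        created=created,
    )


class AnnotationStore:
    """An id-indexed collection of location cards (JSON-lines on disk)."""

    def __init__(self, cards: Iterable[LocationCard] = ()):
        self._cards: dict[str, LocationCard] = {}
        for c in cards:
            self.add(c)

    def add(self, card: LocationCard) -> None:
        if card.card_id in self._cards:
            raise ModelError(f"duplicate card id {card.card_id!r}")
        self._cards[card.card_id] = card

    def __len__(self) -> int:
        return len(self._cards)

    def __iter__(self):
        return iter(self._cards.values())

    def get(self, card_id: str) -> LocationCard:
        return self._cards[card_id]

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for cid in sorted(self._cards):
                fh.write(
                    json.dumps(_round_floats(self._cards[cid].to_dict()), sort_keys=True)
                    + "\n"
                )

    @classmethod
    def load(cls, path: str | Path) -> "AnnotationStore":
        store = cls()
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line:
                    store.add(LocationCard.from_dict(json.loads(line)))
        return store


def _dilated(roi: RoiInterval, eps: float) -> tuple[float, float]:
    if roi.length_mm == 0:
        return roi.s_start_mm - eps, roi.s_end_mm + eps
    return roi.s_start_mm, roi.s_end_mm


def interval_jaccard(
    roi_a: RoiInterval, roi_b: RoiInterval, eps: float = POINT_EPSILON_MM
) -> float:
    """1D interval Jaccard index |A ∩ B| / |A ∪ B|.

    Zero-length (point) ROIs are dilated by ``eps`` mm on each side so that
    point samples can still overlap and rank.
    """
    if roi_a.path_id != roi_b.path_id:
        raise ModelError(
            f"ROIs lie on different paths ({roi_a.path_id!r} vs "
            f"{roi_b.path_id!r}); map to a common path first"
        )
    if roi_a.model_id != roi_b.model_id:
        raise ModelError(
            f"ROIs refer to different models ({roi_a.model_id!r} vs "
            f"{roi_b.model_id!r}); map to a common model first"
        )
    a0, a1 = _dilated(roi_a, eps)
    b0, b1 = _dilated(roi_b, eps)
    inter = min(a1, b1) - max(a0, b0)
    if inter <= 0:
        return 0.0
    union = max(a1, b1) - min(a0, b0)
    return inter / union


def query_store(
    query_roi: RoiInterval,
    store: AnnotationStore,
    models: Mapping[str, GutModel1D],
    eps: float = POINT_EPSILON_MM,
) -> list[tuple[LocationCard, float]]:
    """Rank a store's cards against a query ROI by interval Jaccard.

    Cards referencing other models are mapped onto the query's model first;
    cards that cannot be mapped are skipped with a logged warning.  Only
    overlapping cards are returned, sorted by descending Jaccard with ties
    broken by card id.
    """
    target = models[query_roi.model_id]
    hits: list[tuple[LocationCard, float]] = []
    for card in store:
        roi = card.roi
        if roi.path_id != query_roi.path_id:
            continue  # cross-path: no principled 1D overlap
        if roi.model_id != query_roi.model_id:
            try:
                roi = map_roi(roi, models[roi.model_id], target)
            except (KeyError, ModelError) as exc:
                log.warning("skipping unmappable card %r: %s", card.card_id, exc)
                continue
        j = interval_jaccard(query_roi, roi, eps=eps)
        if j > 0:
            hits.append((card, j))
    hits.sort(key=lambda cj: (-cj[1], cj[0].card_id))
    return hits
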