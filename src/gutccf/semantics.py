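"""Semantic extension: standardized anatomy, wall-layer and cell-type terms.

A 1D coordinate says *where along the gut* a sample comes from; the semantic
layer adds *which tissue* at that position — the radial wall layers (mucosa,
submucosa, muscularis propria, serosa) and optionally a cell type — using
term tables in the ASCT+B style with UBERON / FMA / CL cross-references.
Ontology identifiers are treated as opaque strings: terms are attached, not
reasoned over.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .model import GcaLocation, ModelError, RoiInterval

__all__ = [
    "AnatomyTerm",
    "TermRegistry",
    "SemanticLocation",
    "load_term_table",
    "annotate",
]

KINDS = ("region", "landmark", "wall_layer", "cell_type")


@dataclass(frozen=True)
class AnatomyTerm:
    term_id: str
    label: str
    kind: str
    uberon: str = ""
    fma: str = ""
    cl: str = ""


class TermRegistry:
    """Lookup of anatomy terms by id or label."""

    def __init__(self, terms=()):
        self._by_id: dict[str, AnatomyTerm] = {}
        self._by_label: dict[str, AnatomyTerm] = {}
        for t in terms:
            self.add(t)

    def add(self, term: AnatomyTerm) -> None:
        if term.kind not in KINDS:
            raise ModelError(
                f"term {term.term_id!r}: unknown kind {term.kind!r} "
                f"(expected one of {KINDS})"
            )
        if term.term_id in self._by_id:
            raise ModelError(f"duplicate term_id {term.term_id!r}")
        self._by_id[term.term_id] = term
        self._by_label[term.label] = term

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self):
        return iter(self._by_id.values())

    def get(self, term_id: str) -> AnatomyTerm:
        try:
            return self._by_id[term_id]
        except KeyError:
            raise ModelError(f"unresolvable term {term_id!r}") from None

    def by_label(self, label: str) -> AnatomyTerm:
        try:
            return self._by_label[label]
        except KeyError:
            raise ModelError(f"no term with label {label!r}") from None


def load_term_table(source: str | Path) -> TermRegistry:
    """Load an anatomy-term CSV with columns term_id,label,kind,uberon,fma,cl."""
    df = pd.read_csv(source, dtype=str).fillna("")
    required = {"term_id", "label", "kind"}
    missing = required - set(df.columns)
    if missing:
        raise ModelError(f"term table missing required columns: {sorted(missing)}")
    reg = TermRegistry()
    for row in df.itertuples(index=False):
        reg.add(
            AnatomyTerm(
                term_id=row.term_id,
                label=row.label,
                kind=row.kind,
                uberon=getattr(row, "uberon", ""),
                fma=getattr(row, "fma", ""),
                cl=getattr(row, "cl", ""),
            )
        )
    return reg


@dataclass(frozen=True)
class SemanticLocation:
    """A gut location or ROI together with its tissue semantics."""

    location: GcaLocation | RoiInterval
    wall_layer: AnatomyTerm | None = None
    cell_type: AnatomyTerm | None = None
    qualifier: str = ""

    def render(self) -> str:
        """Human-readable phrase, e.g. 'mucosa at fraction 0.5 between RSJ and DSJ'."""
        parts = []
        if self.wall_layer:
            parts.append(self.wall_layer.label)
        if self.cell_type:
            parts.append(f"({self.cell_type.label})")
        if isinstance(self.location, GcaLocation):
            f = self.location.fraction
            where = "halfway" if f == 0.5 else f"at fraction {f:g}"
            parts.append(
                f"{where} between {self.location.distal_landmark} and "
                f"{self.location.proximal_landmark}"
            )
        else:
            parts.append(
                f"between {self.location.s_start_mm:g} and "
                f"{self.location.s_end_mm:g} mm on {self.location.path_id}"
            )
        if self.qualifier:
            parts.append(f"[{self.qualifier}]")
        return " ".join(parts)


def annotate(
    location: GcaLocation | RoiInterval,
    registry: TermRegistry,
    layer_id: str | None = None,
    cell_id: str | None = None,
    qualifier: str = "",
) -> SemanticLocation:
    """Attach wall-layer and/or cell-type terms to a location.

    The coordinate itself is never altered: ``result.location`` is the input
    object, so stripping semantics recovers the original exactly.
    """
    layer = cell = None
    if layer_id is not None:
        layer = registry.get(layer_id)
        if layer.kind != "wall_layer":
            raise ModelError(
                f"term {layer_id!r} has kind {layer.kind!r}, expected 'wall_layer'"
            )
    if cell_id is not None:
        cell = registry.get(cell_id)
        if cell.kind != "cell_type":
            raise ModelError(
                f"term {cell_id!r} has kind {cell.kind!r}, expected 'cell_type'"
            )
    return SemanticLocation(
        location=location, wall_layer=layer, cell_type=cell, qualifier=qualifier
    )
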