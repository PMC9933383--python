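"""gutccf — a common coordinate framework for the human gut.

The gut's natural coordinate is distance along its centreline.  This package
models the small and large intestines as 1D landmark/region paths, extracts
midline curves from segmented 2D/3D image domains, embeds the 1D model's
landmarks on those curves, and maps locations and regions of interest
between models — consensus, patient-specific, image-based or cross-species —
by landmark-anchored piecewise-linear transfer.
"""

from importlib import resources

from .cards import (
    AnnotationStore,
    LocationCard,
    interval_jaccard,
    make_location_card,
    query_store,
)
from .curve import MidlineCurve, ModelEmbedding, fit_midline_curve, place_landmarks
from .domains import DomainError, LabelledDomain, load_domain, save_domain
from .mapping import (
    MidlineProjectionIndex,
    cross_species_map,
    location_to_point,
    map_location,
    map_roi,
    point_to_location,
)
from .model import (
    GcaLocation,
    GutModel1D,
    MappingError,
    ModelError,
    ModelValidationError,
    RoiInterval,
    abs_to_location,
    load_model,
    location_to_abs,
    offset_location,
    path_length,
    proportion_location,
    rescale_model,
    save_model,
)
from .pathfind import DiscretePath, boundary_distance, extract_midline, geodesic_distance
from .phantoms import TubePhantom, TubeSpec, make_toy_model, make_tube, toy_model_dict
from .semantics import SemanticLocation, TermRegistry, annotate, load_term_table

__version__ = "0.1.0"


def consensus_model() -> GutModel1D:
    """The shipped editable human consensus 1D model."""
    with resources.as_file(
        resources.files("gutccf.data") / "human_consensus_1d.json"
    ) as p:
        return load_model(p)


def default_terms() -> TermRegistry:
    """The shipped gut anatomy / wall-layer / cell-type term table."""
    with resources.as_file(resources.files("gutccf.data") / "terms.csv") as p:
        return load_term_table(p)
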