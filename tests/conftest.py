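import numpy as np
import pytest

import gutccf as g
from gutccf.curve import fit_midline_curve, place_landmarks
from gutccf.pathfind import boundary_distance, extract_midline, geodesic_distance
from gutccf.phantoms import TubeSpec, make_tube

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50)
    settings.load_profile("ci")
except ImportError:
    pass


def simple_model(landmarks, model_id="toy", path_id="large_intestine", **kw):
    return g.make_toy_model(landmarks, model_id=model_id, path_id=path_id, **kw)


@pytest.fixture(scope="session")
def toy_abc():
    return simple_model([("A", 0), ("B", 100), ("C", 300)])


@pytest.fixture(scope="session")
def clinical_toy():
    """LI toy with the hepatic flexure 200 mm distal of the ileocaecal valve."""
    return simple_model(
        [("ANUS", 0), ("SF", 250), ("HF", 400), ("ICVc", 600), ("APT", 700)],
        model_id="clinical_toy",
    )


@pytest.fixture(scope="session")
def consensus():
    return g.consensus_model()


def segmented_model(n_regions, total, model_id="segmodel"):
    """Toy model whose region ids are seg1..segN, matching phantom labels."""
    step = total / n_regions
    lms = [("L0", 0.0)] + [(f"L{i + 1}", step * (i + 1)) for i in range(n_regions)]
    doc = {
        "model_id": model_id,
        "paths": [
            {
                "path_id": "large_intestine",
                "reference_landmark": "L0",
                "landmarks": [{"id": lid, "s_mm": s} for lid, s in lms],
                "regions": [
                    {
                        "id": f"seg{i + 1}",
                        "start_landmark": f"L{i}",
                        "end_landmark": f"L{i + 1}",
                        "length_mm": step,
                    }
                    for i in range(n_regions)
                ],
            }
        ],
    }
    return g.load_model(doc)


class PhantomBundle:
    """A phantom plus everything derived from it, computed once per session."""

    def __init__(self, spec, n_regions=None):
        self.phantom = make_tube(spec)
        d = self.phantom.domain
        self.boundary = boundary_distance(d)
        self.geodesic = geodesic_distance(d, self.phantom.end_index)
        self.path = extract_midline(
            d,
            self.phantom.start_index,
            self.phantom.end_index,
            geodesic_to_end=self.geodesic,
            boundary_dist=self.boundary,
        )
        self.curve = fit_midline_curve(self.path)
        self.model = None
        self.embedding = None
        if n_regions:
            self.model = segmented_model(
                n_regions, 100.0 * n_regions, model_id=f"{spec.domain_id}_1d"
            )
            self.embedding = place_landmarks(
                self.curve, d, self.model, "large_intestine"
            )


@pytest.fixture(scope="session")
def straight3():
    return PhantomBundle(
        TubeSpec(
            kind="straight",
            shape=(41, 200),
            half_width=10,
            splits=(1 / 3, 1 / 3, 1 / 3),
            domain_id="straight3",
        ),
        n_regions=3,
    )


@pytest.fixture(scope="session")
def sinusoid():
    return PhantomBundle(
        TubeSpec(
            kind="sinusoid",
            shape=(61, 200),
            half_width=8,
            amplitude=12,
            period=100,
            domain_id="sinusoid",
        )
    )


@pytest.fixture(scope="session")
def ubend2():
    return PhantomBundle(
        TubeSpec(
            kind="ubend",
            shape=(120, 120),
            half_width=8,
            radius=30,
            splits=(0.5, 0.5),
            domain_id="ubend2",
        ),
        n_regions=2,
    )


@pytest.fixture(scope="session")
def helix():
    return PhantomBundle(
        TubeSpec(
            kind="helix",
            shape=(64, 64, 64),
            half_width=5,
            radius=18,
            pitch=14,
            turns=2,
            domain_id="helix",
        )
    )


def hausdorff_cells(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric Hausdorff distance between two point sets, in cells."""
    from scipy.spatial import cKDTree

    d1, _ = cKDTree(a).query(b)
    d2, _ = cKDTree(b).query(a)
    return float(max(d1.max(), d2.max()))
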