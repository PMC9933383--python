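"""Model-to-model mapping, point projection and cross-species composition."""

import numpy as np
import pytest

import gutccf as g
from gutccf.mapping import (
    MidlineProjectionIndex,
    cross_species_map,
    location_to_point,
    map_location,
    map_roi,
    point_to_location,
)
from gutccf.model import MappingError
from gutccf.phantoms import TubeSpec, make_tube

from conftest import PhantomBundle, simple_model


@pytest.fixture(scope="module")
def patient(clinical_toy):
    return g.rescale_model(
        clinical_toy, {"SF": 300, "ICVc": 900, "APT": 1050}, model_id="patient"
    )


def random_locations(model, path_id, n, seed):
    rng = np.random.default_rng(seed)
    total = g.path_length(model, path_id)
    return [
        g.abs_to_location(model, path_id, s) for s in rng.uniform(0, total, n)
    ]


class TestMapLocation:
    def test_pair_and_fraction_preserved(self, clinical_toy, patient):
        loc = g.GcaLocation("clinical_toy", "large_intestine", "HF", "ICVc", 0.45)
        out = map_location(loc, clinical_toy, patient)
        assert (out.distal_landmark, out.proximal_landmark, out.fraction) == (
            "HF", "ICVc", 0.45,
        )
        assert g.location_to_abs(patient, out) != g.location_to_abs(clinical_toy, loc)

    def test_identity_to_source_model(self, clinical_toy):
        loc = g.GcaLocation("clinical_toy", "large_intestine", "SF", "HF", 0.2)
        assert map_location(loc, clinical_toy, clinical_toy) == loc

    def test_roundtrip_exact_for_shared_vocabulary(self, clinical_toy, patient):
        for loc in random_locations(clinical_toy, "large_intestine", 1000, 17):
            back = map_location(
                map_location(loc, clinical_toy, patient), patient, clinical_toy
            )
            assert (
                back.distal_landmark, back.proximal_landmark, back.fraction
            ) == (loc.distal_landmark, loc.proximal_landmark, loc.fraction)

    def test_rebracket_when_target_splits_interval(self, clinical_toy):
        # target inserts an extra landmark inside (SF, HF)
        target = simple_model(
            [("ANUS", 0), ("SF", 250), ("X", 320), ("HF", 400), ("ICVc", 600),
             ("APT", 700)],
            model_id="finer",
        )
        loc = g.GcaLocation("clinical_toy", "large_intestine", "SF", "HF", 0.5)
        out = map_location(loc, clinical_toy, target)
        # proportional position across the shared (SF, HF) span is preserved
        assert g.location_to_abs(target, out) == pytest.approx(325.0)
        back = map_location(out, target, clinical_toy)
        assert abs(back.fraction - 0.5) < 1e-9

    def test_missing_landmark_without_shared_span_errors(self, clinical_toy):
        other = simple_model([("Q", 0), ("R", 10)], model_id="other")
        loc = g.GcaLocation("clinical_toy", "large_intestine", "SF", "HF", 0.2)
        with pytest.raises(MappingError, match="missing"):
            map_location(loc, clinical_toy, other)

    def test_order_preservation(self, clinical_toy, patient):
        rng = np.random.default_rng(23)
        s_sorted = np.sort(rng.uniform(0, 700, 300))
        mapped = [
            g.location_to_abs(
                patient,
                map_location(
                    g.abs_to_location(clinical_toy, "large_intestine", s),
                    clinical_toy,
                    patient,
                ),
            )
            for s in s_sorted
        ]
        assert all(a <= b for a, b in zip(mapped, mapped[1:]))


class TestMapRoi:
    def test_zero_length_maps_to_zero_length(self, clinical_toy, patient):
        roi = g.RoiInterval("clinical_toy", "large_intestine", 420.0, 420.0)
        out = map_roi(roi, clinical_toy, patient)
        assert out.length_mm == 0.0

    def test_landmark_spanning_roi_preserves_endpoint_fractions(
        self, clinical_toy, patient
    ):
        roi = g.RoiInterval("clinical_toy", "large_intestine", 380.0, 420.0)
        out = map_roi(roi, clinical_toy, patient)
        a, b = out.to_locations(patient)
        assert a.fraction == pytest.approx((380 - 250) / 150)
        assert b.fraction == pytest.approx(20 / 200)

    def test_ordering_preserved_for_random_rois(self, clinical_toy, patient):
        rng = np.random.default_rng(31)
        for _ in range(500):
            a, b = np.sort(rng.uniform(0, 700, 2))
            out = map_roi(
                g.RoiInterval("clinical_toy", "large_intestine", a, b),
                clinical_toy,
                patient,
            )
            assert out.s_start_mm <= out.s_end_mm


@pytest.fixture(scope="module")
def species_models():
    human = simple_model(
        [("ANUS", 0), ("SF", 250), ("HF", 400), ("ICVc", 600)], model_id="human"
    )
    # the abstract intermediate lacks the hepatic flexure
    abstract = simple_model(
        [("ANUS", 0), ("SF", 150), ("ICVc", 300)], model_id="abstract"
    )
    mouse = simple_model(
        [("ANUS", 0), ("SF", 40), ("HF", 70), ("ICVc", 95)], model_id="mouse"
    )
    return human, abstract, mouse


class TestCrossSpecies:

    def test_identical_landmark_sets_preserve_pair(self, clinical_toy, patient):
        loc = g.GcaLocation("clinical_toy", "large_intestine", "HF", "ICVc", 0.45)
        out = cross_species_map(loc, clinical_toy, clinical_toy, patient)
        assert (out.distal_landmark, out.proximal_landmark, out.fraction) == (
            "HF", "ICVc", 0.45,
        )

    def test_sparser_abstract_roundtrip_identity(self, species_models):
        human, abstract, mouse = species_models
        loc = g.GcaLocation("human", "large_intestine", "HF", "ICVc", 0.45)
        there = cross_species_map(loc, human, abstract, mouse)
        back = cross_species_map(there, mouse, abstract, human)
        assert (back.distal_landmark, back.proximal_landmark) == ("HF", "ICVc")
        assert back.fraction == pytest.approx(0.45, abs=1e-9)

    def test_many_random_roundtrips(self, species_models):
        human, abstract, mouse = species_models
        for loc in random_locations(human, "large_intestine", 500, 41):
            back = cross_species_map(
                cross_species_map(loc, human, abstract, mouse),
                mouse,
                abstract,
                human,
            )
            assert back.path_id == loc.path_id
            assert abs(
                g.location_to_abs(human, back) - g.location_to_abs(human, loc)
            ) < 1e-9


class TestPointConversion:
    def test_fraction_zero_maps_to_landmark_curve_point(self, straight3):
        emb, model = straight3.embedding, straight3.model
        loc = g.GcaLocation(model.model_id, "large_intestine", "L1", "L2", 0.0)
        pt = location_to_point(loc, emb, model)
        expect = emb.curve.point_at_arclength(emb.landmark_arclengths["L1"])
        assert np.allclose(pt, expect, atol=1e-9)

    def test_straight_tube_midpoint(self, straight3):
        emb, model = straight3.embedding, straight3.model
        loc = g.GcaLocation(model.model_id, "large_intestine", "L0", "L1", 0.5)
        pt = location_to_point(loc, emb, model)
        arc_mid = 0.5 * emb.landmark_arclengths["L1"]
        assert pt[0] == pytest.approx(20.0, abs=0.2)
        assert pt[1] == pytest.approx(arc_mid, abs=0.2)

    def test_point_location_roundtrip_within_resample_step(self, ubend2):
        emb, model, dom = ubend2.embedding, ubend2.model, ubend2.phantom.domain
        step = emb.curve.resample_step_mm
        for f in np.linspace(0.02, 0.98, 17):
            for pair in (("L0", "L1"), ("L1", "L2")):
                loc = g.GcaLocation(model.model_id, "large_intestine", *pair, float(f))
                pt = location_to_point(loc, emb, model)
                back = point_to_location(pt, emb, dom, model)
                err = abs(
                    g.location_to_abs(model, back) - g.location_to_abs(model, loc)
                )
                assert err <= step

    def test_on_curve_point_is_fixed_point(self, ubend2):
        emb, model, dom = ubend2.embedding, ubend2.model, ubend2.phantom.domain
        pt = emb.curve.point_at_arclength(50.0)
        back = point_to_location(pt, emb, dom, model)
        s = g.location_to_abs(model, back)
        s_anchor, arc_anchor = emb.anchors(model)
        arc = np.interp(s, s_anchor, arc_anchor)
        assert np.linalg.norm(emb.curve.point_at_arclength(arc) - pt) < emb.curve.resample_step_mm

    def test_background_point_rejected(self, ubend2):
        with pytest.raises(Exception, match="background"):
            point_to_location(
                (0.0, 0.0), ubend2.embedding, ubend2.phantom.domain, ubend2.model
            )

    def test_off_centre_point_keeps_axial_position(self, straight3):
        emb, model, dom = straight3.embedding, straight3.model, straight3.phantom.domain
        on = point_to_location((20.0, 80.0), emb, dom, model)
        off = point_to_location((28.0, 80.0), emb, dom, model)
        assert abs(
            g.location_to_abs(model, on) - g.location_to_abs(model, off)
        ) <= emb.curve.resample_step_mm + 1e-9

    def test_projection_is_region_restricted_at_bend(self, ubend2):
        """A point just distal of the mid-bend boundary, displaced toward the
        other arm's region, must project into its own region."""
        emb, model, dom = ubend2.embedding, ubend2.model, ubend2.phantom.domain
        mid_arc = emb.landmark_arclengths["L1"]
        pt = np.asarray(emb.curve.point_at_arclength(mid_arc - 2.0))
        idx = dom.world_to_index(pt)
        assert dom.label_grid[idx] == 1
        loc = point_to_location(pt, emb, dom, model)
        assert g.location_to_abs(model, loc) <= 100.0  # stays in seg1's span

    def test_matches_region_restricted_brute_force(self, ubend2):
        emb, model, dom = ubend2.embedding, ubend2.model, ubend2.phantom.domain
        samples = emb.curve.sample_points()
        spacing = np.asarray(dom.spacing)
        sample_cells = np.round(samples / spacing).astype(int)
        sample_labels = dom.label_grid[tuple(sample_cells.T)]
        for i in range(1, len(sample_labels)):
            if sample_labels[i] == 0:
                sample_labels[i] = sample_labels[i - 1]
        rng = np.random.default_rng(3)
        cells = np.argwhere(dom.label_grid > 0)
        for cell in cells[rng.choice(len(cells), 60, replace=False)]:
            w = cell * spacing
            label = dom.label_grid[tuple(cell)]
            cand = np.flatnonzero(sample_labels == label)
            brute_arc = emb.curve.arc_s[
                cand[np.argmin(np.linalg.norm(samples[cand] - w, axis=1))]
            ]
            loc = point_to_location(w, emb, dom, model)
            s_anchor, arc_anchor = emb.anchors(model)
            got_arc = np.interp(
                g.location_to_abs(model, loc), s_anchor, arc_anchor
            )
            assert got_arc == pytest.approx(brute_arc, abs=1e-6)


@pytest.fixture(scope="module")
def small_helix():
    return PhantomBundle(
        TubeSpec(
            kind="helix", shape=(32, 32, 32), half_width=3.5, radius=9,
            pitch=8, turns=1.5, splits=(0.5, 0.5), domain_id="helix_s",
        ),
        n_regions=2,
    )


class TestProjectionIndex:
    @pytest.mark.parametrize("bundle_name", ["ubend2", "small_helix"])
    def test_index_agrees_with_direct_projection(self, bundle_name, request):
        b = request.getfixturevalue(bundle_name)
        dom, emb, model = b.phantom.domain, b.embedding, b.model
        index = MidlineProjectionIndex(emb, dom, model)
        rng = np.random.default_rng(13)
        cells = np.argwhere(dom.label_grid > 0)
        spacing = np.asarray(dom.spacing)
        for cell in cells[rng.choice(len(cells), 40, replace=False)]:
            w = cell * spacing
            assert index.lookup(w) == point_to_location(w, emb, dom, model)
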