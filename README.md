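# gutccf

A common coordinate framework (CCF) for the human gut: tools for recording,
comparing and transferring the anatomical location of biological samples —
endoscopic biopsies, surgical resections, single-cell and spatial
transcriptomics samples, radiological findings — along the small and large
intestines.

The gut's biology varies along its length much more than across it, while
its 3D folding varies between individuals and over time, so 3D proximity is
a poor basis for comparing sample locations.  `gutccf` instead uses the
gut's natural coordinate: **distance along the centreline**.  Each intestine
is a 1D path of anatomical landmarks (anus, flexures, ileocaecal valve, …)
joined by regions (rectum, sigmoid colon, …), and a location is expressed
canonically as

```
s = s_distal + f · (s_proximal − s_distal),   f ∈ [0, 1]
```

the fraction *f* between its two bracketing landmarks.  Because landmarks
are shared across models, this proportional representation transfers
unchanged between a consensus model, a patient-specific rescaling, a 2D
anatomogram, a 3D CT-derived model, or another species via an abstract
intermediate — the *base-level* piecewise-linear mapping.

The package provides:

* **1D core model** (`gutccf.model`) — validated landmark/region models
  from JSON configs, clinical location expressions ("110 mm distal from the
  ileocaecal valve", "two-thirds of the way to the hepatic flexure"),
  patient-specific rescaling from measured landmark distances.
* **Midline extraction** (`gutccf.pathfind`, `gutccf.curve`) — boundary and
  geodesic distance fields, priority-propagation midline paths through
  labelled 2D (PNG) / 3D (NIfTI) domains, cubic B-spline curves with
  arc-length tables, landmark embedding at sub-domain boundary crossings.
* **Mapping** (`gutccf.mapping`) — model↔model location and ROI transfer,
  location↔physical-point conversion through an embedding, and
  region-restricted projection of off-midline points (never across a loop).
* **ROI queries** (`gutccf.cards`) — "location cards" (serializable sample
  annotations) and store queries ranked by 1D interval Jaccard index.
* **Semantics** (`gutccf.semantics`) — wall-layer (mucosa … serosa) and
  cell-type terms with UBERON/FMA/CL cross-references, ASCT+B-style CSV.
* **Phantoms** (`gutccf.phantoms`) — synthetic labelled tube domains
  (straight / sinusoid / U-bend / helix) with analytic centreline ground
  truth, plus toy model builders; every feature is testable offline.
* **CLI** (`gutccf`) — `validate`, `simulate`, `extract-path`, `map`,
  `query`, `annotate`.

See `docs/methods.md` for the model conventions, algorithms and their
assumptions.

## Worked example

```python
import gutccf as g

model = g.consensus_model()           # shipped editable consensus distances

# "ascending colonic lesion located 110 mm distal from the ileocaecal valve"
lesion = g.offset_location(model, "ICVc", 110, "distal")
print(lesion)
# GcaLocation(model_id='human_consensus_1d', path_id='large_intestine',
#             distal_landmark='HF', proximal_landmark='CAJ', fraction=0.4)
print(g.location_to_abs(model, lesion))   # 1400.0  (mm from the anus)

# a patient's colonoscopy measured three landmark distances; the rest are
# interpolated proportionally
patient = g.rescale_model(
    model,
    {"large_intestine": {"SF": 700, "HF": 1100, "APT": 1400}},
    model_id="patient_017",
)
print(patient.path("large_intestine").s_of("RSJ"))   # 158.33  (was 190)

# same lesion, same landmark pair and fraction — different millimetres
mapped = g.map_location(lesion, model, patient)
print(g.location_to_abs(patient, mapped))            # 1162.07

# add tissue semantics
sem = g.annotate(
    g.proportion_location(model, "SF", "HF", 0.5),
    g.default_terms(),
    layer_id="mucosa",
)
print(sem.render())   # mucosa halfway between SF and HF
```

The lesion stays 40 % of the way from the hepatic flexure to the
caecum-ascending junction in both models: the proportional coordinate is
the invariant, the millimetre value is model-specific.

On the image side, a labelled domain plus a 1D model yields an embedding:

```sh
gutccf simulate tube --kind sinusoid --shape 61,200 --splits 0.5,0.5 \
       --out tube.png --truth truth.json
gutccf extract-path --domain tube.png --model model.json \
       --path large_intestine --start 30,0 --end 30,199 -o embedded.json
gutccf map --from model.json --to patient.json \
       --point 30,50 --embedding embedded.json --domain tube.png
```

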