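{
  "schema_version": "1.0",
  "model_id": "human_consensus_1d",
  "model_kind": "1d",
  "species": "human",
  "provenance": "literature consensus; distances are editable defaults typical of adult human anatomy, not measurements of any individual",
  "paths": [
    {
      "path_id": "large_intestine",
      "reference_landmark": "ANUS",
      "landmarks": [
        {"id": "ANUS", "name": "anus", "s_mm": 0.0, "intermediate": false, "term_ref": "anus"},
        {"id": "ARJ", "name": "anorectal junction", "s_mm": 40.0, "intermediate": false, "term_ref": null},
        {"id": "APR", "name": "anterior peritoneal reflection", "s_mm": 115.0, "intermediate": true, "term_ref": "anterior_peritoneal_reflection"},
        {"id": "RSJ", "name": "rectosigmoid junction", "s_mm": 190.0, "intermediate": false, "term_ref": null},
        {"id": "DSJ", "name": "descending-sigmoid junction", "s_mm": 590.0, "intermediate": false, "term_ref": null},
        {"id": "SF", "name": "splenic flexure", "s_mm": 840.0, "intermediate": false, "term_ref": "splenic_flexure"},
        {"id": "HF", "name": "hepatic flexure", "s_mm": 1340.0, "intermediate": false, "term_ref": "hepatic_flexure"},
        {"id": "CAJ", "name": "caecum-ascending colon junction", "s_mm": 1490.0, "intermediate": false, "term_ref": null},
        {"id": "ICVc", "name": "ileocaecal valve (caecum centreline)", "s_mm": 1510.0, "intermediate": true, "term_ref": "ileocaecal_valve"},
        {"id": "APB", "name": "appendix base", "s_mm": 1550.0, "intermediate": false, "term_ref": null},
        {"id": "APT", "name": "appendix tip", "s_mm": 1630.0, "intermediate": false, "term_ref": null}
      ],
      "regions": [
        {"id": "anal_canal", "name": "anal canal", "start_landmark": "ANUS", "end_landmark": "ARJ", "length_mm": 40.0, "term_ref": "anal_canal"},
        {"id": "rectum", "name": "rectum", "start_landmark": "ARJ", "end_landmark": "RSJ", "length_mm": 150.0, "term_ref": "rectum"},
        {"id": "sigmoid_colon", "name": "sigmoid colon", "start_landmark": "RSJ", "end_landmark": "DSJ", "length_mm": 400.0, "term_ref": "sigmoid_colon"},
        {"id": "descending_colon", "name": "descending colon", "start_landmark": "DSJ", "end_landmark": "SF", "length_mm": 250.0, "term_ref": "descending_colon"},
        {"id": "transverse_colon", "name": "transverse colon", "start_landmark": "SF", "end_landmark": "HF", "length_mm": 500.0, "term_ref": "transverse_colon"},
        {"id": "ascending_colon", "name": "ascending colon", "start_landmark": "HF", "end_landmark": "CAJ", "length_mm": 150.0, "term_ref": "ascending_colon"},
        {"id": "caecum", "name": "caecum", "start_landmark": "CAJ", "end_landmark": "APB", "length_mm": 60.0, "term_ref": "caecum"},
        {"id": "appendix", "name": "vermiform appendix", "start_landmark": "APB", "end_landmark": "APT", "length_mm": 80.0, "term_ref": "appendix"}
      ]
    },
    {
      "path_id": "small_intestine",
      "reference_landmark": "ICVi",
      "landmarks": [
        {"id": "ICVi", "name": "ileocaecal valve (ileum side)", "s_mm": 0.0, "intermediate": false, "term_ref": "ileocaecal_valve"},
        {"id": "IJJ", "name": "ileum-jejunum junction", "s_mm": 1700.0, "intermediate": false, "term_ref": null},
        {"id": "DJF", "name": "duodenojejunal flexure", "s_mm": 4200.0, "intermediate": false, "term_ref": null},
        {"id": "GDJ", "name": "gastro-duodenal junction", "s_mm": 4450.0, "intermediate": false, "term_ref": null}
      ],
      "regions": [
        {"id": "ileum", "name": "ileum", "start_landmark": "ICVi", "end_landmark": "IJJ", "length_mm": 1700.0, "term_ref": "ileum"},
        {"id": "jejunum", "name": "jejunum", "start_landmark": "IJJ", "end_landmark": "DJF", "length_mm": 2500.0, "term_ref": "jejunum"},
        {"id": "duodenum", "name": "duodenum", "start_landmark": "DJF", "end_landmark": "GDJ", "length_mm": 250.0, "term_ref": "duodenum"}
      ]
    }
  ]
}
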