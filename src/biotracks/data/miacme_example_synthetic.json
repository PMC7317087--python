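{
  "miacme_version": "1.1",
  "investigation": {
    "title": "Synthetic example: single-cell migration of suspension cells under kinase inhibition",
    "description": "Synthetic illustrative metadata document shipped with the package; it is constructed to exercise every MUST and SHOULD field of the requirement table and does not describe a real experiment.",
    "studies": [{"identifier": "study-1", "title": "Dose response of inhibitor on random migration"}],
    "publications": [],
    "people": [{"name": "A. Researcher", "role": "data curator", "affiliation": "Example Institute"}],
    "organizations": [{"name": "Example Institute"}],
    "grants": [{"identifier": "EX-0001", "funder": "Example Funder"}]
  },
  "experimental_setup": {
    "assay_type": {
      "label": "single cell random migration assay",
      "source": "EXO",
      "accession": "EXO:0000101"
    },
    "cell_model": [
      {"label": "Ba/F3 cell", "source": "CLO", "accession": "CLO:0001958"}
    ],
    "cell_input": "cells seeded in suspension on fibronectin-coated glass",
    "environment": {
      "temperature": 37.0,
      "temperature_unit": "degree Celsius",
      "co2_percent": 5.0,
      "medium": "RPMI-1640 with 10% FBS"
    },
    "perturbations": [
      {"agent": {"label": "imatinib", "source": "CHEBI", "accession": "CHEBI:45783"},
       "dose": 1.0, "dose_unit": "micromolar"}
    ]
  },
  "imaging_condition": {
    "modality": {
      "label": "phase contrast microscopy",
      "source": "FBbi",
      "accession": "FBbi:00000247"
    },
    "instrument": "inverted widefield microscope, 10x/0.3 objective",
    "channels": [{"name": "transmitted light"}],
    "time_interval": 2.0,
    "time_interval_unit": "minute",
    "duration": 240.0,
    "pixel_size": 0.65,
    "pixel_size_unit": "micrometer"
  },
  "data": {
    "raw_data_summary": {
      "number_of_images": 120,
      "image_dimensions": "1024x1024x1",
      "number_of_replicates": 3
    },
    "processed_data": [{"description": "segmented object masks", "format": "OME-TIFF"}],
    "analysis_outputs": [{"description": "cell trajectories", "format": "biotracks package"}]
  }
}
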