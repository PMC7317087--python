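# Requirement levels for MIACME 1.1 field paths (dotted paths into the
# document). MUST -> missing field is an error; SHOULD -> warning.
# This table is data, editable without code changes; the canonical field
# list lives in the MIACME specification's own spreadsheet, of which this
# is a working approximation.
"1.1":
  experimental_setup: MUST
  experimental_setup.assay_type: MUST
  experimental_setup.cell_model: MUST
  imaging_condition: MUST
  imaging_condition.modality: MUST
  data: MUST
  data.raw_data_summary: MUST
  investigation: SHOULD
  investigation.title: SHOULD
  investigation.people: SHOULD
  experimental_setup.cell_input: SHOULD
  experimental_setup.environment: SHOULD
  experimental_setup.perturbations: SHOULD
  imaging_condition.instrument: SHOULD
  imaging_condition.time_interval: SHOULD
  imaging_condition.pixel_size: SHOULD
  data.raw_data_summary.number_of_images: SHOULD
  data.raw_data_summary.number_of_replicates: SHOULD
  data.analysis_outputs: SHOULD
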