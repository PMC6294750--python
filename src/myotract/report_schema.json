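{
  "description": "Required entries of a pipeline run report (dotted paths into the JSON object).",
  "required": [
    "version",
    "config",
    "config.seed",
    "config.out_dir",
    "stages",
    "stages.data",
    "stages.data.source",
    "stages.data.n_mask_voxels",
    "stages.tensor.n_valid_voxels",
    "stages.tensor.mean_fa_in_mask",
    "stages.fact.n_tracts_raw",
    "stages.fact.n_tracts_after_length_filter",
    "stages.gibbs.n_particles",
    "stages.gibbs.n_tracts_after_length_filter",
    "stages.gibbs.energy_first10pct_mean",
    "stages.gibbs.energy_last10pct_mean"
  ]
}
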