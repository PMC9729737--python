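# Example configuration for `timeuse-coda report --config examples/pipeline_config.yml`
# (keys mirror timeuse_coda.pipeline.PipelineConfig; omitted keys keep defaults)
seed: 1
n: 426                           # enrolment roster size
invalid_accel_fraction: 0.0493   # ~21/426 fail the valid-week rule
missing_covariate_fraction: 0.0493
alpha: 0.05
drop_covariates: false           # keep the collective covariate block regardless of p
outcomes: [global_cognition, ltm, stm, exec, speed]
reallocate_behaviour: mvpa
reallocate_max_delta: 60
out_dir: results
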