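# compact synthetic experiment used by the end-to-end golden test:
# 6 fields of view, 40 airpuff trials at 0.2 Hz, elevated response
# probability so that coupling pairs exist in a small run
n_fovs: 6
n_trials: 40
stimulus_interval_s: 5.0
p_response: 0.25
n_fibres_per_fov: [8, 16]
coupling_structure:
  group_size: 2
  reliability: 0.9
  trial_reliability: 0.9
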