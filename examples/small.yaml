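generator: {n_subjects: 2, circuits_per_subject: 6, segment_duration_range: [2.0, 2.5]}
training: {max_iters: 20, hidden_units: 20}
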