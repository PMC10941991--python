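{
  "alpha": 0.01,
  "beta": 2000.0,
  "lapse": 0.0,
  "bias_side": 1,
  "bias_strength": 0.0,
  "latency_median_correct_s": 7.3,
  "latency_sigma": 0.5,
  "latency_ratio_incorrect": 3.0,
  "fatigue_trials": null,
  "learning_rate": 0.0,
  "seed": 0
}
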