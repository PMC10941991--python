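{
  "alpha": 0.95,
  "beta": 4.0,
  "lapse": 0.1,
  "bias_side": 1,
  "bias_strength": 0.0,
  "latency_median_correct_s": 8.6,
  "latency_sigma": 0.5,
  "latency_ratio_incorrect": 3.0,
  "fatigue_trials": null,
  "learning_rate": 30.0,
  "seed": 0
}
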