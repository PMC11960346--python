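# Example preprocessing config for `coda24 preprocess`.
# Cut-point values are illustrative; substitute the set validated for your
# device, wear location and population.
cutpoints:
  epoch_length_s: 60
  sb_upper: 2860      # counts/epoch (VM3); <= sb_upper is sedentary
  lpa_upper: 3940     # <= lpa_upper is light activity, above is MVPA
nonwear:
  window_min: 90      # minimum zero-count run flagged as non-wear
  spike_tolerance_min: 2
sleep:
  weights: [0.04, 0.04, 0.2, 1.0, 0.2, 0.04, 0.04]
  threshold: 100.0    # weighted window score below this is sleep
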