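# Detection parameters for low-spatial-precision recordings.
# Start from the shipped preset and override per participant as needed.
preset: low_precision
# velocity_threshold: 20      # deg/s
# min_fixation_duration: 120  # ms

smoothing:
  window_ms: 100
  temporal_sigma_ms: 20
  range_sigma_deg: 0.5
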