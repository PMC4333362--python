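# Detection parameters for high-spatial-precision recordings, spelled out
# in full (equivalent to `preset: high_precision`).
interpolation_latency: 60            # ms
velocity_threshold: 9                # deg/s
max_interpolation_displacement: 0.25 # deg
degrees_per_pixel: 0.0177            # deg/pixel
merge_max_distance: 0.24             # deg
merge_max_gap: 50                    # ms
max_rms_per_fixation: 0.24           # deg
min_fixation_duration: 99            # ms
include_single_eye: true
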