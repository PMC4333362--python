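# Synthetic recording emulating a low-precision infant session.
sampling_rate: 120
n_fixations: 20
fixation_duration_ms: [200, 800]
saccade_amplitude_deg: [3, 7]
saccade_duration_ms: 30
noise_rms: 0.3          # deg; measured combined-trace RMS precision
gap_rate_hz: 1.0        # both-eye dropouts per second
gap_length_ms: [20, 80]
single_eye_rate_hz: 0.5
degrees_per_pixel: 0.0177
seed: 7
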