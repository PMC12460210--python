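# Synthetic cohort with a planted beta-band decrease on a right-lateral
# edge set and a latent state coupling theta connectivity to tracking
# noise; sized to finish in seconds on one CPU.
out_dir: runs/example
seed: 7
n_subjects: 12
n_trials: 3
trial_duration: 16.0
effect_size: -0.33
latent_gain: 0.35
nbs_k: 4096
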