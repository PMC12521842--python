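# Full-pipeline defaults: 250 synthetic recordings (50 per class) at
# 15 dB SNR, EEMD denoising, 5-fold stratified cross-validation.
sim:
  n_per_class: 50
  fs: 4000.0
  duration_s: 5.0
  heart_rate_bpm: 60.0
  snr_db: 15.0
  seed: 11
denoise: true
eemd_trials: 3
eemd_noise_sd: 0.1
eemd_max_imfs: 8
lms_taps: 8
smote_k: 5
select_particles: 12
select_iters: 15
select_threshold: 0.5
fis_inputs: 4
fis_mfs: 2
fis_epochs: 30
seg_len: 512
xcnn_epochs: 30
xcnn_lr: 0.001
xcnn_dropout: 0.5
cv_folds: 5
seed: 11
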