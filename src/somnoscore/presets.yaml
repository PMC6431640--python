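# Synthetic polysomnography presets (format version 1).
#
# Bout means and transition weights parameterize the semi-Markov hypnogram
# model; band profiles are relative EEG power in (delta, theta, alpha,
# sigma, beta) and must sum to 1; emg/eog/acc levels are relative signal
# amplitudes per stage (wake > NREM > REM muscle tone by construction).
version: 1
presets:
  human:
    epoch_length: 30
    stages: [W, N1, N2, N3, REM]
    mean_bout_s: {W: 150, N1: 60, N2: 600, N3: 450, REM: 600}
    transitions:
      W: {N1: 0.9, N2: 0.1}
      N1: {W: 0.25, N2: 0.75}
      N2: {W: 0.1, N1: 0.1, N3: 0.45, REM: 0.35}
      N3: {W: 0.2, N2: 0.8}
      REM: {W: 0.3, N1: 0.4, N2: 0.3}
    band_profile:
      W: [0.15, 0.20, 0.40, 0.10, 0.15]
      N1: [0.25, 0.45, 0.15, 0.08, 0.07]
      N2: [0.45, 0.25, 0.10, 0.15, 0.05]
      N3: [0.75, 0.12, 0.05, 0.05, 0.03]
      REM: [0.20, 0.50, 0.12, 0.08, 0.10]
    emg_level: {W: 1.0, N1: 0.5, N2: 0.35, N3: 0.3, REM: 0.08}
    eog_level: {W: 0.8, N1: 0.3, N2: 0.15, N3: 0.1, REM: 1.0}
    acc_level: {}
    channels:
      - {label: "EEG C3:A2", modality: EEG, rate: 128}
      - {label: "EEG C4:A1", modality: EEG, rate: 128}
      - {label: "EOG L", modality: EOG, rate: 128}
      - {label: "EOG R", modality: EOG, rate: 128}
      - {label: "EMG chin", modality: EMG, rate: 128}
    noise_floor: 0.05
  rodent:
    epoch_length: 4
    stages: [W, NREM, REM]
    mean_bout_s: {W: 120, NREM: 160, REM: 60}
    transitions:
      W: {NREM: 0.98, REM: 0.02}
      NREM: {W: 0.35, REM: 0.65}
      REM: {W: 0.6, NREM: 0.4}
    band_profile:
      W: [0.15, 0.35, 0.15, 0.10, 0.25]
      NREM: [0.60, 0.15, 0.10, 0.10, 0.05]
      REM: [0.10, 0.60, 0.12, 0.08, 0.10]
    emg_level: {W: 1.0, NREM: 0.35, REM: 0.08}
    eog_level: {}
    acc_level: {}
    channels:
      - {label: "EEG frontoparietal", modality: EEG, rate: 128}
      - {label: "EMG nuchal", modality: EMG, rate: 128}
    noise_floor: 0.05
  avian:
    epoch_length: 4
    stages: [W, NREM, REM]
    # REM bouts in birds are very short: a 6.4 s geometric mean puts the
    # 95th percentile of bout duration at 16 s (4 epochs of 4 s)
    mean_bout_s: {W: 60, NREM: 40, REM: 6.4}
    transitions:
      W: {NREM: 1.0}
      NREM: {W: 0.5, REM: 0.5}
      REM: {W: 0.3, NREM: 0.7}
    band_profile:
      W: [0.20, 0.30, 0.20, 0.10, 0.20]
      NREM: [0.60, 0.20, 0.10, 0.06, 0.04]
      REM: [0.15, 0.50, 0.15, 0.10, 0.10]
    emg_level: {}
    eog_level: {}
    acc_level: {W: 1.0, NREM: 0.15, REM: 0.1}
    channels:
      - {label: "EEG hyperpallium", modality: EEG, rate: 128}
      - {label: "ACC head", modality: ACC, rate: 64}
    noise_floor: 0.05
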