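# 70-cow farm with one AMS and three ceiling cameras; one week of emulation.
farm:
  farm_id: H1
  n_cows: 70
  barn_area: 625
  n_cubicles: 66
  n_water_troughs: 2
  n_ams: 1
  n_cameras: 3
  camera_height: 4.9
  camera_spacing: 14.5

seed: 7

sim:
  n_days: 7
  tick: 5

error_model:
  daily_miss: 0.07
  ghost_rate: 0.10
  id_correct: 0.75
  id_swap_share: 0.5
  activity_accuracy: 0.90
  location_cooccur: 0.80
  location_base_rate: 0.02
  night_detect_drop: 0.10

evaluation:
  alpha: 0.01

samplesize:
  - {label: identification, p: 0.5, margin: 0.05, confidence: 0.95, population: 70}
  - {label: unbounded, p: 0.5, margin: 0.05, confidence: 0.95}
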