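{
  "phantom": {
    "grid_shape": [12, 64, 64],
    "spacing_ch1": [4, 2, 2],
    "spacing_ch2": [4, 1, 1],
    "lesion_radius_range": [6, 10],
    "t1_hypointense_fraction": 0.5,
    "confuser_count": 3,
    "confuser_radius_range": [4, 7],
    "misregistration_offset": [0.0, 1.0, 1.0]
  },
  "network": {
    "base_channels": 4,
    "channels_per_stage": [4, 8, 8, 8],
    "growth_rate": 4,
    "dense_micro_blocks": 2,
    "gn_groups": 4
  },
  "training": {
    "learning_rate": 0.001,
    "epochs": 10,
    "augment": false
  }
}
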