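# Committed base schedule for Elastic YOLO (lambda = 1.0 reference).
# Calibrated by scripts/calibrate_schedule.py so the full-scale profile at
# 256x256 input reproduces the published 12.4M-parameter / 30.1-GFLOP budget.
base_channels: [96, 168, 224, 224, 248]
base_depths: [4, 6, 6, 3, 2]
head_channels: 96
epsilon: 0.01
deformable: true
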