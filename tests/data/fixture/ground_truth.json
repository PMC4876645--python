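{
 "M1_000": {
  "area": "M1",
  "baseline_rate": 5.0,
  "latency_ms": 22.380287085796144,
  "peak_amplitude": 120.0,
  "preferred_angle_rad": 0.14320933676546635,
  "ptd_elbow": "null",
  "ptd_shoulder": "flexor",
  "sign_flipped": false,
  "task_delay_ms": {
   "in": 0.0,
   "movie": 0.0,
   "out": 0.0,
   "posture": 0.0
  },
  "task_gain": {
   "in": 1.0,
   "movie": 1.0,
   "out": 1.0,
   "posture": 1.0
  },
  "unit_id": "M1_000"
 },
 "M1_001": {
  "area": "M1",
  "baseline_rate": 5.0,
  "latency_ms": 20.862458950873872,
  "peak_amplitude": 120.0,
  "preferred_angle_rad": 2.364224114408375,
  "ptd_elbow": "flexor",
  "ptd_shoulder": "extensor",
  "sign_flipped": false,
  "task_delay_ms": {
   "in": 0.0,
   "movie": 0.0,
   "out": 0.0,
   "posture": 0.0
  },
  "task_gain": {
   "in": 1.0,
   "movie": 1.0,
   "out": 1.0,
   "posture": 1.0
  },
  "unit_id": "M1_001"
 },
 "M1_002": {
  "area": "M1",
  "baseline_rate": 5.0,
  "latency_ms": 23.076920698355572,
  "peak_amplitude": 120.0,
  "preferred_angle_rad": 3.4261253586362006,
  "ptd_elbow": "null",
  "ptd_shoulder": "extensor",
  "sign_flipped": false,
  "task_delay_ms": {
   "in": 0.0,
   "movie": 0.0,
   "out": 0.0,
   "posture": 0.0
  },
  "task_gain": {
   "in": 1.0,
   "movie": 1.0,
   "out": 1.0,
   "posture": 1.0
  },
  "unit_id": "M1_002"
 }
}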