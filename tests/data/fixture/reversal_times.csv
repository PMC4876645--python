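unit_id,area,task,shoulder_load,elbow_load,trial,evoked_count,reversal_time_ms
M1_000,M1,posture,flexor,flexor,0,2,167.0000
M1_000,M1,posture,flexor,flexor,1,6,200.0000
M1_000,M1,posture,flexor,flexor,2,0,200.0000
M1_000,M1,posture,flexor,flexor,3,1,200.0000
M1_000,M1,posture,flexor,flexor,4,2,200.0000
M1_000,M1,posture,flexor,flexor,5,1,200.0000
M1_000,M1,posture,null,flexor,0,3,200.0000
M1_000,M1,posture,null,flexor,1,3,182.0000
M1_000,M1,posture,null,flexor,2,2,200.0000
M1_000,M1,posture,null,flexor,3,1,200.0000
M1_000,M1,posture,null,flexor,4,1,200.0000
M1_000,M1,posture,null,flexor,5,0,200.0000
M1_000,M1,posture,extensor,flexor,0,0,200.0000
M1_000,M1,posture,extensor,flexor,1,0,200.0000
M1_000,M1,posture,extensor,flexor,2,1,200.0000
M1_000,M1,posture,extensor,flexor,3,0,200.0000
M1_000,M1,posture,extensor,flexor,4,0,200.0000
M1_000,M1,posture,extensor,flexor,5,0,184.0000
M1_000,M1,posture,flexor,null,0,3,200.0000
M1_000,M1,posture,flexor,null,1,0,200.0000
M1_000,M1,posture,flexor,null,2,2,200.0000
M1_000,M1,posture,flexor,null,3,3,200.0000
M1_000,M1,posture,flexor,null,4,0,200.0000
M1_000,M1,posture,flexor,null,5,6,200.0000
M1_000,M1,posture,null,null,0,2,200.0000
M1_000,M1,posture,null,null,1,0,200.0000
M1_000,M1,posture,null,null,2,0,176.0000
M1_000,M1,posture,null,null,3,0,185.0000
M1_000,M1,posture,null,null,4,0,200.0000
M1_000,M1,posture,null,null,5,0,200.0000
M1_000,M1,posture,extensor,null,0,0,197.0000
M1_000,M1,posture,extensor,null,1,0,187.0000
M1_000,M1,posture,extensor,null,2,0,200.0000
M1_000,M1,posture,extensor,null,3,0,200.0000
M1_000,M1,posture,extensor,null,4,0,200.0000
M1_000,M1,posture,extensor,null,5,0,200.0000
M1_000,M1,posture,flexor,extensor,0,2,200.0000
M1_000,M1,posture,flexor,extensor,1,1,200.0000
M1_000,M1,posture,flexor,extensor,2,2,200.0000
M1_000,M1,posture,flexor,extensor,3,1,195.0000
M1_000,M1,posture,flexor,extensor,4,3,200.0000
M1_000,M1,posture,flexor,extensor,5,3,193.0000
M1_000,M1,posture,null,extensor,0,1,200.0000
M1_000,M1,posture,null,extensor,1,1,200.0000
M1_000,M1,posture,null,extensor,2,0,200.0000
M1_000,M1,posture,null,extensor,3,2,193.0000
M1_000,M1,posture,null,extensor,4,2,200.0000
M1_000,M1,posture,null,extensor,5,2,200.0000
M1_000,M1,posture,extensor,extensor,0,0,200.0000
M1_000,M1,posture,extensor,extensor,1,0,191.0000
M1_000,M1,posture,extensor,extensor,2,0,200.0000
M1_000,M1,posture,extensor,extensor,3,0,200.0000
M1_000,M1,posture,extensor,extensor,4,0,186.0000
M1_000,M1,posture,extensor,extensor,5,0,200.0000
M1_001,M1,posture,flexor,flexor,0,1,200.0000
M1_001,M1,posture,flexor,flexor,1,1,200.0000
M1_001,M1,posture,flexor,flexor,2,3,200.0000
M1_001,M1,posture,flexor,flexor,3,1,200.0000
M1_001,M1,posture,flexor,flexor,4,2,200.0000
M1_001,M1,posture,flexor,flexor,5,0,193.0000
M1_001,M1,posture,null,flexor,0,2,200.0000
M1_001,M1,posture,null,flexor,1,0,200.0000
M1_001,M1,posture,null,flexor,2,2,194.0000
M1_001,M1,posture,null,flexor,3,0,200.0000
M1_001,M1,posture,null,flexor,4,2,200.0000
M1_001,M1,posture,null,flexor,5,1,191.0000
M1_001,M1,posture,extensor,flexor,0,3,200.0000
M1_001,M1,posture,extensor,flexor,1,3,200.0000
M1_001,M1,posture,extensor,flexor,2,4,198.0000
M1_001,M1,posture,extensor,flexor,3,1,200.0000
M1_001,M1,posture,extensor,flexor,4,1,200.0000
M1_001,M1,posture,extensor,flexor,5,2,200.0000
M1_001,M1,posture,flexor,null,0,0,200.0000
M1_001,M1,posture,flexor,null,1,0,200.0000
M1_001,M1,posture,flexor,null,2,1,200.0000
M1_001,M1,posture,flexor,null,3,0,200.0000
M1_001,M1,posture,flexor,null,4,1,200.0000
M1_001,M1,posture,flexor,null,5,0,187.0000
M1_001,M1,posture,null,null,0,0,200.0000
M1_001,M1,posture,null,null,1,0,200.0000
M1_001,M1,posture,null,null,2,0,200.0000
M1_001,M1,posture,null,null,3,0,200.0000
M1_001,M1,posture,null,null,4,0,194.0000
M1_001,M1,posture,null,null,5,0,200.0000
M1_001,M1,posture,extensor,null,0,0,200.0000
M1_001,M1,posture,extensor,null,1,0,200.0000
M1_001,M1,posture,extensor,null,2,4,181.0000
M1_001,M1,posture,extensor,null,3,0,200.0000
M1_001,M1,posture,extensor,null,4,4,200.0000
M1_001,M1,posture,extensor,null,5,1,200.0000
M1_001,M1,posture,flexor,extensor,0,0,200.0000
M1_001,M1,posture,flexor,extensor,1,0,200.0000
M1_001,M1,posture,flexor,extensor,2,0,200.0000
M1_001,M1,posture,flexor,extensor,3,1,200.0000
M1_001,M1,posture,flexor,extensor,4,1,200.0000
M1_001,M1,posture,flexor,extensor,5,0,156.0000
M1_001,M1,posture,null,extensor,0,0,200.0000
M1_001,M1,posture,null,extensor,1,2,200.0000
M1_001,M1,posture,null,extensor,2,1,200.0000
M1_001,M1,posture,null,extensor,3,1,200.0000
M1_001,M1,posture,null,extensor,4,1,200.0000
M1_001,M1,posture,null,extensor,5,0,200.0000
M1_001,M1,posture,extensor,extensor,0,2,200.0000
M1_001,M1,posture,extensor,extensor,1,3,200.0000
M1_001,M1,posture,extensor,extensor,2,2,174.0000
M1_001,M1,posture,extensor,extensor,3,2,177.0000
M1_001,M1,posture,extensor,extensor,4,0,200.0000
M1_001,M1,posture,extensor,extensor,5,0,200.0000
M1_002,M1,posture,flexor,flexor,0,0,170.0000
M1_002,M1,posture,flexor,flexor,1,0,200.0000
M1_002,M1,posture,flexor,flexor,2,0,200.0000
M1_002,M1,posture,flexor,flexor,3,3,200.0000
M1_002,M1,posture,flexor,flexor,4,0,193.0000
M1_002,M1,posture,flexor,flexor,5,0,200.0000
M1_002,M1,posture,null,flexor,0,0,200.0000
M1_002,M1,posture,null,flexor,1,1,200.0000
M1_002,M1,posture,null,flexor,2,0,169.0000
M1_002,M1,posture,null,flexor,3,2,200.0000
M1_002,M1,posture,null,flexor,4,3,200.0000
M1_002,M1,posture,null,flexor,5,1,198.0000
M1_002,M1,posture,extensor,flexor,0,4,200.0000
M1_002,M1,posture,extensor,flexor,1,3,200.0000
M1_002,M1,posture,extensor,flexor,2,1,200.0000
M1_002,M1,posture,extensor,flexor,3,3,200.0000
M1_002,M1,posture,extensor,flexor,4,1,200.0000
M1_002,M1,posture,extensor,flexor,5,1,200.0000
M1_002,M1,posture,flexor,null,0,1,200.0000
M1_002,M1,posture,flexor,null,1,0,200.0000
M1_002,M1,posture,flexor,null,2,0,173.0000
M1_002,M1,posture,flexor,null,3,0,194.0000
M1_002,M1,posture,flexor,null,4,0,182.0000
M1_002,M1,posture,flexor,null,5,0,198.0000
M1_002,M1,posture,null,null,0,0,200.0000
M1_002,M1,posture,null,null,1,0,200.0000
M1_002,M1,posture,null,null,2,0,200.0000
M1_002,M1,posture,null,null,3,0,200.0000
M1_002,M1,posture,null,null,4,0,188.0000
M1_002,M1,posture,null,null,5,0,200.0000
M1_002,M1,posture,extensor,null,0,3,175.0000
M1_002,M1,posture,extensor,null,1,4,200.0000
M1_002,M1,posture,extensor,null,2,1,200.0000
M1_002,M1,posture,extensor,null,3,4,200.0000
M1_002,M1,posture,extensor,null,4,0,200.0000
M1_002,M1,posture,extensor,null,5,2,200.0000
M1_002,M1,posture,flexor,extensor,0,0,200.0000
M1_002,M1,posture,flexor,extensor,1,1,196.0000
M1_002,M1,posture,flexor,extensor,2,1,180.0000
M1_002,M1,posture,flexor,extensor,3,2,200.0000
M1_002,M1,posture,flexor,extensor,4,0,200.0000
M1_002,M1,posture,flexor,extensor,5,0,200.0000
M1_002,M1,posture,null,extensor,0,3,200.0000
M1_002,M1,posture,null,extensor,1,1,200.0000
M1_002,M1,posture,null,extensor,2,1,187.0000
M1_002,M1,posture,null,extensor,3,1,200.0000
M1_002,M1,posture,null,extensor,4,2,200.0000
M1_002,M1,posture,null,extensor,5,1,175.0000
M1_002,M1,posture,extensor,extensor,0,3,164.0000
M1_002,M1,posture,extensor,extensor,1,1,177.0000
M1_002,M1,posture,extensor,extensor,2,2,200.0000
M1_002,M1,posture,extensor,extensor,3,2,185.0000
M1_002,M1,posture,extensor,extensor,4,4,200.0000
M1_002,M1,posture,extensor,extensor,5,5,200.0000
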