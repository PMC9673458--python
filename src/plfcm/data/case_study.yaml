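scale_state:
  tau: 5
scale_weight:
  tau: 3
nodes:
- id: C1
  label: Balanced diet
  group: lifestyle
  role: factor
  initial: '{s-3:0.15, s0:0.2, s3:0.65}'
- id: C2
  label: Quality of sleep
  group: lifestyle
  role: factor
  initial: '{s-3:0.1, s0:0.3, s3:0.6}'
- id: C3
  label: Physical exercise
  group: lifestyle
  role: factor
  initial: '{s-3:0.75, s0:0, s3:0.25}'
- id: C4
  label: Unhealthy lifestyle
  group: lifestyle
  role: factor
  initial: '{s-3:0.3, s0:0, s3:0.7}'
- id: C5
  label: Mentality
  group: lifestyle
  role: factor
  initial: '{s-3:0.15, s0:0, s3:0.85}'
- id: C6
  label: Preventive medical service utilization
  group: health management
  role: factor
  initial: '{s-3:0.4, s0:0, s3:0.6}'
- id: C7
  label: Chronic diseases management
  group: health management
  role: factor
  initial: '{s-3:0.3, s0:0, s3:0.7}'
- id: C8
  label: Income
  group: socio-economic status
  role: factor
  initial: '{s-3:0.4, s0:0.55, s3:0.05}'
- id: C9
  label: Occupation
  group: socio-economic status
  role: factor
  initial: '{s-3:0.1, s0:0.75, s3:0.15}'
- id: C10
  label: Education
  group: socio-economic status
  role: factor
  initial: '{s-3:0.6, s0:0.35, s3:0.05}'
- id: C11
  label: Environmental pollution
  group: living environment
  role: factor
  initial: '{s-3:0.3, s0:0.5, s3:0.2}'
- id: C12
  label: Intergenerational relationship
  group: living environment
  role: factor
  initial: '{s-3:0.1, s0:0.4, s3:0.5}'
- id: R
  label: Self-rated health
  group: health
  role: outcome
  initial: '{s-3:0.15, s0:0.4, s3:0.45}'
edges: []
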