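version: 1
# Named stroke programs. Angles in radians, net accumulated per phase.
# Neonate durations are seconds (one period = 1.243 s); juvenile durations
# are fractions of the period and require a beat frequency (beats/minute).
neonate:
  citation: >-
    Video-derived neonate stroke program (420 fps high-speed recordings of
    tethered hatchlings, eight averaged sequences).
  blend_fraction: 0.10
  setup_time: 0.0
  durations_are_fractions: false
  phases:
    - {name: down,   duration: 0.384, roll: -1.15, pitch: 0.45,  yaw: -0.32, bend: 0.16}
    - {name: bottom, duration: 0.199, roll: 0.06,  pitch: -0.71, yaw: 0.16,  bend: -0.20}
    - {name: up,     duration: 0.497, roll: 0.96,  pitch: -0.55, yaw: 0.11,  bend: -0.16}
    - {name: top,    duration: 0.163, roll: 0.06,  pitch: 0.81,  yaw: 0.07,  bend: 0.20}
juvenile:
  citation: >-
    Stroke program measured from public video of freely swimming adults;
    stroke frequencies for tethered juveniles from Bostrom et al. (2010).
  blend_fraction: 0.10
  setup_time: 0.5
  durations_are_fractions: true
  phases:
    - {name: down,   duration: 0.323, roll: -0.95, pitch: 0.0,  yaw: -0.15, bend: 0.0}
    - {name: bottom, duration: 0.170, roll: 0.0,   pitch: 2.40, yaw: 0.0,   bend: 0.80}
    - {name: up,     duration: 0.337, roll: 0.95,  pitch: 0.0,  yaw: 0.15,  bend: 0.0}
    - {name: top,    duration: 0.170, roll: 0.0,   pitch: -2.40, yaw: 0.0,  bend: -0.80}
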