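version: 1
# Morphometrics and swimming-simulation outputs per turtle/run.  The
# heat-transfer coefficients (W/K m^2) and stroke powers (W) are outputs of
# moving-mesh Navier-Stokes swimming simulations and are used here as
# authoritative inputs to the internal-conduction model.
seawater:
  citation: Seawater property set used by the swimming simulations.
  density: 1015.0          # kg/m^3
  specific_heat: 4053.0    # J/kg K
  conductivity: 0.6        # W/m K
  viscosity: 9.68e-3       # kg/m s

metabolism:
  citation: >-
    Allometric RMR level for leatherbacks after the Wallace & Jones (2008)
    review (per-mass rate a*m^b W/kg at 30 C; b = -0.25 i.e. whole-body
    mass^0.75); Boltzmann-Arrhenius scaling for reptiles after Gillooly et
    al. (2001), E = 0.76 eV; aerobic efficiency of tortoise muscle 35%
    (Woledge 1968).
  allometric_scale: 1.05     # W/kg at 1 kg
  allometric_exponent: -0.25
  activation_energy: 0.76    # eV
  reference_temperature_c: 30.0
  aerobic_efficiency: 0.35

materials:
  citation: >-
    Blubber density (Parry 1949), blubber conductivity (Kvadsheim et al.
    1996), blubber heat capacity from lipid/water-content weighting, core
    density set for neutral buoyancy, live/dead tissue properties (Cheng &
    Plewes 2002); high 47 C anchor prevents unrealistic hot spots.
  blubber: {density: 980.0, heat_capacity: 2940.0, conductivity: 0.280}
  core:
    density: 1035.0
    heat_capacity: 4180.0
    conductivity_anchors: [[17.0, 0.531], [28.0, 0.622], [47.0, 50.0]]
  che: {density: 1035.0, heat_capacity: 4180.0, conductivity: 0.531}

neonate:
  citation: Neonate morphometrics (7 cm CCL hatchling) and simulated mean thrust.
  surface_area: 0.014   # m^2
  volume: 5.80e-5       # m^3
  mass: 0.06            # kg
  average_thrust: 4.88e-3  # N
  stroke: neonate

juvenile_6bpm:
  citation: Juvenile (72 cm CCL) swimming-simulation outputs at 6 beats/minute.
  surface_area: 0.89
  volume: 0.036
  mass: 36.9
  bpm: 6
  average_thrust: 0.060
  flipper_htc: 464.0
  body_htc: 260.0
  power: 0.043
  stroke: juvenile

juvenile_19bpm:
  citation: Juvenile (72 cm CCL) swimming-simulation outputs at 19 beats/minute.
  surface_area: 0.89
  volume: 0.036
  mass: 36.9
  bpm: 19
  average_thrust: 0.832
  flipper_htc: 775.0
  body_htc: 303.0
  power: 0.371
  stroke: juvenile

juvenile_25bpm:
  citation: Juvenile (72 cm CCL) swimming-simulation outputs at 25 beats/minute.
  surface_area: 0.89
  volume: 0.036
  mass: 36.9
  bpm: 25
  average_thrust: 1.540
  flipper_htc: 952.0
  body_htc: 305.0
  power: 0.904
  stroke: juvenile

juvenile_29bpm:
  citation: Juvenile (72 cm CCL) swimming-simulation outputs at 29 beats/minute.
  surface_area: 0.89
  volume: 0.036
  mass: 36.9
  bpm: 29
  average_thrust: 2.070
  flipper_htc: 1019.0
  body_htc: 311.0
  power: 1.418
  stroke: juvenile
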