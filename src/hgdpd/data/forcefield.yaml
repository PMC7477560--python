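# Default force field and unit constants for the three-bead-type model of
# homogalacturonan in water: (H2O)4 water beads (coarse-graining ratio 4:1),
# GalA (protonated galacturonic acid unit) and GalA(-) (deprotonated unit).
# All interaction parameters are given in DPD reduced units (lengths in r_C,
# energies in k_BT, masses in water-bead masses).

base_units:
  # cut-off radius r_C in Angstrom, from r_C = (rho*V/N)^(1/3) of the
  # reference water system (rho=3, V=29894 A^3, N=240 beads)
  length_angstrom: 7.2
  # mass of one (H2O)4 bead in kg
  mass_kg: 11.968e-26
  # k_B * 298 K in Joule
  energy_joule: 4.115e-21
  temperature_kelvin: 298.0
  # time unit tau in ps fixed a posteriori by velocity matching; shipped as
  # the calibrated reference value, recomputable via hgdpd.calibration
  time_ps_velocity_matched: 12.47

bead_masses:          # reduced, water bead = 1
  "(H2O)4": 1.0
  "GalA": 2.623
  "GalA(-)": 2.609

# Conservative repulsion a_ij in k_BT/r_C (symmetric)
repulsion:
  - {pair: ["(H2O)4", "(H2O)4"], a: 50.0}
  - {pair: ["GalA(-)", "(H2O)4"], a: 75.0}
  - {pair: ["GalA(-)", "GalA(-)"], a: 100.0}
  - {pair: ["GalA", "(H2O)4"], a: 67.0}
  - {pair: ["GalA", "GalA(-)"], a: 65.0}
  - {pair: ["GalA", "GalA"], a: 58.5}

# Harmonic distance bonds: k_S in k_BT/r_C^2, l0 in r_C
bonds:
  - {types: ["GalA(-)", "GalA(-)"], k_s: 2700.0, l0: 0.63}
  - {types: ["GalA(-)", "GalA"], k_s: 2920.0, l0: 0.63}
  - {types: ["GalA", "GalA"], k_s: 3375.0, l0: 0.62}

# Harmonic angle bonds: k_A in k_BT/rad^2, theta0 in rad (middle type second;
# lookups are symmetric under sequence reversal)
angles:
  - {types: ["GalA(-)", "GalA(-)", "GalA(-)"], k_a: 17.0, theta0: 2.81}
  - {types: ["GalA", "GalA(-)", "GalA(-)"], k_a: 25.0, theta0: 2.79}
  - {types: ["GalA(-)", "GalA", "GalA(-)"], k_a: 26.0, theta0: 2.76}
  - {types: ["GalA", "GalA", "GalA(-)"], k_a: 32.0, theta0: 2.77}
  - {types: ["GalA", "GalA(-)", "GalA"], k_a: 24.0, theta0: 2.82}
  - {types: ["GalA", "GalA", "GalA"], k_a: 29.0, theta0: 2.83}

# Calibrated thermostat for the full force field (weight exponent s = 0.5)
thermostat:
  sigma: 6.86
  gamma: 23.53
  s: 0.5

# Standard literature thermostat used as the uncalibrated starting point
thermostat_standard:
  sigma: 3.0
  gamma: 4.5
  s: 2.0
  a_water: 25.0

# Dynamical targets of the fine-grained reference (coarse-grained water
# clouds of the 967-molecule SPC box at 298 K)
reference_targets:
  v_md_angstrom_per_ps: 1.021      # average CG particle speed
  d_md_angstrom2_per_ps: 0.151     # CG self-diffusion coefficient

# Reference fine-grained water system used to derive the unit system
reference_water_system:
  n_molecules: 967
  box_angstrom: 31.036
  n_cg_beads: 240                  # rounded down, leaves 7 free molecules
  cg_ratio: 4
  density_number: 3.0
  frame_interval_ps: 2.0
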