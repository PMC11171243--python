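# Tissue dielectric, thermal and damage-kinetics constants for hepatic
# microwave ablation at 2.45 GHz, assembled from the published literature
# values behind the package's default scenarios.
#
# Sigmoid dielectric laws (liver, tumor):
#   eps_r(T) = amplitude * (1 - 1 / (1 + exp(steepness * (midpoint - T)))) + 1
#   sigma(T) = amplitude * (1 - 1 / (1 + exp(steepness * (midpoint - T))))
# with T in degC.  The tumor pairs are commonly tabulated in "offset form"
# exp(c1 - c2*T); here they are stored as steepness = c2 and
# midpoint = c1/c2 (permittivity: 5.223/0.052, conductivity: 6.583/0.059),
# which written the same way reproduces the liver row
# (0.076 * 82.271 = 6.25).  Edit freely; nothing below is hard-coded in
# solver code.
frequency_hz: 2.45e9

blood:
  density_kg_m3: 1060.0
  specific_heat_J_kgK: 3600.0
  temperature_C: 37.0
  # omega_b(T) = slope * T + intercept, T in degC, result in 1/s
  perfusion_slope_per_sC: 2.1e-5
  perfusion_intercept_per_s: 3.5e-4
  metabolic_heat_W_m3: 33800.0

antenna:
  # Coaxial slot antenna stand-in for a 2.45 GHz interstitial applicator:
  # nested radii in mm, ring slot in the outer conductor near the tip.
  inner_conductor_radius_mm: 0.135
  dielectric_radius_mm: 0.470
  outer_conductor_radius_mm: 0.595
  catheter_radius_mm: 0.895
  slot_center_from_tip_mm: 5.0
  slot_width_mm: 1.0
  tip_length_mm: 1.0

tissues:
  liver:
    density_kg_m3: 1079.0
    specific_heat_J_kgK: 3540.0
    permittivity_sigmoid: {steepness_per_C: 0.076, midpoint_C: 82.271, amplitude: 48.391}
    conductivity_sigmoid: {steepness_per_C: 0.069, midpoint_C: 85.375, amplitude_S_m: 2.173}
    thermal_conductivity_law: {slope_W_mKC: 1.265e-3, intercept_W_mK: 0.4882}
    perfused: true
    arrhenius: {frequency_factor_per_s: 7.39e39, activation_energy_J_mol: 2.58e5}
  tumor:
    density_kg_m3: 1040.0
    specific_heat_J_kgK: 3960.0
    permittivity_sigmoid: {steepness_per_C: 0.052, midpoint_C: 100.44230769230769, amplitude: 54.8}
    conductivity_sigmoid: {steepness_per_C: 0.059, midpoint_C: 111.57627118644068, amplitude_S_m: 2.0}
    thermal_conductivity_law: {slope_W_mKC: 1.265e-3, intercept_W_mK: 0.4882}
    perfused: true
    arrhenius: {frequency_factor_per_s: 3.25e4, activation_energy_J_mol: 2.81e5}
  vessel:
    electrical_conductivity_S_m: 2.54
    relative_permittivity: 58.3
    thermal_conductivity_W_mK: 0.5
    specific_heat_J_kgK: 3600.0
    density_kg_m3: 1060.0
    perfused: false
    # static blood-vessel compartment; damage kinetics as for liver
    arrhenius: {frequency_factor_per_s: 7.39e39, activation_energy_J_mol: 2.58e5}
  background:
    # liver exterior modeled as generic soft tissue with liver properties
    density_kg_m3: 1079.0
    specific_heat_J_kgK: 3540.0
    permittivity_sigmoid: {steepness_per_C: 0.076, midpoint_C: 82.271, amplitude: 48.391}
    conductivity_sigmoid: {steepness_per_C: 0.069, midpoint_C: 85.375, amplitude_S_m: 2.173}
    thermal_conductivity_law: {slope_W_mKC: 1.265e-3, intercept_W_mK: 0.4882}
    perfused: true
    arrhenius: {frequency_factor_per_s: 7.39e39, activation_energy_J_mol: 2.58e5}
  antenna_inner_conductor:
    is_conductor: true
    thermal_conductivity_W_mK: 18.0
    specific_heat_J_kgK: 500.0
    density_kg_m3: 7900.0
  antenna_outer_conductor:
    is_conductor: true
    thermal_conductivity_W_mK: 18.0
    specific_heat_J_kgK: 500.0
    density_kg_m3: 7900.0
  antenna_dielectric:
    electrical_conductivity_S_m: 0.0
    relative_permittivity: 2.03
    thermal_conductivity_W_mK: 0.25
    specific_heat_J_kgK: 1050.0
    density_kg_m3: 2200.0
    perfused: false
  antenna_slot:
    electrical_conductivity_S_m: 0.0
    relative_permittivity: 2.03
    thermal_conductivity_W_mK: 0.25
    specific_heat_J_kgK: 1050.0
    density_kg_m3: 2200.0
    perfused: false
  catheter:
    electrical_conductivity_S_m: 0.0
    relative_permittivity: 2.60
    thermal_conductivity_W_mK: 0.25
    specific_heat_J_kgK: 1050.0
    density_kg_m3: 2200.0
    perfused: false

profiles:
  # Printed tumor damage kinetics give vanishing necrosis rates at any
  # physiological temperature; this profile restores a reachable tumor
  # endpoint (likely typographic exponent in the tabulated frequency factor).
  tumor_kinetics_adjusted:
    tissues:
      tumor:
        arrhenius: {frequency_factor_per_s: 3.25e43, activation_energy_J_mol: 2.81e5}
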