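# Default material table for the implantation-site / device system.
# Units: stresses and moduli in MPa, densities in kg/m^3, thicknesses in mm.
# The frame-alloy (mp35n) yield stress and density could not be fixed from the
# source table unambiguously; the values below are documented literature
# defaults and are plain configuration — override them freely.
artery:
  model: linear_elastic
  young_modulus: 7.78
  poisson_ratio: 0.45
  density: 1250.0
  thickness: 1.9
leaflet:
  model: linear_elastic
  young_modulus: 6.375
  poisson_ratio: 0.45
  density: 1250.0
  thickness: 0.5
calcium:
  model: elastoplastic
  young_modulus: 250.0
  poisson_ratio: 0.3
  yield_stress: 0.25
  density: 2000.0
mp35n:
  model: elastoplastic
  young_modulus: 232800.0
  poisson_ratio: 0.34
  yield_stress: 414.0
  density: 8000.0
pet:
  model: linear_elastic
  young_modulus: 600.0
  poisson_ratio: 0.4
  density: 1380.0
  thickness: 0.06
nitinol:
  model: superelastic
  austenite_modulus: 45000.0
  martensite_modulus: 32000.0
  transformation_start_stress_loading: 440.0
  transformation_finish_stress_loading: 540.0
  transformation_start_stress_unloading: 250.0
  transformation_finish_stress_unloading: 140.0
  transformation_strain: 0.045
  poisson_ratio: 0.33
  density: 6450.0
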