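# Calibrated synthetic site configuration for the Montana study site
# (47.52 N, -113.67 E, 1230 m). The monthly normals below are NOT measured
# climatology: they are synthetic calibration constants chosen so that the
# current-scenario hourly simulation reproduces the published site maxima
# (June air maximum 20.9 degC; sun-leaf maximum 25.7 degC). Scenario deltas
# are back-derived from published scenario maxima (23.8-20.9, 24.6-20.9).
# Replace normals with real station climatology for any other use.
site:
  latitude: 47.522
  longitude: -113.668
  elevation: 1230.0
  reference_height: 1.2
  normals:
    5: {t_min: 3.0, t_max: 16.5, wind_mean: 2.2, rh_mean: 62.0, cloud_fraction: 0.45}
    6: {t_min: 6.5, t_max: 20.95, wind_mean: 0.6, rh_mean: 60.0, cloud_fraction: 0.08}
    7: {t_min: 8.0, t_max: 20.4, wind_mean: 1.9, rh_mean: 55.0, cloud_fraction: 0.30}
scenarios:
  - {name: current, delta: 0.0}
  - {name: ssp2-4.5, delta: 2.9}
  - {name: ssp5-8.5, delta: 3.7}
leaf:
  shortwave_absorptance: 0.5
  emissivity: 0.97
  characteristic_dimension: 0.05
  stomatal_conductance: 0.2
  exposure: sun
analysis:
  levene_center: median
  link: logit
seed: 0
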