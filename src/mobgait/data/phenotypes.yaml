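# Disease-phenotype presets for the synthetic generator.
#
# Values are the cohort medians (and interquartile ranges) reported for the
# three groups: supervised 2x10m gait-test parameters (iga), daily-life
# walking-bout gait metrics by bout-duration class (daily), daily physical
# activity volumes (macro), 95th-percentile all-bout performance (p95) and
# clinical motor scores (clinical).  cv = inter-stride coefficient of
# variation; asymmetry_pct = median left/right asymmetry index in percent.
version: 1
groups:
  MSA:
    iga:
      gait_velocity: {center: 0.90, iqr: 0.27, cv: 0.09, asymmetry_pct: 3.91}
      stride_length: {center: 0.99, iqr: 0.31, cv: 0.07, asymmetry_pct: 3.91}
      stride_time: {center: 1.15, iqr: 0.15, cv: 0.05, asymmetry_pct: 1.64}
      stance_percentage: {center: 63.77, iqr: 2.41, cv: 0.04, asymmetry_pct: 3.43}
      max_sensor_lift: {center: 0.05, iqr: 0.03, cv: 0.17, asymmetry_pct: 19.76}
    daily:
      short: {gait_velocity: 0.43, stride_length: 0.60, cadence: 93.78, wb_per_day: 108.5}
      medium: {gait_velocity: 0.50, stride_length: 0.69, cadence: 93.22, wb_per_day: 12.0}
      long: {gait_velocity: 0.77, stride_length: 0.91, cadence: 98.23, wb_per_day: 3.5,
             max_wb_per_day: 9.0, duration_s: 92.19}
    macro:
      step_count: {center: 6471, iqr: 3221}
      active_sedentary_ratio: {center: 0.13, iqr: 0.06}
      mvpa_min: {center: 24.88, iqr: 20.67}
      entropy: {center: 0.21, iqr: 0.08}
    p95:
      gait_velocity: 0.88
      stride_length: 1.00
    clinical:
      mds_updrs_iii: {center: 39.0, iqr: 19.0}
      pigd: {center: 6.0, iqr: 3.37}
      bbs: {center: 47.0, iqr: 10.0}
      ipaq_walking: {center: 495.0, iqr: 1225.1}
  PSP:
    iga:
      gait_velocity: {center: 0.91, iqr: 0.23, cv: 0.11, asymmetry_pct: 3.85}
      stride_length: {center: 1.10, iqr: 0.22, cv: 0.07, asymmetry_pct: 3.30}
      stride_time: {center: 1.28, iqr: 0.22, cv: 0.07, asymmetry_pct: 2.15}
      stance_percentage: {center: 65.42, iqr: 2.89, cv: 0.04, asymmetry_pct: 2.92}
      max_sensor_lift: {center: 0.06, iqr: 0.02, cv: 0.14, asymmetry_pct: 15.37}
    daily:
      short: {gait_velocity: 0.42, stride_length: 0.67, cadence: 89.02, wb_per_day: 92.5}
      medium: {gait_velocity: 0.54, stride_length: 0.72, cadence: 86.96, wb_per_day: 11.25}
      long: {gait_velocity: 0.93, stride_length: 1.05, cadence: 98.79, wb_per_day: 6.0,
             max_wb_per_day: 13.0, duration_s: 99.92}
    macro:
      step_count: {center: 6189, iqr: 3762}
      active_sedentary_ratio: {center: 0.13, iqr: 0.11}
      mvpa_min: {center: 21.85, iqr: 42.86}
      entropy: {center: 0.21, iqr: 0.10}
    p95:
      gait_velocity: 1.07
      stride_length: 1.15
    clinical:
      mds_updrs_iii: {center: 40.5, iqr: 22.0}
      pigd: {center: 6.7, iqr: 4.72}
      bbs: {center: 46.0, iqr: 11.0}
      ipaq_walking: {center: 313.5, iqr: 878.6}
  PD:
    iga:
      gait_velocity: {center: 1.24, iqr: 0.27, cv: 0.08, asymmetry_pct: 2.91}
      stride_length: {center: 1.31, iqr: 0.25, cv: 0.05, asymmetry_pct: 2.55}
      stride_time: {center: 1.08, iqr: 0.08, cv: 0.04, asymmetry_pct: 1.63}
      stance_percentage: {center: 63.72, iqr: 2.07, cv: 0.02, asymmetry_pct: 2.15}
      max_sensor_lift: {center: 0.07, iqr: 0.02, cv: 0.13, asymmetry_pct: 13.17}
    daily:
      short: {gait_velocity: 0.53, stride_length: 0.71, cadence: 95.65, wb_per_day: 137.0}
      medium: {gait_velocity: 0.64, stride_length: 0.82, cadence: 91.96, wb_per_day: 14.5}
      long: {gait_velocity: 1.01, stride_length: 1.17, cadence: 104.62, wb_per_day: 7.0,
             max_wb_per_day: 14.0, duration_s: 110.25}
    macro:
      step_count: {center: 9614, iqr: 3835}
      active_sedentary_ratio: {center: 0.21, iqr: 0.12}
      mvpa_min: {center: 42.92, iqr: 40.80}
      entropy: {center: 0.27, iqr: 0.10}
    p95:
      gait_velocity: 1.25
      stride_length: 1.32
    clinical:
      mds_updrs_iii: {center: 18.0, iqr: 14.0}
      pigd: {center: 2.2, iqr: 2.56}
      bbs: {center: 55.0, iqr: 3.0}
      ipaq_walking: {center: 1386.0, iqr: 1889.2}
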