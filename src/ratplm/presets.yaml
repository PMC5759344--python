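# Cohort presets for the synthetic rat-PSG generator (version 1).
#
# The generator is index-parameterized: motor rates are the target indices
# (events per hour of the relevant state), stage percentages and mean bout
# durations (minutes) parameterize the alternating-renewal hypnogram chain.
# 24-h presets (C, ID, IR1-IR4) carry the group means of 24-h recordings;
# 8-h presets (ID+baseline, ID+saline, ID+pmx*) describe the ZT2-ZT10
# post-injection window, whose printed stage totals (minutes/8 h) are
# converted to percentages here. `sd` fields are the printed between-animal
# SDs, used for hematocrit sampling and as documentation of cohort spread.
#
# Bout means for the 8-h presets are a generator choice (no bout durations
# are printed for the post-injection recordings); they are set so the
# renewal topology (Wake->SWS; SWS->REM with prob q else Wake; REM->SWS
# with prob r else Wake) can reproduce the printed stage balance.

defaults: &defaults
  epoch_s: 10.0
  qw_fraction: 0.4
  p_bilateral: 0.5
  imi_mean: 25.0
  imi_sd: 10.0
  imi_min: 5.0
  imi_max: 89.0
  train_length_mean: 7.0
  amp_factor_range: [3.5, 5.0]
  duration_range: [0.3, 0.8]
  tone: {AW: 0.85, QW: 0.85, SWS: 0.6, REM: 0.5}
  rate_cv: 0.10
  bout_cv: 0.05
  duration_h: 24.0
  zt_start: 0.0

presets:
  C:
    <<: *defaults
    group: C
    hct_mean: 47.1
    hct_sd: 0.1
    stage_percent: {Wake: 49.5, SWS: 44.5, REM: 6.0}
    bout_min: {Wake: 1.95, SWS: 1.67, REM: 1.10}
    plms_rate: 7.8
    plms_sd: 2.6
    plmw_prob_nonzero: 0.0
    plmw_nonzero_mean: 0.0
    plmw_nonzero_sd: 0.0
    ilms_rate: 18.8
    ilms_sd: 5.5
  ID:
    <<: *defaults
    group: ID
    hct_mean: 25.2
    hct_sd: 1.5
    # the running text reports 20.6 +/- 3.2 for the same animals; the group
    # table value above is the default, the text value is kept here:
    hct_alt: [20.6, 3.2]
    stage_percent: {Wake: 49.7, SWS: 45.6, REM: 4.7}
    bout_min: {Wake: 1.41, SWS: 1.28, REM: 1.21}
    plms_rate: 49.8
    plms_sd: 16.9
    plmw_prob_nonzero: 0.714      # 5 of 7 animals show PLM in wake
    plmw_nonzero_mean: 19.6       # cohort mean 14 /h QW including zeros
    plmw_nonzero_sd: 8.0
    ilms_rate: 16.9
    ilms_sd: 2.2
  IR1:
    <<: *defaults
    group: IR1
    hct_mean: 38.7
    hct_sd: 1.1
    stage_percent: {Wake: 47.7, SWS: 46.1, REM: 6.2}
    bout_min: {Wake: 1.97, SWS: 1.79, REM: 1.27}
    plms_rate: 18.5
    plms_sd: 6.9
    plmw_prob_nonzero: 0.714
    plmw_nonzero_mean: 8.1
    plmw_nonzero_sd: 4.0
    ilms_rate: 18.6
    ilms_sd: 3.9
  IR2:
    <<: *defaults
    group: IR2
    hct_mean: 41.0
    hct_sd: 0.6
    stage_percent: {Wake: 46.3, SWS: 47.3, REM: 6.4}
    bout_min: {Wake: 1.95, SWS: 1.87, REM: 1.31}
    plms_rate: 9.3
    plms_sd: 6.4
    plmw_prob_nonzero: 0.714
    plmw_nonzero_mean: 3.8
    plmw_nonzero_sd: 2.0
    ilms_rate: 17.6
    ilms_sd: 7.7
  IR3:
    <<: *defaults
    group: IR3
    hct_mean: 44.8
    hct_sd: 0.3
    stage_percent: {Wake: 46.0, SWS: 47.9, REM: 6.1}
    bout_min: {Wake: 2.02, SWS: 1.98, REM: 1.22}
    plms_rate: 6.8
    plms_sd: 4.0
    plmw_prob_nonzero: 0.714
    plmw_nonzero_mean: 2.0
    plmw_nonzero_sd: 1.0
    ilms_rate: 18.5
    ilms_sd: 5.3
  IR4:
    <<: *defaults
    group: IR4
    hct_mean: 47.2
    hct_sd: 0.1
    stage_percent: {Wake: 46.2, SWS: 47.9, REM: 5.9}
    bout_min: {Wake: 1.98, SWS: 1.96, REM: 1.23}
    plms_rate: 4.6
    plms_sd: 4.6
    plmw_prob_nonzero: 0.714
    plmw_nonzero_mean: 1.4
    plmw_nonzero_sd: 0.8
    ilms_rate: 18.0
    ilms_sd: 6.2

  # ---- 8-h post-injection presets (recording starts at ZT2) ----
  ID+baseline:
    <<: *defaults
    group: ID
    duration_h: 8.0
    zt_start: 2.0
    hct_mean: 25.2
    hct_sd: 1.5
    stage_percent: {Wake: 36.82, SWS: 57.22, REM: 5.96}   # 176.7/274.6/28.6 min
    bout_min: {Wake: 1.7, SWS: 2.3, REM: 1.0}
    plms_rate: 55.5
    plms_sd: 18.8
    plmw_prob_nonzero: 0.8
    plmw_nonzero_mean: 16.0
    plmw_nonzero_sd: 8.0
    ilms_rate: 14.3
    ilms_sd: 3.5
  ID+saline:
    <<: *defaults
    group: ID
    dose_mg_per_kg: 0.0
    duration_h: 8.0
    zt_start: 2.0
    hct_mean: 25.2
    hct_sd: 1.5
    stage_percent: {Wake: 34.92, SWS: 58.23, REM: 6.85}   # 167.6/279.5/32.9 min
    bout_min: {Wake: 1.7, SWS: 2.3, REM: 1.0}
    plms_rate: 50.2
    plms_sd: 15.8
    plmw_prob_nonzero: 0.8
    plmw_nonzero_mean: 24.1
    plmw_nonzero_sd: 10.0
    ilms_rate: 14.9
    ilms_sd: 3.5
  ID+pmx0.01:
    <<: *defaults
    group: ID
    dose_mg_per_kg: 0.01
    duration_h: 8.0
    zt_start: 2.0
    hct_mean: 25.2
    hct_sd: 1.5
    stage_percent: {Wake: 34.77, SWS: 59.23, REM: 6.00}   # 166.9/284.3/28.8 min
    bout_min: {Wake: 1.7, SWS: 2.3, REM: 1.0}
    plms_rate: 25.6
    plms_sd: 5.6
    plmw_prob_nonzero: 0.8
    plmw_nonzero_mean: 17.5
    plmw_nonzero_sd: 8.0
    ilms_rate: 20.2
    ilms_sd: 2.7
  ID+pmx0.02:
    <<: *defaults
    group: ID
    dose_mg_per_kg: 0.02
    duration_h: 8.0
    zt_start: 2.0
    hct_mean: 25.2
    hct_sd: 1.5
    stage_percent: {Wake: 40.48, SWS: 53.96, REM: 5.56}   # 194.3/259/26.7 min
    bout_min: {Wake: 1.7, SWS: 2.1, REM: 1.0}
    plms_rate: 18.2
    plms_sd: 4.1
    plmw_prob_nonzero: 0.8
    plmw_nonzero_mean: 4.6
    plmw_nonzero_sd: 2.0
    ilms_rate: 19.0
    ilms_sd: 3.6
  ID+pmx0.05:
    <<: *defaults
    group: ID
    dose_mg_per_kg: 0.05
    duration_h: 8.0
    zt_start: 2.0
    hct_mean: 25.2
    hct_sd: 1.5
    stage_percent: {Wake: 41.85, SWS: 51.92, REM: 6.23}   # 200.9/249.2/29.9 min
    bout_min: {Wake: 1.7, SWS: 2.0, REM: 1.0}
    plms_rate: 14.3
    plms_sd: 4.2
    plmw_prob_nonzero: 0.8
    plmw_nonzero_mean: 2.3
    plmw_nonzero_sd: 1.0
    ilms_rate: 22.1
    ilms_sd: 6.1
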