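# Default 15-analyte antimicrobial panel for milk.
# Concentrations in ug/kg (ppb) on the undiluted-sample scale; calibration
# ranges already account for the 1:1 wash-buffer dilution (factor 2).
# Dapsone (DAP) is a prohibited substance: no MRL; its screening target is
# set to its spike level. Thirteen sulphonamides count jointly toward a
# 100 ug/kg group MRL; trimethoprim has its own 50 ug/kg MRL.
analytes:
  - {name: SDZ,  full_name: Sulphadiazine,           mrl: 100, spike_level: 20, calib_min: 0, calib_max: 40,  lod: 0.5}
  - {name: SDIM, full_name: Sulphadimethoxine,       mrl: 100, spike_level: 20, calib_min: 0, calib_max: 40,  lod: 0.6}
  - {name: SQX,  full_name: Sulphaquinoxaline,       mrl: 100, spike_level: 20, calib_min: 0, calib_max: 40,  lod: 0.5}
  - {name: SMTZ, full_name: Sulphamethazine,         mrl: 100, spike_level: 20, calib_min: 0, calib_max: 40,  lod: 2.5}
  - {name: SMXZ, full_name: Sulphamethoxazole,       mrl: 100, spike_level: 12, calib_min: 0, calib_max: 25,  lod: 0.5}
  - {name: STZ,  full_name: Sulphathiazole,          mrl: 100, spike_level: 20, calib_min: 0, calib_max: 40,  lod: 0.5}
  - {name: SSX,  full_name: Sulphisoxazole,          mrl: 100, spike_level: 20, calib_min: 0, calib_max: 40,  lod: 0.5}
  - {name: SPD,  full_name: Sulphapyridine,          mrl: 100, spike_level: 20, calib_min: 0, calib_max: 40,  lod: 0.5}
  - {name: SMZ,  full_name: Sulphamerazine,          mrl: 100, spike_level: 20, calib_min: 0, calib_max: 40,  lod: 0.5}
  - {name: SMMX, full_name: Sulphamonomethoxine,     mrl: 100, spike_level: 50, calib_min: 0, calib_max: 240, lod: 2}
  - {name: SMPD, full_name: Sulphamethoxypyridazine, mrl: 100, spike_level: 20, calib_min: 0, calib_max: 40,  lod: 2}
  - {name: SCPD, full_name: Sulphachlorpyridazine,   mrl: 100, spike_level: 20, calib_min: 0, calib_max: 40,  lod: 0.5}
  - {name: DAP,  full_name: Dapsone,                 prohibited: true, screening_target: 20, spike_level: 20, calib_min: 0, calib_max: 40, lod: 0.5}
  - {name: SDX,  full_name: Sulphadoxine,            mrl: 100, spike_level: 20, calib_min: 0, calib_max: 40,  lod: 0.5}
  - {name: TMPM, full_name: Trimethoprim,            mrl: 50,  spike_level: 10, calib_min: 0, calib_max: 20,  lod: 0.5}
validation:
  n_blank: 20
  n_spiked: 20
  t_factor: 1.6
  fm_factor: 1.64
  max_false_compliant: 1
  beta: 0.05
  dilution_factor: 2
sulphonamide_members: [SDZ, SDIM, SQX, SMTZ, SMXZ, STZ, SSX, SPD, SMZ, SMMX, SMPD, SCPD, SDX]
sulphonamide_sum_mrl: 100
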