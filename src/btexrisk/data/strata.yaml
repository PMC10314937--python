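# Per-workstation, per-season breathing-zone concentration summaries
# (mg/m3) for the four BTEX analytes in an oil-refinery campaign:
# observed range [low, high], arithmetic mean, sample SD.
# These profiles parameterize the synthetic campaign generator.
schema_version: 1
strata:
  - {workstation: supervisor, season: summer, analyte: benzene,      low: 0.032, high: 2.556,  mean: 0.359,  sd: 0.626}
  - {workstation: supervisor, season: winter, analyte: benzene,      low: 0.032, high: 0.831,  mean: 0.267,  sd: 0.228}
  - {workstation: supervisor, season: summer, analyte: toluene,      low: 0.038, high: 3.806,  mean: 1.129,  sd: 1.508}
  - {workstation: supervisor, season: winter, analyte: toluene,      low: 0.038, high: 3.429,  mean: 1.078,  sd: 1.294}
  - {workstation: supervisor, season: summer, analyte: ethylbenzene, low: 0.004, high: 3.951,  mean: 1.032,  sd: 1.342}
  - {workstation: supervisor, season: winter, analyte: ethylbenzene, low: 0.043, high: 4.168,  mean: 1.002,  sd: 1.441}
  - {workstation: supervisor, season: summer, analyte: xylene,       low: 0.043, high: 3.391,  mean: 0.755,  sd: 1.042}
  - {workstation: supervisor, season: winter, analyte: xylene,       low: 0.004, high: 3.083,  mean: 0.533,  sd: 0.986}
  - {workstation: safetyman,  season: summer, analyte: benzene,      low: 0.003, high: 2.140,  mean: 0.522,  sd: 0.660}
  - {workstation: safetyman,  season: winter, analyte: benzene,      low: 0.032, high: 1.636,  mean: 0.384,  sd: 0.485}
  - {workstation: safetyman,  season: summer, analyte: toluene,      low: 0.038, high: 4.937,  mean: 1.160,  sd: 1.705}
  - {workstation: safetyman,  season: winter, analyte: toluene,      low: 0.038, high: 4.145,  mean: 0.782,  sd: 1.380}
  - {workstation: safetyman,  season: summer, analyte: ethylbenzene, low: 0.043, high: 4.776,  mean: 1.333,  sd: 1.639}
  - {workstation: safetyman,  season: winter, analyte: ethylbenzene, low: 0.004, high: 3.517,  mean: 0.734,  sd: 1.285}
  - {workstation: safetyman,  season: summer, analyte: xylene,       low: 0.043, high: 4.264,  mean: 0.975,  sd: 1.379}
  - {workstation: safetyman,  season: winter, analyte: xylene,       low: 0.004, high: 2.649,  mean: 0.735,  sd: 1.078}
  - {workstation: repairman,  season: summer, analyte: benzene,      low: 0.073, high: 19.775, mean: 7.193,  sd: 7.166}
  - {workstation: repairman,  season: winter, analyte: benzene,      low: 0.351, high: 7.539,  mean: 2.023,  sd: 1.944}
  - {workstation: repairman,  season: summer, analyte: toluene,      low: 0.136, high: 79.139, mean: 27.200, sd: 29.304}
  - {workstation: repairman,  season: winter, analyte: toluene,      low: 0.038, high: 41.454, mean: 10.070, sd: 12.467}
  - {workstation: repairman,  season: summer, analyte: ethylbenzene, low: 0.043, high: 95.522, mean: 18.326, sd: 26.886}
  - {workstation: repairman,  season: winter, analyte: ethylbenzene, low: 0.043, high: 44.722, mean: 10.027, sd: 14.537}
  - {workstation: repairman,  season: summer, analyte: xylene,       low: 0.043, high: 44.722, mean: 14.833, sd: 15.257}
  - {workstation: repairman,  season: winter, analyte: xylene,       low: 0.004, high: 43.853, mean: 10.615, sd: 13.323}
  - {workstation: siteman,    season: summer, analyte: benzene,      low: 0.064, high: 20.190, mean: 4.311,  sd: 5.622}
  - {workstation: siteman,    season: winter, analyte: benzene,      low: 0.511, high: 10.031, mean: 3.369,  sd: 2.540}
  - {workstation: siteman,    season: summer, analyte: toluene,      low: 2.540, high: 64.856, mean: 26.791, sd: 22.749}
  - {workstation: siteman,    season: winter, analyte: toluene,      low: 0.113, high: 37.685, mean: 13.685, sd: 11.958}
  - {workstation: siteman,    season: summer, analyte: ethylbenzene, low: 0.043, high: 52.668, mean: 15.822, sd: 15.783}
  - {workstation: siteman,    season: winter, analyte: ethylbenzene, low: 0.043, high: 52.103, mean: 12.135, sd: 14.422}
  - {workstation: siteman,    season: summer, analyte: xylene,       low: 0.043, high: 66.041, mean: 14.242, sd: 19.846}
  - {workstation: siteman,    season: winter, analyte: xylene,       low: 0.043, high: 40.467, mean: 13.325, sd: 13.172}
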