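# Toxicological and physical constants for the BTEX aromatics.
# RfC: inhalation reference concentration (mg/m3), IRIS.
# SF: cancer slope factor ((mg/kg-day)^-1), IRIS; absent where IRIS lists none.
# TLV: ACGIH threshold limit value, 8 h/day 5 d/week schedule, in ppm.
# Molecular weights in g/mol; xylene is the mixed-isomer technical value.
schema_version: 1
analytes:
  benzene:
    molecular_weight: 78.11
    rfc: 0.03
    sf: 0.029
    tlv_ppm: 0.5
  toluene:
    molecular_weight: 92.14
    rfc: 5.00
    sf: null
    tlv_ppm: 20.0
  ethylbenzene:
    molecular_weight: 106.17
    rfc: 1.00
    sf: 0.0087
    tlv_ppm: 20.0
  xylene:
    molecular_weight: 106.16
    rfc: 0.10
    sf: null
    tlv_ppm: 100.0
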