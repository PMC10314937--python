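"""Deterministic USEPA risk for a single exposure scenario.

Evaluates the hazard quotient (HQ = EC/RfC) and lifetime cancer risk
(LCR = CDI x SF) for a repairman exposed to benzene at the summer stratum
mean, with mid-range questionnaire factors.
"""

from btexrisk import ExposureFactors, assess, load_analytes

analytes = load_analytes()
factors = ExposureFactors(c=7.193, et=10, ed=30, ef=252, bw=83)

for name in ("benzene", "toluene"):
    res = assess(analytes[name], factors)
    lcr = f"{res.lcr:.3e} ({res.lcr_category})" if res.lcr is not None else "n/a (no slope factor)"
    print(f"{name:12s} EC={res.ec:.4f} mg/m3  CDI={res.cdi:.5f} mg/kg-day  "
          f"HQ={res.hq:.2f} ({res.hq_category})  LCR={lcr}")
# EC discounts the airborne concentration by the fraction of time exposed;
# HQ >= 1 flags potential non-carcinogenic effects, and an LCR above 1e-4
# is conventionally read as definite carcinogenic risk.  Toluene has no
# published slope factor, so its LCR is reported absent rather than zero.
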