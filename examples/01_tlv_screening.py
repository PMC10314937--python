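"""Screen measured shift exposures against schedule-adjusted occupational
limits.

Builds a repairman's summer shift from three personal samples, computes the
duration-weighted TWA, adjusts the benzene TLV for a 12 h/day schedule with
the Brief & Scala model, and reports the exceedance decision.
"""

from btexrisk import (
    ShiftSample,
    adjusted_tlv,
    brief_scala_factor,
    compute_twa,
    load_analytes,
    tlv_exceedance,
)

analytes = load_analytes()
benzene = analytes["benzene"]

shift = [
    ShiftSample(concentration=8.1, duration_min=95),
    ShiftSample(concentration=6.4, duration_min=110),
    ShiftSample(concentration=7.0, duration_min=85),
]
twa = compute_twa(shift)

rf = brief_scala_factor(hours_per_day=12, days_per_week=6)
limit = adjusted_tlv(benzene, rf)

print(f"shift TWA:          {twa:.3f} mg/m3")
print(f"Brief & Scala RF:   {rf:.3f}  (12 h/day, 6 d/week)")
print(f"adjusted TLV:       {limit:.3f} mg/m3  (standard: {adjusted_tlv(benzene):.2f})")
print(f"exceedance:         {tlv_exceedance(twa, limit)}")
# The TWA is the duration-weighted mean over the shift; the reduction
# factor shrinks the 8 h/5 d limit to account for the longer daily dose and
# shorter recovery, so the exceedance call is against the adjusted limit.
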