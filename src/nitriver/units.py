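"""Centralized unit conversion constants.

Internal convention: mass in kgN, length in m, area in m2, volume in m3,
time in years (365-day calendar, no leap days). Reporting units follow the
field's convention: global/regional fluxes in TgN yr-1, concentrations in
mgN L-1, temperature in degrees Celsius.
"""

DAYS_PER_YEAR = 365.0
SECONDS_PER_YEAR = 365.0 * 86400.0

KG_PER_TG = 1.0e9
TG_PER_KG = 1.0e-9

#: kgN m-3 -> mgN L-1  (1 kg/m3 = 1e6 mg / 1e3 L)
KG_M3_TO_MG_L = 1000.0

#: density of water, kg m-3 (converts precipitation mass flux to volume flux)
WATER_DENSITY = 1000.0
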