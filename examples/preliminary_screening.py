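"""Screen a handful of early measurements against the OEL.

Both EN689 editions allow a quick compliance call from 1-5 samples by
comparing each result with a fraction of the OEL; anything above the OEL is
immediate non-compliance, anything in between stays undecided.
"""

from ohcompliance import OELSpec, preliminary_1995, preliminary_2018

oel = OELSpec(substance="respirable dust", oel=1.0)  # mg m⁻³

samples = [0.08, 0.12, 0.07]

d95 = preliminary_1995(samples, oel)
d18 = preliminary_2018(samples, oel)
print(f"measurements (mg m⁻³): {samples}, OEL = {oel.oel}")
print(f"EN689:1995 screen (3 samples < 0.25·OEL): {d95.outcome.value}")
print(f"EN689:2018 screen (3 samples < 0.1·OEL):  {d18.outcome.value}")
# The same three results pass the looser 1995 screen but leave the 2018
# decision open: the revised standard demands lower exposures (or more
# samples) before declaring compliance.
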