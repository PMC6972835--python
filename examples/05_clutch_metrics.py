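"""Clutch quality and female morphometrics.

Emergence success summarises the nest inventory; female body size is the
surface area of a half ellipsoid fitted to the carapace measurements.
"""

from clutchkin.clutchmetrics import (
    MorphometricRecord,
    NestInventory,
    emergence_success,
    group_comparisons,
)

inv = NestInventory(hatched=80, total=100, live_in_nest=5, dead_in_nest=5)
print(f"emergence success E = {emergence_success(inv):.2f} "
      "(hatched minus stragglers, over all eggs)")

female = MorphometricRecord("F001", ccl=98.0, ccw=90.0, scl=90.0, scw=70.0)
print(f"semi-axes a = {female.a:.1f}, b = {female.b:.1f}, c = {female.c:.1f} cm")
print(f"half-ellipsoid surface area = {female.surface_area:.0f} cm^2")

single = [5931.6, 6100.0, 5800.0, 6050.0]
multi = [5007.9, 5200.0, 4900.0, 5100.0]
rep = group_comparisons(single, multi)
print(f"surface area, single vs multiple paternity females: "
      f"t({rep.t_df}) = {rep.t_stat:.2f}, two-tailed p = {rep.t_p_two_tailed:.3g}")
# The t test compares mean body size between mating groups; the F test in
# the same report compares their variances.
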