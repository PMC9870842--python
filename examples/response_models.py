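"""The two response models: minimum jerk and mass-spring-damper.

Both describe the correction for a 3.33 mm target displacement whose response
starts 100 ms after the step, with T the time remaining until the tap.
"""

import numpy as np

import interceptsim as isim
from interceptsim.finger import MSDSpec

D = 3.33  # mm, twice the 1.67 mm step

print("minimum jerk: peak correction velocity 1.875*D/T")
for T_ms in (200, 150, 100, 50):
    grid = np.linspace(0, 1, 1001)
    peak = isim.min_jerk_velocity(D, T_ms / 1000, grid).max()
    print(f"  T = {T_ms:3d} ms: peak {peak:6.1f} mm/s")
# shorter available time forces a more vigorous correction

print("\nmass-spring-damper (b = 75 1/s, k = 3800 - 16 T):")
print(f"  underdamped below T* = {isim.critical_time_ms():.1f} ms")
for T_ms in (200, 150, 100, 50):
    t, v = isim.msd_response(MSDSpec(D, T_ms), duration=0.3)
    overshoot = "reverses (overshoot)" if v.min() < -1e-6 else "monotone settle"
    print(f"  T = {T_ms:3d} ms: peak {v.max():6.1f} mm/s at {t[v.argmax()] * 1000:3.0f} ms, "
          f"{overshoot}")
# the stiffening spring reproduces both the growing vigour and the
# overcorrection of steps ~150-200 ms before the tap
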