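"""Summarize an MST titration: dFnorm transform and saturation fit.

Emulates a 16-step 1:1 dilution of target cells from 2e7 cells/mL measured
in triplicate, converts normalized fluorescence (Fnorm, per-mille) to
baseline-subtracted dFnorm, and fits dF = A*c/(m+c). The midpoint m is a
response midpoint, not a dissociation constant - whole-cell titrations do
not yield a Kd.
"""

import numpy as np

from selexpipe import Titration, delta_fnorm, fit_saturation, serial_dilution

rng = np.random.default_rng(5)
conc = serial_dilution(2e7, steps=16)  # cells/mL, descending 1:1 series

# synthetic binder: 20 per-mille amplitude on a Fnorm baseline near 850
amplitude_true, midpoint_true = 20.0, 1.5e6
response = amplitude_true * conc / (midpoint_true + conc)
fnorm = 850.0 + np.column_stack(
    [response + rng.normal(0, 0.4, size=conc.size) for _ in range(3)]
)

titration = Titration(conc, fnorm)
dfn = delta_fnorm(titration)
print("dFnorm (per-mille) vs cell concentration:")
for c, d in zip(titration.concentrations[::3], dfn[::3]):
    print(f"  {c:12.3g} cells/mL  ->  {d:6.2f}")

curve = fit_saturation(titration)
print(f"\nfitted amplitude: {curve.amplitude:.2f} per-mille "
      f"(simulated: {amplitude_true})")
print(f"response midpoint: {curve.midpoint:.3g} cells/mL "
      f"(simulated: {midpoint_true:.3g})")
print(f"signal-to-noise: {curve.signal_to_noise:.1f}  flag: {curve.flag}")
print("\nA non-binding control stays flat and is flagged:")
flat = Titration(conc, np.full((16, 3), 850.0))
print(f"  flag = {fit_saturation(flat).flag}")
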