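"""Patch-clamp feature extraction on one synthetic cell: a current-clamp
step family (Delta = 10 pA, 500 ms) and a voltage-clamp family
(-100..+80 mV, Delta = 10 mV).

Run:  python examples/patch_clamp_features.py
"""

from neurodish import synth
from neurodish.patch import extract_ap_features, iv_analysis

# Current clamp: planted rheobase 60 pA, threshold -40 mV, peak +30 mV.
cc, cc_truth = synth.gen_cc_sweeps(rheobase=60.0, capacitance=20.0, seed=3)
feats = extract_ap_features(cc, at_current=100.0)
print("--- current clamp ---")
print(f"rheobase               : {feats.rheobase:.0f} pA (planted 60)")
print(f"AP amplitude           : {feats.ap_amplitude:.1f} mV (planted 70)")
print(f"AP width (FWHM)        : {feats.ap_width:.2f} ms")
print(f"mean firing freq @100pA: {feats.mean_ff:.2f} Hz")
print(f"inst. firing freq      : {feats.inst_ff:.2f} Hz")

# Voltage clamp: default density profiles peak at -305.6 pA/pF (-30 mV).
vc, vc_truth = synth.gen_vc_sweeps(capacitance=20.0, seed=4)
iv = iv_analysis(vc)
print("--- voltage clamp ---")
print(f"J_in(-30 mV) : {iv.density_at(-30.0):.1f} pA/pF "
      f"(planted {vc_truth.planted_peak_inward_pa[-30.0] / 20.0:.1f})")
print(f"J_out(+80 mV): {iv.density_at(80.0, 'outward'):.1f} pA/pF "
      f"(planted {vc_truth.planted_steady_outward_pa[80.0] / 20.0:.1f})")
print("Current densities J = I/C normalize macroscopic currents for cell "
      "size; the fast inward component is the Na+ current that drives AP "
      "firing.")
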