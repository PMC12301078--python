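"""Phase-based vs amplitude-based binning equivalence.

Reconstructs the same motion — a 15 mm sinusoid and a synthetic 3D
patient-like breathing trace — with both retrospective binning modes and
reports the worst plug-dimension delta against the stationary scan for
each.  Both modes should hold the surrogate dimensions within 1 mm.
Runtime: a couple of minutes (four full simulations).
"""

from fourdqa.studies import binning_equivalence

res = binning_equivalence(seed=1)
for trace_name, by_mode in res.items():
    print(f"{trace_name}:")
    for mode, delta in by_mode.items():
        print(f"  {mode:10s} max |dimension delta| = {delta:.3f} mm")
print("\nValues within 1 mm mean either binning mode reconstructs the "
      "moving surrogates at their stationary size.")
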