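"""Plug dimensioning against manufacturer-nominal sizes.

Renders both phantom models stationary and noise-free, measures the
motion-surrogate plugs by the half-maximum profile method, and compares to
the nominal dimensions (12.3 mm diameter; 25.0 mm length; 33.0 mm for the
model-604 Air plug).  Sub-nominal readings of a couple of tenths of a mm
are expected physics: Gaussian blur pulls the half-maximum contour of a
convex object slightly inward.
"""

from fourdqa.studies import nominal_dimension_study

for model in (504, 604):
    print(f"model {model}:")
    for plug_id, (measured, nominal) in nominal_dimension_study(model).items():
        m = ", ".join(f"{v:5.2f}" for v in measured)
        n = ", ".join(f"{v:5.2f}" for v in nominal)
        print(f"  {plug_id:8s} measured ({m}) mm   nominal ({n}) mm")
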