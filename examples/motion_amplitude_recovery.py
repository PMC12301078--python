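"""Motion-amplitude recovery from per-bin plug centroids.

A noiseless 10-bin phase-binned sinusoid whose bins are anchored at the
trace extremes: the extent (max - min) of the surrogate-plug centroids
across bins should equal the 15 mm platform input to sub-voxel accuracy.
The same measurement with default blur and noise stays within 1 mm.
"""

from fourdqa.synth import BinningSpec
from fourdqa.studies import sinusoid_study

ideal = sinusoid_study(noiseless=True, binning=BinningSpec(intra_bin_samples=1),
                       include_hu=False, include_projections=False)
noisy = sinusoid_study(seed=1, include_hu=False, include_projections=False)

print("input peak-to-peak amplitude: 15.0 mm (along Z)")
for label, study in (("noiseless, bins at extremes", ideal),
                     ("default blur + noise", noisy)):
    print(f"{label}:")
    for plug, extent in study.amplitude_extents().items():
        print(f"  {plug:8s} measured extent {extent:6.2f} mm "
              f"(delta {extent - 15.0:+.2f} mm)")
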