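"""Targeted depth profiling and layer segmentation.

Builds a synthetic sputter-depth scan series in which a marker ion
(the phospholipid head group PO3-, m/z 78.959) jumps from a low to a
high level at a buried layer boundary, then tracks the marker per scan
and places the boundary where the smoothed profile crosses half its
maximum — the same logic used to assign tissue layers from marker
abundance.
"""

from orbitag import TargetIon, segment_layers, targeted_profile
from orbitag.experiments import two_layer_scans
from orbitag.profiling import PO3_MZ

scans, true_boundary = two_layer_scans(boundary=8, n_scans=20, seed=3)
profile = targeted_profile(scans, [TargetIon("PO3", PO3_MZ)], normalize="max")
values = profile.profile("PO3")

print("scan :", " ".join(f"{i:>4}" for i in range(len(scans))))
print("PO3  :", " ".join(f"{v:>4.2f}" for v in values))

boundaries = segment_layers(values, threshold_fraction=0.5)
print(f"\ntrue boundary before scan {true_boundary}; detected: {boundaries}")
print("within one scan of truth:",
      any(abs(b - true_boundary) <= 1 for b in boundaries))
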