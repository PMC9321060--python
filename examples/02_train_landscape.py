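"""Train the metagene SOM and segment the over-expression spot modules.

Runs the full landscape chain on the default synthetic cohort: per-gene
centering, batch-SOM training (20x20 grid), group-mean portraits per
stratum, the pixel-wise-maximum summary map and spot segmentation. The
recovered spots are then matched to the planted modules by gene-set Jaccard.
"""

from lymphoscape import run_synthetic_landscape
from lymphoscape.pipeline import recovery_jaccard

result = run_synthetic_landscape(seed=1)

print("recovered spots (letters ranked by summary-map peak):")
print(result.spots.table().to_string(float_format=lambda v: f"{v:.3f}"))

jac = recovery_jaccard(result)
print("\nplanted module -> best recovered spot (gene-set Jaccard):")
for letter, j in jac.items():
    print(f"  module {letter} -> spot {result.spot_of_module[letter]}  Jaccard {j:.2f}")
print(f"\nmodules recovered at Jaccard >= 0.5: {(jac >= 0.5).sum()}/10")
print("-> a Jaccard near 1 means the spot's gene set is essentially the")
print("   planted module; B/C stay partially merged because their planted")
print("   activation patterns are nearly collinear, and E sits at the")
print("   resolution limit of a 20x20 grid (129 genes ~ 2-3 pixels).")
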