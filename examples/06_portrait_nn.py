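"""Classify whole metagene portraits with a small neural network.

The "face recognition" stage: instead of thresholding individual spot
scores, a fully connected network reads the entire portrait. Compared here
against the best single-spot GSZ threshold classifier on the same
five-class task (BL, GCB, ABC, DHL, FL).
"""

import numpy as np

from lymphoscape import gsz, run_synthetic_landscape
from lymphoscape.nn import predict, train_portrait_classifier

CLASSES = ("BL", "DLBCL-GCB", "DLBCL-ABC", "DHL", "FL")

result = run_synthetic_landscape(seed=1)
keep = [p for p in result.sample_portraits if result.labels[p.sample_id] in CLASSES]
labels = {p.sample_id: result.labels[p.sample_id] for p in keep}

clf = train_portrait_classifier(keep, labels, seed=1)
print(f"portrait network: validation accuracy {clf.validation_accuracy:.3f} "
      f"({len(keep)} samples, {len(CLASSES)} classes)")

# baseline: assign each sample the class whose hallmark spot scores highest
hallmark = {"BL": "B", "DLBCL-GCB": "K", "DLBCL-ABC": "H", "DHL": "A", "FL": "I"}
scores = {c: gsz(result.centered, result.module_spot_genes(m), name=m).series()
          for c, m in hallmark.items()}
correct = 0
for p in keep:
    best = max(scores, key=lambda c: scores[c][p.sample_id])
    correct += best == labels[p.sample_id]
print(f"best single-spot GSZ argmax baseline: accuracy {correct / len(keep):.3f}")
print("-> the network reads combinatorial portrait structure beyond single")
print("   spots; its margin over the one-spot rule quantifies that extra")
print("   information (spot ambiguity, e.g. A up in BL, DHL, GCB and FL).")
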