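"""Build a STAPLE consensus mask from a rater panel with one outlier.

Five raters segment the same block; one adds a spurious disjoint blob.
The EM estimate recovers the majority mask and reports each rater's
sensitivity/specificity, exposing the outlier's reduced specificity.
"""

import numpy as np

from ctvmargins import BinaryVolume, staple_consensus

block = np.zeros((12, 10, 8), dtype=bool)
block[2:6, 3:7, 2:6] = True
majority = BinaryVolume(block, (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))

outlier_occ = block.copy()
outlier_occ[8:11, 3:6, 2:5] = True  # extra disjoint blob
raters = [majority] * 4 + [majority.with_occupancy(outlier_occ)]

result = staple_consensus(raters, threshold=0.5)

print(f"converged: {result.converged} after {result.n_iterations} iterations")
print("consensus equals majority mask:",
      bool(np.array_equal(result.consensus_mask.occupancy, majority.occupancy)))
for j, (p, q) in enumerate(zip(result.sensitivities, result.specificities)):
    print(f"rater {j}: sensitivity {p:.5f}, specificity {q:.5f}")
# sensitivity = P(rater marks foreground | consensus foreground); the
# outlier (rater 4) keeps sensitivity 1 but loses specificity for the blob.
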