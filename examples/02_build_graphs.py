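"""Build the two static channel graphs and sweep their sparsity thresholds.

The spatial-distance graph depends only on electrode geometry; the
functional-connectivity graph is computed per EEG segment from Pearson
correlation. Both are sparsified by a threshold, whose effect on edge
count this script tabulates.
"""

import numpy as np

from seizuregraph import (
    SyntheticSpec,
    build_correlation_adjacency,
    build_distance_adjacency,
    canonical_layout,
    generate_recording,
    threshold_sweep,
)

layout = canonical_layout()
a1 = build_distance_adjacency(layout, r1=0.4)
print(f"distance graph at R1=0.4: {a1.edge_count()} edges, "
      f"mean weight {a1.mean_weight():.3f}")

rec = generate_recording(
    SyntheticSpec(duration_s=30.0, seizure_intervals=[(5.0, 20.0)], seed=3)
)
seg = rec.signal[:, : int(3 * rec.fs)]  # one 3-s window
a2 = build_correlation_adjacency(seg, r2=0.25)
print(f"connectivity graph at R2=0.25: {a2.edge_count()} edges, "
      f"mean weight {a2.mean_weight():.3f}")

print("\ndistance-threshold sweep (edge count grows with R1):")
grid = [round(0.2 + 0.1 * i, 1) for i in range(6)]
print(threshold_sweep("distance", grid, layout=layout).to_string(index=False))

print("\nconnectivity-threshold sweep (edge count shrinks with R2):")
grid = [round(0.1 + 0.1 * i, 1) for i in range(5)]
print(threshold_sweep("connectivity", grid, segment=seg).to_string(index=False))
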