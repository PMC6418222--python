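"""Contribution of each pipeline phase on the synthetic suite.

Runs the full pipeline on five seeded images, reads back the label image
after each phase (phases form a prefix chain, so one run yields all
four), and prints mean centroid precision/recall/F1 per prefix.
"""

import numpy as np

from nucleisplit import (
    PHASES,
    SegmentationParams,
    SyntheticSpec,
    centroids_from_labels,
    generate,
    match_centroids,
    run_pipeline,
)

scores = {ph: [] for ph in PHASES}
for seed in range(5):
    image, truth, cents = generate(SyntheticSpec(seed=seed))
    res = run_pipeline(image, SegmentationParams(omega_min=50),
                       return_intermediates=True)
    for ph in PHASES:
        rep = match_centroids(centroids_from_labels(res[ph]), cents)
        scores[ph].append((rep.p, rep.r, rep.f1))

names = {"I": "I (local threshold)", "II": "I-II (+splitting)",
         "III": "I-III (+merging)", "IV": "I-IV (+correction)"}
for ph in PHASES:
    p, r, f1 = np.mean(scores[ph], axis=0)
    print(f"{names[ph]:24s} precision={p:.3f} recall={r:.3f} f1={f1:.3f}")
print("splitting (phase II) lifts recall by separating clumped nuclei that "
      "phase I leaves as single connected objects.")
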