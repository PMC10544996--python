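"""The accuracy/coverage trade-off along the RMSD threshold.

Lowering the clustering threshold makes clusters purer (accuracy, the
fraction of epitope-consistent multiple-occupancy clusters) but strands
more antibodies in singletons (coverage, the fraction of antibodies in
multiple-occupancy clusters). Sweeping the threshold on a noisy scene
shows the plateau in between — the basis for choosing a default.

Run: python examples/05_threshold_sweep.py
"""

import numpy as np

from epibin import (
    ClusteringParams,
    SceneParams,
    adjusted_rand_index,
    compute_metrics,
    generate_scene,
    run_pipeline,
)

scene = generate_scene(SceneParams(sigma_within=0.35, seed=19))
records = scene.record_map()
n = len(scene.models)

print(f"{'threshold':>9} {'clusters':>8} {'ARI':>6} {'accuracy':>8} {'coverage':>8}")
for threshold in np.arange(0.25, 3.01, 0.25):
    assignment = run_pipeline(scene.models, scene.scheme,
                              ClusteringParams(rmsd_threshold=float(threshold)))
    ari = adjusted_rand_index(assignment.assignments, scene.truth)
    report = compute_metrics(assignment.assignments, records)
    accuracy = report.fraction_consistent_clusters
    coverage = report.n_in_multi_clusters / n
    acc_str = "  --  " if accuracy is None else f"{accuracy:8.2f}"
    print(f"{threshold:9.2f} {len(assignment.clusters()):8d} "
          f"{ari:6.2f} {acc_str:>8} {coverage:8.2f}")
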