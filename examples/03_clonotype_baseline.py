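"""Sequence clonotyping: the baseline that structural clustering improves on.

A VH clonotype requires the same IGHV gene, a length-matched CDRH3 and
CDRH3 identity strictly above 80%; pairs passing the rule are linked and
clonotypes are the transitive closure. Clonotyping can only ever group
antibodies with near-identical sequences, whereas structural clustering
can put sequence-distant antibodies in the same bin when their CDR loops
adopt the same conformation.

Run: python examples/03_clonotype_baseline.py
"""

from epibin import (
    ClonotypeParams,
    ClusteringParams,
    SceneParams,
    fv_clonotype,
    generate_scene,
    run_pipeline,
    vh_clonotype,
)

scene = generate_scene(SceneParams(seed=11))

vh = vh_clonotype(scene.records)
fv = fv_clonotype(scene.records)
structural = run_pipeline(scene.models, scene.scheme, ClusteringParams())

print(f"{len(scene.records)} antibodies")
print(f"VH clonotypes: {len(set(vh.values()))}")
print(f"Fv clonotypes: {len(set(fv.values()))} (always a refinement of VH)")
print(f"structural clusters: {len(structural.clusters())}")

# How many structural clusters span more than one clonotype?
spanning = 0
for cid, members in structural.clusters().items():
    if len(members) > 1 and len({vh[m] for m in members}) > 1:
        spanning += 1
print(f"structural clusters mixing several VH clonotypes: {spanning}")

# A stricter identity threshold can only split clonotypes, never merge them
strict = vh_clonotype(scene.records, ClonotypeParams(identity_threshold=0.9))
print(f"VH clonotypes at 90% identity: {len(set(strict.values()))}")
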