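"""Find duplicated accessions and flag synonym/homonym candidates.

Pairwise mismatch in a clonal collection is strongly bimodal: genotyping
error keeps identical material below ~0.1% while distinct varieties differ
at >10% of markers.  Clustering below 0.12% recovers clone groups; crossing
clusters with accession names exposes naming problems.
"""

import numpy as np

import grapekin as gk

sc = gk.standard_scenario(seed=1)
mm = gk.pairwise_mismatch(sc.panel)
iu = np.triu_indices(len(mm.samples), k=1)
vals = mm.percent[iu]
print(f"pairwise mismatch: min {vals.min():.3f}%  max {vals.max():.1f}%")
low, high = vals[vals < 1].max(), vals[vals >= 1].min()
print(f"bimodal gap: nothing between {low:.3f}% and {high:.1f}%")

clusters = gk.cluster_identicals(mm, threshold=0.12, panel=sc.panel)
dup = [c for c in clusters if len(c.members) > 1]
print(f"{len(clusters)} unique genotypes; {len(dup)} clusters of duplicates:")
for c in dup:
    print(f"  {c.members} (max internal mismatch {c.max_internal_mismatch:.3f}%)")

# give two clone mates different variety names, and reuse one name elsewhere
names = {s: f"Variety {s.split('_')[0]}" for s in sc.panel.samples}
names["F01_clone"] = "Crepolino"       # synonym: same genotype, new name
names["F02"] = "Crepolino"             # homonym: same name, other genotype
report = gk.name_crosstab(clusters, names)
print("synonym candidates:\n", report["synonym_candidates"].to_string(index=False))
print("homonym candidates:\n", report["homonym_candidates"].to_string(index=False))

deduped, mapping = gk.dedupe(sc.panel, clusters)
print(f"deduplicated panel: {deduped.n_samples} of {sc.panel.n_samples} kept")
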