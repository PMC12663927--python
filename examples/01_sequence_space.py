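"""Sequence-space basics: identity, clustering, and diversity coverage.

Generates a small synthetic rubisco survey, clusters the alignment at
90% identity, and asks how well the kinetically characterized panel
covers the representative diversity at each identity threshold X.
"""

from rubiscope import SimConfig, simulate_dataset
from rubiscope.seqspace import diversity_coverage, greedy_cluster, pairwise_identity

ds = simulate_dataset(SimConfig(n_leaves=80, length=200, seed=42))
aln = ds.aln

print(f"alignment: {len(aln)} sequences x {aln.length} columns")
print(f"identity(seq0, seq1) = {pairwise_identity(aln.rows[0], aln.rows[1]):.3f}")

clusters = greedy_cluster(aln, threshold=0.9)
print(f"\n90%-identity clustering: {len(clusters.clusters)} clusters")

reps = aln.subset_ids(clusters.centroid_ids)
characterized = aln.subset_ids(ds.characterized_ids)
curve = diversity_coverage(reps, characterized)
print(f"\ncoverage of {curve.n_representatives} representatives "
      f"by {curve.n_characterized} characterized variants:")
for x, c in zip(curve.thresholds, curve.coverage):
    print(f"  X = {x:.2f}  coverage = {c:.2f}")
print("\nCoverage at X is the fraction of representatives sharing >= X")
print("identity with some characterized variant; it can only fall as X rises.")
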