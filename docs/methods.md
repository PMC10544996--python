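# Methods note

## Model

An antibody Fv model is a set of Cα coordinates keyed by (chain, IMGT
position, insertion code), chains `H` and `L`. A region scheme partitions
positions into the six CDRs and framework; the default uses North CDR
boundaries expressed as IMGT intervals (CDR1 24–40, CDR2 55–66, CDR3
105–117 on both chains; framework is the complement up to position 128).
The scheme is configurable (`RegionScheme.from_dict`, `--scheme` on the
CLI), and insertion codes accommodate loops longer than their interval.

Two antibodies are structurally comparable only when all compared CDRs
have identical lengths; antibodies are therefore partitioned into
length groups before any RMSD is computed. Distances are never defined
across groups — group members are reported with a group-qualified
cluster id (`<lengths>:<ordinal>`).

### Distance

For a pair within a group: superpose the models on the intersection of
their framework Cα positions (matched by residue key; at least 20 shared
positions required) with a Kabsch least-squares fit restricted to proper
rotations (SVD with determinant sign correction), then report the pooled
RMSD over the Cα atoms of the compared CDRs:

RMSD = sqrt( (1/m) Σ_i ‖a_i − b_i‖² ),  m = total compared CDR atoms.

Pooling (rather than averaging per-CDR RMSDs) weights every CDR atom
equally; displacing a single atom by d gives exactly d/√m, which the
tests check in closed form. The default compares each pair directly
(`alignment="pairwise"`); `alignment="reference"` superposes every model
once onto the group's first member, an O(n) approximation that is exact
when all frameworks share the same residue set.

## Clustering

All four algorithms operate on a precomputed within-group distance
matrix. Threshold boundary conventions differ deliberately:

| algorithm | typical operating point | boundary | notes |
|---|---|---|---|
| agglomerative | complete linkage, 1.25 Å | merges while min linkage ≤ t | ties broken toward the lowest pair index; equivalent to cutting a scipy linkage tree at t for single/average/complete (all reducible, no inversions) |
| greedy | 0.75 Å | absorbs strictly < t | order-dependent by construction: centers are taken in input order |
| dbscan | eps 1 Å, min_samples 2 | neighbourhood ≤ eps, includes self | with min_samples = 2 provably equal to connected components of the eps-graph; noise points become singletons |
| butina | 1 Å | ≤ t | sphere exclusion; without `reorder` neighbour counts are not recomputed after removals (the classic variant), with `reorder` they are |

Defaults: agglomerative/complete at 1.25 Å, the configuration that
bounds every intra-cluster pair by the threshold ("cluster diameter"
guarantee). The greedy configuration at 0.75 Å reproduces the earlier
center-based protocol. A heavy-chain mode (CDRH1–H3 + heavy framework)
and a paratope mode (per-antibody CDR subsets supplied as flags; grouped
first by flag set, then by lengths) relax the comparison.

Caveat on threshold monotonicity: for single linkage, raising the
threshold never shrinks the set of antibodies in multiple-occupancy
clusters (a theorem about eps-graphs). For greedy clustering this is
*not* true in general — a larger threshold can grow an early cluster and
strand the remainder — although it holds on well-separated scenes.

## Clonotyping

VH clonotype rule for a pair: same IGHV gene (allele suffixes stripped,
`IGHV3-53*01` → `IGHV3-53`; allele-level matching is a switch), same
CDRH3 length, CDRH3 identity strictly greater than the threshold
(default 0.8). Identity is positional (Hamming) — no alignment, since
length-matched CDR3s are compared index-by-index. Clonotypes are the
transitive closure (connected components) of the pairwise rule: the only
order-independent extension of a pairwise predicate to sets. The Fv
level additionally requires matching light V gene and the same rule on
CDRL3, so Fv clonotypes always refine VH clonotypes. Records missing
required fields become warned singletons. Raising the identity threshold
only ever splits clonotypes.

## Evaluation

Per-cluster verdicts at two resolutions:

- **Epitope level**: consistent iff all members share the epitope-group
  label. Singletons are excluded; clusters containing an unknown label
  are "unevaluable", excluded from accuracy numerators and denominators
  and reported separately.
- **Domain level**: consistent iff all members share the antigen and
  (1) all share one domain, or (2) exactly one labeled domain appears
  alongside domain-unknown labels, or (3) no member has a domain label,
  or (4) the labeled domains form a chain under a configured subdomain
  hierarchy (e.g. NTD ⊂ non-RBD). Rule 4 with a domain unknown to the
  hierarchy warns and classifies inconsistent.

Rule 2 is formalized as "exactly one distinct labeled domain"; mixed
distinct domains fall to rule 4 or inconsistency. Rule 4 is formalized
as a chain under the partial order, the minimal generalization of the
two-element subdomain example that still rejects disjoint domains.

Seven dataset metrics: fraction of consistent multiple-occupancy
clusters; fraction of multiple-occupancy antibodies in consistent
clusters; number of multiple-occupancy clusters; antibodies therein;
antibodies in consistent multiple-occupancy clusters; fraction of
consistent clusters containing >1 clonotype; and mean CDRH3 identity in
consistent clusters. The last is computed pair-then-cluster: mean over
unordered pairs within each cluster, then an unweighted mean over
clusters; pairs with unequal CDRH3 lengths score 0 (possible in
heavy-chain/paratope modes where full six-length keys are not enforced).
Fractions with empty denominators are reported as `None`/blank.

The random baseline permutes antibody identities into the observed
cluster sizes (100 repetitions by default, seeded) and reports the mean
and standard deviation of each metric; coverage-type counts are
invariant under permutation by construction. Relaxed consistency
additionally credits clusters where at least 70% (configurable) of
members carry the modal label, reported as the *extra* fraction of
clusters and antibodies admitted. An interspecies count reports
consistent multi-occupancy clusters containing more than one species.

## Synthetic generator

Scenes are geometrically abstract: a helical scaffold provides framework
Cα positions (the same for every model), each planted cluster has its
own CDR conformation obtained by displacing the CDR atoms by a
cluster-specific offset vector, members add i.i.d. Gaussian noise
(`sigma_within`, Å) to CDR coordinates only, and each model optionally
receives a random proper rigid motion (which the superposition must
undo). Offsets are constructed so every pair of cluster templates is at
least `min_between` apart in pooled CDR RMSD — across *all* clusters,
not just those sharing a length key, so heavy-chain and paratope modes
remain separable. Because per-coordinate differences of two noisy copies
have variance 2σ², the expected pairwise pooled RMSD is ≈ √6·σ, which
the tests verify empirically.

Metadata is generated alongside: per-cluster clonal families (V/J genes,
CDRH3/CDRL3 mutated from a family template at `mutation_rate` per
position), species, and an epitope group per planted cluster; a truth
table records the planted partition. Outputs are byte-identical under a
fixed seed. Note that at mutation rate 0.05 on a 12-residue CDRH3 a
five-member family stays within the 0.8-identity clonotype rule (via
transitive closure) only with probability ≈ 0.9, not ≈ 1 — the tests
compare the generator against a direct Monte-Carlo simulation of the
mutation model rather than assuming cohesion.

### What the benchmarks do and do not show

Passing the planted-recovery tests shows the machinery is correct:
superposition is exact on rigid copies, distances match closed forms and
independent implementations, clustering matches reference oracles, and
well-separated planted structure is recovered exactly (adjusted Rand
index 1.0) across a wide threshold window. It does **not** show
biological performance: synthetic scenes have no predictor error modes,
no chemically valid geometry, and separation margins chosen for
testability. Claims about real repertoires require real model ensembles
and labels.

## Defaults at a glance

| parameter | default | unit | rationale |
|---|---|---|---|
| clustering algorithm | agglomerative, complete | — | cluster-diameter guarantee |
| RMSD threshold | 1.25 | Å | plateau of the accuracy/coverage trade-off |
| greedy threshold | 0.75 | Å | earlier center-based protocol |
| clonotype identity | 0.8 (strict >) | fraction | ">80% identity" convention |
| min shared framework | 20 | residues | guards degenerate superpositions |
| baseline repetitions | 100 | — | Monte-Carlo error ≈ sd/10 |
| relaxed agreement | 0.7 | fraction | "≥70% of members" relaxation |
| scene noise σ | 0.2 | Å | intra-cluster RMSD ≈ 0.49 Å, well under thresholds |
| scene separation | 5.0 | Å | wide recovery plateau |
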