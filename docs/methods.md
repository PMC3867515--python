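# Methods

This note documents the models and procedures implemented in
`pharmensemble`, the parameters that govern them, the design choices made
where the design was genuinely open, and what the synthetic fixtures do
and do not demonstrate.

## Activity curation

All affinity records are harmonised to an equivalent Ki in nM before
labelling.  Ki passes through unchanged; IC50 is assumed to equal 2·Ki
(the classical Cheng–Prusoff-style working assumption for competitive
binding reported at matched conditions); pKi and pIC50 are read off the
log10 molar scale, `Ki[nM] = 10^(9 − p)`, with pIC50 routed through
IC50 first.  Units nM/µM/M are normalised before conversion.

When one compound has several records, only the most-preferred
(species, measure) stratum present is kept, in the order: human Ki >
human non-Ki > rat Ki > rat non-Ki > other.  Both preferences (Ki over
derived measures, human over rat) are standard; their interaction is
not canonical, so the ordering applies species first within the measure
preference and is fixed in `config.STRATUM_ORDER`.  The surviving
records are collapsed by the median (arithmetic mean of the central two
for even counts).

Labels: Ki ≤ 100 nM → active (boundary inclusive), Ki > 1000 nM →
inactive (boundary exclusive), otherwise ambiguous.  Ambiguous
compounds are excluded from model building and test sets but written to
an exclusion report rather than silently dropped.

## Fingerprints and clustering

**M2D.**  A MOLPRINT-2D-style atom-environment fingerprint: for every
heavy atom, the multiset of (topological distance ∈ {0,1,2}, atom type)
pairs within bond radius 2 is canonicalised by sorting and hashed
(blake2b, 64 bit) into one key; the fingerprint is the key set.  Atom
type is (element, aromatic flag, heavy-atom degree) — a deliberately
small open typer; the original scheme's Sybyl types would need a
proprietary typer.  The typing is configurable.

**P3D.**  A pharmacophore-triplet fingerprint over typed feature
points: every feature triplet contributes the key (sorted type triple,
sorted distance bins), with 1 Å bins on [0, 15] Å and larger distances
clamped to the top bin.  The key is invariant under relabeling of the
three points by construction.

For a compound with a conformer ensemble the **consensus fingerprint**
(`compound_p3d`) keeps the keys present in at least half of the
conformers.  Whether triplet fingerprints should be mono- or
multi-conformer was an open choice; consensus was adopted because
conformational noise perturbs distance bins independently per
conformer, so majority voting recovers the underlying feature geometry
quadratically better than any single conformer: with 0.2 Å coordinate
noise, single-conformer fingerprints of same-scaffold compounds sit at
Soergel distance ≈ 0.5–0.9 (bin flips dominate the key sets), while
10-conformer consensus fingerprints sit at ≈ 0.07 against ≈ 1.0 between
scaffolds.

**Distance and hierarchy.**  Compounds are compared by the Soergel
distance, 1 − |A∩B|/|A∪B| (1 − Tanimoto on binary sets; 0 for two empty
sets), which is a proper metric on finite sets.  Agglomeration uses
scipy's average linkage by default (the linkage used by the original
clustering tool is unpublished; the choice is configurable).

**Kelley level.**  For each cut with k clusters the average spread is
the mean, over clusters with ≥ 2 members, of their mean pairwise
distance.  Spreads are min-max normalised onto [1, N−1] and the level
minimising `normalised_spread(k) + k` is returned, ties to the smaller
k.  If every level has the same spread (e.g. all-equal distances) there
is no informative level and 1 is returned with a warning.  The
criterion balances within-cluster tightness against cluster count; it
is reliable when clusters are compact relative to their separation,
which is why the consensus fingerprint above matters.

**Post-processing.**  Clusters below `min_size = 3` (singletons and
doubletons) are pooled into a special class.  Clusters larger than
`max_size` (default 20% of the input set) are re-clustered recursively
with the same machinery, at most 4 rounds.  The size cap exists for the
one-dominant-cluster pathology seen with 2D fingerprints on large
ligand families; for balanced inputs (e.g. the planted synthetic
worlds, where every correct cluster holds ~1/K of the input) the cap is
disabled by passing `max_size_fraction=None`, since it would otherwise
force-split correct clusters.  Post-processing never loses or
duplicates a compound.

## Diversity selection and test sets

Sphere exclusion over a distance function: pick a seed uniformly at
random from the unexcluded pool (seeded RNG), keep it, exclude
everything within the radius (default 0.5 Soergel), repeat.  Any two
kept picks are therefore > radius apart.  If a target count is not
reached before the pool empties, the selection is padded with excluded
items farthest from the current selection (max-min fill); padded items
are flagged because they may violate the separation guarantee.

Cluster representatives: a cluster of n members receives
`max(4, round(n · 0.94 / 50))` representatives chosen by sphere
exclusion within the cluster.  The rate 0.94 per 50 members is
calibrated so that a 533-member cluster yields 10 representatives, the
documented reference density.

"Most diverse n" is operationalised by growing/shrinking the exclusion
radius by bisection until the unconstrained selection size reaches n,
then capping at n.  Proportional test-set quotas use largest-remainder
rounding so quotas sum exactly to the target.  The three paired schemes
(random, most diverse, population-proportional actives; shared most
diverse decoys and assumed inactives; default 200 per role) assert role
disjointness at construction.

## Pharmacophore perception, matching, model selection

Features are perceived on 3D conformers with documented open SMARTS
patterns (acceptors, donor heavy atoms, protonatable nitrogens),
hydrophobic atoms grouped into connected components represented by
centroids, and aromatic rings represented by ring centroids.  The
definitions live in `config.FEATURE_SMARTS` and make no claim of
equivalence to any proprietary feature typer.

**Matching contract.**  A hypothesis (4–7 typed features, reference
coordinates, derived distance matrix) matches a conformer iff some
type-consistent injective assignment of hypothesis features to
conformer feature points superposes with RMSD ≤ 2 Å (Kabsch, rotation
only, no reflection).  The search visits scarce feature types first and
prunes any partial assignment whose pairwise distance deviates from the
hypothesis geometry by more than 2× the tolerance; the best surviving
RMSD is reported.  A compound matches if any conformer matches.
Matching is invariant under rigid motion of the conformer and monotone
in the tolerance.  This global-RMSD semantic is simpler than per-site
tolerance spheres; note that with k features the total squared-error
budget k·tol² can concentrate on one feature when the rest align well —
the span constraint below and the ≥ 50% mapping requirement are what
keep that slack from being exploited by spurious candidates.

**Hypothesis generation.**  Candidates are feature k-tuples (k = 7 down
to 4) drawn from each representative's conformers, capped at 5000 per
representative with seeded uniform subsampling.  Tuples whose features
span more than `HYP_MAX_SPAN = 15 Å` are discarded: a pharmacophore
describes one binding-site arrangement, and features farther apart than
a binding site's extent cannot participate in the same hypothesis.
Candidates must map at least half of the input compounds; this is
computed over the representatives (the model-building input) by
default, with `match_rate_min` and the representative-vs-full-cluster
choice exposed.  Selectivity is scored as 1 − (fraction of a background
set matched) — a monotone open surrogate for proprietary selectivity
scores, flagged as such in serialised output.  Selection is
lexicographic: more features, then higher match rate, then higher
selectivity, then smallest id.  Clusters whose candidates all fail the
mapping requirement yield no hypothesis; that is an expected outcome,
not an error.

## Ensemble optimisation and benchmarks

The hit matrix (compounds × hypotheses, boolean) is the optimizer's
sole input besides labels.  Hit-once predicts active at ≥ 1 matching
model, hit-twice at ≥ 2; hit-twice actives are a subset of hit-once
actives by construction.  MCC / accuracy / recall are computed per
test-set half (actives vs decoys, actives vs assumed inactives) and
averaged; MCC is defined as 0 when a denominator factor vanishes (the
usual convention; real screens do not hit this case).

`best_combination` enumerates all k-subsets (guarded by a 5·10⁶-subset
budget, the scale of the published workload) and returns the maximiser;
ties break to the lexicographically smallest sorted id tuple, which the
enumeration order guarantees with strict improvement.  A greedy forward
selection is available beyond the budget and is labelled
non-exhaustive.  The optimisation curve reports the best combination at
every length and the global argmax (smallest k on ties).  Under
hit-once the recall curve is non-decreasing in k (supersets never lose
hits).

The random benchmark draws 10 uniform k-subsets (seeded), reports their
mean and sample SD, and the percent gain
`100 · (optimized − mean) / mean`.  The universal-hypothesis benchmark
picks one representative per cluster (fingerprint medoid with
smallest-id ties, or a seeded random pick), pools the picks as one
pseudo-cluster and runs the standard generation/selection on it; with
structurally diverse clusters this often yields no surviving hypothesis
or a weak one, which is the point of the baseline.  Hypotheses from
different clustering methods are never mixed in one combination.
Reported tables round to 3 decimals.

## Synthetic worlds (synthpharm)

A planted world contains K template pharmacophores (default 5–6
features each, sampled in a 12 Å box with ≥ 2.5 Å feature separation),
per-template actives, and verified inactives:

* **Templates** are relaxed so inter-feature distances sit at 1 Å bin
  centres (and below the 15 Å clamp).  Without this, distances near bin
  edges flip bins under jitter and the planted cluster structure
  becomes invisible to the binned triplet fingerprint at the default
  noise level.  Five-plus-feature templates are used because a 4-point
  template yields only four triplet keys — too coarse a fingerprint to
  cluster on.
* **Actives** are 10-conformer ensembles; each conformer jitters the
  template's points with per-coordinate Gaussian noise (σ = 0.2 Å
  default).  Every active also carries one spurious hydrophobic
  decoration at a compound-specific position 20–60 Å from the core
  (random direction and radius, jittered per conformer like the core).
  The decoration emulates peripheral structure unrelated to binding:
  it adds only clamped top-bin fingerprint keys (shared within a
  scaffold, so the consensus fingerprint is unaffected) and gives the
  hypothesis search a decoy point that is self-consistent within a
  compound but not between compounds — candidates that include it
  cannot reach the 50% mapping bar, and the span constraint excludes
  it from candidate tuples outright.
* **Inactives** are random feature clouds or geometry-distorted
  template copies (distances scaled ×1.6–2.2, same types).
* **Verification**: generation only returns a world in which every
  active matches its own template and no other (the hit matrix against
  the planted templates is exactly block-structured) and no inactive
  matches any template, checked with the real match operation; failed
  configurations are resampled from a derived sub-seed.

Pseudo-Ki values for the emitted activity table are log-uniform within
each label's range (actives 1–100 nM, inactives > 1000 nM), so the
curation module reproduces the planted labels exactly.

**What passing tests show.**  The planted-recovery results (Kelley
level = K, recall ≥ 0.95, one-to-one template recovery across seeds)
demonstrate that the pipeline's machinery — consensus fingerprints,
Kelley level selection, sphere-exclusion representatives, candidate
enumeration and lexicographic selection, exhaustive combination search
— is internally consistent and recovers planted structure under
realistic noise.  They do not demonstrate performance on real ligand
data: feature-point clouds have no conformational coupling, no
activity cliffs, no assay noise, and their cluster structure is planted
rather than emergent, so absolute statistics on real screens will be
lower and depend on data and conformer quality.

## Problem sizes and numerical choices

The default test and acceptance workloads use worlds of 3–5 templates,
10 actives per template and 30 inactives, chosen to exercise every code
path at interactive runtimes.  Tolerances: match RMSD 2 Å; bin width
1 Å; fingerprint cap 15 Å; candidate span cap 15 Å; enumeration budget
5·10⁶ subsets; all in `config.py`.  Ties break deterministically
everywhere (smallest k, smallest id, lexicographic subsets).  Degenerate
inputs are defined rather than undefined: empty fingerprints have
Soergel distance 0 to each other, MCC is 0 on a vanishing denominator,
sub-3-point feature sets give an empty triplet fingerprint with a
warning, and an all-equal distance matrix yields one cluster with a
warning.

## Known limitations

* Feature perception uses fixed SMARTS; tautomers, pH states and metal
  coordination are out of scope.
* The global-RMSD match has no per-feature tolerance or excluded
  volumes; partial matches score nothing.
* Exhaustive search is factorial in pool size; beyond the budget only
  the labelled greedy fallback is offered.
* The Kelley criterion's min-max normalisation has no absolute scale:
  on data with near-duplicate items the spread floor is ~0 and the
  criterion can over- or under-split loose clusterings.  Consensus
  fingerprints mitigate this for conformer-ensemble inputs.
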