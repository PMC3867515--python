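# pharmensemble

Ensemble pharmacophore virtual screening: instead of filtering a compound
library with a single pharmacophore hypothesis, build one hypothesis per
ligand *cluster* and search exhaustively for the **linear combination of
hypotheses** that maximises a screening statistic when the models are used
jointly as a classifier.

A pharmacophore hypothesis is a spatial arrangement of typed interaction
features — hydrogen-bond acceptor (**A**), donor (**D**), hydrophobic
group (**H**), positively charged group (**P**), aromatic ring (**R**) —
stored as reference coordinates with an inter-feature distance matrix (Å).
A compound matches a hypothesis when some type-consistent assignment of
hypothesis features to the compound's perceived conformer features
superposes (Kabsch least squares) with RMSD ≤ 2 Å.  A combination of
hypotheses flags a compound as active under the **hit-once** rule (≥ 1
model matches) or the stricter **hit-twice** rule (≥ 2 models match).
Screening quality is summarised per test-set pair and averaged:

```
MCC      = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN))
Accuracy = (TP+TN) / (TP+FP+TN+FN)
Recall   = TP / (TP+FN)
```

The pipeline, end to end:

1. **curation** — harmonise activity records (Ki, IC50, pKi, pIC50; IC50
   taken as 2·Ki) to Ki in nM, aggregate duplicates (human Ki preferred,
   median), and label compounds: Ki ≤ 100 nM active, Ki > 1000 nM
   inactive, in between ambiguous (excluded).
2. **clustering** — MOLPRINT-2D-style atom-environment fingerprints (2D)
   or pharmacophore-triplet fingerprints over conformer features (3D,
   consensus over the conformer ensemble), Soergel distance, average-
   linkage hierarchy, cut level chosen by the Kelley penalty, tiny
   clusters pooled into a special class, oversized clusters re-split.
3. **selection** — sphere-exclusion diversity picking for per-cluster
   representatives (proportional to cluster size) and for the three
   paired test-set schemes (random / most diverse / cluster-population-
   proportional actives, each against the most diverse true decoys and
   assumed inactives).
4. **pharmacophore** — perceive A/D/H/P/R features on conformers (SMARTS
   + ring/hydrophobe centroids), enumerate feature k-tuples (k = 4..7)
   from cluster representatives, keep candidates mapping ≥ 50% of the
   representatives, and select per cluster the candidate with the most
   features, then the highest match rate, then the best selectivity.
5. **ensemble** — screen compounds × hypotheses into a hit matrix,
   exhaustively enumerate k-subsets to maximise MCC / accuracy / recall,
   trace the optimisation curve over k, and benchmark against random
   equal-size combinations and a single "universal" hypothesis built
   from one representative per cluster.
6. **synthpharm** — a synthetic-world generator that plants template
   pharmacophores with jittered actives and verified non-matching
   inactives, so the whole pipeline is testable without any database.

## Worked example

```python
from pharmensemble import generate_world, planted_recovery

world = generate_world(n_templates=3, actives_per_template=10,
                       n_inactives=30, noise_sigma=0.2, seed=7)
res = planted_recovery(world, seed=7)
```

prints, when the fields are reported:

```
templates planted:    3
clusters found:       3
hypotheses built:     3
  cluster0/act-t0-000/c0/n6/0: PPRHPR (match rate 1.00, selectivity 1.00)
  cluster1/act-t1-000/c0/n5/0: RPAAH (match rate 1.00, selectivity 1.00)
  cluster2/act-t2-000/c0/n5/0: HDRRA (match rate 1.00, selectivity 1.00)
best 3-combination:   recall=1.000, mcc=1.000
templates recovered:  3/3
```

The three planted templates were recovered as three clusters (the Kelley
level equals the planted count), each cluster yielded a hypothesis whose
feature types and geometry match its template, and the recall-optimal
3-model combination under hit-once classifies every active and no
inactive correctly (recall 1.0, MCC 1.0 averaged over the decoy and
assumed-inactive halves).

The same steps are available as a CLI for file-based pipelines:

```bash
pharmensemble synth --templates 3 --actives 30 --inactives 60 --seed 7 --out world/
pharmensemble curate --activities world/activities.csv --out curated/
pharmensemble cluster --method p3d --in curated/curated.csv \
    --features world/features.json --out clustered/
pharmensemble select-reps ... ; pharmensemble build-hypotheses ...
pharmensemble screen ... ; pharmensemble optimize --metric mcc --mode hit-once
```

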