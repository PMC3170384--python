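# taxonsignal

Phylogenetic signal in DNA-barcode datamatrices, measured through
taxonomic congruence under graded taxon sampling.

Short mitochondrial barcodes (~650 bp of COI) offer few characters per
taxon but unmatched taxon coverage — hundreds of species per family.
`taxonsignal` is for systematists and molecular ecologists who want to
quantify how much higher-level phylogenetic signal such a matrix
carries, and whether adding more species helps or hurts. It provides a
tested, fully offline pipeline: simulate (or ingest) a family-structured
alignment, subsample it at increasing species-per-family levels, infer
maximum-parsimony cladograms with a ratchet search, and score how well
the recognized families hold together on the result.

## The statistic

Each family is a *concordance group* whose membership is coded as a
binary character and scored on the cladogram by Fitch parsimony. For
group *t* with *n<sub>t</sub>* members on an *N*-leaf tree:

* *m<sub>t</sub>* = 1 — minimum steps (monophyly, a single origin);
* *s<sub>t</sub>* — observed Fitch steps = number of clades the family
  forms on the (unrooted) tree;
* *g<sub>t</sub>* = min(*n<sub>t</sub>*, *N − n<sub>t</sub>*) — steps on
  the completely unresolved star tree.

With ensemble sums *M* = Σ*m<sub>t</sub>*, *S* = Σ*s<sub>t</sub>*,
*G* = Σ*g<sub>t</sub>*:

> **TCI** = *M*/*S*  (taxon consistency index)
> **TRI** = (*G* − *S*)/(*G* − *M*)  (taxon retention index)

Both reach their best value 1 exactly when every family is
monophyletic; TRI scales for matrix size, so it is the more informative
measure as species are added. These are the ensemble CI and RI of the
membership datamatrix. The package also computes molecular CI/RI and
uncorrected p-distance summaries (pairwise deletion), mirroring the rest
of the standard protocol. See `docs/methods.md` for the full model
description and numerical choices.

## Worked example

Simulate four families with a 30% chance that each species is regrafted
into a foreign family (imperfect signal), then run the taxon-sampling
experiment at 8 and 16 species/family, two replicate draws each:

```python
import taxonsignal as ts

table = ts.run_experiment(
    sim=ts.SimConfig(n_families=4, spp_per_family=16, seq_length=650,
                     scramble_p=0.3, seed=1),
    scheme=ts.SamplingScheme(levels=(8, 16), replicates=2, master_seed=2),
    search=ts.SearchConfig(n_starts=1, ratchet_iters=1, seed=0))
summary, digest = ts.report(table)
print(digest)
```

prints

```
Taxon-sampling experiment digest
================================

level    8: TCI=0.21 TRI=0.47 CI=0.78 RI=0.89 clades/group=4.7 p_within=0.040 p_overall=0.052
level   16: TCI=0.12 TRI=0.51 CI=0.73 RI=0.92 clades/group=8.3 p_within=0.039 p_overall=0.052

mean TRI contribution share by group:
  Fam01: 0.286
  Fam04: 0.260
  Fam03: 0.246
  Fam02: 0.208
```

Reading the digest: doubling the species per family raises the mean
number of clades each family splinters into (4.7 → 8.3), which drags the
TCI down (0.21 → 0.12) — more species do not buy family monophyly. The
TRI, which accounts for matrix size, holds steady or rises slightly
(0.47 → 0.51): species from a family keep clustering *locally*, i.e.
there is substantial signal below the family branch. The contribution
shares show how much of the retained grouping each family supplies.

The same stages are scriptable from a shell (`taxonsignal simulate`,
`sample`, `search`, `score`, `distances`, `experiment`); run
`taxonsignal --help`.

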