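# grapekin

SNP-based kinship and parentage reconstruction for clonal germplasm
collections.

Collections of clonally propagated crops — grapevine being the canonical
case — accumulate centuries of undocumented crosses, vegetative copies and
naming confusion. Given a few thousand biallelic SNP genotypes per
accession, `grapekin` answers the questions a curator or geneticist asks of
such a panel:

- **Which accessions are the same plant?** Pairwise genotype mismatch is
  strongly bimodal (identical material differs only by genotyping error);
  clustering below a 0.12% mismatch threshold recovers clone groups, and
  crossing clusters with accession names flags synonym candidates (one
  genotype, several names) and homonym candidates (one name, several
  genotypes).
- **Who is related to whom, and how?** For every pair, identity-by-state
  counts are inverted into IBD-state probabilities (k0, k1, k2) by the
  PLINK-style method of moments, with kinship φ = k1/4 + k2/2.
  Parent–offspring pairs satisfy k1 ≈ 1 (called at k0 < 0.03 and confirmed
  by the absence of opposite-homozygote Mendelian errors); full sibs are
  called conservatively at k2 > 0.3; trios are confirmed when the offspring
  genotype is Mendelian-consistent with both parents at essentially every
  marker (true and false trios differ by two orders of magnitude in error
  count).
- **What about parents that were never genotyped?** Given a confirmed duo,
  markers where the parent is homozygous and the offspring heterozygous
  carry an *obligate allele* contributed by the missing parent. Candidates
  carrying that allele far above the Hardy–Weinberg carrier background
  (z ≥ 4 and excess ≥ 0.15) are second-degree relatives of the offspring
  through the missing lineage — half sibs, grandparents, avuncular. A
  Mendelian variant of the same idea tests whole grandparent pairs, and the
  asymmetry of the scan between the two orientations of a duo helps orient
  parent → offspring edges.

Every stage is validated against a gene-dropping pedigree simulator with a
ground-truth oracle (clones, selfings, trios, half-sib clusters through
hidden parents, genotyping error and missingness), so recovery can be scored
exactly.

## Worked example

`examples/` holds one short script per capability. Discovering relatives
through a non-genotyped parent (`python examples/04_missing_parents.py`):

```
candidate    truth   n_inf  f_obs  f_exp       z  accepted
HSA4         HS       1112  0.790  0.558   15.59  True
HSA2         HS       1111  0.779  0.558   14.81  True
HSA3         HS       1103  0.778  0.558   14.70  True
AVU          AV       1114  0.776  0.559   14.58  True
F01_clone    GP       1108  0.772  0.559   14.29  True
F02          GP       1111  0.766  0.559   13.88  True
F24          UNREL    1105  0.564  0.558    0.37  False
F29          UNREL    1107  0.563  0.558    0.32  False

grandparent pair (F01, F02): 0 incompatibilities over 1104 informative markers
100 random candidate pairs:  min rate 0.121, mean 0.265
```

Read: over ~1,100 informative markers of the focal duo, every true relative
of the offspring through its missing mother carries the obligate allele at
~0.77–0.79 versus a 0.56 background (z ≈ 14–16), while unrelated candidates
sit exactly at background. The missing mother's true parents jointly explain
*every* obligate allele; random pairs leave ≥ 12% unexplained.

The whole workflow also runs as a shell pipeline with file artifacts per
stage:

```bash
grapekin all --out-dir runs/demo --seed 1
# unique genotypes: 70; PO duos: 35; trios: 13
```

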