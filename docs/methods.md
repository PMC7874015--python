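# Methods

## Data model

Genotypes are diploid biallelic SNP dosages: the count of B-allele copies
(0, 1, 2) per individual and marker, with an explicit missing sentinel
(never 0, which is a valid homozygote). Panels carry marker metadata
(chromosome, 1-based position, allele labels); merging datasets genotyped on
a shared array matches markers by identifier and reconciles allele
orientation by the (A, B) labels, flipping dosages d → 2−d where the labels
are swapped and dropping markers whose labels neither match nor swap.

## Quality control

Markers are dropped at missingness > 1% or MAF < 5%; individuals at
missingness > 5% (general QC) or, before parentage analysis, missingness
> 1% with heterozygosity outside [25%, 45%] — grossly aberrant
heterozygosity indicates sample quality problems, inter-specific material or
strong inbreeding, all of which distort pairwise statistics. For IBD
estimation, markers are LD-pruned at r² > 0.8 (composite, i.e. squared
Pearson correlation of dosage columns over pairwise-complete individuals —
the right LD measure for unphased array data) in 50-marker windows advancing
by 5, dropping the later marker of an offending pair; windows never span
chromosomes and the greedy rule is deterministic. Window and step are
conventional values and configurable; on the simulator's unlinked markers
pruning is a no-op, which is itself a useful negative control.

## Duplicate detection

Pairwise mismatch is the percentage of pairwise-complete markers with
unequal dosage; pairs sharing fewer than 500 comparable markers are flagged
unreliable. Accessions with mismatch < 0.12% are grouped by single-linkage
clustering — at a threshold this far below the distribution's empty middle
the linkage choice is immaterial, and single linkage is order-independent.
Each cluster keeps its least-missing member as representative (ties broken
by input order). Synonym/homonym candidates come from crossing clusters
with names; the final curation labels are human decisions and are emitted
as blank columns.

## Relatedness

For a pair, the observed IBS-state counts (N0, N1, N2) over
pairwise-complete polymorphic markers are inverted into IBD-state
probabilities using the Hardy–Weinberg conditional expectations
(p = B-allele frequency, q = 1−p):

    P(IBS0|IBD0) = 2p²q²        P(IBS1|IBD1) = 2pq
    P(IBS1|IBD0) = 4p³q + 4pq³  P(IBS2|IBD1) = 1 − 2pq
    P(IBS2|IBD0) = p⁴ + q⁴ + 4p²q²

solved sequentially: k0 = N0/E[0|0], k1 = (N1 − k0·E[1|0])/E[1|1],
k2 = (N2 − k0·E[2|0] − k1·E[2|1])/n. Kinship is φ = k1/4 + k2/2. Monomorphic
markers are excluded from both counts and expectations; the all-pairs path
computes per-pair expectation sums honouring each pair's missingness
pattern. Allele frequencies are taken from the deduplicated panel (clones
would bias p); the small-sample bias correction some implementations offer
is omitted — frequencies come from the full panel, where it is negligible.

**Constraint and boundary bias.** Two estimator forms are exposed. The raw
sequential solve is mean-calibrated for every relationship class but can
leave the probability simplex. The constrained form truncates each k to
[0, 1] and renormalizes, guaranteeing k0+k1+k2 = 1 and φ ∈ [0, 0.5]; the
price is an inward bias at boundary-true classes — for an unrelated pair at
2,000 panel-like markers, sd(k0) ≈ 0.09, so projection pulls the mean k0 to
≈ 0.94. This is a property of any constrained estimator at a vertex of the
parameter space, not an implementation artifact; the raw form is the one to
use when checking calibration, the constrained form when classifying (the
classification thresholds k0 < 0.03 and k2 > 0.3 sit far from the truncation
region, so the choice does not move any call). The constrained form is the
default.

**Mendelian errors.** Duo errors are opposite-homozygote markers; trio
errors are markers where the offspring genotype cannot be assembled from one
allele per parent (offspring AA needs an A from both; AB needs an A from one
and a B from the other). A duo error against either parent is always a trio
error on the same marker, so trio counts dominate duo counts — a tested
invariant.

## Calling rules

- **PO duos**: k0 < 0.03 on the LD-pruned set, annotated with duo errors on
  the full marker set as confirmation. The threshold sits inside the wide
  empty gap between the PO mode (k0 ≈ 0) and everything else (k0 ≳ 0.2); the
  full k0 table is emitted so the gap can be inspected rather than trusted.
- **Trios**: for each individual, every unordered pair of its PO partners is
  tested; accepted at error rate ≤ 0.2% of tested markers. A rate transfers
  across panel sizes where an absolute count would not; the observed
  separation (single-digit errors for true trios versus hundreds for false
  ones, including the adversarial parent-plus-own-child configuration)
  leaves the threshold two orders of magnitude of slack on either side.
- **Full sibs**: non-PO pairs with k2 > 0.3. This deliberately conservative
  default reflects germplasm practice, where background relatedness and
  inbreeding push FS pairs upward and blur the FS/half-sib boundary. On
  pedigrees with unrelated founders the realized FS k2 concentrates at
  0.25 ± 0.01, so the 0.3 default accepts essentially nothing there — by
  design, not defect; recall on such data needs a threshold below 0.25
  (0.15 separates FS cleanly from second-degree pairs, whose k2 ≈ 0).

## Second-degree scan for missing parents

Given a duo and an assumed direction, informative markers are those with the
assumed parent homozygous and the offspring heterozygous; the obligate
allele is the offspring allele the assumed parent lacks. Both homozygous
parent classes are used (the argument is symmetric, and it doubles the
informative set; a switch restores the single-sided variant). For each
candidate, f_obs is the fraction of informative markers where it carries the
obligate allele; f_exp is the HWE carrier expectation (1−q² or 1−p²)
averaged over the same markers; z standardizes the excess. Acceptance
requires z ≥ 4 AND f_obs − f_exp ≥ 0.15 over ≥ 100 informative markers — the
z floor kills small-n flukes, the absolute excess kills large-n trivial
excesses. A relative of the offspring through the missing parent shares each
obligate allele with probability 1/2, landing at f_obs ≈ 0.5 + 0.5·f_exp
(observed z ≈ 14–16 at panel scale, against |z| < 4 for unrelated
candidates).

Panel-estimated frequencies include the conditioning individuals and the
missing parent's lineage, which inflates f_exp by ~0.02 at this panel size.
The bias is conservative — it suppresses candidates, never promotes them —
and vanishes against the ~0.2–0.3 excess of true relatives.

Candidates already first-degree to the assumed offspring (its PO, FS or
clone partners) are excluded from the scan-driver's accepted-candidate
counts: an offspring's own children and sibs carry its alleles at ~1/2
excess *whichever* parent transmitted them, so counting them would
manufacture missing-parent evidence in the wrong direction of a duo. Scans
are always run on the deduplicated panel — a clone of the offspring would
trivially carry every obligate allele.

**Grandparent test.** For a candidate pair, an incompatibility is an
informative marker whose obligate allele neither candidate carries —
impossible (bar genotyping error) if they really are the missing parent's
parents. Because no single acceptance threshold is defensible a priori, the
test is reported against an empirical background of 100 random candidate
pairs: true pairs sit at rate ≈ 0 against a background of ~0.12–0.4
(≈ E[q⁴]-type non-carrier rates).

## Direction inference

Rules are applied in strict priority, and soundness is preferred to
completeness (an edge may stay undirected; it must never point the wrong
way):

1. **Trio**: membership directs both parental edges toward the offspring.
2. **Full-sib rule**: if A has a full sib C, and C is PO with none of A's PO
   partners, A is the parent in all its unresolved duos — were A the
   offspring, its full sib would be related to A's co-parent's side too.
3. **Second-degree rule**: a duo direction is adopted when scanning it that
   way yields ≥ 2 accepted SD candidates and the opposite direction yields
   fewer than 2. Requiring the opposite scan to stay quiet (on top of the
   first-degree exclusions above) is what makes the rule sound.

Conflicting rule outcomes leave the edge undirected with the conflict
logged. Individuals whose kinship exceeds 0.13 with a focal accession but
whose pair is not classified PO/FS/clone are reported as "unclassified close
relatives" — the kinship coefficient alone cannot separate the second-degree
configurations, nor ancestors from descendants.

## Synthetic pedigrees

The simulator is the package's validation instrument: founders are drawn
under Hardy–Weinberg at per-marker frequencies with MAF ~ U(0.05, 0.4)
(mean founder heterozygosity E[2pq] ≈ 0.33, the value array panels of
outbred clonal crops show after MAF filtering); children receive one
uniformly chosen allele per parent per marker, selfings draw both gametes
from the one parent, clones copy dosages exactly. Corruption replaces each
call with one of the other two dosages uniformly at rate ε, then masks calls
at the missingness rate. Markers are unlinked by default — the pairwise
statistics assume post-pruning quasi-independence — with an optional
block-copying LD mode (founder dosage columns duplicated within blocks)
that exists solely to exercise the pruner. All randomness flows from a
single seed and every fixture is byte-reproducible.

**Error-rate calibration.** ε defaults to 1e-4 per call, back-calculated
from two observable anchors of high-quality array panels rather than assumed:
(i) two independently corrupted clone copies disagree at rate
≈ 2ε(1−ε) + ε²/2, and the Poisson tail of that count over ~6.5k markers must
stay below the strict 0.12% identity threshold with headroom (at ε = 1e-4
the mean clone mismatch is 0.02%; at ε ≥ 3e-4 the tail crosses the threshold
often enough to break clone clustering); (ii) a true trio accumulates
roughly 3εκn Mendelian errors (κ ≈ 0.4 the chance a single-call error
creates an impossible configuration), giving the single-digit counts such
panels show. Missingness defaults to 0.5%.

**The standard scenario** is a ~74-accession, 6,800-marker (≈ 4.5k post-QC),
three-generation pedigree containing four clone pairs, a selfing, five
founder trios plus third-generation crosses, a full-sib pair, half sibs
through two non-genotyped parents — one with genotyped grandparents and an
avuncular relative — a hidden-lineage founder with a genotyped full sib
(exercising the FS direction rule), and unrelated singletons. The truth
object exposes a relationship oracle (clone/PO/self/FS/HS/GP/AV/unrelated),
recursive pedigree kinship, and the exact clone/duo/trio sets restricted to
any sample list.

What the simulator does **not** emulate — and what passing tests therefore
do not certify for real data: linkage between markers (real panels are
pruned toward this assumption, not born with it), population structure and
background relatedness among founders (which inflate FS k2 and blur the k0
gap), somatic mutations within clone lineages, allele-dropout-style
asymmetric genotyping error, and non-random missingness.

## Validation problem sizes

The test suite scores full recovery on ten scenario replicates
(precision = recall = 1 for clones, duos and trios on every seed at the
default thresholds), checks the moments estimator against an independent
per-marker enumeration oracle on panels up to 10 × 50 (agreement to 1e-12),
calibrates the raw estimator over 50 independent pairs per relationship
class at 2,000 markers (class means within 0.05 of pedigree expectation),
and verifies the exact zero-error properties on an error-free replicate.
`scripts/acceptance.py` recomputes all of it from scratch, over five
replicates, in under a minute.

## Known limitations

- Inbred material interacts badly with the two-allele IBD model (k2 of a
  selfed line against its parent is not meaningful); the parentage
  heterozygosity filter removes most such individuals, as it does in
  practice.
- The FS threshold cannot be simultaneously faithful to germplasm practice
  (0.3) and sensitive on structure-free simulations (≤ 0.25); the default
  follows practice and the trade-off is documented above.
- The SD scan needs a few hundred informative markers to be decisive;
  duos between two founders, or selfings (where the informative-marker set
  is empty by construction), yield no direction evidence and stay
  undirected.
- Direction inference is rule-based and abstains readily; it does not
  attempt joint likelihood over the whole pedigree.
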