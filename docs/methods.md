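# Methods

## Scope and model

fampri analyses a single extended pedigree in which a monogenic,
late-onset, autosomal-dominant trait is assumed to segregate. Three
computations carry the scientific weight: (i) the co-segregation filter and
annotation cascade that reduce a joint multi-sample VCF to a handful of
candidates, (ii) the intersection of pairwise IBD segments across the
sequenced affected members, and (iii) the single-point parametric LOD under
an explicit penetrance model. A gene-dropping simulator supplies synthetic
datasets with complete truth so every step can be validated end to end.

## Pedigree likelihood

The likelihood is defined over joint two-locus diplotypes: each haplotype
carries one disease allele (frequency $p$) and one marker allele (frequency
$q$), giving 4 haplotypes and 16 ordered diplotype states per individual.

- **Founders**: Hardy–Weinberg and linkage-equilibrium prior,
  $P(h) = p^{d}(1-p)^{1-d}\,q^{m}(1-q)^{1-m}$ per haplotype.
- **Meioses**: a parent with diplotype $(h_1, h_2)$ transmits $h_1$ or
  $h_2$ with probability $(1-\theta)/2$ each and either recombinant with
  probability $\theta/2$.
- **Penetrance**: an affected individual contributes $f_g$, an unaffected
  $1-f_g$, an unknown 1, where $g$ is its disease-allele dosage and
  $(f_0, f_1, f_2)$ the penetrance vector ($f_0$ = phenocopy rate).
- **Marker observations**: an indicator that the state's marker dosage
  equals the observed genotype; missing genotypes contribute 1.

The sum over all joint assignments is evaluated exactly by Elston–Stewart
peeling. `pedio.peeling_order` decomposes the pedigree into nuclear
families and orders them so each family, when processed, shares at most one
member (the pivot) with the still-unprocessed remainder; leaf families
(pivot is a parent) peel before peel-down families, with a lexicographic
tie-break, making the order deterministic. Messages are 16-vectors over the
pivot's states, rescaled by their maximum with the log-scale accumulated
separately, so deep pedigrees cannot underflow. Pedigrees with marriage or
inbreeding loops are rejected rather than approximated: loop-breaking would
forfeit the exact equivalence with the enumeration oracle, and the intended
use case is loop-free.

`enumerate_loglik` recomputes the same likelihood by brute force,
materializing the full joint state tensor (after pruning states
incompatible with observed marker genotypes) and summing it. It shares no
code path with the peeler beyond the factor definitions and is the
validation oracle: on random pedigrees of up to 8 members the two agree to
better than 1e-9 in log space (observed: ~1e-15).

### LOD and tails

The single-point LOD compares $\theta = 0$ against $\theta = 1/2$; the same
code path evaluates both, so `lod` at $\theta = 1/2$ is exactly 0.0, not
merely close. The p-value is half the upper tail of a 1-df chi-square at
$2\ln(10)\,\mathrm{LOD}$ (the one-sided boundary asymptotics of a
likelihood-ratio test); `t_two_tailed` wraps the Student-t survival
function. Both go through scipy's implementations of the regularized
incomplete gamma/beta functions.

A closed-form regression point: in a fully penetrant dominant family whose
transmitting parent's phase is fixed by an affected, marker-heterozygous
grandparent, each informative non-recombinant child multiplies the
likelihood by $(1-\theta)/2$, and the grandparental phase sum is
$\theta$-free; four such children give LOD $= 4\log_{10}2 \approx 1.204$
exactly, independent of the allele frequencies. The test asserts this to
1e-9.

### Parameter choices

- **Prevalence 0.01, penetrances (0, 0.9, 0.9)**: the default dominant
  model of the intended analysis; the disease-allele frequency is derived
  from the prevalence (0.005571 under the defaults) by the smaller root of
  the Hardy–Weinberg quadratic.
- **Phenocopy rate $f_0 = 0$** by default. It is configurable because the
  LOD depends on it materially: with $f_0 = 0$ an affected non-carrier has
  likelihood zero, which is strong information.
- **Marker allele frequency 0.001** by default: the marker being tested is
  an ultra-rare candidate variant itself; its population frequency is far
  below any cohort estimate, and the LOD of a rare co-segregating allele
  grows as the marker frequency shrinks. User-supplied when known.
- Only $\theta \in \{0, 1/2\}$ enters the reported score; a $\theta$-grid
  evaluator exists for diagnostics, without maximization.

## Segregation filter and cascade

Thresholds are inclusive: gnomAD max AF ≤ 0.001, cohort AF ≤ 0.02, CADD ≥
15\. The two frequency conditions form a single "rare" step because they are
reported as one. Decisions taken where the rule is underdetermined:

- A missing genotype among the pattern individuals disqualifies the variant
  from both candidate lists — the conservative reading of "shared by all".
- A missing gnomAD frequency counts as 0 (absent from a large reference
  collection is evidence of rarity; discarding novel variants would defeat
  the purpose of the filter).
- A missing CADD score fails the CADD step (no evidence of deleteriousness).
- A site with all genotypes missing has undefined cohort frequency and
  fails the rare step rather than raising, so batch runs never abort.
- IBD membership (step 5) uses gene-span semantics by default — the gene's
  interval must intersect a shared region — with position semantics as an
  option.

`rank_survivors` is a deliberately transparent stand-in for network-based
gene prioritizers: seed-list membership, then maximum CADD, then name. It
makes the end-to-end report deterministic and testable; it does not attempt
to model phenotype relevance.

## IBD intersection

`shared_regions` computes, per chromosome, the maximal intervals covered by
at least one segment for *every* unordered pair of the required samples —
the strictest reading of multi-way sharing — via a breakpoint sweep on
half-open coordinates (public coordinates are 1-based inclusive; BED output
converts at the boundary). A `min_pairs` parameter relaxes completeness.
The sweep is validated exhaustively against a per-base membership oracle on
randomized instances with coordinates up to 1e4.

`naive_ibd_scan` is an exclusion heuristic, not an HMM: maximal runs of at
least `window` markers containing at most `max_opposite_homozygotes`
opposite-homozygote sites. It exists so synthetic data can be pushed
through the IBD step without an external caller; its defaults (window 50,
1 allowed opposite homozygote) are tuned for multi-megabase tracts at ~100
markers/Mb and it should not be used for real inference.

## Synthetic data generator

`simfam` emulates the outputs of a familial exome study, not the reads: a
pedigree, a joint VCF over the genotyped members plus an unrelated cohort,
an annotation table, truth IBD tracts, and phenotypes.

- **Genome model**: one 80-Mb chromosome, uniform 1 cM/Mb map, crossovers
  Poisson per meiosis with uniform positions. Founder haplotypes carry
  globally unique labels; descent mosaics are recorded exactly, so truth
  IBD tracts (intervals where two members share a founder haplotype) are
  byproducts of the dropping, guaranteed consistent with every genotype.
- **Study-emulation preset**: a fixed four-generation family with 15
  genotyped members — 6 affected carriers of a planted het variant and 9
  unaffected non-carriers — emulating the realized co-segregation design
  such a study ascertains. The transmission at the causal position is
  conditioned on the designated carriers by resampling each meiosis
  (rejection sampling), which preserves full cross-consistency of the
  surrounding mosaic. Phenotypes in the preset reproduce the realized
  family (carrier ⇔ affected among genotyped members); in the random mode
  phenotypes are drawn from the penetrances, and the calibration test
  checks the affected fraction among ≥10,000 carriers is within three
  binomial standard errors of 0.90.
- **Causal variant**: gnomAD AF 2.64e-5, CADD 23, missense, PASS — an
  ultra-rare damaging variant comfortably inside every threshold.
- **Background variants** (199 by default): population frequencies
  log-uniform on [0.005, 0.5] (conditioned on presence in the pedigree,
  emulating ascertainment); gnomAD frequencies either tied to the
  population frequency with log-normal jitter or drawn rare (35%), so the
  0.001 boundary is exercised from both sides; CADD a 50/50 mixture of
  U(0,15) and U(15,40) straddling the 15 cutoff; consequences 55% missense
  / 10% splice / 5% frameshift / 5% nonsense / 25% other; 85% PASS.
- **Cohort**: 185 unrelated samples genotyped at Hardy–Weinberg
  proportions. Without them a family-private variant could never pass a
  within-VCF frequency threshold (6 carriers among 15 samples is AF 0.2);
  with 200 total samples the causal cohort AF is 6/400 = 0.015.
- **Marker panel**: 100 markers/Mb (500 per 5 Mb) with allele frequencies
  U(0.1, 0.5), family members only — input for the exclusion IBD scan.
- **Determinism**: one `numpy` generator seeded from the config; identical
  configs produce byte-identical files.

What the generator does *not* emulate: genotyping error, sequencing
coverage structure, age-dependent penetrance or censoring (relevant to
late-onset traits), population structure in the cohort, and linkage
disequilibrium between background variants. Passing tests therefore
demonstrate the correctness of the filtering, intersection and likelihood
machinery on idealized data, not robustness of the study design to noisy
real-world genotypes.

## Numerical and degenerate-input choices

- Likelihoods in linear space with per-message max-rescaling and
  accumulated log scale; an impossible configuration returns `-inf` rather
  than raising.
- The prevalence quadratic switches to the linear solution when the leading
  coefficient vanishes ($f_2 - 2f_1 + f_0 = 0$); a supplied allele
  frequency inconsistent with the prevalence beyond 1e-6 is rejected.
- Ledger survivor ordering is (chrom, pos, ref, alt) throughout;
  monotonicity and the het+hom split are asserted on every run.
- Empty inputs (no variants, no segments) propagate to empty outputs and
  all-zero ledgers, never to errors.

## Problem sizes used in validation

The oracle-equivalence suite uses 200 random pedigrees of 2–8 members
(enumeration beyond 8 fully genotyped members is memory-hostile: the
pruned joint tensor reaches $8^8 \approx 1.7\times10^7$ states);
permutation nulls use 200 relabelings; IBD oracle checks use coordinates up
to 1e4 so the per-base oracle stays exhaustive; calibration accumulates
carriers over ~1,400 light-configuration replicates. These sizes are the
package's validation design and are encoded in the tests and
`scripts/acceptance.py`.

## Known limitations

- Two-point (disease + one marker) analysis only; no multipoint linkage,
  haplotyping or nonparametric scores.
- Loop-free pedigrees only; consanguinity requires loop-breaking, which is
  out of scope.
- The segregation filter models complete dominant or recessive patterns;
  compound heterozygotes and X-linked inheritance are not modeled.
- `hgvslite` performs codon arithmetic on user-supplied codons; it does not
  project genomic coordinates onto transcripts.
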