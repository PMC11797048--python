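# Methods

## Haplotype model

A haplotype is a binary vector over a position-sorted panel of biallelic
variants (0 = reference, 1 = panel alternate). Classification uses seven
role-tagged sites:

| role | variant | meaning |
|---|---|---|
| `M1` | rs73885316, chr22:36265628 C>A | protective p.N264K |
| `G1_snp1`, `G1_snp2` | rs73885319 (36265860 A>G), rs60910145 (36265988 T>G) | the two SNPs jointly defining G1 |
| `G2_del` | rs71785313, 36265995 AATAATT>A | 6 bp in-frame deletion defining G2 |
| `bg150`, `bg228`, `bg255` | codons 150/228/255 | EMR (ref) / EIK (0,1,1) / KIK (1,1,1) backgrounds |

Risk class: G2 whenever the deletion allele is present; G1 when both G1
SNPs are present without G2; `G1_partial` (with a logged warning) when
exactly one G1 SNP is present — the two SNPs are expected to co-occur, so a
lone tag is surfaced rather than silently absorbed into G0 or G1. A
haplotype carrying both G1 and G2 tags is classified G2 but flagged
(`conflict=True`). Any 150/228/255 combination other than the three named
backgrounds maps to `OTHER`.

## Extraction from phased VCF

Records are matched to panel variants by (chrom, pos, REF, ALT); the panel
must use the VCF's own indel normalization (no left-alignment is performed
— re-implementing normalization invites silent mismatches). In
multiallelic records the panel alternate is located among the ALTs; a
haplotype carrying any *other* alternate is an explicit allele-mismatch
error, because the panel defines biallelic markers. Policy switches, all
defaulting to the conservative choice:

- missing panel site → error (silent reference-fill would fabricate
  haplotypes); optional `drop-site` proceeds on the reduced panel, logged;
- unphased heterozygote at a panel site → error; optional `drop-sample`;
- missing genotype (`./.`) → drop that sample, logged (configurable to
  error). Homozygous unphased calls (`0/0`, `1/1`) are accepted: phase is
  irrelevant there.

## LD and the four-gamete test

With phased input the two-locus gamete frequencies are observed directly,
so no EM estimation is involved. D, D′ and r² follow the standard
definitions (README); `D_max` uses the sign-dependent bound. A monomorphic
locus raises an explicit error rather than yielding NaN, and LD-matrix
rows for monomorphic sites are NaN-masked, never zero-filled — zeros would
be indistinguishable from equilibrium. The four-gamete test accepts a
`min_count` (default 1, so singleton gametes count) to harden against
genotyping error when desired.

## Breakpoint inference

Given a recombinant candidate `r`, a left parent set A and right parent set
B, only sites where a given (a, b) pair differs are informative. For every
pair and every split between consecutive informative sites, the mismatch
count is the number of sites explained by neither side (a site where `r`
matches neither parent counts once, regardless of the split — uninformative
sites never constrain the placement). Feasible placements within
`max_mismatch` (default 0) are ranked by mismatches, then interval width,
then the lowest (a, b) indices, making the result deterministic. Interval
endpoints are the flanking informative-site positions, exclusive on both
ends, and the width is their simple difference — hence 367 for the
(M1, G2) window. `r` identical to a parent, or explainable by one parent
alone, is `ambiguous` (no crossover required); anything needing two or more
crossovers is `infeasible` — the model deliberately stops at a single
crossover and does not fit gene conversion or double crossovers.

Origin parsimony: the recurrent-mutation hypothesis costs 1 (the M1
mutation) plus the Hamming distance (M1 site excluded) to the nearest G2
haplotype — every residual difference is a mutation that must arise again;
the recombination hypothesis costs 1 crossover plus residual mismatches of
the best decomposition.

## Clustering

Unique haplotypes are clustered on Jaccard distance
(1 − shared/union of alternate-allele sites). The empty-union distance
(two all-reference haplotypes) is defined as 0: identical vectors are
identical, whatever the convention elsewhere leaves undefined. Linkage is
agglomerative with Lance–Williams updates (single/complete/average;
default complete), ties broken by the lowest cluster-index pair so trees
are bit-reproducible; unit-weight average linkage matches
`scipy.cluster.hierarchy.linkage`, which the test suite uses as an
independent cross-check. Each unique haplotype enters with unit weight by
default, matching a row-per-unique-haplotype repertoire display; a
count-weighted mode weights average-linkage merges by cohort counts.

## Presence profiles and matching

Low-coverage unphased carriers are represented per site as
`alt_observed` (alt reads ≥ threshold, default 1), `ref_only`, or
`no_data` (zero reads). Matching a profile against the repertoire scores
each candidate diplotype (or single haplotype in homozygous mode) on
informative sites only: an observed alternate must be present on at least
one candidate haplotype, a ref-only site on neither; ranking is by fewest
conflicts, then most consistent sites.

## The synthetic cohort generator

Forward multinomial sampling of founder lineages — not a coalescent: the
claims under test concern haplotype structure, not genealogy depth, and
multinomial sampling keeps every recovery test analytically checkable.
Five founders (G0/EIK, G0/KIK, G1/EIK, G2/EIK, M1-G0/KIK) over a 28-site
panel; the M1-G0/KIK founder additionally carries three intronic markers
absent from all other founders, emulating the M1-lineage-specific intronic
SNPs. The M1-G2 recombinant is built by one crossover at a position drawn
uniformly from the open (36265628, 36265995) interval (or fixed), taking
parent-A alleles strictly left of the crossover. Because the five tag
variants sit at their real published coordinates, the inferred breakpoint
window is literally 367 bp; all remaining panel positions are synthetic
placements inside chr22:36253528–36270279 (ids prefixed `syn_`).

Default parameters, chosen once:

- `n_individuals = 500` (1,000 haplotypes — the order of an AFR reference
  cohort while keeping hundred-seed sweeps fast on one CPU);
- founder frequencies G0/EIK 0.398, G0/KIK 0.240, G1/EIK 0.210, G2/EIK
  0.130, M1-G0/KIK 0.018, recombinant 0.004 — G1/G2 at typical
  African-ancestry risk-allele frequencies, M1 classes at the observed
  cohort proportions (about 7 recombinant chromosomes per ~1,760);
- `per_site_flip_rate = 0` (noise-free null; sweeps of ε against
  `max_mismatch` probe robustness to recurrent mutation/genotyping error);
- degradation depth λ = 4.9 (shotgun-aDNA coverage regime). Per-site depth
  is Poisson(λ) with reads drawn equally from the two chromosomes, so a
  heterozygous alternate is detected with probability 1 − e^{−λ/2}
  (≈ 0.9137 at λ = 4.9) — the calibration target of the test suite.

All randomness flows from one seed; identical configurations reproduce
bit-identical cohorts.

What the generator does *not* emulate: mutation/recombination elsewhere in
the region (every non-recombinant haplotype is an exact founder copy under
ε = 0), population structure and relatedness, phasing errors, allele-
frequency drift, and reference-panel ascertainment. Passing recovery tests
therefore demonstrates the correctness of the machinery under the stated
haplotype model, not robustness to every artifact of real cohort data;
the extraction and analysis layers accept real phased VCFs unchanged for
that purpose.

## Numerical and interface choices

- Coordinates are 1-based (VCF convention); breakpoint intervals are open
  at both ends; widths are simple position differences.
- `exclusive_variants` defaults to `min_fraction_a = 1.0` (count-weighted):
  "exclusive" reads as present across all of group A and absent from B;
  the stringency and an annotation-class filter (e.g. intronic-only) are
  parameters. A 1e−12 tolerance guards the fraction comparison against
  float round-off in count weighting.
- Pipeline TSVs print floats at 6 significant digits so identical
  configurations produce byte-identical reports.
- The pipeline's recombinant candidates are records with M1 ∧ G2; parents
  are M1 ∧ ¬G2 (left) vs ¬M1 ∧ G2 (right).

## Known limitations

- The shipped core panel contains only the four tag variants with
  published coordinates; full-panel analyses of real cohorts require the
  user to supply the complete panel TSV.
- Single-crossover model only; no gene conversion, no double crossovers,
  no event dating, no selection inference.
- LD is computed from phased gametes only; unphased (composite) LD is out
  of scope, as are map-function conversions between cM and physical
  distance.
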