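# Methods

## The measurement problem

Target-site pyrethroid resistance (*kdr*) in *Aedes albopictus* is scored
by Sanger-sequencing three *VGSC* amplicons per mosquito and reading the
diploid genotype at codons 1016 (Domain II), 1532 and 1534 (Domain III);
Domain IV is screened but no resistance allele is catalogued there. A
population's resistance profile is then summarised as allele and genotype
frequencies, a mutant-carrier frequency, multi-site combination counts,
an intron-type association, and correlations with insecticide exposure.
`kdrsurv` implements each of these steps as a typed, tested operation.

## Reference anchoring and the allele catalog

Codon numbers follow the house-fly convention and are community labels,
not sequence-derived: each `ReferenceFragment` carries explicit
(codon number → fragment position) anchors validated to sit wholly inside
exons. The allele catalog fixes, per site, the permitted codons with
amino acid and status: 1016 GTA/V wild, GGA/G mutant; 1532 ATC/I wild,
ACC/T mutant; 1534 TTC/F wild, TTT/F synonymous wild, TCC/S, TGC/C and
ATC/I mutants; Domain IV's codon 1763 is anchored with only its wild
allele (GAC/D) so any nonsynonymous variant there is surfaced as novel.
Catalog entry order doubles as reporting order, which reproduces the
field's genotype labels (F/S, S/C, S/I — wild first, mutants in their
reported order). The shipped reference fragments are synthetic stand-ins
with the survey's amplicon structure (Domain III: exon — 83 bp type-A
intron — exon, with 1532/1534 on the downstream exon); real accession
sequences can be swapped in through the YAML+FASTA config without code
changes.

## Alignment

Reads are aligned to their fragment with a semi-global pairwise aligner
(free end gaps on both sequences): match +2, mismatch −1, gap open −5,
gap extend −1, and IUPAC-aware scoring in which an ambiguity code matches
any constituent base at full match score. These parameters are
configuration, not science — any sensible scheme recovers the exon
blocks, since reads differ from the reference only by point variants and
the intron-length polymorphism. An alignment is accepted when identity
over the reference's *exon* positions is ≥0.80 (configurable); failed
alignments exclude the individual from that fragment's tables and shrink
the per-table denominators, which is why a survey's N can differ between
the genotype tables and the intron table.

## Diploid decoding and phasing

A consensus codon window of IUPAC codes is decoded by enumerating every
unordered plain-codon pair whose per-position base sets equal the
window's sets. One ambiguous position yields a single pair; *k* ≥ 2
ambiguous positions yield 2^(k−1) phasings, which the consensus alone
cannot distinguish. The catalog restricts candidates:

* exactly one fully catalogued pair → unique call;
* several catalogued pairs → ambiguous: candidates are listed and the
  call is excluded from counts rather than guessed (the wet-lab
  equivalent is TA cloning the product);
* no catalogued pair → unique only if a single explanation exists at
  all, with its uncatalogued codon flagged through the novel-allele
  channel; otherwise ambiguous.

Any window position encoding more than two bases (e.g. N) fails the
call. A correctness oracle — brute-force enumeration of all 64×64 codon
pairs — is checked against the decoder on all 3375 IUPAC windows in the
test suite.

Zygosity classes are wild-homozygous, wild/mutant heterozygous, mutant
homozygous and mutant heterozygous (two different mutant alleles); the
synonymous 1534 TTT allele is wild-class, so TTC/TTT is a wild homozygote
with a note. For display, an uncatalogued nonsynonymous allele is
classed with the mutant-containing labels, but the `mutant_carrier` flag
counts only *catalogued* mutant alleles: a novel allele should prompt
review, not silently enter the carrier statistic.

## Intron typing

The Domain III intron is cut from the read between the aligned flanking
exon bases and typed by exact length (A 83, B 68, C 80, D 72, E 70,
F 67 bp); the GT…AG boundary check is advisory only, since classification
is by length. Sequence subtypes are exact matches against a library
(shipped synthetic: 6 A, 6 B, 1 C, 1 D, 2 E, 1 F, GT…AG-bounded, fixed
deterministic sequences; a real library is a drop-in mapping). Because
types are length classes, a single consensus implies a length-homozygous
individual and hence one type on both chromosomes; individuals supplied
as two haplotype records contribute haplotype-resolved types. For the
intron × genotype table — which, like the field's reporting, assigns one
intron per mosquito — individuals whose two haplotype types differ, or
whose intron could not be extracted cleanly, are excluded and tallied,
mirroring how length-heterozygous traces are unreadable in a real
consensus. The association statistic collapses 1534 genotypes into
wild-homozygous vs mutant-carrying among 1532 I/I individuals and tests
the intron A/B split with Pearson's chi-square (no continuity
correction), flagging expected counts <5.

## Population statistics

Per-site denominators are unique-resolution calls. Allele frequency is
computed on exact counts, (2·hom + het)/2N, and the aa-level
allele-from-genotype identity (hom + het/2 on class weights) is exposed
separately so it can be applied to published percentage rows. Pooled
("Total") rows always pool counts across populations, never average
per-population percentages. The mutation frequency is carriers/N with a
carrier defined as ≥1 nonsynonymous mutant allele at any surveyed site.
`pooled_rate` reconstructs per-population counts from printed
percentages by round-half-up(pct·n/100) before pooling — the only
faithful way to pool rows published to two decimals. The Pearson
correlation reports r, t = r·√((n−2)/(1−r²)) and the two-sided p from
the t distribution with n−2 df. Usage density is grams of pyrethroid
per km² of district area; rows without a positive area are dropped.

## The synthetic-population generator

The simulator stands in for field collection. Its model, and what it
does and does not emulate:

* **Genotypes.** Each site's two alleles are drawn independently from the
  configured allele-frequency vector (Hardy–Weinberg), and sites are
  mutually independent — real linkage between codons (and any joint
  structure behind observed multi-site combinations) is *not* modelled;
  combinations arise only by chance, which matches their observed rarity.
* **Introns.** Each chromosome's intron type is drawn from a conditional
  distribution given the individual's 1534 amino-acid genotype class. The
  default conditional is estimated from the bundled survey's 638-count
  intron × genotype table, pooled over 1532 classes and renormalised,
  with the overall marginal as fallback for unobserved classes. The
  survey tabulates individuals, not chromosomes, so using its row
  proportions per chromosome is a modelling choice; it reproduces the
  qualitative A/B–wild/mutant coupling and its chi-square direction, not
  the exact published cell counts.
* **Rendering.** Haplotypes are the reference with alleles substituted at
  anchors (Domain III with each chromosome's intron); equal-length
  haplotypes merge into one consensus with IUPAC codes at heterozygous
  positions, and length-heterozygous intron pairs are emitted as two
  `|hap1`/`|hap2` records, since one string cannot carry a length
  polymorphism. Uniform per-base substitution noise (default 0) is
  applied after merging; chromatogram artefacts, quality values and
  indel errors are not modelled, so zero-noise runs are exactly
  recoverable and noisy runs only probe the alignment/exclusion path.
* **Determinism.** All draws derive from `numpy` generators seeded as
  ([seed, stream]) with separate streams for genotypes, introns and
  noise; identical configs give byte-identical FASTA and truth tables.
* **The `paperlike` preset** instantiates the bundled survey's sixteen
  population sizes (658 total) and per-population allele frequencies
  (renormalised from the published rounded percentages), with child seeds
  spawned from one master seed.

Consequently, green end-to-end tests demonstrate that calling inverts
rendering exactly under clean-Sanger assumptions; they do not certify
performance on chromatograms with base-calling noise, indels, or linked
loci.

## Numerical conventions and edge cases

Frequencies are compared in tests at ±0.01 percentage points, matching
two-decimal reporting; printed-table reconstruction uses round-half-up.
Frequency vectors must sum to 1 within 1e-9 (then renormalised to wash
float dust). Chi-square requires an r×c table, r,c ≥ 2, with positive
margins; Pearson correlation requires n ≥ 3 and nonzero variance, and
|r| = 1 returns p = 0. Empty populations produce empty-but-valid outputs.
Levenshtein distances are computed with edlib and cross-checked against a
dynamic-programming oracle in tests.

## Known discrepancies in the published values

Three published numbers cannot be reproduced from the published tables,
and `kdrsurv` reports the correctly computed values instead:

* The pooled 1016 allele frequency (7.14 %) is consistent with the pooled
  genotype row but not with reconstruction from the per-population rows
  (≈6.7 %); pooled-count semantics are followed and the pooled genotype
  row is used where the survey's own aggregation is ambiguous.
* One population's published 1534 F/F entry (4.44 % at n = 40) is not a
  multiple of 1/40 and is treated as a typo, not imitated.
* The two usage-density correlation p-values published as 0.4755 and
  0.2223 do not follow from the printed 14 district pairs under a
  two-sided Pearson test (computed: 0.6418 and 0.4449). The second
  printed "p" exactly equals the correlation coefficient r = 0.2223,
  indicating the statistics output was mislabelled at the source. The
  substantive conclusion — no significant correlation — is unchanged.

## Problem sizes

Default test and demonstration runs use cohorts of 6–658 simulated
individuals (the full survey-sized preset runs in a few seconds), 5 000
individuals for allele-frequency recovery, 10 000 for the Hardy–Weinberg
goodness-of-fit and 20 000 for intron-association recovery, chosen so
each statistical check has comfortable power at fixed seeds.
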