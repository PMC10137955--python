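# Methods

## Coordinate system and regions

All positions are 1-based on the 16,569 bp circular mtGenome, numbered
against the rCRS (NC_012920.1). The region table has 38 entries: the
control region (CR, nps 16,024–576, the only interval spanning the
origin) and 37 gene-coding regions, including TF (tRNA-Phe, 577–647).
Overlapping genes (TI/TQ, ATP8/ATP6, ND4L/ND4) all annotate a position;
operations that need a single region use the first in table order.
Positions outside every interval (e.g. the CO2–TK spacer 8270–8294)
annotate "non-coding" and do not participate in the 38-region consistency
count, because forensic region tabulations never list them.

## Variant nomenclature

Calls follow SWGDAM forensic notation: `73G` (substitution), `315.1C`
(insertion, 1-based index after the anchor), `249DEL` (deletion), `152Y`
(point heteroplasmy as IUPAC mixed base), and lowercase forms (`309.1c`,
`523a`) for minor-length components of a length heteroplasmy. Labels are
the identity of a call: they parse back losslessly into (position, kind,
allele, insertion index).

## Calling thresholds

The reporting gates mirror the defaults of current whole-mtGenome MPS
analysis software: analytical and interpretation thresholds both 6 % of
the positional depth, minimum 45 reads, minimum mean quality Q30. The two
frequency thresholds play the same role here and are applied as one gate;
they remain separate configuration fields for fidelity to the upstream
convention. Each allele is gated independently (the 45-read minimum
applies per reported allele, so a 20-of-100-reads minor allele is dropped
and the majority allele is reported homoplasmic). The frequency
denominator is all reads at the position, deletion-supporting reads
included; insertion frequency uses the anchor position's depth. Quality
gating operates on mean per-allele quality because the input contract is
count-level, not read-level. A 50/50 mixture still receives its IUPAC
genotype; for MAF bookkeeping the reference allele is treated as major.
MAF is always the smaller of the two mixed-base frequencies, regardless
of which allele is the reference. Report strings print percentages to two
decimals, rounded half-up.

## C-stretch resolution

Molecule length in a homopolymer region can only be established from
reads spanning the whole stretch, so the seven length-variable regions
are called from molecule-length read profiles, not positional pileups.
Each molecule's run-length profile is decoded into an rCRS-relative call
set by enumerating driver substitutions (310C; 961C; 16182C, 16183C,
16189C) and per-run insertion counts, preferring fewest substitutions and
rightmost insertion placement (insertions are named after the last
position of their run, hence 309.x, 965.x, 16193.x, 12425.x). The
reported set is the union of call sets over molecules passing the LHP
thresholds; a call present in every passing molecule is uppercase, the
rest lowercase. This single rule reproduces all fourteen documented
variant-type → reported-haplotype mappings, including the distinction
between `309.1C, 315.1C` (competing molecule below threshold) and
`309.1c, 315.1C` (reference-length molecule passing).

Deletion-type regions are special-cased: a deletion/reference mixture at
514–524 reports the residual bases of the rightmost repeat unit lowercase
(`523a524c`); the 9-bp deletion region 8272–8280 reports 8272–8274 as
clean deletions and 8275–8280 as lowercase mixtures, matching the
amplicon-tiling behaviour observed with this chemistry, where base reads
at the first three positions fall below the read-count gate.

LHP thresholds default to the 6 % interpretation threshold and can be
raised to the stricter recommended values (20 % insertions, 30 %
deletions) via configuration; raising them can only remove lowercase
calls, never add them.

Two systematic nomenclature corrections are provided: `16189c` →
`16189C + 16193.1c`, and `310Y` → 309.x insertion calls derived from the
insertion-count read distribution (an error if the distribution is
missing).

## Transmission classification

For a mother–offspring sample pair, every position carrying a PHP in
either sample yields one record: inherited (same mixed-base code in
both), de novo (offspring only), disappearing (mother only). A PHP at the
same position with different codes is two events, not an inheritance.
The MAF change of an inherited PHP is later generation minus former;
reports print the magnitude. Cross-tissue pairs (blood vs hair) are
supported and classified per compared pair. Positions no-call in either
sample are skipped.

## Three-level comparison and verdicts

Level 1 compares homoplasmic variants outside the homopolymer regions;
level 2 adds PHP presence/identity differences; level 3 adds length-unit
differences, where all calls inside one homopolymer region (driver
substitutions included) collapse into one comparable unit — so a
`961c/961C` flip plus differing 965.x components count once. A PHP in one
sample against the corresponding homoplasmic allele in the other is one
difference. The consistent-region count is 38 minus the number of
distinct gene regions containing any difference at the full level;
duplicate regions are retained in the difference list for display but
deduplicated for the count, and non-coding differences do not decrement
the 38.

Verdicts follow the control-region comparison guidelines extended to the
whole molecule: ≥ 2 differences → exclusion, 1 → inconclusive, 0 →
cannot exclude. At the first two levels length heteroplasmy is excluded
from the count per the guidelines; the third level deliberately includes
LHP units to quantify how length variation would inflate exclusions
between true maternal relatives.

## The bundled reference dataset

The fixture reconstructs, at the variant-call level, a published
whole-mtGenome study of ten maternal pedigrees: eight two-generation
families, one three-generation pedigree (six individuals, blood only) and
one four-generation pedigree (eleven individuals, blood and hair), 44
samples in all. It carries the eleven universal backbone variants, all 26
reported PHPs with their printed allele frequencies, per-sample call sets
for the homopolymer regions inferred from the printed pairwise
comparison details, one de novo homoplasmic 4475C in one hair sample,
and 54 no-call positions in the one sample with 99.67 % coverage.
Pedigree-private marker variants are synthetic: they only make the ten
maternal haplotypes distinct, never differ within a pedigree, and no
reported quantity depends on them.

The source tables contain internal inconsistencies; the dataset resolves
them so that one consistent engine reproduces the headline results, and
each resolution is recorded in the fixture docstring and the golden test
table: two PHPs (4776S, 15115Y) are listed in samples whose printed
pairwise comparisons omit them — encoded as no-call positions in the
partner samples, which the comparison contract skips; three of the 53
printed comparison rows disagree with the table's own counting rules, and
the golden expectations carry the self-consistent values for those rows
(noted inline) and the printed values for the other fifty. One printed
singleton length variant (12425.1a) cannot be placed in any sample
without contradicting the printed comparisons and is omitted; the
12,417–12,426 region logic is exercised by its documented reporting case
instead.

## Simulator

The generative model is deliberately minimal: one binomial resampling of
each PHP frequency per meiosis with effective bottleneck size N (default
32, in the range inferred by human germline-bottleneck studies), fixation
converting a PHP to a homoplasmic substitution or removing it; founder
PHPs at a Poisson rate with MAF uniform on the reportable 6–50 % band; de
novo PHPs per transmission at a Poisson rate; one extra within-tissue
resampling to emulate blood/hair divergence (observed tissue pairs share
no PHPs); homopolymer regions emitted as molecule mixtures whose N−1
stutter molecule carries 13.74 % of the parental reads, the rate measured
for the 16,189 stretch. Depths are lognormal around 4,000× per position;
by default pileups carry rounded expected counts so the caller's output
is an exact inverse for MAFs ≥ 8 % at depth ≥ 1,000 — sampling noise can
be enabled, in which case recovery near the threshold is necessarily
stochastic. The simulator does not model read-level errors, NUMT
contamination, amplicon dropout, or selection on heteroplasmy
frequencies; passing round-trip tests therefore demonstrate internal
consistency of the caller and nomenclature logic, not robustness to those
real-data artefacts.

A full synthetic reference genome is generated from the seed with the
real homopolymer segments planted at their true coordinates; no operation
outside those segments depends on the actual reference sequence, so the
package does not ship the full 16,569 bp reference.

## Problem sizes and determinism

All reference-dataset computations are desk-scale (53 comparisons, 272
relationship comparisons) and run in well under a second; the default
test suite, including 100 random round-trip haplotypes and several
simulated pedigrees of 14–80 samples, completes in a few seconds. Every
stochastic component is driven by a single integer seed through
numpy's Generator; a fixed seed reproduces pileups, ground truth, and
all derived tables byte-identically.
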