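# Methods

## Problem and model

Microsatellites (short tandem repeats, STRs) are loci of tandemly repeated
1–6 bp motifs whose alleles differ in repeat count and, cryptically, in
sequence content. Amplicon sequencing of STR loci gives exact allele
lengths and sequences, but the reads carry systematic PCR and sequencing
artifacts that must be removed before genotypes can be called:

- **stutter**: polymerase slippage products, typically one repeat unit
  *shorter* than the template allele, present at a minority read fraction;
- **substitution and indel errors**: single-base sequencing or polymerase
  errors scattered around each true allele;
- **off-target amplification**: reads from other loci or nonspecific
  products;
- **allelic dropout**: stochastic failure to amplify one allele of a
  heterozygote, which turns it into a false homozygote — the dominant
  error mode for low-input noninvasive samples (feces, hair).

`strtool` implements a three-stage pipeline over demultiplexed,
adapter-trimmed **forward reads** (forward-only reads avoid pairing
misalignments inside the repeat region; base qualities are ignored
throughout, as no quality-dependent step exists in the model).

### Stage 1 — dereplication and artifact annotation

Reads of one sample × locus are collapsed into exact unique sequences
with counts. Each unique sequence is annotated with three locus
attributes: forward-primer prefix match (positional comparison, at most
`primer_max_mismatch` substitutions, no indels — trimmed amplicon reads
begin at the primer), presence of at least `motif_min_repeats`
(default 3) consecutive motif copies, and amplicon length within the
locus range. Lengths always count the full amplicon including both
primers, so they are directly comparable with fragment-sizing results.

Each sequence *s* is then compared against every strictly more abundant
sequence *a* in the same table. *s* is flagged an artifact of *a* when
`count(s) < artifact_ratio × count(a)` (default ratio 1/3, strict
inequality) and either

- *s* equals *a* with one contiguous motif-length block deleted from a
  run of ≥ 2 motif copies (**stutter**), or
- *s* is at edit distance 1 from *a* (**substitution** when the same
  length, **indel** otherwise).

The most abundant qualifying *a* is recorded as the source. Comparing
against *all* more abundant sequences (not only candidate alleles)
subsumes stutter-of-stutter cascades. The one-third default reflects the
empirical observation that true second alleles of heterozygotes carry
more than a third of the partner allele's reads, while stutter carries
less. Ordering everywhere is by descending count with lexicographic
sequence tie-breaks, making the pipeline invariant to read input order.

For multiplexed reactions, reads are first assigned to loci by forward
primer (ambiguous or unmatched reads are dropped); singleplex reactions
keep all reads under their declared locus so that off-target signal
remains visible to the contamination report.

### Stage 2 — filters and zygosity

Candidate alleles are the unique sequences passing all three attributes
with no artifact flag. The **filtered read count** is the sum of
candidate counts; candidates must additionally carry at least
`min_allele_fraction` (default 5%, inclusive) of it. The fraction is
deliberately computed over filtered reads, not raw reads, so off-target
and artifact reads cannot dilute true alleles. A locus is genotyped only
when the filtered count is *strictly above* `min_locus_reads`
(default 500): one surviving candidate is homozygous, two or more report
the two most abundant as a heterozygote.

QC flags concretize "needs attention" conditions: `stutter_filter_invoked`
(any stutter flag fired upstream), `more_than_two_candidates` (more than
two sequences passed every filter), `high_unassigned_fraction` (more than
`unassigned_flag_fraction`, default 0.3, of filtered reads outside the
called alleles), and `dropout_risk` (a homozygote whose filtered count is
below `dropout_flag_multiplier × min_locus_reads`, default 3×, where a
second allele could plausibly have been missed). The 0.3 and 3× defaults
are this package's quantifications of qualitative flag descriptions; both
are configurable.

### Stage 3 — reporting

Alleles are named from the known-allele table on exact sequence match,
otherwise auto-named `<length>-<first 4 hex of a SHA-1 content digest>`.
Hash-based names are stable across runs without global state; a
publication-style alphabetical suffix scheme (-a, -b by carrier count)
can be layered on afterwards but is not the primary naming, since letters
require a whole-study ordering. Within a locus and run, label ↔ sequence
is enforced to be a bijection.

Run outputs: the genotype summary table (samples × loci, label cells,
homozygotes shown once, no-calls empty), four per-flag tables, a
contamination matrix of raw read counts matching each locus's forward
primer per sample (off-column counts in singleplex rows indicate
cross-locus contamination), per-locus allele FASTA plus a multiple
alignment (MAFFT, rendered as aligned FASTA text rather than an image,
for testability), per-sample length-frequency histogram tables with
filter status, and a run-report JSON with thresholds and seed.

## Downstream analyses

**Distance and identification.** Genotypes are compared per locus as
multisets of two alleles (homozygotes doubled); the per-locus mismatch is
`2 − |multiset intersection|` and a locus uncalled in the query counts 2
(both alleles unmatched). The total over the reference's panel is the
distance score. A sample is assigned to the minimum-distance known
individual when that score is ≤ `id_max_distance` (default 3 — tolerant
of, e.g., one missing locus plus one allelic dropout); ties break on
individual id. The missing-locus-counts-2 convention is a design choice:
it makes the default tolerance interpretable and keeps the score equal to
the number of unmatched alleles.

**Mendelian consistency.** A trio is consistent at a locus iff the
offspring's pair splits into one allele present in the mother's pair and
one in the father's pair (both assignment orders tried; parent labels are
symmetric). Missing loci are skipped; a single inconsistent locus
excludes a candidate parent.

**Diversity statistics.** Allele frequencies count two observations per
called genotype; individuals are excluded locus-wise at uncalled loci
(wholesale exclusion of incomplete individuals is available via
`complete_only`). Expected heterozygosity (gene diversity) is
`H = 1 − Σ p_i²`; the default estimator applies the small-sample
correction `2n/(2n−1)` and requires n ≥ 2. Both forms are exposed because
the appropriate choice depends on sample size; the corrected form is the
default for the small populations this tool targets. Allelic diversity is
the count of distinct alleles in called genotypes, summed over loci.

**Error tallies.** Against reference genotypes, per locus: an uncalled
locus is a *missing locus* (2 erroneous alleles), an observed homozygote
for one allele of a reference heterozygote is an *allelic dropout* (1),
and any distinct observed allele absent from the reference pair is a
*false allele* (1 each), subcategorized *PCR stutter* when it is one
motif unit shorter than a reference allele. The rate is erroneous alleles
over `2 × compared loci`, a quantity in [0, 1].

## Synthetic data generator

The simulator emulates a pooled-replicate amplicon run of a diploid
population typed at eight synthetic tetranucleotide loci (150–360 bp
amplicons, fixed invented primers and flanks; `example_loci()`). Per
locus it draws an allele pool sharing a flank template and differing in
repeat count; with probability `same_length_variant_prob` (default 0.25)
a new allele is instead a same-length homoplasy variant of an existing
one — 2–3 flank substitutions or a compensated 1-bp deletion+insertion.
Variants are kept at edit distance ≥ 2 from their base: a true allele at
edit distance 1 from its heterozygous partner would sit inside the
generic single-edit artifact rule, and making that the default would
conflate two separate failure modes; single-base-resolution homoplasy is
still exercised through the compensated-indel class.

Founder genotypes draw two alleles uniformly with replacement
(homozygotes arise naturally); pedigree children draw one allele from
each parent's pair, so simulated trios are Mendelian-consistent by
construction.

Per allele of a genotype (unless dropped out with `dropout_prob`),
coverage is negative-binomial with mean `coverage_mean` (default 2000,
emulating pooled replicates) and shape `coverage_dispersion` (default 20,
i.e. a coefficient of variation ≈ 0.23). Reads then carry, independently:

- **stutter** — `stutter_rate` is defined as the expected ratio of
  stuttered to correct reads per allele, the exact quantity the one-third
  artifact filter tests; `Binomial(coverage, stutter_rate)` stuttered
  copies (one motif unit deleted from a repeat run) are emitted in
  addition to the correct reads. Only the minus-one-unit form is
  simulated by default, matching the dominant slippage direction.
- **substitutions** at `substitution_rate` per base (default 0.003) and a
  **single indel** per read at `indel_rate` (default 0.002), applied to
  correct and stuttered reads alike;
- **off-target reads** at `off_target_rate` (default 0.02), replaced by a
  random allele of another locus.

Quality strings are constant (the pipeline ignores them). All randomness
flows from one `numpy` generator, so a fixed seed reproduces FASTQ output
byte for byte.

What the generator does **not** model: position-dependent quality decay,
PCR chimeras, plus-one-unit stutter (off by default), primer-dimer and
adapter artifacts, and template competition between loci in multiplexed
reactions. Passing round-trip tests therefore demonstrates correctness of
the filtering logic under the modeled error processes, not performance on
real fecal-sample libraries, where input DNA quality dominates.

## Verification sizes and numerical choices

The test-suite and acceptance-script problem sizes are chosen to exercise
every code path at realistic coverage while completing in minutes on one
CPU: exact-recovery runs use 20 individuals × 8 loci × 3 seeds at
coverage 2000 (480 genotypes); the stutter sweep uses 6 individuals with
substitution/indel/off-target rates zeroed to isolate the threshold
behavior (at coverage 2000 the binomial noise of the stutter:allele ratio
at rate 0.25 is ≈ 0.01, several standard deviations clear of the 1/3
boundary); the brute-force oracle comparison uses 1000 random ≤10-sequence
tables; trio checks use 500 trios over 60 founders.

Numerical conventions worth stating: the artifact ratio test is strict
(`count(s) < ratio × count(a)`), the allele-fraction test inclusive
(`≥`), and the locus read floor strict (`> min_locus_reads`) — a filtered
total of exactly 500 is a no-call and a count at exactly one-third of a
source is retained. Since `float(1/3) < 1/3` exactly, the default ratio
never misclassifies integer counts sitting exactly on the boundary. All
orderings use (descending count, lexicographic sequence) so every result
is deterministic and permutation-invariant.

## Known limitations

- Only diploid calling (at most two alleles) is supported; polyploid or
  mixed-sample deconvolution is out of scope.
- The stutter rule models deletions only; a plus-one-unit slippage
  product above the 5% fraction and below no other rule would survive to
  stage 2 and be reported (it would then need the top-2 rule or manual
  review to remove).
- Primer matching allows substitutions but not indels; a read with an
  indel inside the primer is unassigned.
- Identification compares allele labels/sequences exactly; it does not
  model genotyping uncertainty probabilistically (no likelihood-based
  paternity statistics, Hardy–Weinberg tests, or relatedness estimators).
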