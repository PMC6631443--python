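# Methods

## The phenomenon being modelled

When two genomic regions are nearly identical, a read drawn from one of
them often shows no base that distinguishes the copies within its own
window. A best-match aligner then faces a score tie and must choose a
placement arbitrarily; with paired reads whose windows avoid every
inter-copy difference the whole pair is ambiguous. Reads carrying a
true difference relative to the reference — an individual's variant
inside a paralog, or an inter-copy difference site — deposit that
difference wherever they land. The result is a class of SNV calls that
recur at fixed sites of a given genome but only intermittently across
replicate analyses: recurrent false positives (RFPs). `rfpsim`
reproduces this end to end in a fully synthetic, ground-truthed setting
and implements the two detection routes (repeated simulation rounds for
one genome; population frequency across a cohort) plus the downstream
analyses (accumulation, alignability association, read-length
dependence, catalogue comparison, blacklist filtering).

## Synthetic genomes (genome_forge)

A genome is a single contig of i.i.d. background sequence (GC fraction
configurable, default 0.5) into which two kinds of regions are placed
in random order with randomized gaps:

- **Paralog families.** Each family is a duplicated block of
  `copy_length` bases. Copy 0 is the ancestor; each further copy flips
  every position independently with probability `1 − paralog_identity`
  to a uniformly chosen different base. Every resulting difference
  site, with its per-copy alleles, is recorded in the *paralog ledger*;
  the realized identity `1 − n_diff/copy_length` is exact by
  construction. The exon-like target of a copy is the block minus a
  `pad_length` (default 325 bp) margin on each side, so the duplicated
  unit extends into the non-coding flanks — as it does around recently
  duplicated genes, where paralogy covers UTRs and surrounding
  sequence. A copy flagged as pseudogene-like is present in the
  reference but contributes no target: it is never sequenced, only
  aligned to.
- **Unique targets.** Exon-sized background intervals. Their number is
  auto-sized to fill roughly 70% of the space left by the paralog
  blocks (it can be set explicitly). These exist so that null controls
  and out-of-paralog variants have somewhere to live; gaps between
  regions always exceed twice the pad so padded targets never overlap.

Individuals are derived by planting `n_private_snvs` SNVs uniformly
over target positions — a chosen fraction inside paralog copies —
with alleles uniform over the three alternatives. Ledger difference
sites are excluded from the placement pool so planted alleles never
coincide with inter-copy differences. Zygosity defaults to homozygous
(the inbred-strain analogue); het variants live on one of two realized
haplotypes. Applying the variant list to the reference reproduces the
haplotypes exactly, which the tests verify.

## Read simulation (read_sampler)

Fragments are sampled with replacement, uniformly over the padded
target space (intervals weighted by length), one haplotype per
fragment, fragment length Normal(500, 50) truncated to
[2·read_length, 2000]. Defaults: 120 bp mates, 1% per-base
substitution error to a uniformly chosen different base, constant
Q25 base qualities (callers must not rely on quality variation),
coverage expressed in sequenced bases over the target space.
No indels are simulated. Fragments longer than their interval are
truncated to it (with a warning) rather than resampled.

## Alignment and the tie contract (micro_aligner)

Seeds are exact k-mers (default k = 21) at read offsets
{0, ⌊L/3⌋, ⌊2L/3⌋}, looked up on both strands in a full-genome index;
every seed hit is extended by ungapped Hamming comparison, N counting
as a mismatch. A placement is kept if its mismatch count is at most
`max_mismatch = ⌈3 + 4·error_rate·L⌉` (8 at the defaults) — generous
enough that true placements survive 1% error. MAPQ is
`min(60, 10·(second_best − best) + 20)` for a unique best, 0 for a tie;
the monotone-in-score-gap form is a design choice, only the tie → 0
contract matters downstream.

Ties are broken uniformly by a counter-based draw keyed on
(master seed, round index, read id), so rounds are order-independent
and reproducible, and repeated draws over independent streams are
uniform (verified by chi-square).

**Pairing.** Each mate is scored and placed independently: a mate with
a unique best placement anchors itself, and a tied mate is resolved by
its own random draw. Only when *both* mates are tied and their
candidate sets pair up into proper pairs is the pair placed as a unit
with a single draw. The alternative — joint score with a hard proper-
pair preference — would let an informative mate drag its ambiguous
partner to the "right" copy, which production aligners cannot reliably
do either (mate rescue operates on score, and score is exactly what a
tie lacks); it would also make the effective ambiguity footprint the
union of both mate windows, roughly squaring the clean-window
probability and suppressing the miscall mechanism far below what is
observed in real data at ~99% identity. Per-mate placement keeps the
ambiguity footprint at one read length (clean-window probability
`identity^L`, ≈0.30 at 0.99/120 bp), which is the regime in which the
phenomenon lives. Properness (FR orientation, implied fragment within
mean ± 4 sd, same contig) is recorded as a flag after placement.

An exhaustive Hamming scan over every position and strand serves as the
oracle in tests: for mapped reads the best score, tie-set size and
chosen placement must match it exactly.

## Pileup and calling (pileup_caller)

Duplicate fragments (identical mate positions and strands) are
collapsed before piling (rmdup), and reads below `min_mapq` are
excluded — the default 0 *includes* tied reads, which is precisely what
lets misassigned reads reach the caller; `min_mapq=1` is the
suppression control. Two independent rules:

- **Caller A (threshold):** emit a non-reference allele when
  depth ≥ 5, allele count ≥ 3 and allele fraction ≥ 0.2; qual = count.
- **Caller B (likelihood):** per site, Binomial(depth, ·) likelihoods
  for genotypes RR/RA/AA with alt-read probabilities ε, 0.5 and 1−ε
  (ε = 0.01); call when the best non-RR likelihood exceeds RR by a
  factor ≥ 10; qual = 10·log10 of the ratio.

The two rules deliberately differ in philosophy so that their
intersection semantics can be studied: A's depth gate makes it robust
to thin coverage but prone to dropout when tied reads are removed;
B calls confidently at low depth and therefore picks up recurrent
error-driven calls at coverage edges. Calls are exchanged as
VCF 4.2.

## Classification and accumulation (rfp_engine)

Round r derives its sampling seed from (master seed, r); the union of
per-round call sets forms a boolean key × round matrix. Classification
uses the call frequency f with *strict* intermediate inequalities:
consistent at f ≥ 0.95, sporadic at f ≤ 0.05, RFP strictly between.
Consistent keys are retained in the catalogue (flagged), matching the
downstream step that discards them as true strain variation.

The accumulation curve counts cumulative unique *candidate* keys per
round, where the candidate universe is fixed at the end of the run as
the intermediate-frequency keys of the final matrix (a fixed-endpoint
definition that makes the curve reproducible); `candidates="all"`
disables the filter. λ̂ is the sample mean of per-round increments for
rounds ≥ 2 — round 1 is burn-in, revealing the standing catalogue
rather than the discovery rate — and the dispersion index is their
sample variance over λ̂. `fraction_discovered(n_small, n_large)` is the
saturation ratio of the curve; for independent per-key call probability
p it has the closed form `(1−(1−p)^n_small)/(1−(1−p)^n_large)`, which
the tests verify (p = 0.11 gives ≈0.69 for 10 vs 100 rounds, the
saturation level that makes a ten-round protocol worthwhile).

## Mechanism oracle

`predicted_miscall_sites` computes, from ledger plus truth alone, every
key a misassigned read could recurrently deposit: for each ordered pair
of copies (source → destination; pseudogenes are never a source, since
they are not sequenced), the positions where the *individual's* source
copy differs from the destination's reference base, emitted as
(destination position, destination ref, source allele). This covers
both reference difference sites and the homologs of the individual's
in-paralog variants. In practice the recurrent miscalls are almost
entirely of the second kind: a read must match the copy it is placed on
at every difference site it covers (that is what "best match" means),
so depositing a *sister-copy allele at a reference difference site*
requires a read spanning two difference sites with an error at exactly
one — second-order rare at 1% error and 30×, and visible only as
sporadic-class noise. A variant-carrying read, by contrast, mismatches
*both* copies equally at its variant position and ties whenever its
window is otherwise clean, so the individual's own in-paralog variation
is the dominant source of recurrent miscalls — which is also why
individuals genetically farther from the reference generate more RFPs,
and why catalogues are individual-specific.

## Study scenarios and problem sizes

The canonical scenarios (module `rfpsim.scenarios`) fix the study
conditions: 120 bp reads, 1% error, 30× base coverage, 325 bp pads,
caller A, 5%/95% thresholds.

- **Null control:** 200 kb, no paralogs, 220 planted hom SNVs,
  30 rounds. Expected outcome: zero RFP-class keys (three identical
  error reads at one site in >5% of rounds is vanishingly unlikely) and
  ≥99% of planted variants consistent.
- **Mechanism:** 100 kb, one family of two 8 kb copies at 0.99
  identity, 80 hom SNVs half inside the copies, 30 rounds.
- **Sweep/accumulation genome:** 60 kb, two 6 kb copies at 0.99, 60
  SNVs two-thirds in-paralog; read-length sweep 80/100/120/140 bp at
  matched base coverage over 5 master seeds; accumulation from a
  100-round run.
- **Individual pairs:** same genome class; two individuals share a
  30-SNV background and carry 5/15/30 private in-paralog SNVs each
  (three seeds per level).

Genome sizes are desk-scale stand-ins for an exome chosen so a full
multi-round run completes in seconds to minutes; the mechanism depends
on local window statistics (identity, read length, error rate,
coverage), not genome size, so scaling down the genome scales the
number of RFP sites, not their per-site behaviour.

One quantity is genuinely a fixed-genome property: the read-length
trend. Lengthening reads both removes marginal sites from the
intermittent band (their windows start crossing difference sites) and
adds formerly fully-ambiguous sites into it (their call frequency drops
below 95%); which flux wins depends on the realized spacing of
difference sites around the miscall-prone positions. With the few dozen
sites of a desk-scale genome, individual realizations can flatten or
even reverse the net decrease. The sweep and the saturation/accumulation
analyses are therefore defined on the fixed canonical study genome with
the simulation seed varying — the same design as measuring one
individual's genome at several read lengths — while the null, mechanism,
suppression and individual-pair analyses hold for any generated genome.

## What the synthetic setting does and does not show

The generator reproduces the ingredients the mechanism needs: paralogy
at realistic identity extending into non-coding flanks, pseudogene-like
unsequenced copies, individual-specific variation inside paralogs,
uniform redundant sampling and i.i.d. substitution error. It omits
indels, quality-score structure, GC-coverage bias, capture
inefficiency, divergence hotspots between real paralogs, and gapped or
quality-aware alignment. Passing tests therefore demonstrate the causal
chain (ties → misassignment → recurrent intermittent calls, removable
by tie-exclusion or blacklisting) and the qualitative dependencies
(read length, divergence, individual specificity); they do not
calibrate absolute RFP counts for any real genome.

## Numerical and design notes

- Coordinates are 0-based half-open internally; SAM/VCF/TSV emissions
  are 1-based.
- Frequencies are compared to thresholds as plain doubles; `k/N`
  versus the literal thresholds is exact for the boundary cases used
  (5/100, 95/100).
- The alignability score of a *position* is 1/occurrences of the k-mer
  starting there (k defaults to the run's read length). For the
  association test a site is scored as the mean over all windows
  *covering* it, since a read calling a base may start anywhere in the
  preceding k−1 positions; the start-window variant is available. The
  Welch one-sided test is cross-checked against a direct
  Welch–Satterthwaite/t-CDF computation.
- Excluding MAPQ-0 reads (suppression control) removes the miscall
  pathway entirely but causes intermittent dropout of true variants in
  highly ambiguous stretches (surviving depth falls below caller A's
  gate). The suppression analysis therefore reports the reduction of
  miscall RFP keys (RFP keys not in the planted truth) and the dropout
  count separately.
- Similarity between catalogues is Jaccard on RFP key sets; the metric
  is pluggable.
- With both input sets empty, similarity is defined as 1 with a
  warning; an accumulation denominator of zero raises rather than
  returning a value.

## Known limitations

Single-contig genomes by default (multi-contig is supported by the data
structures); no gapped alignment, BAQ or quality-aware calling; exact-
match (mismatch-intolerant) alignability; substitution-only error
model; tie probabilities of real aligners (suboptimal-hit heuristics,
soft clipping) are not modelled beyond the uniform-assignment contract.
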