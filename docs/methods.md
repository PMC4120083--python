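# Methods

## The measurement problem

Conventional bisulfite sequencing reads one strand per molecule, so a
partially methylated CpG position cannot distinguish (a) strand-asymmetric
hemi-methylation within single molecules, (b) allelic differences within a
cell, and (c) cell-to-cell heterogeneity. Hairpin bisulfite sequencing links
the two strands of each fragment with a hairpin adaptor before conversion, so
one read pair observes both cytosines of every CpG dyad in one molecule.
Per-dyad counts of the four patterns (methylated/methylated, two
hemi-methylated forms, unmethylated/unmethylated) then separate these cases:
case (a) drives the **methylation fidelity** `MF = (nMM + nUU) / depth`
toward its theoretical minimum `|2·ML − 1|`, while cases (b) and (c) keep
`MF = 1` at any methylation level.

## Recovery model

Both arms of a pair are images of one fragment, so they are globally aligned
after collapsing the bisulfite ambiguity (C→T and G→A), making conversion
differences invisible to the aligner while real differences still count.

* **Hairpin trimming.** Reads are scanned for the adaptor
  (`CGCCGGCGGCAAGTGAAGCCGCCGGCGT`, the biotin-dT of the stem-loop written as
  plain T) in raw, C→T and G→A form, for both the adaptor and its reverse
  complement (read 2 traverses the complementary PCR strand), allowing up to
  2 mismatches; partial adaptor prefixes at the 3' end are trimmed when at
  least 8 bases match exactly in the converted alphabet. Arms shorter than
  40 bp after trimming are discarded.
* **Alignment.** Global Needleman–Wunsch with affine gaps (Gotoh; match +1,
  mismatch −1, gap open −2, gap extend −1; a run of L gaps costs
  open + (L−1)·extend). The scores are configurable; the defaults assume
  arms derive from one molecule so indels are rare. Traceback ties break
  deterministically preferring diagonal, then gap-in-arm2, then gap-in-arm1.
  Terminal-gap overhangs are trimmed, and identity is computed in the reduced
  alphabet over the remaining both-base columns; pairs under 90% identity
  are discarded. Because identity is defined on the trimmed core, a
  substitution at the extreme end of an arm can be realigned as an overhang
  and trimmed, occasionally *raising* identity — interior substitutions can
  only lower it.
* **Recovery.** Each aligned column has at most one consistent pre-image:
  (A,A)→A; (T,T)→T; (C,C)→C with a methylated Watson call; (T,C)→C
  unmethylated; (G,G)→G methylated Crick; (G,A)→G unmethylated. Any other
  combination, and any gap column, recovers N with no call: this preserves
  the rest of the molecule rather than discarding it.
* **Conversion filter.** Molecules with more than 3 methylated non-CpG
  cytosines on either strand arm are discarded as unconverted. The filter
  runs after recovery (context is needed to recognise non-CpG cytosines) and
  before mapping; CHG and CHH are counted jointly. Context at the very ends
  of a molecule is judged from the recovered sequence alone, so a CpG whose
  G falls just outside the molecule counts as non-CpG there — at most one
  such position per arm end, well under the threshold.
* **Mapping.** Recovered sequences are placed by an internal exhaustive
  forward-strand matcher (≤2 mismatches, N as wildcard, unique hit
  required). This suits desk-scale references; genome-scale data would be
  mapped externally and ingested by setting each molecule's locus directly.

Every read pair receives exactly one terminal status, in the fixed order
SHORT → LOW_IDENTITY → UNCONVERTED → UNMAPPED/MULTIMAPPED → ACCEPTED.

## Statistics

* **Tallies.** Calls accumulate per (position, strand) with context
  (CpG/CHG/CHH) taken from the reference, never from reads; positions where
  the recovered base disagrees with the reference are masked (SNP masking).
  At each reference CG, the Watson and Crick calls of one molecule merge
  into one of nMM/nMU/nUM/nUU.
* **Non-conversion.** The per-context rate `r` is the pooled methylated
  fraction over the unmethylated spike-in control; corrected
  `ML = max(0, (ML − r)/(1 − r))`, applied per context. The correction is a
  population-level bias removal: individual shallow sites with one retained
  C legitimately stay positive after correction.
* **Depth filter.** A dyad needs ≥5 read-pair observations; each pair covers
  both strands, so this is a 10× depth requirement. The pair interpretation
  (rather than 5 strand observations) is configurable.
* **Caller.** Site p-values are binomial tails `P(X ≥ n_meth)` under
  `X ~ Binomial(depth, p_null)` with `p_null` the non-conversion-plus-error
  rate; Benjamini–Hochberg is applied within each context at FDR 0.01.
* **Regional statistics** pool counts across sites before applying the
  ML/MF formulas (count-weighted, not mean-of-fractions).
* **Strand concordance** is the phi coefficient of the pooled 2×2 table of
  paired Watson/Crick calls. CpG dyads pair (i, i+1); CHG sites pair
  (i, i+2) when both sides read CHG (the CCG/CGG edge case is excluded
  because its opposite-strand cytosine is CpG-context). CHH has no
  strand-symmetric cytosine, so CHH concordance is undefined and requesting
  it raises an error.
* **Sample comparison** reports fractions of shared depth-filtered dyads
  whose ML or MF changes by more than a threshold (default 20%) — purely
  descriptive, no hypothesis test, matching how such deltas are usually
  reported for this assay.

## Genomic context

Coordinates are 0-based half-open everywhere; BED/bedGraph exports are
native. Promoters are the 1 kb upstream of each TSS on the coding strand;
CGI shores are 2-kb flanks (a conventional width) minus the island;
intergenic space excludes 10-kb genic flanks. Element profiles use 20 equal
bins (strand-flipped for minus-strand elements; per-element pooled values
averaged bin-wise across elements; elements shorter than the bin count are
skipped) or 200-bp windows tiled around element centers. Dyad groups
(fully unmethylated / fully methylated / half-methylated with 0% or 100%
fidelity / other) use an exact tolerance by default, configurable because
finite depth makes near-boundary values common; the half-methylation band
defaults to ML ∈ [0.4, 0.6]. The joint ML×MF distribution uses 10 ML
intervals with 20-bin MF histograms and summary fractions (MF ≥ 0.9, MF
within 0.1 of the theoretical minimum). Correlating non-CpG ML with nearby
CpG ML is done by composing `region_stats` over windows rather than a
dedicated operation.

## Simulator

The generator emulates the assay's essential statistics, not the instrument:

* fragments are Normal(200, 50) bp, reflecting sonication to ~200 bp, with a
  100-bp size-selection floor by default — the real protocol size-selects
  adaptor-ligated molecules well above read length, which matters because a
  fragment leaving fewer than 8 adaptor bases at a read's 3' end falls below
  the minimum trimmable overlap and those residual bases would corrupt the
  recovered tail (a limitation shared by any overlap-based trimmer; lower
  `min_fragment_length` to study the read-through regime);
* each CpG dyad draws one of the four molecule states per molecule from its
  truth mixture, independently across molecules and dyads — within-molecule
  correlation between neighbouring dyads is deliberately not modelled, so
  tests validate per-site statistics, not spatial co-methylation;
* non-CpG cytosines are methylated independently per strand at a configurable
  rate (default 0.004, a realistic stem-cell-scale mean non-CpG level);
* bisulfite chemistry retains unmethylated Cs with per-context probability
  `r` (defaults 1.03% / 1.18% / 1.12% for CpG/CHG/CHH, realistic kit-scale
  rates); 5-hmC is not modelled separately since regular bisulfite cannot
  distinguish it from 5-mC;
* a fraction of pairs (default 10⁻⁴, the usual spike-in proportion) come
  from a fully unmethylated control reference and are flagged in the truth
  table;
* read 2 is emitted directly in Watson orientation; sequencing error is a
  uniform substitution (default 10⁻³); indel errors, PCR duplicates, and
  quality-score variation are not modelled (qualities are constant Q40), and
  restriction-digest CG enrichment is off by default since it shapes
  coverage, not the computation.

What passing tests therefore show: the recovery chain inverts the generative
chemistry exactly in the noise-free limit, estimators are calibrated against
known mixtures, and filters reject what they are designed to reject. What
they do not show: robustness to indels, mapping artefacts of repetitive
genomes, or spatially correlated methylation — all properties of real data
the generator does not emulate.

## Numerical and design choices

* The non-conversion-corrected ML uses the standard `(ML − r)/(1 − r)` form
  floored at zero; contexts are corrected separately.
* Zero-depth sites, zero-variance concordance tables, zero-coverage control
  contexts, and windows without C or G all return NaN ("undefined, flagged")
  rather than raising, except where an empty input makes the whole operation
  meaningless (empty expression table, disjoint sample comparison), which is
  an error.
* Expression groups: group 1 is exactly zero expression; remaining genes are
  split into quantile groups whose sizes differ by at most one, ties broken
  by gene identifier for determinism.
* One top-level pipeline seed derives all stage seeds, making full runs
  byte-reproducible.
* Problem sizes in the test-suite and acceptance script (50-kb references,
  2,000-pair libraries, 10⁴-site caller nulls, 200-pair-deep estimator
  checks) are chosen so each property is measured with comfortable
  statistical margin while a full run stays interactive on a laptop.

## Known limitations

* Forward-strand-only mapping: the simulator emits Watson-frame pairs, and
  the internal matcher mirrors that; reverse-strand placement is an ingest
  concern.
* Residual ≤7-bp adaptor contamination at read 3' ends is undetectable by
  overlap trimming (see above).
* The binomial caller assumes independent strand observations; at CpG dyads
  the two strand calls of one molecule are correlated under high fidelity,
  so site-level depth is not fully independent evidence.
* No smoothing or imputation of low-depth sites, and no between-sample
  hypothesis testing — deltas are descriptive.
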