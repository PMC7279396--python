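# Methods

This note documents the models, conventions and design choices behind
`rootedit`, and what its synthetic-data tests do and do not demonstrate
about real data.

## Coordinate frame and cut model

All positions are 0-based half-open in amplicon coordinates internally;
report writers use 1-based closed intervals. A guide site is a 20-nt
protospacer that must occur exactly once on its stated strand with an NGG
PAM immediately 3′. The cut is modelled as the canonical SpCas9 blunt cut
between positions 17 and 18 of the protospacer (3 bp 5′ of the PAM on the
protospacer strand); `cut_pos` is the coordinate of the cut bond and can
be overridden in the locus config. The inter-guide span is the distance
between the two cut bonds.

Edits are attributed to a guide when they overlap a window of ±10 bp
around its cut (config-overridable). The window value is a pragmatic
choice: NHEJ products concentrate within a few bp of the cut, and 10 bp
keeps the two windows of a 54–64 bp dual-guide design disjoint. An
"inter-guide dropout" is a deletion whose interval contains both cut
bonds — the expected product of simultaneous cutting.

## Event calling

Reads are near-full-length clones of the amplicon, so the caller uses a
global pairwise alignment with affine gap penalties (match +2, mismatch
−3, gap open −10, gap extend −1; the open penalty applies to the first
gapped base, extension to each subsequent one). The first optimal
alignment reported by the aligner is taken; placement ambiguity is then
removed by left-aligning every indel (shift left while the flanking
reference base matches), which is the same canonical form the simulator
applies to its planted truth. Left-alignment is floor-bounded so an indel
never slides past a preceding event; this keeps normalization
sequence-preserving for multi-event reads, and applying a called event
list back onto the amplicon always reproduces the read.

A read is rejected as unalignable when its length is outside 0.3–2.0×
the amplicon or when fewer than 60% of alignment columns are matches.
Counting all columns (gap columns included) in the denominator matters:
random DNA is shredded by the aligner into many short gapped segments
whose non-gap identity is deceptively high (~65%), while its all-column
identity is ~40%. Every read produced by the simulator's editing model
stays above ~0.7.

Maximal mismatch runs become single substitution events (size = run
length). Events that touch neither guide window are diverted to a
diagnostics channel rather than entering the allele signature: isolated
distant mismatches are the signature of Sanger/PCR noise, and a
subclone's "edited" status should not depend on them. Reads with
identical normalized event lists collapse into one allele; the
empty-event allele is WT. `min_support` defaults to 1 — singleton alleles
are counted, as in manual subclone scoring — with low-support alleles
flagged rather than dropped.

## Protein consequences

Events are clipped to the CDS segments and applied to the wild-type
coding sequence; both wild-type and mutant coding sequences are extended
with the amplicon sequence downstream of the CDS so a frameshifted frame
can run to its stop, and translated with the standard code. A premature
stop is a first stop codon at an earlier amino-acid index than the
wild-type stop. Significance is hierarchical: frameshift (net coding
indel ≢ 0 mod 3) > ≥15 bp indel without frameshift > everything else.
The two size thresholds in this package are deliberately independent
constants: the mutation-spectrum tables split sizes at ≤15/>15 bp while
the protein-level table uses ≥15 bp, so an exactly-15-bp deletion is
"small" in the spectrum and significant at the protein level. Events
only partly inside the CDS contribute only their CDS-overlapping portion
to the net indel and are flagged `partial_cds`.

## Genotype taxonomy

A diploid transformant maps to WT/WT, homozygous, biallelic, monoallelic
or one of two chimera classes (≥3 distinct alleles, with/without WT);
knock-out requires that no WT allele was observed. Homozygous versus an
under-sampled biallelic or monoallelic plant is undecidable from
subclones alone, so a single edited allele is only *confirmed*
homozygous at support ≥ `homozygote_min` (default 5 subclones);
otherwise the call keeps the homozygous shape with an `unconfirmed`
annotation. Class percentages are reported over all transgenic plants
and, in a second column, over edited plants, because both denominators
are in common use. Percentages round half-up to one decimal so that
printed values are exactly reproducible from the counts.

Table columns for guide attribution use inclusion semantics: the sgRNA1
column counts members that touch sgRNA1 including those that also touch
sgRNA2, so per-kind totals obey total = sg1 + sg2 − sg1&2.

## Degenerate-trace decoding

Direct sequencing of a mixed two-allele amplicon superposes the traces;
`make_degenerate` models this as a position-wise superposition after
anchoring all traces at the read start, each allele walking its own
coordinates (so a heterozygous indel yields IUPAC codes from its
position onward; beyond a shorter allele's end the longer trace reads
alone). The decoder inverts this by hypothesis enumeration: the
consensus-to-amplicon length difference fixes the net shift of the
larger allele; candidate single indels are anchored near the guide
windows (or spanning both cuts) and pinned to the first ambiguous
position up to a 12-bp homopolymer slack; the partner allele is then
reconstructed base-by-base from the ambiguity codes and checked for a
plausible structure (WT, one indel, or short substitution runs inside
the guide windows). A candidate pair is accepted only if its
re-superposition reproduces the consensus end to end, and only if it is
unique — zero or multiple survivors return `undecodable`.

Scope: pairs in which at most one allele carries an insertion are
searched (WT + single indel, substitution-only partners, and
deletion/deletion pairs); both-insertion pairs return undecodable.
Consensus strings containing a position that requires three or more
superposed bases are rejected as `chimeric` — the defining signal of a
>2-allele template. Note a true three-allele mix in which two alleles
have equal net shift and nested positions can superpose to a string
identical to a valid biallelic trace; no decoder can detect those from
the trace alone, and the tests construct chimeric cases with genuine
three-allele structure.

## FTIR preprocessing and PLS-DA

Spectra are processed per sample, in order: baseline correction
(rubberband — the lower convex hull interpolated across the grid — by
default; a low-order polynomial fit as the alternative), unit-area
normalization over the analysis range, and offset correction
(subtracting the per-spectrum minimum). The analysis range defaults to
800–4000 cm⁻¹. Replicate spectra are averaged before modelling.

The discriminant model is NIPALS PLS2: the column-centered absorbance
matrix is regressed against centered one-hot group indicators, with X
deflation after each component; per-component explained X-variance is
reported. Convergence tolerance is 1e-10 with at most 500 iterations;
the implementation is cross-checked in the test suite against an
independent PLS implementation (scores agree to machine precision).
Scores of distinct components are orthogonal by construction and the
per-component explained variance is positive with cumulative ≤ 100%.

Discriminant bands are wavenumbers whose |loading| on component 1 or 2
exceeds the 0.95 quantile of that component's |loading| distribution
(config-exposed); contiguous grid runs merge to their extremum; each
band's direction is the sign of the group-median absorbance difference
at that wavenumber, and bands are annotated from a bundled table of
cell-wall region assignments (polysaccharide C–O ~1000–1180, lignin
aromatic ~1510 and ~1595, carbonyl ~1700–1750, C–H and O–H stretch
regions).

## Synthetic-data model

The simulator defines the conditions under which the pipeline is tested:

* Repair outcomes per allele: with probability 0.25 an inter-guide
  dropout (deletion spanning both cuts, plus 0–3 bp of uniform flank
  jitter); otherwise each guide independently draws small deletion
  (0.30), large deletion (0.10), small insertion (0.08), large insertion
  (0.02), substitution run (0.15) or no edit. Small indel sizes are
  geometric(p = 0.5) truncated at 15 bp; large sizes uniform on
  [16, 100]; substitution runs are 1–3 bp with every base changed.
* Plant compositions follow the diploid taxonomy; chimera plants default
  to 3 distinct alleles. The default cohort mixture (5% WT/WT, 5%
  homozygous, 20% biallelic, 30% monoallelic, 15% chimera without WT,
  25% chimera with WT) spans all classes with the chimera and
  monoallelic classes prominent, as observed in hairy-root cohorts.
* Subclones are drawn uniformly (weights exposed) with optional per-base
  substitution noise injected only outside the guide windows, so planted
  truth attribution stays unambiguous and caller false positives are
  measurable in isolation.
* Spectra on the 400–4000 cm⁻¹ grid at 4 cm⁻¹ (901 points): a random
  order-2 polynomial baseline, fixed shared Gaussian peaks emulating a
  cell-wall fingerprint, group-specific amplitude shifts at planted bands
  (default three bands at 5× the white-noise SD), and white noise.
* One root generator seeds everything; per-plant streams are spawned so
  cohort output does not depend on consumption order, and a fixed seed is
  bit-reproducible.

What the synthetic data does *not* model: chromatogram waveforms and
base-quality decay, PCR chimeras, allele-specific amplification bias,
real cell-wall chemistry (the planted bands are statistical, not
chemical), and instrument drift. Passing tests therefore demonstrate the
correctness of the algorithms under a faithful abstraction of the data-
generating process, not performance on raw chromatograms or real spectra.

## Problem sizes and test design

The verification suite uses: 1,000 simulated reads for caller round-trip
fidelity (≥99% exact event recovery; the misses are reads combining a
large deletion with a large insertion, where the alignment is genuinely
ambiguous); 500 plants × 15 subclones for genotype-class recovery (≥95%,
with every miss explained by allele-sampling dropout and the miss count
checked against a multinomial inclusion–exclusion oracle); 200 WT/edited
pairs for decoding; and 20 spectral cohorts of 10 + 10 samples for
planted-band recovery (median 3/3 within 2 grid steps) with 20 matched
null cohorts. A null "stable band" is a (position ± 2 grid steps,
direction) pair selected in ≥90% of cohorts: zero-effect cohorts produce
none, while planted bands are stable in 100% — the direction criterion
matters because shared variance structure (baseline residuals,
normalization coupling) makes some positions recur under the null with
random direction.

Report-table fixtures are constructed at known per-category composition
and pushed through the *full* pipeline (sequence synthesis → alignment →
event extraction → collapsing → tabulation), so the printed percentages
in the verification suite are recomputed, not asserted constants.
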