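# Methods

## Analysis model

The pipeline treats a Tn-seq experiment as a competition assay read out by
counting.  Each insertion mutant *i* enters the experiment at relative
abundance *a_i*; after the culture completes *D* net population doublings
under a condition in which the mutant has relative fitness *w_i*, its
abundance is

    a_i' ∝ a_i · w_i^D,

renormalized over the population.  Sequencing draws reads approximately
multinomially from these abundances.  Summing reads per gene and dividing
the treated by the untreated sample therefore estimates the per-gene fold
change (w_treated / w_untreated)^D — the competition index (CI).  With the
screen's two-to-four doublings, a fitness ratio of 0.63 maps to a CI near
0.63³ ≈ 0.25, comfortably below the twofold call threshold.

Assumptions: selection is deterministic exponential growth (no drift or
bottleneck term — at the screen's census of ~16,000 cells per mutant,
drift is second-order relative to sampling noise); insertions within a
gene's core region fully inherit that gene's fitness effect; insertions in
gene edges and intergenic space are neutral.

## Pipeline stages and parameters

**Transposon detection.**  The 32-nt transposon end sequence
(`CGATCTAGACCGGGGACTTATCATCCAACCTG`) is located by a minimum-Hamming scan
over every read offset; a match requires at most `max_mismatches` (default
3) mismatches, with N never matching.  Ties go to the leftmost offset of
minimal distance; an `anchor0` option restricts matching to offset 0 for
libraries where the transposon always starts the read.  No quality
filtering is applied — junction reads are accepted or rejected on sequence
identity alone.

**Tag extraction.**  The `tag_length` bases (default 17 nt) after the
match form the genomic tag.  MmeI cleavage yields 16–18 bp of genomic
sequence depending on the site, and published descriptions of this class
of library quote both 16 and 17; the length is a per-run parameter rather
than a constant.  Reads with fewer than `tag_length` bases remaining are
counted `too_short`.

**Mapping.**  Tags are matched exactly (zero mismatches) against an index
of every genomic k-mer on both strands; k-mers containing N are excluded
as unmappable.  Only unique hits are used.  Ambiguous tags (multiplicity
> 1) are discarded by default — a seeded `ambig_mode="random"` exists for
sensitivity analysis only.  The insertion-site coordinate is the genomic
base abutting the transposon: forward-strand k-mer starting at *s* → site
(*s*, +); reverse-strand k-mer occupying [*s*, *s*+k−1] → site
(*s*+k−1, −).  Opposite-strand sites are kept distinct; gene-level sums
make their merging irrelevant, and the WIG track sums strands per
position.

**Gene quantification.**  A site contributes to every gene whose core
region contains its position, on either strand.  The core is the central
80% of the ORF: with gene length L and e = floor(0.1·L), the first and
last e bases are excluded.  `floor` makes genes shorter than 10 bp degrade
to a full-length core instead of an error.  Overlapping cores credit all
covered genes.

**Normalization.**  Intergenic positions are those inside no annotated ORF
(gene edges belong to genes).  Each sample's normalization factor is
NF(s) = min_t I(t) / I(s) over intergenic totals I; the grouping spans the
whole run (both replicates, all conditions) so exactly the minimal
sample(s) get NF = 1.  A `norm_group="replicate"` option normalizes within
replicates instead.  Statistics use unrounded normalized values; printed
sample reports apply NF at three decimals and round totals half away from
zero, reproducing the conventional presentation
`normalized = round(total_reads × NF)`.  A sample with zero intergenic
reads makes normalization undefined and aborts the analysis.

**Filters and classification.**  Genes with a normalized input count
strictly below 100 in either replicate are excluded (comparator
configurable to ≤, since both conventions appear in practice).  Among the
remainder, genes with a nontreated/input ratio below 0.5 in either
replicate (mode configurable to "both") are excluded as growth-impaired —
their depletion is not treatment-specific.  CI cutoffs are inclusive
(≤ 0.5, ≥ 2.0) and configurable.  An undefined CI (untreated count 0)
excludes the gene rather than imputing; a pseudocount option exists but
defaults off.  Both replicates must agree in direction for a call.

## Synthetic data

The simulator emulates the study design at desk scale: a uniform-random
genome (default 300 kb — chosen so 150 genes of 300–3000 bp with ≥ 50 bp
intergenic gaps pack reliably at a realistic ~80% coding density), a
library of 5,000 insertions drawn uniformly without replacement from TA
dinucleotides (strand uniform; the junction base begins TA on its strand),
log-normal(0, σ=0.5) initial abundances, D = 3 doublings (the midpoint of
the screen's two-to-four), and 2×10⁶ reads per sample.  Biological
replicates are independent per-site log-normal jitters (σ = 0.1) of the
library composition, shared across the conditions of that replicate.
Reads carry per-base substitution errors on the transposon segment
(default 1%) and tag (default 0), constant quality 'I'.  The genome is
regenerated until ≥ 99% of its 17-mers are unique so tag mapping stays
essentially unambiguous.

What the simulator does not model: sequencing indels, PCR duplicates,
chimeric adapters, MmeI length heterogeneity, positional insertion bias
beyond TA targeting, and genetic drift or population bottlenecks.  Passing
recovery tests therefore demonstrates correctness of the accounting,
mapping, normalization and classification arithmetic under the stated
generative model — not robustness to every artifact of real libraries.

Calibration and recovery checks run the count-level path (multinomial site
counts fed directly to quantification), which shares every statistical
step downstream of alignment with the read-level path; the read-level path
is itself exercised end-to-end at full default depth (accounting) and at
smaller depth (site recovery, pipeline determinism).  Problem sizes —
150 genes, 10–20 seeds, 10⁶ reads per sample — keep each experiment to a
few seconds while leaving per-gene counts (~6,000 reads) with sub-2%
sampling noise, far tighter than the twofold decision boundary.

## Numerical choices

Rounding in printed reports is half away from zero.  Reported coordinates
are 1-based inclusive (PTT/GFF3 convention); internal arithmetic is
0-based half-open.  The transposon scan is vectorized over read batches
(padding bytes can never match a base); a property test pins it to the
scalar scan.  Classification is symmetric in replicates, monotone in
treated counts, and invariant to rescaling any single sample's counts
(the normalization factor absorbs the scale), each asserted by tests.

## Known limitations

Single-end reads only; no mismatch-tolerant genomic alignment (by design:
tags are short enough that exact unique matching is the defensible rule,
and the multiplicity of an inexact match is ill-defined at 16–18 nt); no
statistical significance machinery (calls are fold-change concordance, as
in the original screen design — no p-values or FDR); circular-genome
features such as origin-spanning genes are rejected rather than handled.
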