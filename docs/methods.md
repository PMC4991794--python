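# Methods

`stresseq` re-implements, as a tested library, a bespoke bulk-RNA-seq
analysis style used for bacterial two-component-system studies: paired-read
fragment assembly, pseudocount RPKM quantification, MA-statistic
differential-transcription calling with a self-calibrated cutoff, operator
binding-site scanning by ungapped percent identity with sequence-logo
information content, and qRT-PCR crossing-point (CP) reduction with
propagated uncertainty.  This note documents the models, the parameters
that matter, the numerical choices, and what the synthetic benchmark does
and does not show.

## Fragment assembly

Mapped mates are grouped by read name.  A pair mapped to the same reference
whose **outer span** (`max(end) − min(start)`) is at most `max_distance`
(default 1000 bp) becomes one fragment covering the full insert; wider or
cross-reference pairs are discarded; a lone mate is retained as a
single-read fragment.  The fragment strand is the strand of the first
(forward-library) mate — for a lone second mate the mapping strand is
flipped, matching a forward-stranded (TruSeq-style) library.  Read names
with more than one mapping per mate are dropped whole by default
(`multimap="first"` keeps the first mapping) to avoid double counting.
Bookkeeping satisfies the conservation identity
`2·combined + 2·discarded_pairs + singles = accepted reads` on every input,
and the output is independent of record order.

## Counting and RPKM

A fragment is assigned to the CDS containing its **midpoint**
(`floor((start+end−1)/2)`), on the matching strand when counting stranded.
Midpoint assignment is unambiguous for non-overlapping annotations; where
CDSs overlap, a midpoint covered by more than one feature is left
unassigned rather than double-counted (operon-dense genomes make
any-overlap counting treacherous).  The library size is the number of
**all** assembled fragments, assigned or not — "per million mapped" refers
to mapping, not feature assignment.  Expression is

    RPKM = (count + 1) · 10⁹ / (length_bp · total_fragments)

with exactly one pseudo read added per gene and sample, so RPKM is strictly
positive and log-transforms safely.  The pseudocount's influence vanishes
for well-expressed genes and simply floors silent ones.

## Differential-transcription calling

For a two-condition contrast with replicates, each condition is summarised
by the arithmetic mean of replicate RPKMs, then (treatment minus reference)

    M = log₂(mean_trt) − log₂(mean_ref),
    A = (log₂(mean_trt) + log₂(mean_ref)) / 2.

Mean-then-log keeps the reported fold change `2^M` equal to the ratio of
mean expressions.  Genes are **filtered** unless the larger of the two
condition means is ≥ `rpkm_min` (30) and `A > a_min` (2.0); the one-sided
reading of the RPKM filter keeps genes silent in one condition but strong
in the other, which are exactly the interesting case.

The M cutoff is self-calibrated under the assumption that most genes are
not differentially transcribed: the sample (n−1) standard deviation of the
filter-passing M-values estimates the null spread, and

    m_min = 2.58 · STDEV(M)

is the two-sided 1% point of a normal null (≈99% of null genes fall within
±m_min).  The effective cutoff is `max(m_floor, m_min)` with
`m_floor = 1.5` (fold change 2.8 up, 0.4 down); both `m_min` and the floor
are surfaced in the output.  Genes with `M ≥ +m_effective` are `up`,
`M ≤ −m_effective` are `down`, the rest `non`; the four categories
partition the gene set.  No variance-modelled test (negative-binomial GLM)
or multiple-testing correction is applied — the method is a deliberate
re-implementation of the MA-cutoff style, not a replacement for DESeq2-type
inference, and the calibrated cutoff inherits that style's limitations
(the STDEV is inflated by true DE genes, making the cutoff conservative).

Because RPKM normalises by library size, a composition effect is inherent:
when strongly induced genes absorb sequencing capacity, all M-values shift
slightly against them (≈0.2 log₂ units under the default benchmark).  This
is a property of the method, not of the generator.

## Operator-site scanning

Candidate sites are compared to the 16-bp reference operator
`CCGGGCCGCGTCCCGT` (SenR binding site III) by sliding the shorter sequence
along the longer over every full-overlap offset, counting positionwise
matches, and scoring `100 · max(matches) / len(shorter)`, reported
round-half-up to an integer.  Ties prefer the smallest offset.  Characters
outside A/C/G/T never match but count toward length.  Gapped (Clustal-style)
alignment is deliberately out of scope; sites only reproducible with gaps
will score lower here.

`scan_upstream` scores every window of length 10–20 (configurable) of a
200-bp upstream region (coding strand, 5'→3', ending at the base before
the start codon) and resolves overlaps greedily by identity, then length,
then leftmost position, so a full-length exact site beats its own
sub-windows.  `distance_to_start` counts the bases strictly between the
site's 3' end and the start codon.  **Null behaviour**: against a GC-0.72
background (Streptomyces-like) the GC-rich operator produces moderate-
identity windows frequently — roughly a third of random 200-bp regions
contain a ≥85%-identity window, versus ~2% at GC 0.5 — while ≥95%-identity
windows stay rare (<5% of regions).  Identity thresholds for candidate
reporting should therefore be read against this GC-dependent null, not an
intuition formed on uniform sequence.

Aligned site sets are summarised per column by
`bits = 2 − H(freqs)` (Shannon entropy over non-gap characters, log base 2,
range 0–2); the optional small-sample correction subtracts
`3 / (2·ln2·n)` and clamps at zero.

## qRT-PCR analysis

CP values are averaged in two stages — technical replicates within each
biological replicate, then the biological-replicate means — and the
standard deviation is taken across biological-replicate means only, so
technical jitter is absorbed where it belongs.  For a contrast,
`ΔCP = mean_b − mean_a` with `sd_Δ = sqrt(sd_a² + sd_b²)` (uncorrelated
errors) and relative amount `efficiency^(−ΔCP)` with efficiency fixed at 2
(configurable).  No reference-gene normalisation is applied: the design
compares fixed RNA input.  A summary needs ≥2 biological replicates;
missing replicates are tolerated with a warning above that floor.

## Synthetic benchmark

The generator emulates the study design end to end with known truth:

- **Genome**: single replicon, 1000 non-overlapping CDSs on both strands,
  lengths uniform 300–3000 bp, 250-bp intergenic gaps, base composition
  GC 0.72 (Streptomyces-like; also shapes the motif-scan null).
- **Expression**: per-gene lognormal(0, 1) baseline weights; 30 up- and 30
  down-regulated genes planted at |log₂FC| = 3, induced only in the
  stressed wild type.  The mutant strain is simulated as fully deregulated
  (fold change 1 everywhere), the qualitative behaviour a regulator-cluster
  knockout should show, so the four-way contrast logic is testable.
- **Counts**: negative binomial with dispersion 0.01
  (Var = μ + 0.01·μ²) per library; 200 000 fragments per library,
  2 replicates per strain/condition.  With only two replicates the MA
  method has no variance model, so the generator's dispersion is the one
  honest knob controlling how hard recovery is.
- **Reads**: 75-bp mates, Gaussian inserts (200 ± 30 bp, truncated to the
  gene), written as proper SAM with pairing flags; 5% of pairs lose one
  mate (orphans) and 1% are emitted with an outer span > 1 kb to exercise
  the discard rule.
- **Upstream regions**: 200 bp at genome GC, with operator copies planted
  at exact mismatch counts so the expected reported identity is known.
- **CP tables**: 3 biological × 2 technical replicates,
  `CP = 20 − log₂(fold)` plus 0.15-cycle biological and 0.05-cycle
  technical Gaussian noise.

Everything is deterministic under the config seed.  Under these defaults
the wild-type contrast recovers ≥90% of filter-passing planted genes in the
correct direction with ≤1% false calls among nulls, and the mutant contrast
calls ≤1% of planted genes; the full run (8 libraries, ~3 M mapped reads)
takes well under a minute on one CPU.  What this does **not** show: the
generator has no positional coverage bias, rRNA contamination, sequencing
error, batch structure, or genuine biological replicate heterogeneity
beyond the NB dispersion, so recovery rates here are an upper bound on what
identical thresholds would achieve on real libraries.

## Numerical choices and degenerate inputs

- Coordinates are 0-based half-open everywhere internally; GFF3 converts at
  the boundary, and GFF3→internal→GFF3 is the identity on coordinates.
- Reporting precision follows the field's tables: M, A and fold change to
  2 decimals (the ±1.5 bound echoed at 1 decimal), identity as a
  round-half-up integer.
- `calibrate_cutoff` requires ≥2 values; all-identical M-values give
  STDEV 0 and the cutoff falls back to the 1.5 floor.
- A CDS of zero or negative length, an inverted scan length range, an empty
  annotation, a zero library size, a non-positive RPKM, and an empty
  sequence are hard errors; rows missing identifiers and CIGARs without
  reference-consuming operators are skipped with warnings.
- Fold-change values printed in the field's tables are computed from
  *rounded* M-values, so `2^M` at 2 decimals reproduces them only where the
  rounding is self-consistent; the round-trip tests use such rows.
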