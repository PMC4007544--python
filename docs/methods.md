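# Methods

This note documents the models, estimators and numerical choices behind
`repeatscape`, and what the synthetic benchmarks do and do not show.

## The synthetic genome model

`default_olive_spec(genome_size)` scales an olive-like repeat landscape to a
desk-size genome. Six satellite families carry the published unit lengths
(80/178/86/179/218/51 nt) and GC contents (45.4/43.2/36.0/36.0/41.8/33.5%).
Their genome percentages are the published per-family estimates normalised to
the 31.161% read-fraction total for the tandem class (the per-family figures
were estimated independently and sum slightly higher). Per-family copy
numbers are not published anywhere, so the simulator derives
`copy_number = fraction × genome_size / unit_length` — a modelling choice,
not a measured value. Gypsy (20.8%) and Copia (17.8%) families use element
geometries of 500+4000+500 and 350+3600+350 nt; the remainder is i.i.d.
single-copy background at the genome mean GC of 38%.

Every placed copy is mutated from its family consensus by independent
per-site substitutions. The per-family rates (Oe218 0.050, Oe178 0.040,
Oe80 0.030, Oe179 0.015, Oe86 0.012, Oe51 0.010) are chosen to reproduce the
published *ordering* of family variability (Oe218 most diverse, then Oe178
and Oe80, the rest minor) — the absolute π values are only published as a
figure. Oe179 carries a 15% truncated-unit fraction, reflecting its
described truncated copies inside arrays. The mutation/error model is
substitution-only by default: the coverage statistics and π targeted here
are substitution-dominated, and indels would mostly stress the aligner, not
the estimators. Copies are arranged head-to-tail in arrays (4 per family by
default); repeat segments are shuffled and separated by background chunks;
coordinates are 0-based half-open with +/− strands; output is byte-identical
for a fixed seed.

Read simulation is uniform single-end sampling from both strands with
per-base substitution errors; `n_reads = round(coverage × G / L)`. Three read
sets mirror the study design: 8.1 genome equivalents of 75-mers for
mapping-based redundancy estimation, 2.03 equivalents of ~100-mers for
assembly, and 1.0 equivalent of 400-mers (454-like) for satellite monomer
extraction — a full unit of the longer families never fits in a 75-mer.

What the generator does **not** emulate: platform error profiles (homopolymer
errors, quality decay), indels, paired-end structure (a `paired` flag exists
but nothing downstream needs it), higher-order repeat structure, and real
organellar genomes (decoys are arbitrary sequences). Passing recovery tests
therefore demonstrates estimator correctness under a clean substitution
model, not robustness to platform artefacts.

## Assembly

`greedy_assemble` is a deliberately simple greedy overlap-layout-consensus
assembler: exact 12-mer seeds propose ungapped overlaps, the best-scoring
pair (score = matching columns; ties to the smallest contig-id pair) is
merged, and the consensus is a per-column majority over all constituent
reads (ties alphabetical). Cutoffs follow the study: 40 nt minimum overlap,
90% identity within packages, 80% for the cross-package merge. Hot k-mers
are capped (40 occurrences per seed, 60 partner evaluations per new contig)
to keep repeat-heavy inputs tractable; this makes the greedy choice locally
rather than globally optimal, which is irrelevant to the properties asserted.

`split_assemble_merge` partitions reads uniformly at random, assembles each
package, and merges *only the package contigs* (plus singletons ≥ 1,000 nt)
across packages. Dropping unassembled package reads is the point of the
strategy: at high split levels the per-package coverage of single-copy DNA
falls below the overlap threshold while repeat reads still co-assemble, so
retained contigs are repeat-enriched and the mean number of mapped reads per
contig rises with the split level. The trend experiment assembles the 2.03×
set and maps the 8.1× set, matching the study design; with the mapping set
used for assembly the subpackage coverages land in the wrong regime and the
trend disappears.

## Read mapping

`map_reads` is a seed-and-extend mapper with CLC-style acceptance rules.
Candidates are contigs sharing an exact k-mer (default 15) with the read or
its reverse complement; each candidate is aligned by banded edit distance
(edlib, infix mode). Since CLC's exact cost semantics are not recoverable,
alignments are *found* under unit edit costs and then *rescored* with the
configured linear mismatch/deletion/insertion costs (defaults 2/3/3) to rank
hits. A hit must cover ≥ `length_fraction` of the read at ≥ `similarity`
identity (defaults 0.8/0.8). All minimum-cost placements — across contigs
and across equally good positions within a contig — are collected and one is
drawn uniformly with a dedicated seeded generator, so multireads are spread
over repeat copies exactly as the downstream read-fraction arithmetic
assumes.

Two numerical details matter at contig termini. Edit-distance alignment
cannot represent soft clipping, so a read hanging off a contig end either
loses its overhang as spurious gapped alignment or is dropped; both bias
coverage near termini. The mapper therefore (a) gaplessly extends trimmed
terminal insertion runs into adjacent target bases, and (b) explicitly
evaluates clipped *edge placements* (read suffix at contig start, read
prefix at contig end) whenever the interior alignment is absent or costs
more than two mismatches, letting the cheaper representation win. For
coverage measurements on short isolated references (LTR elements), the
length fraction is dropped to 0.2 so terminus-straddling reads contribute
their overlapping bases proportionally; without this the LTR coverage of an
element is underestimated by ~10% through edge ramps.

`calibrate_mapping` sweeps a parameter grid (default mirrors the study's
axes: mismatch cost {2,3}, indel costs {2,3}, length fraction {0.5,0.8,1.0},
similarity {0.8,0.9,0.95}), maps against references of known copy number,
and selects the grid point maximising Pearson r between copy number and
average coverage (ties to the most stringent setting). A best point whose
correlation is not significant at α = 0.05 is flagged unstable.

## Redundancy classes and composition

Average coverage is defined as mapped bases over contig length (the CLC
definition is unstated; this is the standard per-base mean depth reading).
With `E` the expected single-copy coverage, classes are NRC < 2E ≤ MR ≤ 200E
< HR; both boundary values fall in MR, following the "comprised between"
wording. The 200 multiplier is inferred from 1,620 = 200 × 8.1 and exposed
as a parameter. Composition percentages are exact fractions of the total
genomic (non-organellar) read count, formatted at 2 decimals for class
tables and 3 for category tables with round-half-even.

## Satellite analysis

`detect_period` scans self-match fractions over lags (the 1-D analogue of
dot-plot diagonals) and returns the smallest lag ≥ 80% matching, capped at
half the sequence length so two full units support every call.
`extract_units` finds the best local match of the consensus in every read
(both strands) under a +1/−2 scoring approximation with Karlin–Altschul
e-values (λ solved numerically for uniform composition, K = 0.62) against
the read set as database; only the best repeat copy per read is kept, so
each monomer represents a distinct locus; the top `n` (default 100) by
identity are returned. Because selection ranks by similarity to the
consensus, π is a *lower-bound-flavoured* estimate — the same bias the
source procedure accepts and discusses.

Monomers are star-aligned to the consensus (insertions relative to the
reference are dropped, deletions become gaps); star alignment replaces a
full progressive MSA because monomers are near-equal length and the star
projection is deterministic and fast. π uses pairwise deletion of gapped
sites; its SD is the square root of the no-recombination sampling variance
`(n+1)/(3(n−1)L)·π + 2(n²+n+3)/(9n(n−1))·π²` with `L` the mean pairwise
compared length. Units shorter than half the consensus are reported as
truncated and excluded from π (they would contribute mostly missing data).
The NJ tree is scikit-bio's neighbor joining on pairwise-deletion
p-distances; bootstrap support resamples alignment columns with a seeded
generator and counts bipartition recovery.

## LTR : inter-LTR ratio

`find_ltrs` votes for self-match lags with exact 12-mers between the two
halves of an element, extends the best lag's run while identity stays ≥ 85%,
and accepts a pair ≥ 100 nt anchored within 50 nt of both termini.

For the ratio, mapped bases in both LTR intervals are pooled and divided by
the length of *one* LTR (the mean of the two annotated intervals): the two
LTRs of an element are copies of a single genomic sequence family, so an
intact-only family then yields cov_ltr = 2 × cov_inter and the statistic has
expectation `(2N+S)/N`. (Dividing by the summed LTR length would halve the
ratio and make the intact expectation 1, contradicting the statistic's
definition.) Reads straddling interval boundaries contribute by overlapping
bases. An element with only one recovered LTR uses that LTR's length and is
flagged. Ratios within ±0.25 of 2 are called intact-dominated; above,
`S/N = ratio − 2`; below, shared-internal-region — each call carries the
caveat that families sharing LTRs but differing in internal regions cannot
be excluded. Superfamily mean ratios are computed from unrounded per-cluster
ratios and rounded for display (the published means are reproduced only
under this order of operations).

## Annotation, filtering, QC

Library masking tiles each library entry into windows sized to the minimum
hit length (≥ 20 nt, final window flushed to the entry end), places windows
by banded infix alignment, masks found spans and repeats the search so every
copy is found, and merges intervals per category. Window hits must clear a
+1/−2 score of 12 in addition to the identity cutoff — at 20–30 nt the
identity cutoff alone is reachable by chance. Masked fractions are detected
at window resolution.

The organellar rule discards a contig when ≥ 1% of its length is masked by
organellar sequence (the strict reading of "1% similarity"; an `any_hit`
mode is available since the wording is ambiguous). Contig labels take the
largest masked fraction above a 0.2 floor; tandem + transposon above the
floor together ⇒ removed as ambiguous; exact ties resolve by a fixed
priority (tandem > rDNA > LTR > non-LTR > DNA transposon > unknown); a
floor-failing contig with a gene hit becomes gene-like, else no-hit.
Unknown-repeat detection links unclassified sequences sharing a ≥ 40 nt
block at ≥ 90% identity (seeded ungapped check with a best-window fallback)
and reports connected components of size ≥ 2. Assembly QC aligns each
trusted sequence to its best contig (shorter partner as query, terminal
overhangs clipped) and pools alignment columns, mismatches and indels.

## Problem sizes and determinism

The bundled benchmarks run on one CPU in well under a minute each: synthetic
composition/copy-number recovery on a 2 Mb default-composition genome at
8.1× (≈ 216 k reads) profiled against the family references — mirroring the
calibration approach of mapping to known sequences, since greedy all-vs-all
assembly of 216 k reads in pure Python is not a sensible use of anyone's
time; ratio recovery on dedicated families (N=20/S=40 solo test at the
expectation 4.0; an N=60 intact-only family at 2.0, sized so read-sampling
noise at 8× sits well inside the assessment band); and the splitting trend
on a 60 kb genome (2.03× assembly set, splits 1/16/64). The end-to-end
pipeline default is 50 kb. Every random decision traces to a named seed;
rerunning a configuration reproduces every report byte for byte.

## Known limitations

Substitution-only by default; ungapped overlap detection in the assembler;
star alignment discards insertions relative to the consensus; monomer
selection biases π downward; masking resolution is the window size; the
greedy assembler's k-mer caps trade global optimality for speed; no TSD
detection, no insertion dating, no protein-domain annotation.
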