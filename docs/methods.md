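# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind each stage of the pipeline, and what the synthetic-data
generator does and does not emulate.

## Genome model and coordinates

A genome is an ordered list of molecules, each linear or circular. All
coordinates are 1-based inclusive. Two display/encoding conventions follow
the field's tabular style: a minus-strand interval prints descending
(`35,975–25,398`), and an interval wrapping a circular molecule's origin is
encoded with `end > length` internally and printed as an ordered segment
list (`34,939–36,490;1–127`). GC% excludes ambiguous bases from the
denominator, so an all-N molecule reports an undefined (NaN) GC rather
than 0. FASTA carries no topology, so topology comes from a sidecar
mapping or a `circular` token in the description line; GenBank's LOCUS
token is honoured. Trans-spliced genes (segments on different molecules,
or a `trans_splicing` qualifier) are merged into one feature whose
segments concatenate in transcription order.

## Repeat detection

**SSRs.** Perfect microsatellites with unit 1–6 bp above MISA's web
defaults (mono 10, di 6, tri 5, tetra 5, penta 5, hexa 5 copies). The
scanner marks positions where `seq[i] == seq[i+u]`; maximal agreement runs
are period-u stretches. A run is reported only at the motif's fundamental
period (a poly-A run is never also a "AA" dimer run), trimmed to whole
copies, with the motif stored as its lexicographically minimal rotation.
N breaks every run.

**Tandem repeats.** A deliberate period-scan approximation of TRF rather
than a reimplementation of its Smith–Waterman/statistical model: for each
period p, agreement runs in the profile `seq[i] == seq[i+p]` are grown
greedily — a gap is absorbed only while it is shorter than one unit and
the running agreement fraction stays above the threshold — and regions
spanning ≥ 2 units at ≥ `min_match_pct` agreement are reported.
`match_pct` is therefore *adjacent-copy agreement*: the fraction of
positions matching one period ahead. Note one consequence: a single
substitution inside an interior copy breaks **two** adjacent-copy
comparisons (against the previous and the next copy), so a (5 bp)×4 array
with one mid-array substitution scores 13/15 ≈ 86.7%, not 14/15. Reports
at harmonically related periods (one divides the other) covering the same
locus collapse to the fundamental period — a mismatch hits fewer
comparisons at a doubled period and would otherwise always win; among
non-harmonic duplicates the best agreement, then the smaller unit, wins.

**Dispersed repeats.** All maximal exact repeated pairs of length ≥ 30 bp
(configurable; < 8 is refused as a seed explosion), classified direct
(same strand) or palindromic (reverse-complementary). The finder builds
one integer text containing every molecule forward and reverse
complemented — circular molecules virtually doubled — with unique negative
sentinels as separators and at N positions, builds a suffix array by
prefix doubling and the LCP array by Kasai's algorithm, and enumerates
pairs of suffixes whose exact LCP is ≥ the threshold and whose preceding
characters differ. These two conditions are exactly right- and
left-maximality, so sub-repeats of a longer pair are never reported.
Mirror images from the reverse-complement half, shift duplicates from
circular doubling, and loci matching their own reverse complement (true
DNA palindromes) are removed; palindromic pairs are canonicalised with
occurrence 1 on the plus strand, occurrences ordered by (molecule, start).
Exact repeats only: mismatched ("degenerate") repeats are out of scope.
The suite proves set-equality against an independent O(n²) shift-run
enumeration on random sequences.

## Recombination genotyping

For a repeat pair with units U at occurrences 1 and 2, the *primary*
references are `L1·U·R1` and `L2·U·R2` (unit plus `flank_len` = 1000 bp of
flank each side, everything in the unit's orientation — minus-strand
occurrences and their flanks are reverse complemented before assembly; the
default follows the standard 1 kb flank-exchange construction). The
*alternative* references exchange the downstream flanks: `L1·U·R2` and
`L2·U·R1`. Flanks truncate at linear molecule ends and wrap on circular
molecules; occurrences on the same molecule closer than `flank_len` are
flagged `inseparable` and the facing flanks shrink to the gap.

A read *spans* a reference when the window unit ± `anchor` bp aligns
within the read with ≥ `min_identity` overall **and** each anchor region
individually meets `min_identity` — the per-anchor condition is what makes
"completely spans" meaningful, since a read missing one whole anchor could
otherwise pass on whole-window identity alone. Alignment is exact
edit-distance infix alignment (edlib) of each window against the read and
its reverse complement; an exact aligner here is both simpler and strictly
stronger than heuristic seeding, and the windows are small enough that it
is also fast. Defaults `anchor` = 100 bp and `min_identity` = 0.75 target
~10–15% Nanopore error; both are exposed as flags.

Because the repeat unit is identical in all four references, only the
2×`anchor` flanking bases discriminate conformations. The ambiguity rule
is scaled accordingly: a read spanning both conformations is `ambiguous`
when its two best edit distances differ by less than 5% of 2×`anchor`
(10 edits at defaults). Scaling the margin to the whole window would mark
nearly every read ambiguous once the unit is much longer than the anchors,
since the shared unit dominates any whole-window score.

`recombination_screen` tests every pair of length ≥ `min_repeat_len`
(default 100 bp) and flags a pair "recombining" at ≥ 2 distinct
alternative-supporting reads — deliberately permissive and configurable.
The estimated frequency `n_alt/(n_primary+n_alt)` is undefined (reported
as such) with no informative reads. Whether counts should require a
unique best alignment or admit multi-mapping is an open design point; the
unique-best rule with the ambiguity margin is this package's choice.

## Codon usage

Standard genetic code (plant mitochondria), stop codons excluded from the
table; whether to include stops is genuinely ambiguous in the field's
tooling, and exclusion is the documented choice here. Frame-0 codons are
tallied over every annotated CDS occurrence (multi-copy genes count per
occurrence; no deduplication), ambiguous-base codons are skipped with a
logged count. RSCU(c) = x_c / mean over c's synonymous family, so each
observed family's RSCU values sum to the family size (asserted to 1e-9)
and single-codon families (AUG, UGG) are exactly 1 when observed. A family
never observed reports 0 by convention. Reports use RNA spelling.

## Chloroplast→mitochondrion transfers

Local alignment is re-implemented as seed–cluster–extend: exact 20-mer
seeds of each mitochondrial molecule against the chloroplast genome (both
strands, chloroplast treated as circular via virtual doubling), seeds
clustered by diagonal, and the median seed of each cluster extended in
both directions by a banded (half-width 50) affine-gap DP with X-drop
termination (drop 20) and full traceback for match/mismatch/gap-opening
counts. Scoring is megablast-like: match +1, mismatch −2, gap open 2.5,
gap extend 0.5 — all configurable; `min_length` defaults to 28 bp, the
evident reporting floor of such tables. Hits wholly contained in a
higher-scoring hit on both genomes are dropped; chloroplast
inverted-repeat duplicates are two genuine loci and are reported twice.
The identity of every hit is checked in the suite against exact local
Smith–Waterman (Biopython's `PairwiseAligner`, used only as an oracle)
to within 0.5 points.

Like any local aligner, the extension trims alignment ends that score
negatively, so a planted fragment whose mutated copy has substitutions
near its edges may be reported slightly shorter than planted — exact DP
does the same. Gene classification is interval arithmetic on the
chloroplast annotation: complete iff the gene's full span lies inside the
hit's chloroplast interval, partial on any overlap, strongest call kept
per gene within a hit. The transfer summary's total is the plain column
sum over reported hits (no overlap deduplication), and the percentage is
that total over the mitogenome length, rounded to two decimals.

## Synthetic data generator

The generator emulates the study conditions the pipeline is meant for: a
three-molecule genome (60 kb linear + 40 kb circular + 15 kb circular =
115 kb — same architecture as, and roughly a quarter the size of, a real
oak-scale mitogenome, keeping the default test run fast) at GC 0.4572;
SSR and tandem tracks; one long (1.5 kb) "recombinationally active" direct
pair at mixture p = 0.45 (the scale reported for active long repeats),
one silent 300 bp pair and one 120 bp palindromic pair; Nanopore-like
reads with gamma-distributed lengths (shape 2, mean anchored at the
~9.8 kb N50 of field data, minimum 500 bp) and i.i.d. errors
(substitution 0.05, insertion 0.025, deletion 0.025, length-1-geometric
indels); and a 30 kb circular chloroplast partner carrying three planted
homologous fragments (1.2 kb at 99% identity with an inverted-repeat
duplicate, 300 bp at 100%, 150 bp at 92%).

Design choices worth knowing:

* **Boundary hardening.** The bases immediately flanking every planted
  SSR run, repeat occurrence and transfer fragment are forced to break
  the repeat/homology, so each element is maximal by construction and its
  truth coordinates are exactly what an exact scanner must report. Without
  hardening, a planted 40-mer extends by one base with probability ~1/4
  per side and exact-recovery tests would be flaky.
* **Read mixture.** Each read comes from the primary genome with
  probability 1−p, else from the flank-exchanged alternative. Because a
  recombined genome is byte-identical to the primary outside the exchanged
  neighbourhood, alternative reads enter the conformation references only
  with probability (reference length / genome length) and otherwise sample
  the shared sequence — this keeps spanning-read composition
  population-proportional, so p is recoverable without bias.
  `spanning_only=True` restricts starts so every read covers unit +
  margin on both sides (symmetric geometry across conformations), which
  is what the frequency-recovery checks use.
* **Determinism.** Every operation takes one integer seed and builds its
  own `numpy` generator; no global state. Same configuration, same bytes.

What the generator does **not** emulate: homopolymer-biased Nanopore
error profiles, chimeric reads, coverage waves, heteroplasmy gradients
along molecules, nuclear insertions, or mismatched (degenerate) repeats.
Passing the round-trip suite therefore shows the pipeline is correct
under idealised i.i.d. noise at realistic rates and scales — not that it
is robust to every artefact of real sequencing runs.

## Problem sizes and numerical notes

The default test and acceptance runs use the 115 kb genome above with
300–800 reads, 100 random 300–600 bp instances for the dispersed-repeat
oracle equivalence, 100×5 kb for the SSR oracle, and 10 replicates × 500
spanning reads × p ∈ {0.1, 0.5, 0.9} for frequency recovery (within 3
binomial standard errors in ≥ 9/10 replicates). The suffix array is
prefix doubling (O(n log² n) with numpy lexsort), comfortably handling
the ~400 k-character doubled two-strand text of the default genome.
Ties everywhere break deterministically: repeats sort by (−length,
molecule order, start), equal-length longest repeats resolve to the
smaller (molecule, start), preferred codons sort by (−RSCU, codon).
Degenerate inputs have defined behaviour: empty read sets give undefined
(not zero) frequency; genomes without repeats return an empty list and
`longest_repeat` returns None; an all-N molecule has NaN GC; a CDS with a
trailing partial codon is truncated with a warning.
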