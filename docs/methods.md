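# Methods

## Model

A consensus matrix is an ordered list of allowed-nucleotide sets over
{A, C, G, T}, between 4 and 30 positions, written as an IUPAC string
(e.g. `DVVCCAATSNV` for the NF-Y CCAAT box). Positions are partitioned
into an invariant *core* and degenerate *flanks*. By default the core is
the set of singleton positions — for the CCAAT matrix, exactly the CCAAT
pentanucleotide — and can be forced to any contiguous range (`--core a:b`)
for matrices whose invariant block is itself degenerate.

A length-L text window matches under the default **identity-threshold
policy** when

* every core position's character is in its allowed set (no core
  mismatch, ever), and
* the fraction of matching flank positions is **strictly** greater than
  `min_identity` (default 0.82).

The strict inequality is deliberate: with the CCAAT matrix's six flanks,
5/6 ≈ 0.833 is the only attainable value above 0.82 short of a perfect
6/6, so the default policy tolerates at most one flank mismatch. An
alternative **max-mismatch policy** bounds the number of flank mismatches
directly and can restrict them to listed positions.

Both orientations are searched: a reverse-strand hit is a match of the
reverse-complemented matrix (`BNSATTGGBBH`, core `ATTGG`) against the same
text. There is no positional weighting — the model is set membership, not
a PWM — and no TRANSFAC/JASPAR import.

### Handling of N

A text `N` matches nothing by default, so assembly gaps cannot generate
hits; under mismatch-tolerant policies an `N` simply consumes one
mismatch. `MatchPolicy(n_matches_n=True)` relaxes this so `N` matches
positions whose allowed set is the full alphabet. Matching is
case-insensitive (soft-masked genomes); any non-IUPAC genome character is
mapped to `N` at extraction time.

## Coordinate frames

* **Genomic**: 1-based inclusive, as in UCSC-style annotation; gene
  intervals supplied as BED are converted from 0-based half-open on load.
* **Window offsets**: 0-based string indices. Windows are stored in
  transcript (5'→3') orientation — minus-strand windows are
  reverse-complemented at extraction — so "upstream" is always leftwards
  in every downstream computation.
* **Anchor-relative**: signed bp, negative upstream, 0 at the anchor base
  (TSS, pre-miRNA 5' or 3' end).

A window covers `up` bp upstream of the pre-miRNA 5' end and `down` bp
downstream of its 3' end (defaults 60 000 / 5 000). Windows running past a
contig edge are truncated with the lost extent recorded
(`clipped_up`/`clipped_down`) rather than dropping the locus. A hit is
anchored at the **first base** of the matched L-mer in window orientation,
on both strands; this is also the base used for region membership and for
reported distances. Overlapping occurrences are all counted, and a forward
and reverse hit covering the same bases are both reported (the CCAAT
matrix cannot match both orientations at one offset; truly palindromic
matrices report two hits there, which the count semantics make explicit).

Regions (`tss:-500:+500`, `pre5:-3000:+5000`, …) are clipped to the window
before scanning; a hit belongs to a region iff its first base lies inside,
so a match may extend past the right edge. Loci lacking the requested
anchor (no TSS) are skipped and reported, not failed.

## Search algorithms

`scan_brute` tests every offset on every selected strand. `scan_bm`
locates occurrences of the longest invariant core literal with
Boyer–Moore's bad-character rule, then extends each candidate to the full
matrix window and validates it under the policy; matrices without a
singleton run of ≥ 3 bases fall back to brute force with a log notice.
The two are bit-for-bit equivalent (a tested invariant, also
cross-checked against an exact k-mer-expansion oracle). The automatic
switch uses brute force up to 32 768 bp and Boyer–Moore beyond —
a default chosen inside the 30–40 kb band where the approaches break even
on typical inputs — and is overridable (`--algorithm`, `--threshold`).
The containment prescreen (core or its reverse complement as a plain
substring) runs before any scan; a negative prescreen guarantees zero
hits, which is tested on core-free random strings.

Per-locus elapsed time is recorded in milliseconds for reporting parity
but excluded from all determinism comparisons.

## Synthetic data

`mirmotif.simulate` generates desk-scale locus sets with exact ground
truth:

* one contig per locus, strand assigned at random, TSS present with
  probability 0.79 (the fraction of real loci with an annotated TSS in
  the survey this package reimplements) and placed 80–450 bp upstream of
  the pre-miRNA 5' end;
* i.i.d. background at GC 0.41 (human-like) with every occurrence of the
  matrix core — in either orientation — removed by rejection resampling;
* 0–3 planted occurrences per locus drawn from policy-passing strings,
  positions uniform, strands random; after planting, the window is
  checked to contain core occurrences at exactly the planted positions
  (junction artefacts are re-rolled), so the planted set is provably the
  complete hit set;
* scaled default windows of **600 bp up / 50 bp down** and a pre-miRNA
  length of 80 bp, keeping a full simulate → build → scan → report cycle
  under a couple of seconds; full-size 60 kb / 5 kb windows are a
  parameter away and exercise the identical code paths (the scanner is
  O(n) in window length with no size-dependent branching besides the
  documented algorithm switch).

Everything is deterministic under a single seed.

What the generator does **not** emulate: real genomes are not i.i.d. —
repeats, CpG islands and local GC structure produce clustered background
matches that the core-free construction removes by design. Passing the
planted-recovery tests therefore demonstrates the correctness of the
matcher and the coordinate bookkeeping, not the biological specificity of
any matrix on real chromatin.

## Curated worked examples

`mirmotif.examples` packages three small datasets transcribed from the
published CCAAT/NF-Y survey of colorectal-cancer-associated miRNA loci
that this package reimplements: the catalogue of up-regulated mature
miRNAs, the minimal-promoter matrix calls for four in-vivo validated
clusters (with signed TSS distances), and the downstream calls for six
pre-miRNAs. Two discrepancies in that source material are preserved
verbatim and documented rather than patched:

* the promoter strings `ataattggttt` (mir-181a2/181b2 row) and
  `atcccaatcat` (mir-21 row) score only 4/6 flank identity and thus fail
  the stated >82 % rule; this package's classifier applies the rule as
  stated and rejects them, so it reproduces the printed count for the
  mir-301b/130b, mir-17-cluster and pre-miRNA-191 rows but counts 2 of 3
  for the mir-21 row;
* the catalogue's prose total is 118 distinct up-regulated miRNAs, but
  the recoverable printed rows contain 114 distinct names; the
  transcription keeps what is printed.

## Numerical and degenerate-input choices

* `min_identity` is compared with strict `>`; a matrix with no flanks has
  identity 1.0 by convention (a literal pattern either matches its core
  or not).
* Empty regions after clipping, patterns longer than the text, and empty
  texts all yield empty results, not errors.
* Tie-break: when several gene intervals overlap a pre-miRNA, the host
  gene is the first in input order; when several core runs tie for
  longest, the leftmost anchors Boyer–Moore.
* Hits are sorted by (offset, strand) with `+` before `-`.
* Exports are atomic (temp file + rename); TSV fields may not contain
  tabs or newlines (validated), CSV quotes as needed, and both round-trip
  exactly.

## Limitations

* No suffix-array/FM-index or multi-pattern search; the design point is
  exactly brute force plus core-anchored Boyer–Moore.
* No statistical enrichment testing; the reports are raw counts and
  distributions.
* The locus database is flat files; no concurrent writers, no SQL.
* TSS annotations are taken at face value from the input; no attempt is
  made to re-derive promoters from expression data.
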