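# Methods

## Model and coordinate system

A transposon is modelled as a nucleotide sequence with three ordered
features — left ITR, transposase CDS, right ITR — plus transposase binding
regions nested inside the ITRs.  All internal coordinates are 0-based
half-open; every user-facing report uses 1-based positions *within* the
named feature, the convention of the transposon literature.  The CDS
reading frame is an explicit model field (`cds_frame`, default 0) because
the canonical SB transposase region length (1022 nt) is not a codon
multiple, so the frame cannot be inferred from the span.

The packaged reference model (`tssmine.synthetic_data.demo_model`,
`data/tss1_demo_synthetic.yaml`) is a **synthetic** stand-in with SB-like
geometry (227/1022/227 in 1638 nt): a random backbone whose right ITR is a
mildly diverged reverse complement of the left, and whose sequence is
pinned only at the positions that matter for the published Tss1-consensus
difference classes (codons AAA/CGA/AAG/AAG/ATC/AAG at CDS 97–99, 376–378,
382–384, 511–513, 634–636, 643–645; fixed ITR bases at left 31/61/88/105/138
and right 60/87/176).  It is not the real Sleeping Beauty sequence; users
analysing real data supply their own model config.  Binding-region spans
are not publicly tabulated as coordinates, so the packaged spans are
synthetic, editable config values, and every binding-region classification
is reported against the spans actually configured (a model without spans
yields an explicit "unevaluable" flag, never a silent `False`).

## Homology search

The built-in search is a seed-and-extend scheme tuned for permissive
recovery of family members down to ~75% identity:

* **Seeding** — all query *k*-mers (default `word_size=11`) on both
  strands, plus every single-mismatch neighbour when `allow_one_mismatch`
  is set; the target is sampled every `step=5` nt.
* **Seed verification** — each seed match must reach ≥ 65% ungapped
  identity over a ±25-nt window before it is kept.  One-mismatch seeding
  makes the raw random-seed rate on a megabase genome of order 10⁴; the
  verification removes essentially all of them while true copies retain
  hundreds of verified seeds each.
* **Chaining** — verified seeds are single-linkage chained within a
  diagonal band of ±10% of the query length.
* **Extension** — each chain's candidate window is aligned to the query
  with a local (Smith–Waterman) DP under linear gap costs
  (match +1, mismatch −1, gap −2).  The within-row dependency is resolved
  with a running-maximum recurrence, which is exact for linear gaps, so
  rows vectorise.  A score-drop (`xdrop`) parameter is accepted for
  interface compatibility but the DP extension does not need it.
* **Overlap resolution** — hits overlapping by more than half the shorter
  span are resolved to the higher score, then the leftmost start.  This is
  applied across strands: an element whose ITRs mirror each other aligns
  full-length on the wrong strand at ~60% identity, and the correct-strand
  alignment always scores higher.

Hits report matches/mismatches/gap columns, plus-strand query coordinates
and an implementation-scale score; `identity = matches / aligned_columns`.
Hits with non-positive score are dropped.  The PSL adapter writes
single-block 21-column rows and reads any standard PSL (header or not),
so an external BLAT-compatible tool can replace the built-in search
bit-for-bit downstream.

## Trim search

A CDS hit alone cannot distinguish a mobile element from an ITR-less
transposase-homologous gene.  Each CDS hit is therefore extended by
`flank=500` nt on each side *in query orientation* (minus-strand hits are
reverse-complemented first, making retention strand-invariant), and kept
only when the left ITR is detected in the upstream flank and the right ITR
in the downstream flank at ≥ 75% identity over ≥ 80% of the ITR query.
These thresholds are the package's own operating point: permissive enough
for ~90%-identity family members, strict enough that a chance 227-nt match
inside a 500-nt flank is vanishingly unlikely.  Flanks clipped by a
chromosome end fail detection (the repeat cannot be observed), so such
hits are dropped.  Literal sequence duplicates are removed afterwards;
note that in degenerate simulations with zero divergence all copies *are*
duplicates and collapse to one representative by design.

## Alignment and curation

The built-in aligner is a center-star progressive alignment anchored on
the reference row (or the longest sequence when none is given), using
Biopython's `PairwiseAligner` global alignment with affine gaps
(+1/−1, open −4, extend −1) for each star edge; insertions relative to the
center are left-justified and padded, which makes the output deterministic
for a fixed input order.  The external adapter shells out to `mafft`
(`--retree 2` fast progressive, or L-INS-i), with an automatic mode switch
at 200 sequences — iterative refinement for the smaller sets, fast
progressive for the larger — and fails loudly if the binary is missing;
it never falls back silently.

Curation replaces manual alignment pruning with a reproducible rule: every
non-reference row whose gap fraction exceeds `max_gap_fraction=0.10` is
dropped (ids logged in the result and the run log), then columns left
all-gap are deleted.  The operation is idempotent.

## Consensus

Column frequencies are exact tallies over the counted rows.  Two explicit
conventions:

* the reference (query) row is **excluded** from the counts by default, so
  the consensus reflects genomic copies only (flag to include it; with
  hundreds of rows the difference is negligible, but the choice is
  explicit);
* gaps count in the denominator as a fifth symbol, making "conserved in at
  least 60% of the sequences" literal.

A base is called when its frequency is ≥ the threshold (default 0.60,
*inclusive* — an exact-60% column is called); a column whose gap frequency
reaches the threshold emits nothing and is recorded as a deletion; any
other column is written `N` and its frequency vector is kept for separate
study.  Raising the threshold can only convert calls into `N`, never the
reverse.  Human-facing frequency tables print percentages to 0.1
precision; the machine-readable differences TSV keeps full precision so it
re-parses exactly.

Mapping onto the reference walks the alignment columns once: consensus
bases over reference gaps become insertion records anchored to the
preceding reference position (consecutive columns merge into one record);
deletion columns over reference bases become deletion records.  An
insertion whose column is below threshold appears as an `N` within the
insertion bases rather than as a separate variable-position record.

## Annotation

Each consensus/reference difference becomes one record with feature-local
position, binding-region membership (ITR positions only) and codon effect.
Synonymy is evaluated **one substitution at a time against the reference
codon**; compound changes within one codon therefore appear as individual
records for manual review rather than being combined.  Indels inside the
CDS are frameshifts unless their length is a codon multiple; the annotator
reports frame consequences and never adjusts frames silently.  An `N` as
the alternative base yields an "ambiguous" codon effect.

## Phylogeny

Distances use pairwise deletion of gap/ambiguous sites — preserving taxa
with partial truncation — with either the p-distance or the Kimura
two-parameter correction (the equal-frequency simplification of HKY85):
*d* = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q), with P/Q the transition and
transversion proportions.  Saturated pairs raise by default; the bootstrap
path substitutes the pair's p-distance so every replicate yields a tree.
Neighbor-joining is implemented in-package with deterministic tie-breaking
(lowest index pair) and negative branch lengths clamped to zero with the
remainder shifted to the sister branch; on additive matrices it recovers
the generating topology and path lengths exactly (verified up to 8 taxa,
and cross-checked against scikit-bio's NJ).  Supports come from
column-resampling bootstrap (seeded, deterministic).  Maximum-likelihood
trees under HKY85 and aLRT-style supports are *not* reimplemented; an
optional adapter drives an external PhyML binary when available.

## Synthetic data

The generator embodies the neutral star-phylogeny reading of the family's
history: all copies diverge independently from one ancestor.  Per copy,
i.i.d. per-site substitutions with probability `p_sub` (alternative base
drawn with transition:transversion weighting `kappa`:1:1, default
`kappa=2`), optional indels (`p_indel`, geometric lengths), optional
end-truncation, placed uniformly without overlap (minimum spacing 1200 nt
so neighbouring insertions never share a 500-nt flank window) on an i.i.d.
background of configurable GC content, reverse-complemented with
probability `strand_prob`.  Decoys are mutated copies of the ancestor's
CDS region only.  Engineered variant sites assign exactly
`round(fraction × n)` carriers per allele, enabling exact threshold-
boundary constructions.  Every draw derives from one mandatory seed via
per-copy substreams: identical parameters give byte-identical genomes, and
each copy's mutation log replays exactly from the ancestor.

What the simulator does **not** emulate: host-genome composition
(isochores, other repeat families), selection, CpG effects, nested or
interrupted elements.  Green tests on synthetic data therefore demonstrate
algorithmic correctness under the neutral divergence model, not robustness
to every feature of real assemblies.

## Pipeline determinism and problem sizes

Every stage writes its artifact (PSL + TSV hits, element FASTA, raw and
curated alignment FASTA, frequency and variable-position TSVs, consensus
FASTA and per-position call table, differences TSV, text report, newick,
JSON run log); tabular artifacts carry a 12-hex configuration hash in
their header, and the run log stores parameters and stage counts but no
timestamps, so identical configurations re-run to byte-identical artifact
directories.  Per-stage wall times go to the `tssmine` logging stream
only.

The shipped benchmark sizes — a 2-Mb genome with 50 copies at 3%
divergence for recovery, a 1-Mb genome for the annotation demo, 8–50 kb
genomes in unit tests — were chosen as the smallest scales at which the
statistical claims are sharp (e.g. at 50 copies and `p_sub=0.03`, no site
can realistically fall below a 60% majority, so consensus recovery is
exact; at 6–8 copies occasional `N` sites are expected and the tests
assert the conditional form of the claim).  Genome-scale runs on a real
assembly use the same code paths with per-stage artifacts as checkpoints.

## Known limitations

* The built-in search is not BLAT; identity is measured on the local
  alignment it produces, so hit boundaries can differ by a few bases from
  an external tool's (mutated terminal bases may be clipped).  The PSL
  adapter exists precisely so an external tool can be swapped in.
* Center-star alignment is exact only relative to its pairwise star edges;
  for heavily indel-laden families the external MAFFT path is preferable.
* Amino-acid-level summarisation of variable codons (beyond the
  most-frequent-base vector) is reported only through the frequency
  vectors.
* The trim search assumes the flank length (500 nt) exceeds the
  ITR-to-CDS spacer; models with longer spacers need a larger `flank`.
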