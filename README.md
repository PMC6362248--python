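# tssmine

Evolution-guided mining and consensus refinement of Tc1/*mariner*
transposon copies in a genome assembly.

## The problem

*Sleeping Beauty* (SB) is a synthetic Tc1/*mariner* transposon resurrected
from a consensus of fish-genome sequences (the salmonid Tss1 subfamily).
Its 1638-nt sequence comprises a transposase CDS (1022 nt) flanked by two
227-nt inverted terminal repeats (ITRs) that carry the transposase binding
regions.  A high-quality genome assembly makes it possible to collect *all*
resident copies of such a family, rebuild a refined majority-rule consensus
under a neutral star-phylogeny divergence model, and ask where — and how —
the genomic consensus differs from the reference element: inside or outside
the binding regions, and synonymously or not within the transposase CDS.

`tssmine` implements that whole procedure as a reusable, deterministic
pipeline:

1. **Homology search** — a permissive seed-and-extend search (word size
   *k* = 11 sampled every 5 nt, one seed mismatch allowed, local-alignment
   extension with +1/−1/−2 scoring) over both strands, with a PSL adapter
   for hits precomputed by an external tool.
2. **Filtering** — hits deviating more than 10% from the query length are
   discarded; optional identity filter (e.g. ≥ 90%); literal sequence
   duplicates removed.
3. **Trim search** — a transposase hit is kept only if the left and right
   ITRs are detected in its 500-nt genomic flanks, excluding ITR-less
   transposase-homologous genes.
4. **Alignment and curation** — center-star progressive alignment anchored
   on the reference (or external MAFFT), then a reproducible curation rule
   dropping rows with > 10% gaps.
5. **Consensus** — per-column frequencies *f<sub>b</sub>*; call base *b* when
   *f<sub>b</sub>* ≥ 0.60 (inclusive), emit a deletion when the gap frequency
   reaches the threshold, otherwise write `N` and keep the frequency vector.
6. **Annotation** — every consensus/reference difference with its 1-based
   feature position, binding-region membership, and codon effect
   (synonymous / nonsynonymous / frameshift).
7. **Phylogeny** — p-distance or Kimura-2-parameter distances with pairwise
   gap deletion, neighbor-joining with bootstrap supports (external PhyML
   adapter for ML trees).

A first-class synthetic-genome generator plants diverged copies, truncated
elements, decoys and engineered variant sites with a full mutation-log
ground truth, so every stage is testable at desk scale without the
multi-gigabase assembly.

## Worked example

Simulate a 150-kb genome with 6 diverged copies of the packaged synthetic
reference model plus 2 ITR-less decoys, then run the two-step trim search:

```bash
tssmine simulate --seed 3 --genome-length 150000 --n-copies 6 --n-decoys 2 \
    --out-genome g.fasta --out-truth t.tsv --out-model m.yaml
tssmine run --genome g.fasta --model m.yaml --strategy trim --outdir run1 --seed 3
tssmine run --genome g.fasta --model m.yaml --strategy full --outdir run2 --seed 3
tssmine compare run1/consensus_calls.tsv run2/consensus_calls.tsv
```

prints (abridged):

```
  search: 8
  length_filter: 8
  trim_search: 6
  elements: 6
  consensus_length: 1638
  variable_positions: 2
run1/consensus_calls.tsv vs run2/consensus_calls.tsv: 100.00% over 1638 positions
```

The CDS search finds all 8 transposase-like loci; the trim verification
rejects the 2 decoys because no ITRs flank them; the 1638-nt consensus over
the 6 copies agrees with the full-sequence strategy at every position, with
2 positions left as `N` (their realized majorities fell below 60% — at 6
copies, 2 such sites are expected by sampling).  Each run directory holds
the per-stage artifacts: `hits.psl`, `hits.tsv`, `elements.fasta`,
`alignment.fasta`, `frequencies.tsv`, `consensus.fasta`,
`differences.tsv`, `report.txt`, `tree.nwk` and `run_log.json`.

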