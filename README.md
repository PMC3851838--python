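# contigmix

Reference-free merging ("finishing") of two or more draft bacterial
assemblies. The tool aligns assemblies against each other, builds a weighted
*extension graph* over terminal contig–contig alignments, extracts a maximal
independent set of longest In→Out paths, stitches the contigs along each path
into merged sequences, and prunes output elements that are largely contained
in others — reducing fragmentation (higher N50, fewer contigs) while keeping
duplication low.

## Command line

Three subcommands are exposed as `mix`:

```bash
# simulate a genome, two staggered fragmentations, truth and alignments
mix sim -o simdir --genome-length 100000 --seed 1

# merge two (or more) assemblies using precomputed alignments
mix run simdir/asm1.fasta simdir/asm2.fasta \
    -a simdir/alignments.tsv -o merged.fasta \
    --layout-out layout.tsv --filter-report filters.json \
    --pruning-report pruning.tsv

# fragmentation statistics (contigs, largest, total, N50)
mix stats simdir/asm1.fasta merged.fasta
```

Alignments are accepted either as nucmer `show-coords -rcl -T` tabular
output (1-based inclusive coordinates, descending query interval on the
reverse strand) or as the internal TSV dialect with header
`ci cj bi ei bj ej l reversed_j` (0-based half-open coordinates). With
`--builtin-overlaps` the tool instead computes maximal exact dovetail
overlaps itself, so no external aligner is ever required; a `nucmer`
subprocess wrapper is available in `contigmix.align` when MUMmer is
installed.

Main tuning flags (all mirrored by a YAML `--config` file; explicit flags
win): `--ta` (minimum alignment length, default 200), `--coverage-threshold`
(containment pruning ratio, default 0.90), `--end-tolerance` (slack in bases
when classifying a coordinate as a contig extremity, default 0),
`--scc-path-cap` (simple-path enumeration cap inside cyclic components).

## How it works

1. **Preprocessing** (`contigmix.preprocess`) — five clean-up rules applied
   in order: drop self alignments; deduplicate reciprocal pairs covering the
   same region; keep only alignments longer than `t_a` (strict); drop
   near-containments (>99% of either contig); drop alignments touching
   spurious contigs (outlier alignment counts, Tukey-style fence).
2. **Extension graph** (`contigmix.extension_graph`) — each terminal
   alignment contributes eight vertices (two footprint ends × two contigs ×
   two reading directions) plus shared In/Out source/sink vertices. Edges
   carry both a weight in bases and the contig slice they contribute, so any
   In→Out path spells a consistent merged sequence whose length equals the
   path weight. The module docstring documents the edge derivation.
3. **Path extraction** (`contigmix.milps`) — strongly connected components
   are expanded into explicit chains (one per simple entry→exit path), then
   maximum-weight paths are extracted iteratively by topological-order
   dynamic programming; vertices of extracted paths (and their
   direction-flipped mirrors) become forbidden, enforcing independence.
4. **Stitching** (`contigmix.stitcher`) — each path becomes one merged
   contig `MIX__path_<k>`; overlap bases come from the contig earlier in the
   path (no consensus calling). Unconsumed input contigs are kept.
5. **Pruning** (`contigmix.pruning`) — a coverage matrix over output
   elements is computed by projecting the original alignments through path
   layouts; pairs above the threshold become directed containment edges,
   cycles are broken in favour of the longest element, and elements that
   cover nothing but are covered are removed iteratively.

`contigmix.synthetic_fixtures` simulates seeded genomes, staggered
fragmentations and exact ground-truth alignments; on error-free simulations
the pipeline reconstructs the genome exactly as a single contig.

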