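# chromoweave

Reconstruction of complex germline genomic rearrangements — chromothripsis
and chromoplexy — by integrating structural-variant (SV) breakpoint calls
from long- and short-read genome sequencing with Hi-C contact maps.

Complex genomic rearrangements shatter one or several chromosomes into
fragments that are rejoined in a new order and orientation, often with
fragment loss.  Individual SV callers see only the junctions ("novel
adjacencies" — pairs of oriented breakends), suffer high false-positive
rates, and cannot by themselves say how the fragments are arranged in the
derivative chromosomes.  Hi-C sees the large-scale outcome: a junction
between two distant loci produces an *ectopic* block of contact signal in
the map.  chromoweave combines the two views:

1. **Filter & merge calls.**  Novel-adjacency calls are removed when read
   support is below 5% of the mean alignment coverage, a breakend lies in a
   window above 3x mean coverage, within 10 kb of a reference gap, inside a
   segmental duplication, or when the adjacency is shared between cohort
   samples (1 kb breakend cutoff).  Matched long/short-read calls merge into
   one representative (short-read coordinates when flagged precise).
2. **Reconstruct derivative chromosomes.**  Curated breakpoints (snapped
   when < 50 bp apart) cut the reference into fragments; each fragment
   contributes a 5′ and a 3′ node to a reconstruction graph and each
   adjacency an edge.  Traversing the maximal paths yields the ordered,
   oriented fragment layout of each derivative chromosome; leftover
   fragments are candidate deletions, classified by read coverage.
3. **Order scaffolds with Hi-C.**  When junctions are missing, scaffolds
   sharing ectopic Hi-C signal (checked on a 2-D breakpoint grid against a
   distance-decay expectation) are grouped into one derivative.  For a group
   of *N* scaffolds with two telomeric ends, all (N−2)!·2^(N−2) orders and
   orientations of the middle scaffolds are enumerated and scored on the
   recomposed map: each tile's signal m_ij is weighted by the distance
   |i−j| to the main diagonal and summed over the four w×w tile corners
   (w = 5); the arrangement with the **lowest** score wins, since
   reconstruction errors push signal away from the diagonal.
4. **Recompose Hi-C maps** along a layout (fragment starts rounded up to
   bin boundaries, ends rounded down, sub-bin fragments dropped), and
   subtract a control map scaled to 50% of the sample signal to suppress
   the wild-type allele's reshuffled patterns.
5. **Characterise junctions** from soft-clipped short reads: InDel size from
   the median clip positions of the left/right read groups, and
   microhomology / untemplated insertion from local alignment of the 50 bp
   junction consensus to the 25 bp aligned consensus of the fusion partner
   (match +2, mismatch/gap-open −1, gap-extend −0.1).
6. **Phase and test.**  Reads spanning ±90 bp of a breakpoint (MAPQ ≥ 20)
   vote their phase set onto the wild-type or rearranged allele; phased
   RNA-seq counts give per-gene allelic imbalance (|log2FC| > 1,
   padj < 0.05).  Breakpoint enrichment in chromatin features (LADs, A/B
   compartments, TAD boundaries, repeats) is tested against empirical
   background models — circular per-chromosome shifts, breakend rewiring,
   or expression permutation — with right-sided p = #(null ≥ observed)/n.

A fully seeded simulator generates ground-truthed inputs for every stage
(rearranged genomes, noisy two-caller BEDPE sets with planted false
positives, two-allele Hi-C matrices with power-law decay, soft-clipped
junction reads, feature tracks, haplotagged reads and expression tables).

## Worked example

Simulate a chromothripsis case, filter the noisy call sets, and reconstruct:

```sh
chromoweave simulate --mode chromothripsis --seed 11 --breakpoints 14 --out demo
# chromothripsis: 11 adjacencies, 4 derivative chromosomes, 3 deleted fragments -> demo
chromoweave filter --long demo/calls_long.bedpe --short demo/calls_short.bedpe \
    --coverage demo/coverage.bed --genome demo/genome.tsv --gaps demo/gaps.bed \
    --segdups demo/segdups.bed --cohort demo/calls_decoy.bedpe --out demo/filtered.tsv
# kept 11, removed 50 -> demo/filtered.tsv
```

All 50 planted false positives (10 each of: low support, high-coverage
region, near-gap, segmental duplication, cohort-shared) are removed and all
11 true junctions kept.  Reconstructing from the curated calls:

```python
import csv
from chromoweave.genome import GenomeModel
from chromoweave.adjacency import Breakend, NovelAdjacency
from chromoweave.reconstruction import (
    simplify_breakpoints, make_fragments, build_graph, traverse)

genome = GenomeModel.from_files("demo/genome.tsv", "demo/gaps.bed", "demo/segdups.bed")
calls = []
with open("demo/filtered.tsv") as fh:
    for row in csv.DictReader(fh, delimiter="\t"):
        if row["filter_reason"] == "PASS":
            calls.append(NovelAdjacency(
                id=row["id"],
                bnd1=Breakend(row["chrom1"], int(row["pos1"]), row["side1"]),
                bnd2=Breakend(row["chrom2"], int(row["pos2"]), row["side2"]),
                caller=row["caller"]))
adjusted, breakpoints = simplify_breakpoints(calls)
fragments = make_fragments(genome, breakpoints)
layouts, singletons = traverse(build_graph(genome, fragments, adjusted))
```

which prints (fragments as `chrom:start-end kb`, `+` forward / `-` inverted):

```
der_1 [complete] chr1:0-2899kb(+) -> chr2:2900-3399kb(+) -> chr2:3901-4401kb(+)
                 -> chr1:4899-5400kb(-) -> chr2:4401-4901kb(-) -> chr1:4399-4899kb(+)
                 -> chr1:3400-3899kb(+) -> chr1:5899-8000kb(+)
der_2 [complete] chr2:0-2900kb(+) -> chr1:2899-3400kb(+) -> chr2:3399-3901kb(+)
                 -> chr2:5400-5900kb(+) -> chr2:5900-8000kb(+)
der_3 [complete] chr3:0-8000kb(+)
der_4 [complete] chr4:0-8000kb(+)
singletons (candidate deletions): chr1:3899-4399kb, chr1:5400-5899kb, chr2:4901-5400kb
```

Both shattered chromosomes are reconstructed telomere-to-telomere, the two
unaffected chromosomes pass through intact, and the three fragments planted
as deleted come out as junction-less singletons.  `chromoweave permute`
ranks scaffold orders by the diagonal-weighted corner score when junctions
are missing, and `chromoweave enrich` tests breakpoint/feature enrichment
against the shift null.

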