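# Methods

This note documents the models, conventions, parameters and design choices
behind chromoweave, and what the simulator-based tests do and do not show
about real data.

## Coordinates and breakend convention

All coordinates are 0-based, half-open.  A breakend is `(chrom, pos, side)`:
`tail` means the reference segment **ending** at `pos` (its 3′ boundary)
participates in the fusion, `head` the segment **starting** at `pos`.  In
BEDPE strand columns, `+` maps to `tail` and `-` to `head`, and the breakend
position is the BEDPE start coordinate.  Adjacencies are canonicalized so
the first breakend is the smaller under (chromosome order, position).

Distance from a position to a gap interval `[s, e)` is measured to the
interval hull `[s, e]`: a position d bases right of `e` is at distance d.
This makes the 10 kb gap filter symmetric around the annotated gap.

## Call filtering and merging

Five filters, each a pure predicate returning (kept, removed):

| filter | rule | default |
|---|---|---|
| support | read support < frac × genome-wide mean coverage | frac = 0.05 |
| high coverage | either breakend in a 10 kb window > factor × mean | factor = 3 |
| near gap | either breakend < 10 kb from a reference gap | 10 kb |
| segdup | either breakend inside a segmental duplication | — |
| cohort | adjacency clusters with a call from another sample | 1 kb |

Cohort clustering is single linkage over calls with matching chromosome
pairs and sides, linking when both breakend distances are ≤ 1 kb; single
linkage is the most permissive choice (removes the most sharing) since no
linkage is otherwise pinned down.  Short-read calls may lack a support
count; the support filter then passes them through (it belongs to the
long-read pipeline).  Technology merging matches calls with equal sides and
both breakends within 1 kb (the same scale as the cohort cutoff; the
merging tolerance is otherwise unspecified) and emits the short-read call
when flagged precise, else the long-read call.  Large scale means trans or
cis span strictly > 100 kb; small-scale calls (1–100 kb) re-enter the set
only when a breakend lies within 50 bp of a curated large-scale anchor.

## Reconstruction graph

Breakends on one chromosome closer than 50 bp are snapped to the leftmost
coordinate of their single-linkage group, avoiding spurious tiny fragments.
Fragments tile each chromosome between breakpoints; non-telomeric fragment
ends become graph nodes, `tail`→3′ node, `head`→5′ node.  Conflicts (two
edges on one node) are resolved by the lexicographic evidence key
(found by both technologies, strand concordance with the Hi-C pattern,
Hi-C support score); exact ties raise and must be pinned by an explicit
override, mirroring a manual curation decision.  Traversal emits each
maximal path once; entering a fragment through its 5′ node lists it
forward, through its 3′ node inverted.  Paths with telomeres at both free
ends are complete, others scaffolds; cycles are reported as circular
scaffolds rather than silently broken.  The whole-path reversal symmetry is
canonicalized by emitting the direction whose first fragment has the
smaller (chromosome, start).  Junction-less fragments with both telomeres
are intact chromosomes; all other junction-less fragments are singletons,
classified by mean coverage ratio: ≤ 0.6 deleted, ≥ 0.85 retained but
unplaced, otherwise ambiguous (thresholds are configurable; they digitise
what is otherwise a visual coverage-plot call).

## Hi-C model

Contact matrices are raw binned counts (25 kb or 100 kb in practice),
symmetric, with a chromosome table and global bin offsets; text I/O is
upper-triangle COO with a JSON header.  Fragment-to-bin rounding follows
the recomposition convention: starts round up to the next bin start, ends
round down; fragments smaller than one bin are flagged sub-bin and dropped
from recomposition and permutation scoring.  Recomposition is a pure
row/column permutation (with reversals for inverted fragments), so it is
exactly invertible on loss-free layouts and conserves total signal over the
retained bins.  Copy gains (a source bin used twice) are rejected.

Control subtraction scales the control map to 50% of the sample's signal —
the wild-type allele's expected share — excluding the main diagonal from
the scaling factor (optionally also the first subdiagonal, the variant used
when evaluating custom-genome maps); the difference is clipped at zero
since counts are nonnegative.  The 50% assumption ignores copy-number
differences; no correction is attempted.

### Ectopic-tile detection

The expectation model is an isotonic (nonincreasing) fit of the mean count
per cis bin distance plus a constant trans expectation, both estimated from
the map itself.  Because a junction concentrates signal at one corner of
the grid tile spanned by two fragments, the ectopic score is the maximum
over the four 5×5 tile corners of the mean observed/expected ratio; a tile
is flagged at score ≥ 3.0 with ≥ 4 nonzero bins in the best corner.  The
threshold digitises a visual curation step and is exposed as configuration.
On simulated maps every true junction tile is flagged and the false-flag
rate on null tiles is below 5%.

## Scaffold grouping and permutation score

Scaffolds link when any fragment of one shares a flagged ectopic tile with
any fragment of the other (union–find; the converse inference — no shared
signal implies different derivatives — is deliberately not drawn).  Groups
with exactly two telomeric ends and N ≤ 5 scaffolds are enumerated: ends
fixed telomere-outward, middle scaffolds in all (N−2)!·2^(N−2) orders and
orientations.  Each candidate's recomposed map m is scored

    score = Σ_{p<q} subscore(s_p, e_p, s_q, e_q)

where the subscore sums |i−j|·m_ij over the four w×w corners of the tile of
fragments p and q, w = min(5, tile extent) per dimension.  Corners of small
tiles may overlap; overlapping pixels are then counted in each corner term
(the formula is applied literally rather than clipped).  The printed form
of the fourth corner's row limit is internally inconsistent; the symmetric
reading (row limit e₁) is implemented.  The candidate with the lowest score
is selected; ties are broken by the canonical layout signature and
reported.

Scoring operates on the raw recomposed map by default.  In the acceptance
pipeline candidates are scored on the control-subtracted map: the wild-type
allele contributes half the signal and, once recomposed along any
candidate, produces off-diagonal blocks that differ between candidates only
through Poisson noise — on raw maps this noise swamps the rearranged-allele
signal in roughly half of simulated replicates, while after subtraction the
planted arrangement is recovered in 100/100.

## Junction signatures

Soft-clipped reads (≥ 10 clipped bases, MAPQ ≥ 20) near a breakpoint are
split into L (right-clipped, aligned left of the junction) and R
(left-clipped) groups; the fetch window starts at 10 bp and doubles to at
most 10 kb per empty side.  The InDel size is the signed distance
R median − L median of clip reference positions, requiring ≥ 3 reads
clipped at one identical position per side (NA otherwise).  Positive values
are reference bases absent from the junction (lost material), negative
values duplicated overlap.

Homology decoding aligns the 50 bp source consensus (25 aligned + 25
clipped bases, per-column majority with ties as N) against the 25 bp
aligned consensus of the fusion partner under +2/−1(−0.1) scoring, where a
gap of length k costs 1 + 0.1(k−1).  A perfect alignment (score = 2 × 25,
all target bases matched) starting exactly at the clip boundary is a blunt
junction; a start shifted left by h indicates h bases of microhomology;
imperfect alignments are probed for untemplated insertions by aligning the
50 bp clipped consensus instead, the insertion length being the alignment
start offset.  The combined junction length (homology + insertion) is
reported alongside both components, since the two mechanisms are distinct.
Strand handling: a `head`-side target contributes its R-group aligned
consensus as is; a `tail`-side target its L-group consensus
reverse-complemented; a `head`-side source is reverse-complemented so the
consensus still reads aligned-then-clipped across the junction.

## Haplotype labeling and allelic imbalance

A read is WT at a breakpoint if one contiguous alignment covers ±90 bp with
MAPQ ≥ 20; CGR if it enters the window from one side, stops inside it, and
continues elsewhere as a supplementary alignment; anything else — including
reads simply ending inside the margin — is uninformative.  Each phase set
votes between the two one-allele scenarios (WT/H1 + CGR/H2 vs the mirror);
the majority labels the set, ties stay unresolved, and a conflict fraction
above 0.2 only warns (no auto-invalidation rule exists).  Labeled sets
combine across chromosomes under the assumption that all rearrangements sit
on one allele.  Phased RNA-seq counts are aggregated per gene, allele and
replicate; genes with < 16 phased reads are dropped.  Allelic-imbalance
calls consume an external per-gene (log2FC, padj) differential-expression
table when available; the built-in stand-in is an exact binomial test of
pooled CGR vs WT counts with Benjamini–Hochberg adjustment, and is flagged
as such.  Genes without padj and genes on sex chromosomes are excluded.

## Empirical background models

Three nulls, all with right-sided empirical p = #(null ≥ observed)/n_iter,
no pseudocount (p = 0 is possible) and no multiple-testing adjustment:

* **shift** — every coordinate on a chromosome moves by one uniform offset
  with wrap-around, preserving relative spacing; configurations with any
  coordinate in a reference gap are redrawn whole.
* **rewire** — the pairing of breakends is permuted, coordinates fixed
  (for fusion-type statistics; marginal label counts are invariant).
* **expression** — expression values/flags permuted over genes,
  coordinates fixed.

Expected-fraction baselines exclude reference gaps from both numerator and
denominator.  The allelic-imbalance distance curve bins genes by the
distance of their most-5′ TSS to the nearest breakpoint (default bin edges
0, 100 kb, 200 kb, 400 kb, 600 kb, 800 kb, 1 Mb, ∞ — genes on chromosomes
without breakpoints fall in the last bin) or in TAD units, with a per-bin
null envelope (5th/50th/95th percentiles) and per-bin empirical p.

Because the per-bin tests are unadjusted at a nominal 5% level over ~7
near-independent bins, the family-wise chance of at least one spuriously
significant bin on null data is structurally ≈ 20–25%.  Single-bin
conclusions at the nominal level are reliable; "any bin significant" is
not a calibrated family-wise test.

Calibration of the empirical p under its own null is checked on a pooled
configuration of breakpoints spread across chromosomes (the enrichment
statistics pool breakpoints across cases).  Tightly clustered
chromothripsis breakpoints shifted chromosome-wide make the feature-
fraction statistic take few distinct values, and the ≥-tie convention then
biases p upward — a property of the prescribed estimator on lumpy
configurations, not an implementation artifact.

## Simulator

The simulator defines the study conditions; its defaults are fixed once.

* **Genome** — 4 chromosomes × 8 Mb with one 150 kb gap (at 5% of the
  chromosome), one 100 kb segmental duplication (88%), and a high-coverage
  zone (94%) reflected in the coverage track (150× vs a 30× baseline,
  10 kb windows).  Small enough that dense contact matrices (≤ ~1300 bins
  at 25 kb) stay cheap, large enough for realistic feature tracks.
* **Chromoplexy** — one balanced cyclic exchange across the chromosomes:
  one clean-zone breakpoint each, derivative i = head of chromosome i +
  tail of chromosome i+1; 4 junctions by default (the few-junction,
  no-gain regime).
* **Chromothripsis** — 20 breakpoints by default, clustered in shatter
  regions (30–80% of the chromosome, ≥ 75 kb apart so fragments cover
  whole bins) on 2 chromosomes; internal fragments deleted with
  probability 0.2, survivors dealt to the affected chromosomes in random
  order and orientation between the original flanks.
* **Calls** — per-caller Gaussian positional jitter (0 by default),
  false-negative rate, and 10 planted false positives per filterable
  class, each placed so only its own filter applies (and ≥ 2 kb from true
  breakpoints so planted artifacts remain distinct events); a decoy cohort
  sample shares the cohort-class calls within ±300 bp.
* **Hi-C** — expected counts are a 50/50 overlay of the wild-type and
  derivative alleles, each with cis decay depth/(1+d)^α (depth 20, α = 1 —
  standard polymer scaling; the method itself does not model decay) plus a
  trans constant (2% of depth), Poisson-sampled symmetrically.  Deleted
  fragments contribute only the wild-type share.
* **Junction reads** — per junction, consensus-level sequences are
  constructed so that decoding recovers the planted homology h ∈ 0..10 and
  InDel d ∈ −20..20 exactly: the source clip carries the target sequence
  shifted by h, and the R group of each source coordinate is displaced by
  d.  Reciprocal junctions sharing a coordinate share its planted InDel.
  6 reads per group, optional per-base error rate.
* **Tracks & expression** — TAD partition (~0.4–0.7 Mb), alternating A/B
  compartments, LADs at a 40% genome fraction, sparse repeats; 200 genes
  (600 in distance-curve experiments) with allelic-imbalance probability
  0.5 within 100 kb of a breakpoint vs 0.05 background, realized as
  allelic counts at a 78:22 ratio over 3 replicates of ~40 reads.
* **Haplotags** — 200 phase sets of 30 reads anchored at true breakpoints,
  rearranged allele fixed to H2, WT reads spanning ±500 bp and CGR reads
  stopping inside the ±90 bp margin with a supplementary alignment;
  optional mislabeling rate.

What the simulator does **not** emulate: mappability structure, repeat-
mediated alignment artifacts beyond the planted classes, Hi-C normalization
biases, copy-number gains, polymorphic SVs shared with real cohorts, or
base-level sequence context of whole genomes (junction-local sequence
only).  Passing tests therefore demonstrate algorithmic correctness under
the stated generative model, not caller-level performance on patient data.

## Numerical and degenerate-input conventions

Seeded `numpy.random.Generator` throughout; identical seeds give
byte-identical files (including SAM output, whose header is fully
specified).  Lower-triangle COO entries are normalized with a warning;
negative counts are errors.  Sub-bin fragments drop from recomposition with
a warning.  An all-zero candidate set ties at score 0 and returns the
canonical first layout with the tie reported.  Local-alignment ties resolve
to the lowest source start, then target start.  Empty read groups propagate
NA rather than raising.  Breakpoints at coordinate 0 are ignored with a
warning (telomeres carry no node).
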