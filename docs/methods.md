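# Methods

`plastcmp` implements the comparative layer of plastome structural
analysis: given annotated plastomes, aligned intron matrices, a rooted
phylogeny, a taxon→family table and tRNA secondary structures, it
profiles inverted-repeat (IR) junctions, detects gene and intron losses,
calls nucleotide-diversity hotspots, codes intron indels as phylogenetic
characters, types plastid tRNA (pttRNA) cloverleaf structures, and maps
the resulting characters onto the tree. Everything upstream — genome
annotation, multiple alignment, tRNA structure prediction, tree
inference — is consumed as input, not reimplemented.

## Quadripartite region inference

A plastome is modelled as a circle tiled by LSC + IRb + SSC + IRa, with
IRa the exact reverse complement of IRb. `infer_regions` finds the
maximal-length pair of disjoint reverse-complement repeats of at least
`min_ir` bp (default 1,000 bp, safely below the ~10–30 kb of real IRs
and above incidental repeats). The search binary-searches the repeat
length; candidate matches come from 64-bit polynomial rolling hashes of
all windows of the sequence and of its reverse complement, and every
hash hit is verified by direct string comparison, so hash collisions
cannot produce a wrong interval. Ties between equal-length candidate
pairs break to the lexicographically smallest pair of start
coordinates. The copy whose downstream neighbour (in LSC-first rotation)
is the SSC is IRb; the larger single-copy segment is the LSC. A genome
with no qualifying repeat is reported IR-lacking rather than forced into
a quadripartite map. Coordinates are 0-based half-open everywhere;
flat-file 1-based positions are converted at the parsing boundary.
Size/GC summaries report one IR copy, and GC% excludes N from the
denominator (composition, not coverage).

## Junction profiling

The four junctions JLB (LSC|IRb), JSB (IRb|SSC), JSA (SSC|IRa) and JLA
(IRa|LSC) are profiled against focal genes rps19, ndhF, ycf1 and
trnH-GUG respectively. Expansion and contraction are defined purely
geometrically, relative to the focal gene: *expansion* means the IR
boundary falls inside the gene body (overlap_bp = bases on the IR side);
*contraction* means the gene lies entirely on the single-copy side
(distance_bp recorded); a gene ending exactly at the boundary *abuts*.
No ancestral IR length is assumed. Overlaps are computed on genome
coordinates irrespective of strand; only the trnH 3'-terminus check is
strand-aware. A pseudo-flagged truncated copy (the fragment IR
duplication writes at the mirrored junction) is reported as
`pseudo-fragment` and never enters family aggregation.

Family patterns condense the rps19@JLB and ndhF@JSB states. Aggregation
uses no majority rule: one deviating record makes a junction `mixed`,
mirroring how exceptional taxa are listed explicitly in comparative
tables. Pattern ids 1–5 cover (exp,con), (con,exp), (mixed,exp),
(exp,exp), (con,con); every other combination involving heterogeneity
collapses to the catch-all id 6.

Two order-wide conserved features are flagged per record: ycf1 spanning
JSA with 400–1,870 bp inside IRa, and trnH-GUG overlapping IRa by
exactly 3 bp at its 3' terminus.

## Gene and intron losses

The shipped reference inventory holds the 17 intron-containing plastid
genes (clpP and ycf3 with two introns each) plus infA and rpl32. A gene
is *present* iff at least one non-pseudo feature bears its name
(case-insensitive; tRNA isoacceptor suffixes significant), so
IR-duplicated copies never double-count; pseudo-only genes are reported
separately rather than as losses, because whether pseudogenization
counts as loss is a downstream judgement. Intron losses are deficits of
(exon count − 1) against the expectation, assessed on the richest
non-pseudo copy; the trans-spliced rps12 is assessed on its 3' exon
cluster only, so it contributes a single intron column. Family
aggregation flags losses observed in every sampled member of a family.

## Nucleotide diversity and hotspots

π is the mean pairwise proportion of differing effective sites,
π = Σ_{i<j} d_ij / (C(n,2)·L_eff). No Jukes–Cantor correction is
applied: the statistic mirrors the raw sliding-window π of the standard
tools at plastome-level divergences. Default gap policy
`exclude-columns` drops any column containing a gap or N (complete
deletion); `pairwise-delete` is available. Windows default to 600
columns with step 200 — common practice for plastome sliding-window
scans — and both are exposed in `WindowSpec`. The trailing partial
window is dropped.

Hotspots (HPRs) are maximal merged runs of qualifying windows under one
of three rules: `zscore:k` (π > mean + k·sd of the profile; default
k = 2, scale-free across groups of different absolute diversity),
`absolute:t`, or `top-n:n`. A zero-variance profile yields no calls
under the z-score rule by construction. Calls are assigned to
LSC/SSC/IR by majority base-pair overlap after mapping alignment columns
to genome coordinates; loci sharing across groups is matched by locus
label.

## Indel events and simple indel coding

An indel event is a maximal internal gap run with identical
(start, end) across its bearers; leading/trailing runs are missing data,
never events (alignment-trim artifacts would otherwise masquerade as
shared indels). Two hygiene rules precede counting. First, gap runs
that can slide within a flanking repeat are left-justified: a run moves
one column left when every residue-bearing row agrees at the destination
column with the residue being displaced; row content is provably
unchanged. Second, the single-position rule: a 1-column run lying
within one column of a *longer* event with the same bearer set is
absorbed into it rather than counted independently; restricting
absorption to longer events keeps the operation well-defined when two
single-column runs are adjacent.

Polarity uses outgroup comparison when outgroups are given (outgroup
residues ⇒ deletion, outgroup gap ⇒ insertion, disagreement ⇒
ambiguous) and falls back to majority row-state with ties ambiguous.
Family-unique tallies use a polarity-aware marker set — gap bearers for
deletions, residue carriers for insertions — because an insertion marks
the taxa that *have* the sequence, not those with the gap. `strict`
mode (default) requires the marker set to equal the family exactly;
`relaxed` accepts any within-family subset.

Simple indel coding emits one binary character per event; a taxon whose
own gap run strictly contains the event's columns scores `?`
(inapplicable inside a longer deletion), which downstream Fitch mapping
treats as a wildcard.

## pttRNA cloverleaf typing

Input is sequence plus dot-bracket (predictor-agnostic). The structure
is decomposed via its helix-nesting tree: the exterior helix chain is
the acceptor stem; the hairpins of the central multiloop are assigned
positionally (first = D arm, second = anticodon arm, last = T/Ψ arm; an
extra hairpin between the AC and T arms is a paired V arm). Four
anomaly categories are recognised: an extra loop interrupting the AC
stem, an expanded anticodon loop (> 7 nt), a long variable region, and
an extra loop interrupting the T stem. V-arm typing follows the
classical scheme — type I at 4–5 nt, type II at ≥ 10 nt — and lengths
outside both definitions (≤ 3 or 6–9 nt) are labelled `intermediate`
rather than silently binned. The V loop is the hairpin loop of a paired
V arm when one exists, otherwise the unpaired variable-region sequence.
The anticodon is taken from the label and cross-checked against the
loop centre when the loop is 7 nt; a mismatch warns rather than errors,
since expanded loops legitimately shift the triplet. A shipped catalog
maps observed motifs (V-loop sequences, extra-loop sequences, anticodon
loop lengths) to short type codes per isotype; family patterns flag
intrafamilial variability (> 1 class signature within a family) and
interfamilial uniqueness (signature absent from all other families).

`fold_trna` is a fixture helper, not a thermodynamic predictor: it
exhaustively enumerates segment-length layouts within canonical
cloverleaf bounds, requires fully canonically paired stems (AU/GC/GU),
maximises pair count and breaks ties toward the 5'-most layout. It
exists so synthetic test sets need no external predictor.

## Character mapping

Characters are mapped with Fitch parsimony on the user-supplied rooted
tree; `?` is a wildcard. Origins of the derived state are counted on
one deterministic most-parsimonious reconstruction that assigns each
node its parent's state whenever the downpass set allows
(delayed-transformation flavour); nodes where an accelerated choice
could differ set an `ambiguous` flag. One origin whose clade equals a
family's taxa is a family marker; one origin on a deeper or shallower
clade is clade-specific; a single-leaf origin is reported as
autapomorphic rather than dropped; two or more origins is homoplasy.
At multifurcating nodes the state-set fold is greedy; the exhaustive
equivalence suite covers all rooted binary trees on 4–6 leaves, the
shape this pipeline's trees actually take.

## Synthetic data and what passing tests show

The generator emulates the *shapes* of real comparative data, not their
evolutionary processes: family-monophyletic random trees; plastomes with
exact IR copies, focal genes placed to realise per-family junction plans
(including exact signature overlaps such as 110 bp into rps19 and
1,077 bp into ycf1, with the mirrored pseudo fragments duplication
implies), and configurable gene/pseudo/intron losses; intron alignments
with planted events of chosen coordinates, size, polarity and bearers
(flanks pinned so no gap can slide and no absorption triggers unless
requested); hotspot alignments with independent per-site substitution at
background rate p₀ and hotspot rate p₁; and tRNA structure sets with
planted anomalies rendered as complementary-stem sequences. Substitution
noise is uniform per site — no stage estimates substitution parameters,
so lineage-correlated noise would add cost without test power. tRNA
renders are identical across taxa for identical plans, so family-level
flags equal planted truth exactly; real pttRNAs additionally vary in
sequence between taxa, which this deliberately does not model.

The default demo study uses 8 families × 5 taxa, genomes of
LSC 30 kb / IR 8 kb / SSC 5 kb (realistic proportions at reduced size;
a full-size 100/25/18 kb genome is exercised separately), 60 planted
indels over 17 intron loci with one outgroup row, four junction
patterns, three loss events, a 1.2 kb hotspot in a 10 kb alignment
(p₀ = 0.01, p₁ = 0.05–0.10), and 36 tRNAs per taxon with eight planted
family patterns. All outputs are byte-deterministic in the seed.

Passing the planted-truth suites shows the pipeline's bookkeeping is
exact under known geometry; it does not validate annotation quality,
alignment quality, or the biological interpretation of any real
dataset, all of which enter as inputs here.

## Numerical and degenerate-input choices

- π with zero effective sites is reported missing (NaN), never 0.
- Region inference verifies every hash match by string comparison;
  tie-breaks are lexicographic throughout (repeat pairs, fold layouts,
  Fitch state choices) so all outputs are deterministic.
- An all-gap alignment column is an input error (the column cannot
  survive correct trimming), as is an alignment whose rows differ in
  length.
- A missing focal gene at a junction is a reported state, not an
  exception; a missing outgroup taxon for polarization is an error.

## Known limitations

- Region inference assumes the canonical LSC-first rotation when the
  repeat pair is found on the linear sequence; an IR copy that itself
  wraps the origin would need pre-rotation.
- classify_pattern condenses heterogeneous family combinations into the
  single catch-all pattern 6.
- The folding helper ignores thermodynamics entirely and cannot model
  non-cloverleaf tRNAs.
- Fitch origin counting reports one most-parsimonious reconstruction;
  alternative reconstructions are only flagged, not enumerated.
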