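# Methods

## Data model

Gene order (rank along a chromosome) is the primary coordinate: all
comparative windows are counted in genes, matching how microsynteny is
read off annotation browsers. Base-pair coordinates are optional,
0-based half-open (GFF3's 1-based closed intervals are converted on
load), and used only by bp-window operations (10-Mb territories, repeat
flank scans). Unplaced scaffolds are kept and flagged rather than
dropped, because fragmentary assemblies (hagfish) are where the flag
changes a call from *territory absent* to *unresolved*.

Homology hits are filtered with strict inequalities — bit score > 40 and
E-value < 1e-4 — and clustered into families by single-linkage connected
components, labelled by the lexicographically smallest member so the
partition is order-independent. Family labels supplied in an annotation
override clustering, since annotation-derived family names are the
currency of the manual procedure this package systematises.

## Microsynteny orthology

A locus's *window profile* is the homology families of its five nearest
protein-coding neighbours on each side (non-coding records skipped by
default; a flag includes them — annotations differ on whether
interleaved ncRNAs "count", so the choice is explicit). Matching is
order-free: two windows share a family or they do not, which tolerates
the local rearrangements that are ubiquitous between distant vertebrates.
An order-aware longest-common-run score is available for diagnostics.

Orthogroup assignment is greedy and deterministic: candidates are sorted
by annotated window size (fullest windows seed groups), each candidate
joins the best-scoring group with ≥ `min_shared` shared families against
the group consensus (families seen in ≥ 2 member species), else founds a
new group. Within a species, group members are suffixed `a`, `b`, … in
decreasing score, ties broken by (chromosome, order index).
`min_shared = 3` mirrors the chromosome-scale "minimum number of aligned
pairs" of 3 applied at window scale; it is a parameter, not an assertion
about the manual procedure, which published no threshold.

Missing loci: a species is called *gene lost, territory present* when ≥
`min_territory` (default 3) consensus families co-occur in a 10-gene
protein-coding span somewhere in the genome; *territory absent* when
not; *unresolved* when the best trace sits on a scaffold shorter than
the span — an assembly-gap caveat, not a biological call.

## Macrosynteny

Collinear chains are runs of homologous gene pairs strictly monotone on
both chromosomes (co-linear or anti-diagonal) with ≤ `max_gap` = 20
genes between consecutive anchors on either axis and ≥ `min_pairs` = 3
anchors. This is the gene-order equivalent of dot-plot chaining on
alignment anchors; it is not claimed bit-identical to any
alignment-based tool. *All maximal* chains are enumerated by walking
only "tight" steps (no insertable anchor between consecutive members)
from anchors with no valid predecessor to anchors with no valid
successor; a subset argument shows this yields exactly the chains that
cannot be extended. Per-chromosome hit counts instead use longest-chain
dynamic programming through each anchor (an anchor lies on a valid chain
iff forward + backward chain lengths − 1 ≥ `min_pairs`), so counting
never pays the enumeration cost; reference genes are deduplicated per
query chromosome because the downstream proportion test uses the
reference chromosome's gene count as its sample size.

The top-2 test builds the 2×2 table `[hits₁, n−hits₁; hits₂, n−hits₂]`,
computes `Σ(O−E)²/E` with df = 1, two-sided, *without* Yates correction
(none was specified for this test; the statistic then equals the
two-proportion z², which the tests assert to 1e-10), and a 95% Wald
interval on the proportion difference. Density normalisation divides
counts by query-chromosome gene totals and reports the Spearman rank
correlation of counts against totals, flagging when the rate leader
differs from the count leader.

## Territories and paralogons

A territory is every gene whose midpoint lies within ±5 Mb of the
anchor midpoint, or the 40 nearest genes when coordinates are absent
(the 40-gene fallback reflects that a 10-Mb window typically captures
macrosynteny of > 40 genes, making the two modes comparable). Overlap
between territories is counted on *family* identity, not gene identity:
a paralogon betrays itself by families with surviving members in both
regions. Deleted loci are anchored by projecting the 10-gene flanking
families of a donor species that retains the gene; when the matches
resolve to two chromosomes each carrying ≥ 2 flank families, the locus
is reported as split — the signature of a fission at the deleted site.

## Dollo and scenarios

Dollo reconstruction places the single gain on the branch above the MRCA
of present lineages and losses on the maximal subtrees below the gain
containing no present lineage; no regain is allowed. This is exact (the
tests check it against exhaustive labelling enumeration on ≤ 8-leaf
trees).

Scenarios are ordered, branch-anchored elementary events replayed down
the tree by the same engine as the simulator, so "what repertoires does
this history predict" is a computation, not an argument. Consistency
against observations checks per-lineage presence/absence over the
receptor universe, required same-chromosome pairs, required
different-chromosome pairs, and (for lineages too fragmentary to name
orthogroups, i.e. hagfish) a total receptor count.

Step counting is unit-cost per elementary event; a segmental duplication
whose copy lands on another chromosome decomposes into duplication +
translocation (2 steps). The two packaged origin scenarios share five
lineage losses (VTR2B in tetrapods, VTR2A in mammals and in teleosts,
VTR1B in holostei+teleostei, VTR2C in birds); these are appended to both
replays for the consistency check but excluded from both counts, which
is the only reading under which the one-round scenario costs 6. The
two-round scenario then needs 9 hypothesis-specific steps: the tandem
duplication, two WGDs, loss of the never-observed fourth chromosome pair
(VTR1C + VTR2D) in the stem ancestor, a fission separating VTR1B from
VTR2C (observed on different chromosomes in every species carrying both,
whereas two WGD rounds would co-locate them), one lamprey and two
hagfish segment losses, and the shark-lineage VTR2C loss. The exact
decomposition behind the published comparison is not printed in the main
text; this encoding is the package's declared interpretation, chosen
before any acceptance measurement and kept fixed.

`min_steps_search` is an exhaustive iterative-deepening search over a
declared grammar (allowed event kinds per branch) with deterministic
enumeration; it is intended for desk-scale verification (≤ ~5 steps,
few-gene genomes), not for open-ended inference.

## The synthetic world

The simulator's packaged configuration is a *stated* world encoding the
observed end-state, fixed before any test outcome was seen:

* One ancestral chromosome carries the receptor precursor flanked by
  proximal neighbour blocks and distal blocks; after the WGD the two
  chromosome copies lose complementary halves of the proximal blocks
  (reciprocal differentiation), so orthologous ten-gene windows share
  all 10 families while paralogous windows share ≤ 2 — the regime in
  which window orthology is decidable at `min_shared = 3`. The distal
  blocks are retained on both copies, so chromosome-scale paralogy (the
  second-highest hit count, 25ish of ~47 families) remains detectable.
* The translocated segmental duplicates (VTR1B, VTR2C) carry the focus
  gene plus two flankers into host chromosomes; the lamprey branch then
  loses the insertion-site context, reproducing the observation that the
  lamprey genome shows no trace of those territories while fish that
  merely lost the genes retain them.
* Receptor spacings (12 surviving genes between co-located receptor
  pairs), the mammalian fission at the deleted VTR2A locus, the bird
  block deletion around VTR2C, the teleost OTR tandem copy and OT
  translocation, the hagfish scaffold fission, and the ligand pair
  (tandem, TE-TIR-flanked copy, placental inversion to tail-to-tail)
  encode the corresponding reported observations at desk scale (the bird
  deletion is 4 genes here, not ~20).

What a green test establishes: the *procedures* are correct on genomes
whose truth is known, at realistic topology but toy scale. What it does
not establish: numbers that depend on real assemblies — GC percentages,
intron lengths, per-chromosome hit magnitudes, bootstrap supports — are
out of desk-scale reach and are exercised only as properties (monotone
curves, oracle equivalences, closed-form identities).

## Numerical and degenerate-input choices

* Strict inequalities in hit filtering; negative E-values rejected.
* GC content excludes N from the denominator and returns an undefined
  flag (None) for an effectively empty sequence; non-nucleotide input is
  an error, not silently skipped.
* Orientation calls need strands on both genes; the inverted member of a
  non-tail-to-head pair is the one disagreeing with the majority strand
  of its five-gene neighbourhood, with ties flagged ambiguous rather
  than guessed. Both the class and the attribution are invariant under
  flipping the whole chromosome.
* Chains prefer longer, then smaller starting reference index; the χ²
  top-2 labels order by count descending then label ascending, making
  every reported table deterministic.
* The simulator's RNG is a single numpy Generator seeded explicitly; the
  seed is recorded in the dataset. Replay of the emitted event log
  reproduces the emitted genomes byte-identically.

## Known limitations

* No nucleotide-level sequence evolution: families are exact descent
  labels, so family inference noise (mis-clustering from borderline
  hits) is representable only by supplying perturbed hit tables.
* The maximal-chain enumerator can be exponential on adversarial dense
  dot plots; use the DP-based hit counts at genome scale.
* The greedy monophyly violator search beyond 3 violators is heuristic
  and flagged as such.
* The minimal-scenario search is exhaustive and therefore limited to toy
  ancestors and small step bounds by design.
* Lineages are the tree's leaves; within-lineage species variation
  (e.g. zebrafish-specific OT placement) is below this resolution.
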