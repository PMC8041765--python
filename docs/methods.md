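# Methods

## The PSPG frame and motif location

The PSPG motif is treated as a rigid 44-column frame; columns are numbered
1..44 following the field's convention (all internal coordinates are 0-based
half-open, converted only at I/O boundaries). Three residue maps define the
frame:

| layer | columns | residues | weight |
|---|---|---|---|
| anchors (sugar-donor contacts, invariant across groups) | 1, 3, 19, 22, 27, 43, 44 | W, P, H, W, E, D, Q | 3 |
| group-O boxes (cisZOG) | 3-8, 16-24, 38-44 | PQLEIL, FMSHCGWNS, WPMHSDQ | 2 |
| group-D reference (AY573820.1, UGT73-like) | 1-44 | WSPQMLILTHPAVGGFLTHCGWNSTLEGITSGVPLLTWPLFGDQ | 2 |

A window residue matches a column if it equals the anchor or either group
residue defined there; matched columns contribute their weight, `X` never
scores, and columns constrained by no map (possible in user-supplied
profiles; the default frame has none, since the group-D map is a complete
printed motif) accept any residue at weight 1. Every ungapped 44-residue
window of a protein is scored; the best window is the motif candidate, with
ties broken toward the C terminus because that is where the motif
biologically sits. A window counts as "motif present" above
`presence_threshold` × maximum score.

`presence_threshold` defaults to 0.55: a window matching only the anchors
plus the group-O boxes scores 55 of the maximum 95, so a clean group-O
consensus passes (0.579) while unrelated sequence — expected match
probability ~1/20 per non-wildcard column — scores far below. No single
non-anchor substitution can hide a full-scoring motif, since
0.55 ≤ (95 − 3)/95. The threshold, weights and column maps are all
configurable and serialize to JSON.

Design choices made here: **ungapped scoring** (no insert/delete states)
keeps column numbers meaningful, which the diagnostic rules depend on; a
profile HMM would blur "position 41" into an alignment question. The
scoring scheme itself is a package choice — the quantitative criterion for
"contains the motif" is not standardized — hence its prominence in config
and logs.

## Group classification

Read from the located window:

* **group O** — His at 41 and Ser at 42. This pair alone defines the group.
* **group D** — Phe-Gly or Phe-Ala at 41-42 *and* all three group-D boxes
  (PQ at 3-4, HCGWNS at 19-24, DQ at 43-44) intact. The conjunction guards
  specificity: Phe at 41 also occurs outside group D.
* **UNCLASSIFIED** — everything else, including group-H-like (UGT76)
  sequences, for which no complete diagnostic residue set is encoded, and
  motif-bearing sequences that lost a diagnostic residue. The latter is the
  "yellow-box" state: classification and tree placement are independent
  axes, so such sequences can still land inside an O-dominant clade and are
  flagged there.

Submotif hit counts for both groups are always recorded as evidence, whatever
the call. The census reports UNCLASSIFIED motif-bearers separately from O
and D rather than folding them into either group.

## Identity, trees, clades

Pairwise global alignment uses Needleman-Wunsch with a linear gap penalty
(match +1, mismatch 0, gap −1 by default; any Biopython substitution matrix
may replace the match/mismatch scheme). The traceback tie-break is fixed —
match/mismatch over gap-in-first over gap-in-second — so alignments are
deterministic. Percent identity = 100 × identical non-gap columns /
columns not gapped in both sequences (terminal gaps count in the
denominator); distance d = 1 − identity/100. For inputs that are already
column-aligned (equal length), identities are computed directly on columns,
which is what the pipeline does with generator output.

Trees are built by neighbor joining (scikit-bio), with negative branch
lengths clamped to zero. NJ stands in deliberately for likelihood or
parsimony search: the clade logic downstream consumes only topology,
support and leaf labels, and NJ keeps the whole path exhaustively testable
(the test suite checks topology recovery on additive matrices against
enumeration of all unrooted topologies for up to six taxa). Bootstrap
support resamples alignment columns with replacement, rebuilds the
distance + NJ tree per replicate, and scores each original bipartition by
the percentage of replicates containing it; 100 replicates by default
(configurable up to the conventional 500-1000), fully seeded.

Clade labeling walks the tree from the root and emits a subtree as one
clade when its edge support reaches `min_support` (default 50%) and the
most frequent group label among its leaves has frequency ≥
`purity_threshold` (default 0.8); otherwise it recurses, so the emitted
clades always partition the leaves. UNCLASSIFIED leaves inside an
O-dominant clade are flagged as yellow-box members.

## The synthetic gene-family generator

The generator emulates the census regime the pipeline is designed for, with
full ground truth. Default conditions: 50 species partitioned into 6
clades, one designated 8-species loss clade ("Brassicaceae-like"); two
ancestral gene lineages per clade, allocated to groups O and D
deterministically from `group_mix` (both groups guaranteed per clade
whenever the mix is strictly between 0 and 1, so the presence/absence
contrast is always evaluable); proteins of 470 residues with the group
motif template embedded 8 residues from the C terminus.

Copy number per species and lineage evolves by Bernoulli duplication trials
(geometric growth at `dup_rate` = 0.35, damped fourfold beyond the target
range 1-5, hard-capped at 9) and a Bernoulli loss (`loss_rate` = 0.1) —
producing the typical one-to-five-copies-per-species regime with occasional
larger families. In the loss clade, every group-O lineage is deleted
outright. Sequences mutate by i.i.d. per-site substitution at
`mutation_rate` (default 0.02, a modest within-family divergence), reduced
by `anchor_conservation` = 0.1 at the seven anchor columns; substitutions
draw uniformly from the 19 alternative residues.

What the generator does **not** emulate: indels (the scanner is ungapped by
contract, so motif columns must stay in frame), realistic substitution
models (WAG/LG), rate heterogeneity, codon structure, isoform redundancy,
or a proper birth-death process on a timed species tree — duplication/loss
is star-within-clades. Passing tests therefore demonstrate that the
pipeline's logic is correct under its stated model, not that the profile
scores or thresholds are optimal for diverged real proteomes; on real data
the presence threshold and the group-D submotif conjunction are the
settings to revisit first.

## Numerical and procedural conventions

* Dedup key on loading is (species, exact sequence), first occurrence kept;
  identical sequences from different species are both retained, as are
  same-species isoforms differing anywhere in the string.
* `X` matches nothing in the scanner (conservative on low-quality
  translations).
* Pairs with no comparable alignment columns get identity 0 (distance 1).
* A run is a pure function of (inputs, config, seed); every artifact except
  the timestamped `run.log` is byte-identical across reruns, and the echoed
  `config.json` omits the output directory so runs into different
  directories stay comparable. Test-suite and pipeline problem sizes (50
  species, ≤ 9 copies, 100 bootstrap replicates) are the package's default
  desk-scale conditions.

## Known limitations

* Group assignments beyond O and D (the full A-P nomenclature, ZOX
  xylosyltransferases) are out of scope; such sequences surface as
  UNCLASSIFIED.
* Clade ids emitted by the labeler are sequential and data-dependent; they
  are not a fixed taxonomy.
* NJ on percent-identity distances is not a substitute for model-based
  phylogenetics when branch lengths themselves are of interest.
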