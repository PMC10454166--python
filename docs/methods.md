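# Methods

## Motif grammars

Two sorting-signal families are modelled as slot grammars over amino-acid
strings (1-based, inclusive coordinates throughout, so a tyrosine
reported at 230 is residue 230 of the mature sequence):

| family     | canonical pattern   | relaxations (any combination) |
|------------|---------------------|-------------------------------|
| tyrosine   | `Y X X Φ`           | spacer 3–5 X residues         |
| di-leucine | `[D/E] X X X L [L/I]` | spacer 2–5; last residue V or R; first residue L |
| NPXY       | `N P X Y`           | none                          |

Φ = {F, M, L, I, V}. Constrained slots (anchors, Φ, the acidic/leucine
slots) accept only their stated residue sets and never the ambiguity
letters X/B/Z/U; unconstrained "X" slots accept any standard residue or
ambiguity letter. The tyrosine anchor is strict: F and phosphotyrosine
do not substitute. The penultimate residue of every di-leucine match is
a literal L — I is never accepted there, and I is not accepted in the
relaxed first slot either (the relaxed set is exactly {D, E, L}). These
choices mirror the reference catalogue, in which all di-leucine-type
entries have a penultimate L and no first-slot I appears; both sets are
configurable in `GrammarConfig` for users who want a looser grammar.

At one anchor several spacer/slot combinations can match. The matcher
returns at most one hit per (anchor, family): canonical beats
non-canonical, and among non-canonical matches the smallest spacer wins.
The reference catalogue never lists two same-family motifs sharing an
anchor, so this deduplication reproduces its reporting granularity;
overlapping hits of *different* families are all retained (e.g. a
D-anchored di-leucine and a Y-anchored tyrosine motif sharing four
residues).

Whole-peptide classification (`classify_peptide`) anchors at the first
residue and requires the match to span the peptide exactly; peptide
length therefore fixes the spacer per family, and the three families
have disjoint first-residue requirements, so classification is
unambiguous.

## Topology-aware filtering

Proteins carry a fixed nine-segment topology (NT, TM1, E1, TM2, IL, TM3,
E2, TM4, CT), contiguous from residue 1, supplied as a flat TSV
mirroring UniProt feature annotations. The scan keeps a raw grammar hit
iff:

1. its whole span lies inside one searched domain (default {IL, CT};
   the N terminus, although cytoplasmic, is excluded by default because
   it is buried in the channel vestibule — configurable);
2. its TM clearance is at least `min_tm_distance` residues (default 10,
   the stricter end of the reported 6–10 requirement), **or** the hit is
   whitelisted.

TM clearance counts residues strictly between the motif and the nearest
flanking helix: for a CT hit, anchor − TM4.end − 1; for an IL hit, the
minimum of the TM2-side and TM3-side clearances; for an NT hit (when
searched), TM1.start − end − 1. Motifs straddling a segment boundary
are dropped with a logged reason rather than assigned to either side.
The default whitelist contains the Cx43 tyrosine anchor at 230: the
reference catalogue lists Y230VFF while describing it as immediately
adjacent to TM4, so reproducing the catalogue requires an explicit,
logged exemption. Every drop and exemption is echoed through the
`cxmotifs` logger so a scan is auditable.

Per-protein categories form a strict priority: ≥1 canonical tyrosine hit
→ `TYR_CANONICAL`; else ≥1 canonical di-leucine → `DILEU_CANONICAL`;
else ≥1 non-canonical hit → `NONCANONICAL_ONLY`; else `NONE`.

## TM4/CT junction scan

The conserved di-leucine-like motif at the TM4/C-terminal transition
zone is searched separately and deliberately ignores the clearance rule.
Anchors within a ±10-residue window of the TM4 end (configurable) are
tested for `[D/E]` followed by three unconstrained residues and a
two-residue terminus; the terminus is classified as canonical (L then
L/I), last-atypical, second-last-atypical or both-atypical. The anchor
closest to the TM4 end wins, ties breaking upstream. The window width
is a reconstruction — the source material shows the motifs at or just
inside the TM4 end but prints no numeric window.

## Conservation

A human motif counts as conserved when the same *family* (not
necessarily the same spacer or classification) matches in the rat
ortholog. Default mode `aligned_overlap`: the human footprint is mapped
through a global pairwise alignment and rat anchors within the mapped
footprint ± the grammar's spacer slack (3 residues) are re-evaluated
with `match_at`; the match must fall in the same topological domain.
Mode `domain_level` is the lenient alternative (any same-family match
anywhere in the same segment kind); the printed catalogue marks motifs,
not positions, as conserved, so neither mode is asserted to be the
published procedure — the mode used is recorded in output.

The aligner is a re-implemented Gotoh dynamic program: BLOSUM62
(Biopython's matrix collection), gap open 10, gap extend 1 (a gap of
length *k* costs 10 + (k−1)·1), end gaps penalised like internal gaps —
conventional protein defaults; the published analysis names CLUSTAL
OMEGA and BLAST but no parameters. The recurrence is vectorised
row-wise in numpy (the within-row gap state reduces to a running
maximum); traceback prefers diagonal, then gap-in-subject, then
gap-in-query, so the reported alignment is unique and deterministic.
Tests verify scores against Biopython's `PairwiseAligner` as an
independent oracle and re-score every emitted alignment column by
column.

Rat topologies may be supplied, or (default) projected from the human
topology through the alignment: each segment boundary maps to the last
subject residue consumed at or before it, gaps collapsing outward, with
degenerate segments widened to one residue.

## Synthetic benchmark generator

`SyntheticSpec` generates connexin-like proteins: segment lengths drawn
per protein from configurable ranges (TM helices 18–24 residues, IL
40–60, CT 80–130, termini and extracellular loops in proportion),
background uniform over the 20 standard residues, TM segments drawn from
a hydrophobic alphabet. Planted motifs overwrite the background at the
position that realises the requested domain and TM clearance exactly;
their unconstrained slots are drawn from residues that cannot seed or
terminate a grammar slot, so each planted motif is recovered at exactly
its intended spacer and classification. Decoys are placed in
extracellular loops, 2 residues past TM4 (inside the exclusion zone), or
as near-miss patterns with exactly one constrained slot corrupted
(Y→F anchor, penultimate L→A). Accidental background matches are
embraced, not prevented — preventing them would bias the background —
and are enumerated into the truth table, which is closed under
re-scanning by construction and verified against an independent
regex-based oracle in the tests.

Ortholog derivation applies per-site substitutions (default probability
0.05) outside planted footprints; preserve-flagged motifs are untouched,
destroy-flagged motifs lose one constrained slot. After destruction the
generator additionally scrubs any residual same-family match inside the
conservation search window (footprint ± spacer slack) with further
single-residue substitutions: without this, background residues can
shadow the destroyed motif and make the expected conservation call
ambiguous. Randomness uses one root seed with per-protein spawned
streams in a fixed order (topology → background → planting → decoys →
ortholog), so adding proteins never reshuffles earlier ones and output
is byte-identical under a repeated seed.

What the generator does *not* emulate: real amino-acid composition
biases, indels between orthologs (point substitutions only), domain
length drift, and the positional clustering of real connexin motifs.
Passing recovery tests therefore demonstrates correctness of the
scanning and conservation machinery, not predictive performance on real
proteomes.

## Bundled catalogue

The printed reference catalogue (33 motif peptides with anchors, domain
assignments, bracket convention and rat-conservation flags across the 21
human connexins) ships as plain TSV. Classification is always
*recomputed* from the peptide; the printed bracket flag is retained only
for comparison. Two internal inconsistencies of the printed source are
resolved in favour of its table: the non-canonical census is 12 motifs
in 7 connexins (the accompanying text says 14 in 8, but 12 + 21
canonical equals the printed total of 33), and 5 motifs are marked not
conserved in rat (the text counts 6 but identifies only these 5, all in
the four connexins it names). The full-sequence censuses — junction
motifs and rat conservation over the real 21 + 21 sequences — require
the user to supply the sequences and UniProt topologies under `data/`;
they are not redistributed. UniProt domain boundaries drift across
releases, so any real scan should record the topology file used
alongside its results.

## Problem sizes and numerics

Recovery statistics are measured over 100 seeded replicates each for
planted-motif sensitivity/decoy rejection and for conservation-call
accuracy, with three planted motifs (and three decoys) per replicate;
aligner agreement uses 100 random pairs of length 3–50. Grammar/oracle
equivalence is checked on 1000 random sequences up to length 60 plus a
derandomised property test up to length 200. All comparisons are exact:
scores are integer-valued sums represented in float64, so equality
checks carry no tolerance.
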