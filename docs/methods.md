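# Methods

## The typing model

A query protein is typed from a `FeatureReport` — the evidence a structural
biologist would tabulate when placing a new PET hydrolase in the I/IIa/IIb
scheme — against four `TypeTemplate`s. Each template has *gates* (hard
predicates) and *scored positions* (expected residues, weight 1 by default):

| type | gates |
|------|-------|
| I    | exactly 1 disulfide AND extended loop absent |
| IIa / IIb | exactly 2 disulfides, all at canonical positions, AND extended loop present |
| III  | lipase box GHSQG AND clamp absent AND ≥2 disulfides all non-canonical AND loop-3 delta ≥ +3 |

Among gate-passing templates the highest scored-position fraction wins and
must win *strictly*; no passer, or a tie, yields `unclassified`. Two
deliberate choices: the type III gate is conjunctive because its defining
features co-occur in the motivating family (a disjunctive "≥k of n" mode
can be configured for exploration), and IIa vs IIb is discriminated only by
scored residue composition at subsite II and the extended loop, since no
sharper published rule exists. `unclassified` is a first-class outcome —
the scheme's whole point is that some enzymes fit none of the old types.

## Feature extraction

All annotated positions live in the *reference's author numbering* and are
carried onto the query through one global pairwise alignment
(`map_positions`). A reference position opposite a gap maps to
"unalignable" and is never forced to a neighbor — this matters for the
subsite residue that sits on a deleted loop in type III queries, where the
correct answer is "no equivalent residue exists".

* **Lipase box**: the 5-mer centered on the catalytic serine (from the
  geometric triad when coordinates exist, else the mapped reference
  serine). Labels: `GHSMG`, `GWSMG`, `GHSQG`, `other` (any other
  G-X-S-X-G), `nonconforming`. A nonconforming window is evidence, not an
  error; only an unlocatable serine blocks classification.
* **Clamp**: present iff both mapped anchor residues are aromatic (F/Y/W);
  an unalignable anchor gives "undetermined", which fails any clamp gate.
* **Loop deltas**: for each annotated loop window, the number of query
  residues aligned within the window's alignment-column span minus the
  number of reference residues in the window (positive = insertion).
  Insertions falling strictly inside the span are counted; a window with no
  aligned query residue is undefined.
* **Extended loop presence**: query coverage of the extended-loop window
  ≥ 50% of its reference residues. The threshold is permissive on purpose:
  type I status is signalled by wholesale absence of the segment, not by
  composition drift.
* **Disulfides**: structure-derived SG–SG bonds override sequence
  inference. Sequence-only inference first pairs cysteines lying within ±2
  alignment positions of both members of a reference canonical pair, then
  pairs the remainder consecutively along the chain — a stated heuristic
  that a structure settles. A pair is *canonical* when both members fall
  within the ±2 window of one canonical pair; the tolerance makes the
  qualitative judgement "located at different positions" testable, and a
  pair sharing only one canonical cysteine (as the family's second bond
  does) is correctly non-canonical.

## Geometry

Parsing is gemmi's (first model, highest-occupancy altloc per atom name,
heteroatoms flagged). Disulfide: SG–SG ≤ 2.3 Å, greedy by ascending
distance with each cysteine in at most one bond — the covalent bond is
~2.05 Å, and the margin absorbs refinement noise while excluding free
cysteine pairs. Triad: the (Ser, His, Asp/Glu) triple minimizing
`d(OG,NE2) + d(ND1,OD)` subject to both ≤ 3.5 Å (hydrogen-bond range);
minimal-sum tie-breaking replaces the visual identification used in
practice with a deterministic rule. Superposition: SVD/Kabsch with proper-
rotation correction; after each fit all pairs deviating > 2 Å are dropped
at once and the fit repeated up to 5 cycles or until stable — the refine-
align protocol of structure viewers. Correspondences come from a pairwise
sequence alignment of the two chains, which is simpler and more
reproducible than structure-based seeding; the 40-residue N-terminal trim
conventionally applied before whole-model alignment is exposed through
`trim_signal`.

## Alignment

Needleman–Wunsch/Gotoh with affine gaps, end gaps penalized; a gap of
length L costs `gap_open + L·gap_extend` (defaults 10 / 0.5, BLOSUM62).
Traceback tie-breaks are fixed (diagonal > up > left; match layer preferred
within a cell) so alignments are bit-reproducible. The inner DP is a numba
kernel; a pure-Python path exists but is only a fallback. Percent identity
divides matches by *aligned columns* — conventions differ (some tools use
the shorter sequence length) and this choice is stated here because it can
move reported identities by a point or two. `AlignmentResult.score` is a
float: the default half-integer gap extension makes integer scores
impossible. The progressive MSA uses pairwise-identity distances, a UPGMA
guide tree (scipy average linkage) and profile–profile NW merges with
linear gap costs; once inserted, gaps are never removed. It is a
deterministic stand-in adequate at fixture scale — consistency-based MSAs
of real families should be computed externally and imported as aligned
FASTA.

## Profile HMM

Nodes 0..k (node 0 = Begin) with match/insert/delete states; every state
at node j transitions to {M_{j+1}, I_j, D_{j+1}}, and at the last node the
delete successor's mass is renormalized over {End, I_k}. Columns with gap
fraction < 0.5 become match states. Emissions and transitions are
maximum-likelihood counts with Laplace (+1) pseudocounts:
`(count + 1)/(total + 20)` for emissions; the null model is the seed MSA's
overall residue frequency, likewise smoothed. Scoring is glocal (global in
the model) forward or Viterbi, reported as log2-odds bits against the
i.i.d. null. These choices (Laplace instead of Dirichlet mixtures, glocal
instead of local) keep the model analyzable by exhaustive path enumeration
in tests; bit scores are on this model's own scale and are not numerically
exchangeable with other profile-HMM software. The mining rule is applied
on whatever scale produced the scores: hit iff bits > 100 (strict, per
"higher than"), and hits split at 200 with the boundary value itself
assigned to the high group (the published interval notation leaves exactly
200 unassigned; a decision was required and is documented here).

## Phylogeny

Distances are uncorrected p-distances over mutually ungapped column pairs
(a Kimura-style correction is deliberately not the default because the
reference workflow's correction setting is unknown; the distance matrix is
exported so alternatives can be applied downstream). Neighbor joining is
Saitou–Nei with the standard Q criterion; ties break on the
lexicographically lowest representative-label pair, and negative branch
lengths are clamped to zero with the clamped deficit recorded on the tree.
On additive matrices the implementation recovers topology and branch
lengths exactly (tested against randomly generated trees, and
cross-checked against scikit-bio's NJ). Bootstrap resamples alignment
columns with replacement; support is the fraction of replicate trees
containing a bipartition, seeded and reproducible.

## Assay reductions

`%Crystallinity = (ΔH_f,sample − ΔH_c,sample)/ΔH_f,100% × 100` with
140 J/g as the fully-crystalline PET fusion enthalpy; values outside
[0, 100] are flagged non-physical rather than raised, because DSC baseline
handling can produce small excursions. Residual activity normalizes an
initial rate to the 0 h rate. Total product release sums BHET + MHET + TPA
in one shared unit; summing molarities counts terephthalate moieties, not
mass — the module sums as the convention does and the caveat stands here.

## Synthetic fixtures

`make_reference_set(seed)` builds four archetypes on one ~300-residue
scaffold whose background residues are drawn uniformly from the 19
non-cysteine amino acids (so disulfide patterns are always planted, never
accidental). Feature layout in reference (type IIb) numbering: triad
S160/H237/D206, motif window 158–162, clamp anchors 87/185, subsite II at
{89, 214, 238}, extended loop 239–250, loop windows 83–91 / 115–123 /
163–172, canonical disulfides (203, 239) and (273, 289). Type I deletes
the extended loop and carries one disulfide and GHSMG; IIa/IIb differ in
planted subsite II/extended-loop residues; type III carries GHSQG, a
threonine at clamp anchor 1, a five-residue loop-2 deletion (removing the
subsite residue there, so it is genuinely unalignable), a five-residue
loop-3 insertion, and disulfides at (64, 126) and (273, 276) in its own
numbering — the second pair shares one cysteine position with a canonical
pair but is still non-canonical, reproducing the family's near-miss.
Archetypes diverge from the scaffold by 12% background substitutions
(loop windows ±3 and all feature positions protected), chosen so that
pairwise identities stay in the comfortably alignable range while the
panel still separates into clades. `mutate` adds seeded point substitutions
outside protected positions and never creates cysteines, so the generating
type remains recoverable by construction; what the degradation curve
therefore measures is the stability of alignment-anchored feature mapping
under background noise, not feature loss. Toy structures are helical Cα
traces with side-chain pseudo-atoms placed to satisfy the triad
(OG–NE2 = 3.0 Å, ND1–OD1 = 2.8 Å) and disulfide (SG–SG = 2.05 Å)
predicates exactly, with pairs separated by >10 Å so greedy detection
cannot cross-pair; they are geometric scaffolds, not folds, which suffices
because every structure operation is a local-geometry predicate.

What the fixtures do **not** emulate: real indel processes (only the
planted loop edits), compositional bias, homologous recombination, or
structurally plausible folds. Passing the suite therefore demonstrates the
pipeline's correctness and determinism, not field performance on divergent
natural sequences; the identity and structure checks that would run
against deposited reference data are exercised on stand-ins constructed to
carry the same features at the same author-numbered positions (every such
stand-in is named and documented as synthetic).

## Problem sizes and determinism

Defaults used by the test suite and `scripts/acceptance.py`: 300-residue
scaffolds; 50 replicates per mutation rate over {0, 0.02, 0.05, 0.1} for
the degradation curve; 200 random short pairs for the alignment oracle;
500 random (model, sequence) pairs for forward ≥ Viterbi; 100 random
additive matrices (≤8 taxa) for NJ; 200 bootstrap replicates for the
two-clade support check. All randomness flows from explicit seeds
(`numpy.random.default_rng`); every command echoes its resolved
configuration into the output directory.

## Known limitations

The progressive MSA is not consistency-based and should not be used for
>200 or deeply divergent sequences. Profile-HMM bits are not portable
across software. Sequence-only disulfide pairing beyond the canonical
windows is a positional heuristic. Subsite membership and loop windows in
the shipped reference annotation are transcribed from structural
comparisons and marked provisional — they are data, not code, and are
meant to be edited. IIa/IIb discrimination inherits whatever residue sets
the templates score; with empty scored sets the two types are deliberately
indistinguishable and yield `unclassified`.
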