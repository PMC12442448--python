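"""Synthetic fixtures: type-consistent sequences, toy structures, profile samples.

Every stage of the typing pipeline is testable offline through this module.
It generates four "archetype" sequences, one per PETase type, each carrying
exactly its type's gating features at annotated positions on a shared
~300-residue scaffold (the length range of bacterial PET hydrolases):

* type I   — GHSMG lipase box, aromatic clamp, one disulfide, the
  extended-loop segment deleted;
* type IIa — GWSMG, clamp, two disulfides at the canonical (type II)
  positions, extended loop present, type-a subsite II composition;
* type IIb — as IIa with type-b subsite II / extended-loop composition
  (the IIb archetype doubles as the reference the others are mapped onto);
* type III — GHSQG, clamp broken (threonine at anchor 1), two disulfides
  away from the canonical positions (one sharing a single canonical
  cysteine, mirroring the real family's near-miss), a five-residue loop-3
  insertion and a five-residue loop-2 deletion.

Toy structures are geometric scaffolds, not folds: a helical Calpha trace
with side-chain pseudo-atoms placed so the triad and disulfide distance
predicates hold exactly. That is sufficient because all structure
operations in the pipeline are local-geometry predicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import gemmi
import numpy as np

from .features import ReferenceAnnotation, write_annotation_tsv
from .hmm import _AA_INDEX, D, I, M, ProfileHmm
from .seqio import AMINO_ACIDS, ProteinSequence, write_fasta

# background alphabet excludes cysteine so disulfide features stay planted
BACKGROUND = "".join(c for c in AMINO_ACIDS if c != "C")

THREE_LETTER = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR", "X": "UNK",
}


class SynthError(ValueError):
    pass


@dataclass(frozen=True)
class FixtureSpec:
    """Generative parameters for one synthetic fixture sequence."""

    target_type: str  # I | IIa | IIb | III
    length: int
    motif: str
    cys_pairs: tuple[tuple[int, int], ...]
    loop3_insertion: int = 0
    loop2_deletion: int = 0
    clamp: bool = True
    mutation_rate: float = 0.0
    seed: int = 0
    protected_positions: tuple[int, ...] = ()  # 1-based string positions

    def __post_init__(self):
        if self.motif and self.target_type in ("I", "IIa", "IIb", "III"):
            if not (
                len(self.motif) == 5
                and self.motif[0] == "G"
                and self.motif[2] == "S"
                and self.motif[4] == "G"
            ):
                raise SynthError(f"motif {self.motif!r} does not conform to G-X-S-X-G")
        for a, b in self.cys_pairs:
            if not (1 <= a <= self.length and 1 <= b <= self.length):
                raise SynthError("cysteine positions outside sequence length")


# --- scaffold layout (base = reference = type IIb numbering) ----------------

BASE_LENGTH = 300
TRIAD = (160, 237, 206)  # ser, his, asp
MOTIF_WINDOW = (158, 162)
CLAMP_ANCHORS = (87, 185)
OXYANION = (87, 161)
SUBSITE1 = (87, 119, 185)
SUBSITE2 = (89, 214, 238)
EXTENDED_LOOP = tuple(range(239, 251))
LOOP_WINDOWS = {1: (83, 91), 2: (115, 123), 3: (163, 172)}
CANONICAL_DISULFIDES = ((203, 239), (273, 289))
TYPE1_DISULFIDE = (275, 292)

# type-discriminating residues at subsite II + extended loop (scored positions)
SCORED_RESIDUES = {
    "IIa": {89: "A", 214: "T", 238: "S", 243: "F", 246: "N"},
    "IIb": {89: "T", 214: "S", 238: "N", 243: "W", 246: "S"},
}

_LOOP2_DELETION = tuple(range(117, 122))  # 5 residues, removes subsite1 Q119
_LOOP3_INSERT_AFTER = 166
_LOOP3_INSERT_SEQ = "NALGD"  # 5 residues; mirrors the leucine-bearing insertion
_EXTLOOP_DELETION = tuple(range(239, 251))  # removed in the type I archetype
_TYPE3_DISULFIDES = ((64, 126), (273, 276))  # final (own) numbering

_DIVERGENCE_RATE = 0.12  # archetype-vs-archetype background divergence


def reference_annotation() -> ReferenceAnnotation:
    """Annotation of the type IIb archetype, the mapping reference."""
    return ReferenceAnnotation(
        ref_id="arch_IIb",
        triad=TRIAD,
        clamp_anchor_1=CLAMP_ANCHORS[0],
        clamp_anchor_2=CLAMP_ANCHORS[1],
        oxyanion_positions=OXYANION,
        subsite1=SUBSITE1,
        subsite2=SUBSITE2,
        extended_loop=EXTENDED_LOOP,
        loop_windows=dict(LOOP_WINDOWS),
        canonical_disulfides=CANONICAL_DISULFIDES,
    )


def _protected_base_positions() -> set[int]:
    """Base-numbering positions never touched by divergence or noise mutations."""
    prot: set[int] = set(TRIAD)
    prot.update(range(MOTIF_WINDOW[0], MOTIF_WINDOW[1] + 1))
    prot.update(CLAMP_ANCHORS)
    prot.update(OXYANION)
    prot.update(SUBSITE1)
    prot.update(SUBSITE2)
    prot.update(EXTENDED_LOOP)
    for s, e in LOOP_WINDOWS.values():
        prot.update(range(s - 3, e + 4))  # margin keeps loop alignments clean
    for a, b in CANONICAL_DISULFIDES + (TYPE1_DISULFIDE,):
        prot.update((a, b))
    for a, b in _TYPE3_DISULFIDES:
        prot.update((a, b))
    return prot


def _base_scaffold(rng: np.random.Generator) -> list[str]:
    res = list(rng.choice(list(BACKGROUND), size=BASE_LENGTH))
    s, h, d = TRIAD
    res[s - 1], res[h - 1], res[d - 1] = "S", "H", "D"
    res[CLAMP_ANCHORS[0] - 1] = "Y"
    res[CLAMP_ANCHORS[1] - 1] = "W"
    res[119 - 1] = "Q"
    return res


def _plant_motif(res: list[str], motif: str) -> None:
    start = MOTIF_WINDOW[0] - 1
    for i, c in enumerate(motif):
        res[start + i] = c


def _diverge(res: list[str], rng: np.random.Generator, protected: set[int]) -> None:
    for i in range(len(res)):
        if (i + 1) in protected or res[i] == "C":
            continue
        if rng.random() < _DIVERGENCE_RATE:
            choices = [c for c in BACKGROUND if c != res[i]]
            res[i] = str(rng.choice(choices))


@dataclass
class ReferenceSet:
    archetypes: dict[str, ProteinSequence]
    annotation: ReferenceAnnotation
    specs: dict[str, FixtureSpec]
    scored: dict[str, dict[int, tuple[str, float]]]


def make_reference_set(seed: int = 0) -> ReferenceSet:
    """Four archetype sequences plus the reference annotation and templates' scores.

    Deterministic: the same seed reproduces the set byte for byte.
    """
    rng = np.random.default_rng(seed)
    protected = _protected_base_positions()
    base = _base_scaffold(rng)
    sub_seeds = {t: int(s) for t, s in zip(
        ("I", "IIa", "IIb", "III"), rng.integers(0, 2**31 - 1, size=4)
    )}

    # --- type IIb: the reference itself ------------------------------------
    res_iib = list(base)
    _plant_motif(res_iib, "GWSMG")
    for p, aa in SCORED_RESIDUES["IIb"].items():
        res_iib[p - 1] = aa
    for a, b in CANONICAL_DISULFIDES:
        res_iib[a - 1] = res_iib[b - 1] = "C"
    seq_iib = ProteinSequence(id="arch_IIb", residues="".join(res_iib))

    # --- type IIa -----------------------------------------------------------
    res_iia = list(base)
    _plant_motif(res_iia, "GWSMG")
    for p, aa in SCORED_RESIDUES["IIa"].items():
        res_iia[p - 1] = aa
    for a, b in CANONICAL_DISULFIDES:
        res_iia[a - 1] = res_iia[b - 1] = "C"
    _diverge(res_iia, np.random.default_rng(sub_seeds["IIa"]), protected)
    seq_iia = ProteinSequence(id="arch_IIa", residues="".join(res_iia))

    # --- type I -------------------------------------------------------------
    res_i = list(base)
    _plant_motif(res_i, "GHSMG")
    a, b = TYPE1_DISULFIDE
    res_i[a - 1] = res_i[b - 1] = "C"
    _diverge(res_i, np.random.default_rng(sub_seeds["I"]), protected)
    # remove the extended loop (delete base positions, highest first)
    for p in sorted(_EXTLOOP_DELETION, reverse=True):
        del res_i[p - 1]
    seq_i = ProteinSequence(id="arch_I", residues="".join(res_i))

    # --- type III -----------------------------------------------------------
    res_iii = list(base)
    _plant_motif(res_iii, "GHSQG")
    res_iii[CLAMP_ANCHORS[0] - 1] = "T"  # break the clamp at anchor 1
    res_iii[CLAMP_ANCHORS[1] - 1] = "Y"
    _diverge(res_iii, np.random.default_rng(sub_seeds["III"]), protected)
    for p in sorted(_LOOP2_DELETION, reverse=True):
        del res_iii[p - 1]
    insert_at = _LOOP3_INSERT_AFTER - len(_LOOP2_DELETION)
    res_iii[insert_at:insert_at] = list(_LOOP3_INSERT_SEQ)
    for a, b in _TYPE3_DISULFIDES:  # planted in final (own) numbering
        res_iii[a - 1] = res_iii[b - 1] = "C"
    seq_iii = ProteinSequence(id="arch_III", residues="".join(res_iii))

    archetypes = {
        "I": seq_i,
        "IIa": seq_iia,
        "IIb": seq_iib,
        "III": seq_iii,
    }
    specs = {
        "I": FixtureSpec(
            target_type="I", length=len(seq_i), motif="GHSMG",
            cys_pairs=(
                (
                    TYPE1_DISULFIDE[0] - len(_EXTLOOP_DELETION),
                    TYPE1_DISULFIDE[1] - len(_EXTLOOP_DELETION),
                ),
            ),
            clamp=True, seed=sub_seeds["I"],
            protected_positions=_protected_in(seq_i, protected, deleted=_EXTLOOP_DELETION),
        ),
        "IIa": FixtureSpec(
            target_type="IIa", length=len(seq_iia), motif="GWSMG",
            cys_pairs=CANONICAL_DISULFIDES, clamp=True, seed=sub_seeds["IIa"],
            protected_positions=_protected_in(seq_iia, protected),
        ),
        "IIb": FixtureSpec(
            target_type="IIb", length=len(seq_iib), motif="GWSMG",
            cys_pairs=CANONICAL_DISULFIDES, clamp=True, seed=sub_seeds["IIb"],
            protected_positions=_protected_in(seq_iib, protected),
        ),
        "III": FixtureSpec(
            target_type="III", length=len(seq_iii), motif="GHSQG",
            cys_pairs=_TYPE3_DISULFIDES,
            loop3_insertion=len(_LOOP3_INSERT_SEQ),
            loop2_deletion=len(_LOOP2_DELETION),
            clamp=False, seed=sub_seeds["III"],
            protected_positions=_protected_in(
                seq_iii, protected, deleted=_LOOP2_DELETION,
                inserted=(insert_at + 1, len(_LOOP3_INSERT_SEQ)),
            ),
        ),
    }
    scored = {
        t: {
            p: (SCORED_RESIDUES["IIb" if t in ("I", "III") else t].get(p, base[p - 1]), 1.0)
            for p in SCORED_RESIDUES["IIb"]
        }
        for t in ("IIa", "IIb")
    }
    scored["I"] = {}
    scored["III"] = {}
    return ReferenceSet(
        archetypes=archetypes,
        annotation=reference_annotation(),
        specs=specs,
        scored=scored,
    )


def _protected_in(
    seq: ProteinSequence,
    protected_base: set[int],
    deleted: tuple[int, ...] = (),
    inserted: tuple[int, int] | None = None,
) -> tuple[int, ...]:
    """Translate protected base positions into an edited sequence's numbering."""
    out: set[int] = set()
    del_sorted = sorted(deleted)
    for p in protected_base:
        if p in deleted:
            continue
        shift = -sum(1 for d in del_sorted if d < p)
        q = p + shift
        if inserted is not None and q > inserted[0]:
            q += inserted[1]
        if 1 <= q <= len(seq.residues):
            out.add(q)
    if inserted is not None:
        out.update(range(inserted[0], inserted[0] + inserted[1] + 1))
    # cysteines are always protected
    out.update(i + 1 for i, c in enumerate(seq.residues) if c == "C")
    return tuple(sorted(out))


def mutate(seq: ProteinSequence, spec: FixtureSpec) -> ProteinSequence:
    """Point substitutions at ``spec.mutation_rate`` outside protected positions.

    Substitutions never create a cysteine, so planted disulfide patterns are
    stable; feature positions are left intact so that the generating type
    remains recoverable by construction at any rate.
    """
    rng = np.random.default_rng(spec.seed)
    protected = set(spec.protected_positions)
    res = list(seq.residues)
    for i in range(len(res)):
        if (i + 1) in protected or res[i] == "C":
            continue
        if rng.random() < spec.mutation_rate:
            choices = [c for c in BACKGROUND if c != res[i]]
            res[i] = str(rng.choice(choices))
    return replace(seq, residues="".join(res))


# ---------------------------------------------------------------------------
# toy structures
# ---------------------------------------------------------------------------


def make_toy_structure(
    seq: ProteinSequence,
    triad_positions: tuple[int, int, int] | None = None,
    cys_pairs: tuple[tuple[int, int], ...] = (),
    chain_id: str = "A",
) -> gemmi.Structure:
    """A helical Calpha trace with exact triad/disulfide side-chain geometry.

    Triad pseudo-atoms: Ser OG at the active-site point, His NE2 3.0 A from
    it, His ND1 offset, Asp OD1 2.8 A from ND1. Each cysteine pair's SG
    atoms sit 2.05 A apart, with pairs separated by >10 A so the greedy
    detector cannot cross-pair them. Positions must carry the right residue
    letters in ``seq`` (S/H/D for the triad, C for the pairs); anything else
    is an infeasible-geometry request.
    """
    triad_positions = triad_positions or ()
    if triad_positions:
        s, h, d = triad_positions
        got = (seq.residue_at(s), seq.residue_at(h), seq.residue_at(d))
        if got != ("S", "H", "D"):
            raise SynthError(
                f"triad positions {triad_positions} carry residues {got}, need (S, H, D)"
            )
    for a, b in cys_pairs:
        if seq.residue_at(a) != "C" or seq.residue_at(b) != "C":
            raise SynthError(f"cysteine pair ({a}, {b}) not cysteines in sequence")

    n = len(seq.residues)
    theta = np.deg2rad(100.0)
    ca = np.stack(
        [
            2.3 * np.cos(theta * np.arange(n)),
            2.3 * np.sin(theta * np.arange(n)),
            1.5 * np.arange(n),
        ],
        axis=1,
    )

    st = gemmi.Structure()
    st.name = f"toy_{seq.id}"
    model = gemmi.Model("1")
    chain = gemmi.Chain(chain_id)

    extra: dict[int, list[tuple[str, str, np.ndarray]]] = {}
    if triad_positions:
        s, h, d = triad_positions
        center = ca[[seq.string_position(p) - 1 for p in triad_positions]].mean(axis=0)
        P = center + np.array([8.0, 8.0, 0.0])
        og = P
        ne2 = P + np.array([3.0, 0.0, 0.0])
        nd1 = P + np.array([3.0, 1.4, 0.0])
        od1 = nd1 + np.array([0.0, 2.8, 0.0])
        extra.setdefault(s, []).append(("OG", "O", og))
        extra.setdefault(h, []).append(("NE2", "N", ne2))
        extra.setdefault(h, []).append(("ND1", "N", nd1))
        extra.setdefault(d, []).append(("OD1", "O", od1))
    for k, (a, b) in enumerate(cys_pairs):
        B = np.array([-15.0 - 10.0 * k, -15.0, 5.0 * k])
        extra.setdefault(a, []).append(("SG", "S", B - np.array([1.025, 0, 0])))
        extra.setdefault(b, []).append(("SG", "S", B + np.array([1.025, 0, 0])))

    for i, letter in enumerate(seq.residues):
        res = gemmi.Residue()
        res.name = THREE_LETTER.get(letter, "UNK")
        author = seq.author_number(i + 1)
        res.seqid = gemmi.SeqId(author, " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*ca[i])
        atom.occ = 1.0
        res.add_atom(atom)
        for name, elem, pos in extra.get(author, []):
            at = gemmi.Atom()
            at.name = name
            at.element = gemmi.Element(elem)
            at.pos = gemmi.Position(*pos)
            at.occ = 1.0
            res.add_atom(at)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_toy_pdb(st: gemmi.Structure, path: str | Path) -> None:
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# profile sampling
# ---------------------------------------------------------------------------


def sample_from_profile(
    hmm: ProfileHmm, n: int, seed: int = 0
) -> list[ProteinSequence]:
    """Sample ``n`` sequences by following the model's transitions/emissions."""
    rng = np.random.default_rng(seed)
    aa = list(AMINO_ACIDS)
    out: list[ProteinSequence] = []
    k = hmm.match_count
    for idx in range(n):
        residues: list[str] = []
        node, state = 0, M
        while True:
            probs = hmm.transitions[state, node]
            nxt = int(rng.choice(3, p=probs / probs.sum()))
            if nxt == M:
                if node == k:
                    break  # End
                node += 1
                state = M
                residues.append(str(rng.choice(aa, p=hmm.match_emissions[node])))
            elif nxt == I:
                state = I
                residues.append(str(rng.choice(aa, p=hmm.insert_emissions[node])))
            else:
                node += 1
                state = D
        out.append(ProteinSequence(id=f"sample_{idx}", residues="".join(residues)))
    return out


def random_sequences(
    n: int, length: int, seed: int = 0, alphabet: str = AMINO_ACIDS
) -> list[ProteinSequence]:
    """Uniform-random decoy sequences (the mining null)."""
    rng = np.random.default_rng(seed)
    return [
        ProteinSequence(
            id=f"decoy_{i}", residues="".join(rng.choice(list(alphabet), size=length))
        )
        for i in range(n)
    ]


def make_divergent_pair(
    identity_pct: float, length: int = 250, seed: int = 0
) -> tuple[ProteinSequence, ProteinSequence]:
    """A synthetic stand-in pair with a prescribed gapless percent identity.

    Emulates a mature-protein pairwise comparison (e.g. a query against its
    closest characterized relative) when the real sequences are not at hand:
    the second sequence carries exactly ``round((1-p) * length)`` scattered
    substitutions, so a global alignment is gapless and its identity equals
    the requested value to rounding. Both records are synthetic.
    """
    rng = np.random.default_rng(seed)
    a = list(rng.choice(list(BACKGROUND), size=length))
    n_mismatch = round((1.0 - identity_pct / 100.0) * length)
    pos = rng.choice(length, size=n_mismatch, replace=False)
    b = list(a)
    for p in pos:
        b[p] = str(rng.choice([c for c in BACKGROUND if c != b[p]]))
    return (
        ProteinSequence(id="synthetic_query", residues="".join(a)),
        ProteinSequence(id="synthetic_relative", residues="".join(b)),
    )


def write_fixture_suite(outdir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write the full fixture suite (FASTA, annotation TSV, toy PDBs) to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    refset = make_reference_set(seed)
    paths: dict[str, Path] = {}
    fasta = outdir / "archetypes.fasta"
    write_fasta(list(refset.archetypes.values()), fasta)
    paths["archetypes_fasta"] = fasta
    ann = outdir / "reference_annotation.tsv"
    write_annotation_tsv(refset.annotation, ann)
    paths["annotation_tsv"] = ann
    # the annotation is anchored to the type IIb archetype; ship it alone too
    ref_fa = outdir / "reference.fasta"
    write_fasta([refset.archetypes["IIb"]], ref_fa)
    paths["reference_fasta"] = ref_fa
    from .classify import default_templates, templates_to_json

    tmpl = outdir / "templates.json"
    templates_to_json(default_templates(refset.scored), tmpl)
    paths["templates_json"] = tmpl
    for t, seq in refset.archetypes.items():
        spec = refset.specs[t]
        triad = _own_triad(t)
        st = make_toy_structure(seq, triad, spec.cys_pairs)
        p = outdir / f"toy_{seq.id}.pdb"
        write_toy_pdb(st, p)
        paths[f"toy_pdb_{t}"] = p
    return paths


def _own_triad(target_type: str) -> tuple[int, int, int]:
    """Triad positions in each archetype's own numbering."""
    s, h, d = TRIAD
    if target_type == "III":
        shift = len(_LOOP2_DELETION)
        ins = len(_LOOP3_INSERT_SEQ)
        # deletions (117-121) precede all triad members; insertion at 166
        # (post-deletion 161) precedes asp and his but not ser
        return (s - shift, h - shift + ins, d - shift + ins)
    return (s, h, d)
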