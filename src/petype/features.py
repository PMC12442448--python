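"""Classification evidence extraction for PET hydrolase typing.

The typing system rests on a handful of active-site features: the lipase-box
pentapeptide G-X-S-X-G around the nucleophile serine (GHSMG in type I, GWSMG
in type II, GHSQG in the type III group), the number and position of
disulfide bonds, the presence of the pi-stacking clamp (two opposing
aromatics sandwiching the substrate ring, e.g. Y87/W185 in the type IIb
benchmark), the residues occupying subsites I and II, and the lengths of the
three active-site loops relative to a reference. All positions are anchored
to a reference protein through a global pairwise alignment, the same way
equivalences such as "Y180 is the W185 equivalent" are derived in structural
comparisons; a reference position sitting opposite a gap maps to
"unalignable" and is never forced.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import structure as structmod
from .align import SubstitutionMatrix, global_align
from .seqio import GAP, ProteinSequence

AROMATIC = {"F", "Y", "W"}
MOTIF_LABELS = ("GHSMG", "GWSMG", "GHSQG")


class FeatureError(ValueError):
    pass


class AnnotationError(FeatureError):
    pass


@dataclass(frozen=True)
class ReferenceAnnotation:
    """Author-numbered feature positions on a reference protein."""

    ref_id: str
    triad: tuple[int, int, int]  # (ser, his, asp)
    clamp_anchor_1: int
    clamp_anchor_2: int
    oxyanion_positions: tuple[int, int]
    subsite1: tuple[int, ...]
    subsite2: tuple[int, ...]
    extended_loop: tuple[int, ...]
    loop_windows: dict[int, tuple[int, int]]  # loop number -> (start, end)
    canonical_disulfides: tuple[tuple[int, int], ...]

    def all_positions(self) -> list[int]:
        out = list(self.triad) + [self.clamp_anchor_1, self.clamp_anchor_2]
        out += list(self.oxyanion_positions) + list(self.subsite1) + list(self.subsite2)
        out += list(self.extended_loop)
        for s, e in self.loop_windows.values():
            out += [s, e]
        for a, b in self.canonical_disulfides:
            out += [a, b]
        return out


def read_annotation_tsv(path: str | Path) -> ReferenceAnnotation:
    """Read a reference annotation from TSV rows (ref_id, feature_class, label, positions)."""
    rows: list[tuple[str, str, str, list[int]]] = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            if not line.strip():
                continue
            ref_id, fclass, label, pos = line.rstrip("\n").split("\t")
            rows.append((ref_id, fclass, label, [int(p) for p in pos.split(",") if p]))
    if not rows:
        raise AnnotationError(f"{path}: empty annotation table")
    ref_id = rows[0][0]
    by_class: dict[str, list[tuple[str, list[int]]]] = {}
    for _, fclass, label, pos in rows:
        by_class.setdefault(fclass, []).append((label, pos))

    def one(fclass: str) -> list[int]:
        return by_class[fclass][0][1]

    loop_windows = {
        int(label): (pos[0], pos[1]) for label, pos in by_class.get("loop_window", [])
    }
    return ReferenceAnnotation(
        ref_id=ref_id,
        triad=tuple(one("triad")),
        clamp_anchor_1=one("clamp_anchor_1")[0],
        clamp_anchor_2=one("clamp_anchor_2")[0],
        oxyanion_positions=tuple(one("oxyanion")),
        subsite1=tuple(one("subsite1")),
        subsite2=tuple(one("subsite2")),
        extended_loop=tuple(one("extended_loop")),
        loop_windows=loop_windows,
        canonical_disulfides=tuple(
            (pos[0], pos[1]) for _, pos in by_class.get("canonical_disulfide", [])
        ),
    )


def write_annotation_tsv(ann: ReferenceAnnotation, path: str | Path) -> None:
    def fmt(pos) -> str:
        return ",".join(str(p) for p in pos)

    with open(path, "w") as fh:
        fh.write("ref_id\tfeature_class\tlabel\tpositions\n")
        w = lambda fc, lbl, pos: fh.write(f"{ann.ref_id}\t{fc}\t{lbl}\t{fmt(pos)}\n")
        w("triad", "ser,his,asp", ann.triad)
        w("clamp_anchor_1", "", [ann.clamp_anchor_1])
        w("clamp_anchor_2", "", [ann.clamp_anchor_2])
        w("oxyanion", "", ann.oxyanion_positions)
        w("subsite1", "", ann.subsite1)
        w("subsite2", "", ann.subsite2)
        w("extended_loop", "", ann.extended_loop)
        for num, (s, e) in sorted(ann.loop_windows.items()):
            w("loop_window", str(num), [s, e])
        for a, b in ann.canonical_disulfides:
            w("canonical_disulfide", "", [a, b])


def load_builtin_annotation(name: str = "ispetase") -> ReferenceAnnotation:
    """A packaged reference annotation table (e.g. ``ispetase``).

    The shipped tables carry the residue equivalences cited for the
    characterized reference enzymes; subsite membership and loop windows are
    transcribed from structural comparisons and are provisional — edit the
    TSV to refine them for your reference of choice.
    """
    from importlib import resources

    path = resources.files("petype").joinpath(f"data/{name}_annotation.tsv")
    with resources.as_file(path) as p:
        return read_annotation_tsv(p)


# ---------------------------------------------------------------------------
# position mapping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PositionMap:
    """Reference author position -> query author position (None = unalignable)."""

    query_id: str
    ref_id: str
    ref_to_query: dict[int, int | None]
    query_to_ref: dict[int, int | None]
    aligned_ref: str
    aligned_query: str

    def get(self, ref_pos: int) -> int | None:
        if ref_pos not in self.ref_to_query:
            raise AnnotationError(f"position {ref_pos} outside reference")
        return self.ref_to_query[ref_pos]


def map_positions(
    query: ProteinSequence,
    reference: ProteinSequence,
    matrix: SubstitutionMatrix | None = None,
) -> PositionMap:
    """Map reference author positions onto the query via global alignment."""
    res = global_align(reference, query, matrix)
    r2q: dict[int, int | None] = {}
    q2r: dict[int, int | None] = {}
    ri = qi = 0
    for rc, qc in zip(res.aligned_a, res.aligned_b):
        rpos = qpos = None
        if rc != GAP:
            ri += 1
            rpos = reference.author_number(ri)
        if qc != GAP:
            qi += 1
            qpos = query.author_number(qi)
        if rpos is not None:
            r2q[rpos] = qpos
        if qpos is not None:
            q2r[qpos] = rpos
    return PositionMap(
        query_id=query.id,
        ref_id=reference.id,
        ref_to_query=r2q,
        query_to_ref=q2r,
        aligned_ref=res.aligned_a,
        aligned_query=res.aligned_b,
    )


# ---------------------------------------------------------------------------
# individual feature extractors
# ---------------------------------------------------------------------------


def extract_lipase_box(seq: ProteinSequence, ser_pos: int) -> tuple[str, str]:
    """The 5-mer centered on the catalytic serine and its variant label.

    Labels: one of the three family motifs, ``other`` for any other
    G-X-S-X-G, or ``nonconforming`` when the window does not fit the
    lipase-box pattern (not an error: the motif's absence is itself evidence).
    """
    p = seq.string_position(ser_pos)
    if p - 2 < 1 or p + 2 > len(seq.residues):
        raise FeatureError(
            f"lipase-box window around author position {ser_pos} out of range"
        )
    motif = seq.residues[p - 3 : p + 2]
    if motif in MOTIF_LABELS:
        label = motif
    elif motif[0] == "G" and motif[2] == "S" and motif[4] == "G":
        label = "other"
    else:
        label = "nonconforming"
    return motif, label


def check_clamp(
    query: ProteinSequence, pmap: PositionMap, ann: ReferenceAnnotation
) -> tuple[bool | None, str | None, str | None]:
    """Clamp status: True iff both mapped anchor residues are aromatic (F/Y/W).

    Returns (present, residue_at_anchor1, residue_at_anchor2); ``present`` is
    None ("undetermined") when an anchor is unalignable.
    """
    q1 = pmap.get(ann.clamp_anchor_1)
    q2 = pmap.get(ann.clamp_anchor_2)
    r1 = query.residue_at(q1) if q1 is not None else None
    r2 = query.residue_at(q2) if q2 is not None else None
    if r1 is None or r2 is None:
        return None, r1, r2
    return (r1 in AROMATIC and r2 in AROMATIC), r1, r2


def _window_columns(
    pmap: PositionMap, reference: ProteinSequence, start: int, end: int
) -> tuple[int, int, int] | None:
    """Alignment column span [c0, c1] of a reference window, and its ref residue count."""
    ref_positions = []
    ri = 0
    cols = {}
    for c, rc in enumerate(pmap.aligned_ref):
        if rc != GAP:
            ri += 1
            cols[reference.author_number(ri)] = c
    inside = [p for p in cols if start <= p <= end]
    if not inside:
        return None
    return min(cols[p] for p in inside), max(cols[p] for p in inside), len(inside)


def measure_loops(
    query: ProteinSequence,
    reference: ProteinSequence,
    ann: ReferenceAnnotation,
    pmap: PositionMap | None = None,
) -> dict[int, int | None]:
    """Signed loop-length differences vs the reference (positive = insertion).

    For each annotated loop window the delta is the number of query residues
    aligned within the window's column span minus the number of reference
    residues in the window. A window with no aligned query residue yields
    None (undefined).
    """
    pmap = pmap or map_positions(query, reference)
    out: dict[int, int | None] = {}
    for loop_num, (start, end) in sorted(ann.loop_windows.items()):
        span = _window_columns(pmap, reference, start, end)
        if span is None:
            out[loop_num] = None
            continue
        c0, c1, ref_count = span
        q_count = sum(
            1 for c in range(c0, c1 + 1) if pmap.aligned_query[c] != GAP
        )
        out[loop_num] = (q_count - ref_count) if q_count > 0 else None
    return out


def extended_loop_coverage(
    query: ProteinSequence,
    reference: ProteinSequence,
    ann: ReferenceAnnotation,
    pmap: PositionMap | None = None,
) -> float:
    """Fraction of the extended-loop window covered by aligned query residues."""
    pmap = pmap or map_positions(query, reference)
    if not ann.extended_loop:
        return 0.0
    start, end = min(ann.extended_loop), max(ann.extended_loop)
    span = _window_columns(pmap, reference, start, end)
    if span is None:
        return 0.0
    c0, c1, ref_count = span
    covered = sum(
        1
        for c in range(c0, c1 + 1)
        if pmap.aligned_query[c] != GAP and pmap.aligned_ref[c] != GAP
    )
    return covered / ref_count


def infer_disulfides_from_sequence(
    query: ProteinSequence,
    ann: ReferenceAnnotation,
    pmap: PositionMap,
    structure_bonds: list[structmod.DisulfideBond] | None = None,
    tolerance: int = 2,
) -> tuple[list[tuple[tuple[int, int], bool]], list[int]]:
    """Disulfide pairs with canonical flags, plus unpaired cysteines.

    Structure-derived bonds, when supplied, override sequence inference.
    Sequence inference first pairs cysteines sitting within ``tolerance``
    alignment positions of both members of a reference canonical pair, then
    pairs the remainder consecutively along the chain (a stated heuristic; a
    structure settles it). A pair is canonical when both members lie within
    the tolerance of one reference canonical pair.
    """
    cys_positions = [
        query.author_number(i + 1)
        for i, c in enumerate(query.residues)
        if c == "C"
    ]
    # map canonical reference pairs into query coordinates
    mapped_canon: list[tuple[int | None, int | None]] = [
        (pmap.ref_to_query.get(a), pmap.ref_to_query.get(b))
        for a, b in ann.canonical_disulfides
    ]

    def is_canonical(pair: tuple[int, int]) -> bool:
        for qa, qb in mapped_canon:
            if qa is None or qb is None:
                continue
            lo, hi = sorted(pair)
            la, lb = sorted((qa, qb))
            if abs(lo - la) <= tolerance and abs(hi - lb) <= tolerance:
                return True
        return False

    if structure_bonds is not None:
        pairs = [(tuple(sorted((b.cys_a, b.cys_b))), None) for b in structure_bonds]
        bonded = {p for pr, _ in pairs for p in pr}
        unpaired = [c for c in cys_positions if c not in bonded]
        return [(pr, is_canonical(pr)) for pr, _ in pairs], unpaired

    remaining = list(cys_positions)
    pairs_out: list[tuple[int, int]] = []
    for qa, qb in mapped_canon:
        if qa is None or qb is None:
            continue
        ca = next((c for c in remaining if abs(c - qa) <= tolerance), None)
        cb = next((c for c in remaining if abs(c - qb) <= tolerance and c != ca), None)
        if ca is not None and cb is not None:
            pairs_out.append(tuple(sorted((ca, cb))))
            remaining.remove(ca)
            remaining.remove(cb)
    while len(remaining) >= 2:
        a = remaining.pop(0)
        b = remaining.pop(0)
        pairs_out.append((a, b))
    pairs_out.sort()
    return [(pr, is_canonical(pr)) for pr in pairs_out], remaining


# ---------------------------------------------------------------------------
# the full report
# ---------------------------------------------------------------------------


@dataclass
class FeatureReport:
    query_id: str
    ref_id: str
    lipase_box: str | None
    lipase_box_label: str | None
    triad_query_positions: tuple[int | None, int | None, int | None]
    clamp_present: bool | None
    clamp_pos1_residue: str | None
    clamp_pos2_residue: str | None
    oxyanion_residues: tuple[str | None, ...]
    subsite1_residues: dict[int, str | None]
    subsite2_residues: dict[int, str | None]
    extended_loop_residues: dict[int, str | None]
    disulfide_pairs: list[tuple[tuple[int, int], bool]]
    unpaired_cysteines: list[int]
    extended_loop_present: bool
    loop_deltas: dict[int, int | None]
    structure_derived: bool
    blocked: bool = False
    notes: list[str] = field(default_factory=list)

    @property
    def n_disulfides(self) -> int:
        return len(self.disulfide_pairs)

    @property
    def all_canonical(self) -> bool:
        return bool(self.disulfide_pairs) and all(c for _, c in self.disulfide_pairs)

    @property
    def all_noncanonical(self) -> bool:
        return bool(self.disulfide_pairs) and all(not c for _, c in self.disulfide_pairs)

    def to_json(self) -> str:
        d = asdict(self)
        d["loop_deltas"] = {str(k): v for k, v in self.loop_deltas.items()}
        d["subsite1_residues"] = {str(k): v for k, v in self.subsite1_residues.items()}
        d["subsite2_residues"] = {str(k): v for k, v in self.subsite2_residues.items()}
        d["extended_loop_residues"] = {
            str(k): v for k, v in self.extended_loop_residues.items()
        }
        return json.dumps(d, indent=2)

    def to_text(self) -> str:
        lines = [
            f"query            {self.query_id} (vs reference {self.ref_id})",
            f"lipase box       {self.lipase_box or 'n/a'} [{self.lipase_box_label}]",
            f"clamp            {'undetermined' if self.clamp_present is None else ('present' if self.clamp_present else 'absent')}"
            f" ({self.clamp_pos1_residue}/{self.clamp_pos2_residue})",
            f"disulfides       {self.n_disulfides}: "
            + ", ".join(
                f"{a}-{b}{'' if canon else ' (non-canonical)'}"
                for (a, b), canon in self.disulfide_pairs
            ),
            f"extended loop    {'present' if self.extended_loop_present else 'absent'}",
            "loop deltas      "
            + ", ".join(
                f"loop{n}: {'undef' if d is None else f'{d:+d}'}"
                for n, d in sorted(self.loop_deltas.items())
            ),
        ]
        if self.blocked:
            lines.append("WARNING          catalytic serine unlocatable; typing blocked")
        return "\n".join(lines)


def extract_features(
    query: ProteinSequence,
    reference: ProteinSequence,
    ann: ReferenceAnnotation,
    model: structmod.StructureModel | None = None,
    extended_loop_min_coverage: float = 0.5,
) -> FeatureReport:
    """Build the complete evidence report for one query.

    Structure-derived facts (triad position, disulfide pairs) supersede
    sequence inference whenever coordinates are supplied; sequence-only
    reports are flagged ``structure_derived=False``.
    """
    pmap = map_positions(query, reference)
    notes: list[str] = []
    structure_derived = model is not None

    triad_q: tuple[int | None, int | None, int | None]
    struct_bonds = None
    ser_pos: int | None = None
    if model is not None:
        struct_bonds = structmod.detect_disulfides(model)
        try:
            triad = structmod.detect_triad(model)
            triad_q = (triad.ser, triad.his, triad.asp)
            ser_pos = triad.ser
        except structmod.NoTriadError:
            notes.append("no geometric triad; falling back to sequence inference")
            triad_q = tuple(pmap.get(p) for p in ann.triad)
            ser_pos = triad_q[0]
    else:
        triad_q = tuple(pmap.get(p) for p in ann.triad)
        ser_pos = triad_q[0]

    blocked = ser_pos is None
    lipase_box = label = None
    if ser_pos is not None:
        try:
            lipase_box, label = extract_lipase_box(query, ser_pos)
        except (FeatureError, IndexError):
            blocked = True
            notes.append("lipase-box window out of range")

    clamp_present, r1, r2 = check_clamp(query, pmap, ann)
    oxy = tuple(
        query.residue_at(q) if (q := pmap.get(p)) is not None else None
        for p in ann.oxyanion_positions
    )
    sub1 = {
        p: (query.residue_at(q) if (q := pmap.get(p)) is not None else None)
        for p in ann.subsite1
    }
    sub2 = {
        p: (query.residue_at(q) if (q := pmap.get(p)) is not None else None)
        for p in ann.subsite2
    }
    ext = {
        p: (query.residue_at(q) if (q := pmap.get(p)) is not None else None)
        for p in ann.extended_loop
    }
    pairs, unpaired = infer_disulfides_from_sequence(
        query, ann, pmap, structure_bonds=struct_bonds
    )
    deltas = measure_loops(query, reference, ann, pmap)
    coverage = extended_loop_coverage(query, reference, ann, pmap)

    return FeatureReport(
        query_id=query.id,
        ref_id=reference.id,
        lipase_box=lipase_box,
        lipase_box_label=label,
        triad_query_positions=triad_q,
        clamp_present=clamp_present,
        clamp_pos1_residue=r1,
        clamp_pos2_residue=r2,
        oxyanion_residues=oxy,
        subsite1_residues=sub1,
        subsite2_residues=sub2,
        extended_loop_residues=ext,
        disulfide_pairs=pairs,
        unpaired_cysteines=unpaired,
        extended_loop_present=coverage >= extended_loop_min_coverage,
        loop_deltas=deltas,
        structure_derived=structure_derived,
        blocked=blocked,
        notes=notes,
    )
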