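"""Coordinate-level analyses: disulfides, catalytic triads, superposition.

Parsing is delegated to gemmi (wwPDB v3.3 column handling, altloc and
multi-model bookkeeping); the geometric predicates on top are deliberately
local and simple. A disulfide is an SG-SG contact under 2.3 A (the covalent
bond is ~2.05 A; the margin absorbs refinement noise while excluding free
cysteine pairs). A Ser-His-Asp/Glu triad is called from hydrogen-bond-range
contacts Ser:OG-His:NE2 and His:ND1-Asp:OD1/OD2 (<= 3.5 A each), taking the
triple with the smallest summed distance, which makes the call deterministic
where visual inspection would be used in practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np


class StructureError(ValueError):
    pass


class EmptyStructureError(StructureError):
    pass


class NoTriadError(StructureError):
    """No Ser/His/Asp(Glu) triple satisfies the distance thresholds."""


class DegenerateFitError(StructureError):
    pass


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    xyz: tuple[float, float, float]
    occupancy: float = 1.0
    altloc: str = ""


@dataclass(frozen=True)
class Residue:
    number: int
    name: str
    atoms: tuple[Atom, ...]
    insertion_code: str = ""
    is_het: bool = False

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass(frozen=True)
class Chain:
    id: str
    residues: tuple[Residue, ...]


@dataclass(frozen=True)
class StructureModel:
    id: str
    chains: tuple[Chain, ...]

    def chain(self, chain_id: str | None = None) -> Chain:
        if chain_id is None:
            return self.chains[0]
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise KeyError(chain_id)


@dataclass(frozen=True)
class DisulfideBond:
    cys_a: int
    cys_b: int
    sg_distance: float

    def __post_init__(self):
        if self.cys_a > self.cys_b:
            raise ValueError("cys_a must be ordered before cys_b")


@dataclass(frozen=True)
class TriadCall:
    ser: int
    his: int
    asp: int
    ser_his_dist: float
    his_asp_dist: float
    acid_is_glu: bool = False


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    retained_pairs: int
    cycles_run: int


def read_pdb(path: str | Path) -> StructureModel:
    """Parse a PDB file: first model only, highest-occupancy altloc per atom.

    Waters and other heteroatoms are retained but flagged ``is_het``.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as e:
        raise StructureError(f"{path}: cannot parse PDB file: {e}") from e
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models/ATOM records")
    model = st[0]
    chains: list[Chain] = []
    n_atoms = 0
    for ch in model:
        residues: list[Residue] = []
        for res in ch:
            # keep one atom per name: highest occupancy, ties to earlier altloc
            best: dict[str, gemmi.Atom] = {}
            for at in res:
                prev = best.get(at.name)
                if prev is None or at.occ > prev.occ:
                    best[at.name] = at
            atoms = tuple(
                Atom(
                    name=a.name,
                    element=a.element.name,
                    xyz=(a.pos.x, a.pos.y, a.pos.z),
                    occupancy=a.occ,
                    altloc=a.altloc if a.altloc != "\x00" else "",
                )
                for a in best.values()
            )
            if not atoms:
                continue
            n_atoms += len(atoms)
            residues.append(
                Residue(
                    number=res.seqid.num,
                    name=res.name,
                    atoms=atoms,
                    insertion_code=(res.seqid.icode or "").strip(),
                    is_het=res.het_flag == "H",
                )
            )
        if residues:
            chains.append(Chain(id=ch.name, residues=tuple(residues)))
    if n_atoms == 0:
        raise EmptyStructureError(f"{path}: no ATOM records")
    return StructureModel(id=st.name or path.stem, chains=tuple(chains))


def _dist(a: Atom, b: Atom) -> float:
    return float(np.linalg.norm(np.asarray(a.xyz) - np.asarray(b.xyz)))


def detect_disulfides(
    model: StructureModel, max_sg_dist: float = 2.3, chain_id: str | None = None
) -> list[DisulfideBond]:
    """All Cys pairs with SG-SG distance <= threshold, greedily by ascending distance.

    Each cysteine joins at most one bond. Returns an empty list when the chain
    has no cysteines.
    """
    chain = model.chain(chain_id)
    cys = [
        (r.number, r.atom("SG"))
        for r in chain.residues
        if r.name == "CYS" and r.atom("SG") is not None
    ]
    candidates = []
    for i in range(len(cys)):
        for j in range(i + 1, len(cys)):
            d = _dist(cys[i][1], cys[j][1])
            if d <= max_sg_dist:
                a, b = sorted((cys[i][0], cys[j][0]))
                candidates.append((d, a, b))
    candidates.sort()
    used: set[int] = set()
    bonds: list[DisulfideBond] = []
    for d, a, b in candidates:
        if a in used or b in used:
            continue
        used.update((a, b))
        bonds.append(DisulfideBond(cys_a=a, cys_b=b, sg_distance=d))
    bonds.sort(key=lambda bd: (bd.cys_a, bd.cys_b))
    return bonds


def detect_triad(
    model: StructureModel,
    d1: float = 3.5,
    d2: float = 3.5,
    chain_id: str | None = None,
) -> TriadCall:
    """Find the catalytic Ser-His-Asp(/Glu) triple with minimal summed distances.

    Constraints: Ser:OG-His:NE2 <= d1 and His:ND1-Asp:(OD1|OD2) <= d2
    (Glu accepted via OE1/OE2 and flagged). Raises :class:`NoTriadError` when
    no triple qualifies, in which case classification proceeds sequence-only.
    """
    chain = model.chain(chain_id)
    sers = [(r.number, r.atom("OG")) for r in chain.residues if r.name == "SER"]
    hiss = [
        (r.number, r.atom("NE2"), r.atom("ND1"))
        for r in chain.residues
        if r.name == "HIS"
    ]
    acids = []
    for r in chain.residues:
        if r.name == "ASP":
            acids.append((r.number, [r.atom("OD1"), r.atom("OD2")], False))
        elif r.name == "GLU":
            acids.append((r.number, [r.atom("OE1"), r.atom("OE2")], True))

    best: TriadCall | None = None
    best_sum = float("inf")
    for s_num, og in sers:
        if og is None:
            continue
        for h_num, ne2, nd1 in hiss:
            if ne2 is None or nd1 is None:
                continue
            dsh = _dist(og, ne2)
            if dsh > d1:
                continue
            for a_num, oxys, is_glu in acids:
                dha = min((_dist(nd1, o) for o in oxys if o is not None), default=np.inf)
                if dha > d2:
                    continue
                total = dsh + dha
                if total < best_sum:
                    best_sum = total
                    best = TriadCall(
                        ser=s_num,
                        his=h_num,
                        asp=a_num,
                        ser_his_dist=dsh,
                        his_asp_dist=dha,
                        acid_is_glu=is_glu,
                    )
    if best is None:
        raise NoTriadError("no Ser-His-Asp/Glu triple satisfies distance thresholds")
    return best


def _kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal proper rotation+translation mapping mobile onto target (SVD)."""
    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    H = (mobile - cm).T @ (target - ct)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ct - R @ cm
    return R, t


def superpose(
    mobile: np.ndarray,
    target: np.ndarray,
    cycles: int = 5,
    reject_cutoff: float = 2.0,
) -> SuperpositionResult:
    """Iterative least-squares Calpha superposition with outlier rejection.

    After each least-squares fit, all pairs deviating by more than
    ``reject_cutoff`` are dropped at once and the fit repeated, up to
    ``cycles`` times or until no pair is dropped (the protocol used by
    structure viewers' refine-align commands). RMSD is over retained pairs.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise StructureError("mobile/target must be matching (n, 3) arrays")
    keep = np.arange(len(mobile))
    if len(keep) < 3:
        raise DegenerateFitError("need at least 3 paired coordinates")
    R = np.eye(3)
    t = np.zeros(3)
    cycles_run = 0
    for _ in range(cycles):
        cycles_run += 1
        R, t = _kabsch(mobile[keep], target[keep])
        dev = np.linalg.norm((mobile[keep] @ R.T + t) - target[keep], axis=1)
        bad = dev > reject_cutoff
        if not bad.any():
            break
        keep = keep[~bad]
        if len(keep) < 3:
            raise DegenerateFitError("fewer than 3 pairs remain after rejection")
    R, t = _kabsch(mobile[keep], target[keep])
    dev = np.linalg.norm((mobile[keep] @ R.T + t) - target[keep], axis=1)
    return SuperpositionResult(
        rotation=R,
        translation=t,
        rmsd=float(np.sqrt((dev**2).mean())),
        retained_pairs=len(keep),
        cycles_run=cycles_run,
    )


def chain_sequence(model: StructureModel, chain_id: str | None = None) -> str:
    """One-letter sequence of a chain's polymer residues (X for non-standard)."""
    chain = model.chain(chain_id)
    out = []
    for r in chain.residues:
        if r.is_het or r.name in ("HOH", "WAT"):
            continue
        info = gemmi.find_tabulated_residue(r.name)
        one = info.one_letter_code.upper() if info else "x"
        out.append(one if one.isalpha() and one != " " else "X")
    return "".join(out)


def ca_coordinates(
    model: StructureModel, chain_id: str | None = None
) -> dict[int, np.ndarray]:
    """Author residue number -> Calpha coordinate for one chain."""
    chain = model.chain(chain_id)
    out: dict[int, np.ndarray] = {}
    for r in chain.residues:
        ca = r.atom("CA")
        if ca is not None:
            out[r.number] = np.asarray(ca.xyz)
    return out
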