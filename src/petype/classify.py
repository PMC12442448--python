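"""Rule-based PET hydrolase type calling (I | IIa | IIb | III | unclassified).

Each type is a template of gating predicates plus scored expected residues:

* type I   — exactly one disulfide bond and no extended loop;
* type IIa/IIb — two disulfides at the canonical (type II) positions and an
  extended loop; a and b differ only in their scored subsite II /
  extended-loop residue composition;
* type III — lipase-box GHSQG, no pi-stacking clamp, at least two disulfides
  all at non-canonical positions, and a loop-3 extension of >= +3 residues.

The type III gate is conjunctive: its defining features are presented as
co-occurring, so all must hold. Among templates whose gates all pass, the
highest fraction of matching scored positions wins; no gate passed, or a
tie at the top, yields ``unclassified`` — a first-class outcome, since the
motivating enzyme family could not be placed in the older I/IIa/IIb scheme.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .features import FeatureReport

TYPE_LABELS = ("I", "IIa", "IIb", "III")


class ClassifyError(ValueError):
    pass


class BlockedCallError(ClassifyError):
    """The feature report carries a classification-blocking flag."""


@dataclass(frozen=True)
class TypeTemplate:
    """Gates and scored expected residues for one PETase type."""

    type_label: str
    disulfide_count: int | None = None  # exact required count (None = no gate)
    disulfide_min: int | None = None
    disulfides_canonical: str | None = None  # "all" | "none" | None
    extended_loop: bool | None = None
    motif_in: tuple[str, ...] | None = None
    clamp: bool | None = None
    loop3_delta_min: int | None = None
    # reference author position -> (accepted residues, weight)
    scored_positions: dict[int, tuple[str, float]] = field(default_factory=dict)

    def gates(self, r: FeatureReport) -> dict[str, bool]:
        g: dict[str, bool] = {}
        if self.disulfide_count is not None:
            g[f"disulfide count == {self.disulfide_count}"] = (
                r.n_disulfides == self.disulfide_count
            )
        if self.disulfide_min is not None:
            g[f"disulfide count >= {self.disulfide_min}"] = (
                r.n_disulfides >= self.disulfide_min
            )
        if self.disulfides_canonical == "all":
            g["disulfides at canonical positions"] = r.all_canonical
        elif self.disulfides_canonical == "none":
            g["disulfides all non-canonical"] = r.all_noncanonical
        if self.extended_loop is not None:
            g["extended loop " + ("present" if self.extended_loop else "absent")] = (
                r.extended_loop_present == self.extended_loop
            )
        if self.motif_in is not None:
            g["lipase box in " + "/".join(self.motif_in)] = (
                r.lipase_box_label in self.motif_in
            )
        if self.clamp is not None:
            g["clamp " + ("present" if self.clamp else "absent")] = (
                r.clamp_present is self.clamp
            )
        if self.loop3_delta_min is not None:
            d3 = r.loop_deltas.get(3)
            g[f"loop-3 delta >= +{self.loop3_delta_min}"] = (
                d3 is not None and d3 >= self.loop3_delta_min
            )
        return g

    def score(self, r: FeatureReport) -> float:
        """Fraction (weighted) of scored positions whose query residue matches."""
        if not self.scored_positions:
            return 0.0
        lookup: dict[int, str | None] = {}
        lookup.update(r.subsite1_residues)
        lookup.update(r.subsite2_residues)
        lookup.update(r.extended_loop_residues)
        total = got = 0.0
        for pos, (accepted, weight) in self.scored_positions.items():
            total += weight
            q = lookup.get(pos)
            if q is not None and q in accepted:
                got += weight
        return got / total if total else 0.0


@dataclass
class TypeCall:
    query_id: str
    call: str  # a type label or "unclassified"
    per_template_score: dict[str, float]
    gating_results: dict[str, dict[str, bool]]
    rationale: list[str]

    def to_json(self) -> str:
        return json.dumps(
            {
                "query_id": self.query_id,
                "call": self.call,
                "per_template_score": self.per_template_score,
                "gating_results": self.gating_results,
                "rationale": self.rationale,
            },
            indent=2,
        )


def default_templates(
    scored: dict[str, dict[int, tuple[str, float]]] | None = None
) -> list[TypeTemplate]:
    """The four built-in type templates; ``scored`` adds per-type expected residues."""
    scored = scored or {}
    return [
        TypeTemplate(
            type_label="I",
            disulfide_count=1,
            extended_loop=False,
            scored_positions=scored.get("I", {}),
        ),
        TypeTemplate(
            type_label="IIa",
            disulfide_count=2,
            disulfides_canonical="all",
            extended_loop=True,
            scored_positions=scored.get("IIa", {}),
        ),
        TypeTemplate(
            type_label="IIb",
            disulfide_count=2,
            disulfides_canonical="all",
            extended_loop=True,
            scored_positions=scored.get("IIb", {}),
        ),
        TypeTemplate(
            type_label="III",
            motif_in=("GHSQG",),
            clamp=False,
            disulfide_min=2,
            disulfides_canonical="none",
            loop3_delta_min=3,
            scored_positions=scored.get("III", {}),
        ),
    ]


def classify_petase(
    report: FeatureReport, templates: list[TypeTemplate] | None = None
) -> TypeCall:
    """Turn a feature report into a type call with an auditable evidence trail."""
    if report.blocked:
        raise BlockedCallError(
            f"{report.query_id}: catalytic serine could not be located"
        )
    templates = templates if templates is not None else default_templates()
    gating: dict[str, dict[str, bool]] = {}
    scores: dict[str, float] = {}
    passers: list[str] = []
    for t in templates:
        g = t.gates(report)
        gating[t.type_label] = g
        scores[t.type_label] = t.score(report)
        if all(g.values()):
            passers.append(t.type_label)

    if not passers:
        call = "unclassified"
    elif len(passers) == 1:
        call = passers[0]
    else:
        ranked = sorted(passers, key=lambda lbl: -scores[lbl])
        if scores[ranked[0]] > scores[ranked[1]]:
            call = ranked[0]
        else:
            call = "unclassified"

    rationale = _rationale(report, call, gating, scores, passers)
    return TypeCall(
        query_id=report.query_id,
        call=call,
        per_template_score=scores,
        gating_results=gating,
        rationale=rationale,
    )


def _rationale(
    report: FeatureReport,
    call: str,
    gating: dict[str, dict[str, bool]],
    scores: dict[str, float],
    passers: list[str],
) -> list[str]:
    lines: list[str] = []
    if call != "unclassified":
        lines.append(f"called type {call}")
        for gate, ok in gating[call].items():
            lines.append(f"  gate passed: {gate}")
        if report.lipase_box:
            lines.append(f"  lipase box {report.lipase_box}")
        if report.clamp_present is not None:
            lines.append(
                "  clamp " + ("present" if report.clamp_present else "absent")
                + f" ({report.clamp_pos1_residue}/{report.clamp_pos2_residue})"
            )
        for (a, b), canon in report.disulfide_pairs:
            lines.append(
                f"  disulfide {a}-{b} ({'canonical' if canon else 'non-canonical'})"
            )
        lines.append(f"  scored-position match {scores[call]:.2f}")
    else:
        if passers:
            lines.append(
                "unclassified: tie among gate-passing templates "
                + ", ".join(passers)
            )
        else:
            lines.append("unclassified: no template's gates all passed")
        for lbl, g in gating.items():
            for gate, ok in g.items():
                if not ok:
                    lines.append(f"  type {lbl} failed: {gate}")
    return lines


def explain(call: TypeCall) -> str:
    return "\n".join(call.rationale)


def calls_to_tsv(calls: list[TypeCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("query_id\tcall\t" + "\t".join(f"score_{t}" for t in TYPE_LABELS) + "\n")
        for c in calls:
            fh.write(
                c.query_id
                + "\t"
                + c.call
                + "\t"
                + "\t".join(f"{c.per_template_score.get(t, 0.0):.3f}" for t in TYPE_LABELS)
                + "\n"
            )


def templates_from_json(path: str | Path) -> list[TypeTemplate]:
    """Load editable type templates from a JSON file."""
    data = json.loads(Path(path).read_text())
    out = []
    for t in data:
        sp = {
            int(k): (v[0], float(v[1])) for k, v in t.get("scored_positions", {}).items()
        }
        out.append(
            TypeTemplate(
                type_label=t["type_label"],
                disulfide_count=t.get("disulfide_count"),
                disulfide_min=t.get("disulfide_min"),
                disulfides_canonical=t.get("disulfides_canonical"),
                extended_loop=t.get("extended_loop"),
                motif_in=tuple(t["motif_in"]) if t.get("motif_in") else None,
                clamp=t.get("clamp"),
                loop3_delta_min=t.get("loop3_delta_min"),
                scored_positions=sp,
            )
        )
    return out


def templates_to_json(templates: list[TypeTemplate], path: str | Path) -> None:
    data = []
    for t in templates:
        data.append(
            {
                "type_label": t.type_label,
                "disulfide_count": t.disulfide_count,
                "disulfide_min": t.disulfide_min,
                "disulfides_canonical": t.disulfides_canonical,
                "extended_loop": t.extended_loop,
                "motif_in": list(t.motif_in) if t.motif_in else None,
                "clamp": t.clamp,
                "loop3_delta_min": t.loop3_delta_min,
                "scored_positions": {
                    str(k): [v[0], v[1]] for k, v in t.scored_positions.items()
                },
            }
        )
    Path(path).write_text(json.dumps(data, indent=2))
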