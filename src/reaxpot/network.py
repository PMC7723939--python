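"""Reaction-network data model and flat-file I/O.

The network is a KEGG-style catalogue of biochemical reactions: each reaction
has substrates and products (compounds, ``C`` identifiers), a set of
catalysing enzymes, and an *approximate stoichiometric exponent* ``m`` per
compound slot — ``m = 1`` for a stoichiometric coefficient of 1 and ``m = 2``
for any larger coefficient. Enzymes decompose into isoenzymes, and isoenzymes
into subunit genes; this structure drives the min/sum activity aggregation in
:mod:`reaxpot.preprocess`.

The library never talks to the KEGG REST API: networks are loaded from three
delimited flat files (``reactions.tsv``, ``enzymes.tsv``, ``pathways.tsv``)
documented in :func:`load_network`, or generated synthetically by
:mod:`reaxpot.simulate`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "Compound",
    "Reaction",
    "EnzymeDefinition",
    "Pathway",
    "ReactionNetwork",
    "NetworkError",
    "EquationParseError",
    "parse_reaction_equation",
    "format_reaction_equation",
    "load_network",
    "serialize_network",
    "validate_network",
]


class NetworkError(ValueError):
    """A reaction network violates a structural invariant."""


class EquationParseError(NetworkError):
    """A reaction equation string could not be parsed."""


@dataclass(frozen=True)
class Compound:
    id: str
    name: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise NetworkError("compound id must be non-empty")


@dataclass(frozen=True)
class Reaction:
    """A reaction with approximate stoichiometry.

    ``substrates`` and ``products`` are tuples of ``(compound_id, m)`` with
    ``m`` in {1, 2}; ``reversible`` records whether the source equation used
    ``<=>``.
    """

    id: str
    substrates: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    enzymes: tuple[str, ...] = ()
    reversible: bool = True

    def __post_init__(self) -> None:
        if not self.substrates or not self.products:
            raise NetworkError(f"reaction {self.id!r}: needs >=1 substrate and >=1 product")
        for side in (self.substrates, self.products):
            for cid, m in side:
                if m not in (1, 2):
                    raise NetworkError(f"reaction {self.id!r}: m={m} for {cid!r} not in {{1, 2}}")
        sub_ids = [c for c, _ in self.substrates]
        prod_ids = [c for c, _ in self.products]
        for ids, label in ((sub_ids, "substrate"), (prod_ids, "product")):
            dup = {c for c in ids if ids.count(c) > 1}
            if dup:
                raise NetworkError(f"reaction {self.id!r}: duplicate {label}(s) {sorted(dup)}")
        both = set(sub_ids) & set(prod_ids)
        if both:
            raise NetworkError(
                f"reaction {self.id!r}: compound(s) {sorted(both)} appear on both sides"
            )

    @property
    def compound_ids(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.substrates) + tuple(c for c, _ in self.products)


@dataclass(frozen=True)
class EnzymeDefinition:
    """An enzyme as a tuple of isoenzymes, each a tuple of subunit gene ids."""

    id: str
    isoenzymes: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        if not self.isoenzymes:
            raise NetworkError(f"enzyme {self.id!r}: needs >=1 isoenzyme")
        for iso in self.isoenzymes:
            if not iso:
                raise NetworkError(f"enzyme {self.id!r}: isoenzyme with no subunit genes")

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(g for iso in self.isoenzymes for g in iso)


@dataclass(frozen=True)
class Pathway:
    id: str
    name: str
    compounds: frozenset[str] = frozenset()
    reactions: frozenset[str] = frozenset()


@dataclass
class ReactionNetwork:
    compounds: dict[str, Compound] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    enzymes: dict[str, EnzymeDefinition] = field(default_factory=dict)
    pathways: dict[str, Pathway] = field(default_factory=dict)

    def validate(self) -> list[str]:
        return validate_network(self)

    def enzyme_genes(self, enzyme_id: str) -> tuple[str, ...]:
        return self.enzymes[enzyme_id].gene_ids


_ARROW_RE = re.compile(r"<=>|=>|<=")
_TERM_RE = re.compile(r"^(?:(\d+)\s+)?([A-Za-z]\w*)$")


def _parse_side(side: str, equation: str) -> tuple[tuple[str, int], ...]:
    side = side.strip()
    if not side:
        raise EquationParseError(f"empty reaction side in {equation!r}")
    out: list[tuple[str, int]] = []
    seen: set[str] = set()
    for raw in side.split("+"):
        term = raw.strip()
        match = _TERM_RE.match(term)
        if match is None:
            raise EquationParseError(f"malformed term {term!r} in {equation!r}")
        coef_str, cid = match.groups()
        if coef_str is not None and int(coef_str) < 1:
            raise EquationParseError(f"non-positive coefficient in term {term!r}")
        coef = 1 if coef_str is None else int(coef_str)
        if cid in seen:
            raise EquationParseError(f"duplicate compound {cid!r} on one side of {equation!r}")
        seen.add(cid)
        out.append((cid, 1 if coef == 1 else 2))
    return tuple(out)


def parse_reaction_equation(
    equation: str,
) -> tuple[tuple[tuple[str, int], ...], tuple[tuple[str, int], ...], bool]:
    """Parse a KEGG-style equation into (substrates, products, reversible).

    A coefficient of 1 (or absent) maps to the approximate exponent ``m = 1``;
    any coefficient >= 2 maps to ``m = 2``. ``<=`` equations are normalized by
    swapping the sides (the written right-hand side becomes the substrates)
    and are marked irreversible, as are ``=>`` equations.

    >>> parse_reaction_equation("2 C00001 <=> C00007")
    ((('C00001', 2),), (('C00007', 1),), True)
    """
    arrows = _ARROW_RE.findall(equation)
    if len(arrows) != 1:
        raise EquationParseError(
            f"equation must contain exactly one of '<=>', '=>', '<=': {equation!r}"
        )
    arrow = arrows[0]
    left, right = equation.split(arrow, 1)
    lhs = _parse_side(left, equation)
    rhs = _parse_side(right, equation)
    overlap = {c for c, _ in lhs} & {c for c, _ in rhs}
    if overlap:
        raise EquationParseError(
            f"compound(s) {sorted(overlap)} appear on both sides of {equation!r}"
        )
    if arrow == "<=":
        return rhs, lhs, False
    return lhs, rhs, arrow == "<=>"


def format_reaction_equation(rxn: Reaction) -> str:
    """Inverse of :func:`parse_reaction_equation` up to the m-collapse.

    ``m = 2`` slots are printed with coefficient 2 (the original coefficient,
    if larger, is not recoverable); the round-trip therefore preserves exactly
    the information the model uses.
    """

    def side(terms: tuple[tuple[str, int], ...]) -> str:
        return " + ".join(cid if m == 1 else f"2 {cid}" for cid, m in terms)

    arrow = "<=>" if rxn.reversible else "=>"
    return f"{side(rxn.substrates)} {arrow} {side(rxn.products)}"


def _split_ids(cell: object) -> tuple[str, ...]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return ()
    text = str(cell).strip()
    if not text:
        return ()
    return tuple(tok.strip() for tok in text.split(";") if tok.strip())


def load_network(
    reaction_table: str | Path,
    enzyme_table: str | Path,
    pathway_table: str | Path | None = None,
) -> ReactionNetwork:
    """Load a network from the three delimited flat files.

    ``reactions.tsv``: columns ``reaction_id``, ``equation``, ``enzyme_ids``
    (semicolon-separated, may be empty). ``enzymes.tsv``: columns
    ``enzyme_id``, ``isoenzyme_index``, ``subunit_gene_ids``
    (semicolon-separated), one row per isoenzyme. ``pathways.tsv``: columns
    ``pathway_id``, ``pathway_name``, ``member_type`` in {compound, reaction},
    ``member_id``. Compounds are auto-registered from the equations.
    """
    rxn_df = pd.read_csv(reaction_table, sep="\t", dtype=str)
    enz_df = pd.read_csv(enzyme_table, sep="\t", dtype=str)

    net = ReactionNetwork()
    for _, row in enz_df.sort_values(["enzyme_id", "isoenzyme_index"], key=_numeric_last).iterrows():
        eid = row["enzyme_id"]
        genes = _split_ids(row["subunit_gene_ids"])
        if eid in net.enzymes:
            prev = net.enzymes[eid]
            net.enzymes[eid] = EnzymeDefinition(eid, prev.isoenzymes + (genes,))
        else:
            net.enzymes[eid] = EnzymeDefinition(eid, (genes,))

    for _, row in rxn_df.iterrows():
        rid = row["reaction_id"]
        if rid in net.reactions:
            raise NetworkError(f"duplicate reaction id {rid!r}")
        subs, prods, rev = parse_reaction_equation(row["equation"])
        rxn = Reaction(rid, subs, prods, _split_ids(row.get("enzyme_ids")), rev)
        net.reactions[rid] = rxn
        for cid in rxn.compound_ids:
            net.compounds.setdefault(cid, Compound(cid))

    if pathway_table is not None:
        pw_df = pd.read_csv(pathway_table, sep="\t", dtype=str)
        members: dict[str, dict[str, object]] = {}
        for _, row in pw_df.iterrows():
            entry = members.setdefault(
                row["pathway_id"],
                {"name": row["pathway_name"], "compounds": set(), "reactions": set()},
            )
            mtype = row["member_type"]
            if mtype not in ("compound", "reaction"):
                raise NetworkError(f"pathway member_type {mtype!r} not in {{compound, reaction}}")
            entry["compounds" if mtype == "compound" else "reactions"].add(row["member_id"])
        for pid, entry in members.items():
            net.pathways[pid] = Pathway(
                pid,
                str(entry["name"]),
                frozenset(entry["compounds"]),  # type: ignore[arg-type]
                frozenset(entry["reactions"]),  # type: ignore[arg-type]
            )

    problems = validate_network(net)
    if problems:
        raise NetworkError("invalid network:\n  " + "\n  ".join(problems))
    return net


def _numeric_last(col: pd.Series) -> pd.Series:
    if col.name == "isoenzyme_index":
        return pd.to_numeric(col)
    return col


def serialize_network(net: ReactionNetwork, out_dir: str | Path) -> dict[str, Path]:
    """Write ``reactions.tsv``, ``enzymes.tsv`` and ``pathways.tsv`` to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "reactions": out / "reactions.tsv",
        "enzymes": out / "enzymes.tsv",
        "pathways": out / "pathways.tsv",
    }
    pd.DataFrame(
        [
            {
                "reaction_id": r.id,
                "equation": format_reaction_equation(r),
                "enzyme_ids": ";".join(r.enzymes),
            }
            for r in net.reactions.values()
        ]
    ).to_csv(paths["reactions"], sep="\t", index=False)
    pd.DataFrame(
        [
            {"enzyme_id": e.id, "isoenzyme_index": i, "subunit_gene_ids": ";".join(iso)}
            for e in net.enzymes.values()
            for i, iso in enumerate(e.isoenzymes)
        ]
    ).to_csv(paths["enzymes"], sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "pathway_id": p.id,
                "pathway_name": p.name,
                "member_type": mtype,
                "member_id": mid,
            }
            for p in net.pathways.values()
            for mtype, mids in (("compound", sorted(p.compounds)), ("reaction", sorted(p.reactions)))
            for mid in mids
        ],
        columns=["pathway_id", "pathway_name", "member_type", "member_id"],
    ).to_csv(paths["pathways"], sep="\t", index=False)
    return paths


def validate_network(net: ReactionNetwork) -> list[str]:
    """Return human-readable diagnostics; empty iff all invariants hold."""
    problems: list[str] = []
    for rxn in net.reactions.values():
        for cid in rxn.compound_ids:
            if cid not in net.compounds:
                problems.append(f"reaction {rxn.id}: unknown compound {cid}")
        for eid in rxn.enzymes:
            if eid not in net.enzymes:
                problems.append(f"reaction {rxn.id}: unknown enzyme {eid}")
    for pw in net.pathways.values():
        for cid in sorted(pw.compounds - set(net.compounds)):
            problems.append(f"pathway {pw.id}: unknown compound {cid}")
        for rid in sorted(pw.reactions - set(net.reactions)):
            problems.append(f"pathway {pw.id}: unknown reaction {rid}")
    return problems
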