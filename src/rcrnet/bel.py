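"""Parsing of BEL-subset causal statements and the signed functional layer.

The curated knowledge consumed here is a small dialect of the Biological
Expression Language: terms are ``p()`` (protein), ``r()`` (mRNA), ``act()``
(molecular activity), ``comp()`` (complex) and ``ma()`` (activity
annotation, e.g. kinase), and a statement joins a subject term to an object
term with one of four causal relations (``increases``, ``decreases`` and
their ``directly`` variants).  Statements are compiled into a signed
directed graph — the *functional layer* or *backbone* — in which entity
forms are collapsed to the gene level and the relation keyword fixes the
edge sign.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "Entity",
    "CausalStatement",
    "SignedEdge",
    "BackboneGraph",
    "BELParseError",
    "RELATION_SIGNS",
    "parse_statement",
    "statement_to_edges",
    "build_backbone",
]

#: Causal relation keywords and the edge sign each implies.
RELATION_SIGNS: dict[str, int] = {
    "increases": +1,
    "directlyIncreases": +1,
    "decreases": -1,
    "directlyDecreases": -1,
}

_FUNCTIONS = {"p", "r", "act", "comp", "ma"}
_FORM_OF_FUNC = {"p": "protein", "r": "rna"}
_FUNC_OF_FORM = {"protein": "p", "rna": "r"}
_SYMBOL_RE = re.compile(r"[A-Za-z0-9][A-Za-z0-9_.\-]*\Z")


class BELParseError(ValueError):
    """Raised on malformed statement text; carries the character offset."""

    def __init__(self, message: str, text: str, offset: int):
        self.text = text
        self.offset = offset
        super().__init__(f"{message} at offset {offset} in {text!r}")


@dataclass(frozen=True)
class Entity:
    """A biological entity at a given form (protein, rna, activity, complex).

    ``members`` is non-empty only for complexes; ``base`` records the
    abundance form wrapped by an activity term; ``note`` keeps any ``ma()``
    molecular-activity annotation (e.g. ``kin``); ``activity`` marks a
    complex whose activity, rather than abundance, is asserted.
    """

    symbol: str
    form: str  # protein | rna | activity | complex
    members: tuple["Entity", ...] = ()
    base: str | None = None
    note: str | None = None
    activity: bool = False

    def __post_init__(self):
        if not self.symbol:
            raise ValueError("entity symbol must be non-empty")
        if self.members and self.form != "complex":
            raise ValueError("only complexes carry members")
        if self.form == "complex" and not self.members:
            raise ValueError("complex requires members")
        for m in self.members:
            if m.form == "complex":
                raise ValueError("complex members must be non-complex")

    @property
    def gene_symbols(self) -> tuple[str, ...]:
        """Gene-level symbols: the member genes for a complex, else one."""
        if self.form == "complex":
            return tuple(m.symbol for m in self.members)
        return (self.symbol,)

    def to_bel(self) -> str:
        """Canonical BEL-subset text for this entity."""
        if self.form == "complex":
            inner = "comp(%s)" % ", ".join(m.to_bel() for m in self.members)
            if self.activity or self.note:
                ann = f", ma({self.note})" if self.note else ""
                return f"act({inner}{ann})"
            return inner
        if self.form == "activity":
            func = _FUNC_OF_FORM.get(self.base or "protein", "p")
            ann = f", ma({self.note})" if self.note else ""
            return f"act({func}({self.symbol}){ann})"
        return f"{_FUNC_OF_FORM[self.form]}({self.symbol})"


@dataclass(frozen=True)
class CausalStatement:
    """One causal assertion: subject --relation--> object."""

    subject: Entity
    relation: str
    object: Entity
    evidence: str = ""
    provenance: str = "curated"  # curated | data_driven

    def __post_init__(self):
        if self.relation not in RELATION_SIGNS:
            raise ValueError(f"unknown relation {self.relation!r}")
        if self.provenance not in ("curated", "data_driven"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def sign(self) -> int:
        return RELATION_SIGNS[self.relation]

    @property
    def direct(self) -> bool:
        return self.relation.startswith("directly")

    def to_bel(self) -> str:
        return f"{self.subject.to_bel()} {self.relation} {self.object.to_bel()}"


@dataclass(frozen=True)
class SignedEdge:
    """A gene-level signed directed interaction."""

    source: str
    target: str
    sign: int
    direct: bool = False
    provenance: str = "curated"
    evidence: tuple[str, ...] = ()

    def __post_init__(self):
        if self.source == self.target:
            raise ValueError(f"self-loop {self.source} -> {self.target} is not allowed")
        if self.sign not in (-1, +1):
            raise ValueError(f"edge sign must be -1 or +1, got {self.sign}")


# ---------------------------------------------------------------------------
# parser


def _check_balance(text: str) -> None:
    depth = 0
    last_open = -1
    for i, ch in enumerate(text):
        if ch == "(":
            if depth == 0:
                last_open = i
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise BELParseError("unbalanced ')'", text, i)
    if depth != 0:
        raise BELParseError("unbalanced '('", text, last_open)


def _split_relation(text: str) -> tuple[str, str, str, int]:
    """Locate the single top-level relation keyword."""
    depth = 0
    for m in re.finditer(r"\S+", text):
        word = m.group(0)
        start = m.start()
        # track depth up to this word
        depth = text[:start].count("(") - text[:start].count(")")
        if depth == 0 and word in RELATION_SIGNS:
            return text[:start].rstrip(), word, text[m.end():].lstrip(), start
    raise BELParseError("no top-level relation keyword found", text, 0)


def _split_args(s: str) -> list[str]:
    """Split a term argument list on top-level commas."""
    args, depth, cur = [], 0, []
    for ch in s:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if ch == "," and depth == 0:
            args.append("".join(cur).strip())
            cur = []
        else:
            cur.append(ch)
    tail = "".join(cur).strip()
    if tail:
        args.append(tail)
    return args


def _normalize_symbol(name: str, aliases: Mapping[str, str], text: str, offset: int) -> str:
    name = name.strip().strip('"')
    key = name.casefold()
    if key in aliases:
        return aliases[key]
    # strip namespace prefixes such as "HGNC:" (and stray bare colons)
    if ":" in name:
        name = name.rsplit(":", 1)[1]
        if name.casefold() in aliases:
            return aliases[name.casefold()]
    if not _SYMBOL_RE.match(name):
        raise BELParseError(f"unknown free-text name {name!r}", text, offset)
    return name.upper()


def _parse_term(text: str, s: str, offset: int, aliases: Mapping[str, str]):
    """Parse one term; returns an Entity, or ('ma', note) for annotations."""
    m = re.match(r"\s*([A-Za-z]+)\s*\(", s)
    if not m:
        raise BELParseError(f"expected a term, got {s!r}", text, offset)
    func = m.group(1)
    if func not in _FUNCTIONS:
        raise BELParseError(f"unknown function symbol {func!r}", text, offset + m.start(1))
    if not s.rstrip().endswith(")"):
        raise BELParseError("unbalanced '('", text, offset + m.end() - 1)
    inner = s.strip()
    body = inner[inner.index("(") + 1 : -1]
    body_off = offset + s.index("(") + 1

    if func == "ma":
        return ("ma", body.strip())

    if func in ("p", "r"):
        sym = _normalize_symbol(body, aliases, text, body_off)
        return Entity(symbol=sym, form=_FORM_OF_FUNC[func])

    args = _split_args(body)
    parsed = []
    cursor = body_off
    for a in args:
        pos = text.find(a, cursor) if a in text[cursor:] else cursor
        if re.match(r"\s*[A-Za-z]+\s*\(", a):
            parsed.append(_parse_term(text, a, pos, aliases))
        else:
            parsed.append(Entity(symbol=_normalize_symbol(a, aliases, text, pos), form="protein"))
        cursor = pos + len(a)

    if func == "comp":
        members = []
        for p in parsed:
            if isinstance(p, tuple):
                raise BELParseError("ma() is not a complex member", text, body_off)
            members.append(p)
        symbol = "_".join(m.symbol for m in members)
        return Entity(symbol=symbol, form="complex", members=tuple(members))

    # func == "act"
    note = None
    entity = None
    for p in parsed:
        if isinstance(p, tuple):
            note = p[1]
        elif entity is None:
            entity = p
        else:
            raise BELParseError("act() takes one entity", text, body_off)
    if entity is None:
        raise BELParseError("act() requires an entity argument", text, body_off)
    if entity.form == "complex":
        return replace(entity, activity=True, note=note)
    base = entity.form if entity.form in ("protein", "rna") else "protein"
    return Entity(symbol=entity.symbol, form="activity", base=base, note=note)


def parse_statement(
    text: str,
    evidence: str = "",
    aliases: Mapping[str, str] | None = None,
    provenance: str = "curated",
) -> CausalStatement:
    """Parse one BEL-subset statement into a :class:`CausalStatement`.

    ``aliases`` maps free-text entity names (case-insensitively) to gene
    symbols; when omitted, the packaged alias table is used.  Namespace
    prefixes (``HGNC:``) are stripped.  ``ma()`` annotations are recorded on
    the entity and otherwise discarded.
    """
    if aliases is None:
        from .resources import load_aliases

        aliases = load_aliases()
    else:
        aliases = {k.casefold(): v for k, v in aliases.items()}
    _check_balance(text)
    subj_text, relation, obj_text, rel_off = _split_relation(text)
    if not subj_text:
        raise BELParseError("missing subject term", text, 0)
    if not obj_text:
        raise BELParseError("missing object term", text, rel_off + len(relation))
    subject = _parse_term(text, subj_text, 0, aliases)
    obj = _parse_term(text, obj_text, rel_off + len(relation) + 1, aliases)
    if isinstance(subject, tuple) or isinstance(obj, tuple):
        raise BELParseError("ma() cannot stand alone as subject or object", text, 0)
    return CausalStatement(subject=subject, relation=relation, object=obj,
                           evidence=evidence, provenance=provenance)


# ---------------------------------------------------------------------------
# statements -> edges -> graph


def statement_to_edges(s: CausalStatement) -> list[SignedEdge]:
    """Expand a statement to gene-level signed edges.

    A complex subject with *k* members yields *k* edges sharing the
    statement's sign and direct flag.  Entity forms are dropped here; they
    remain available on the statement itself.
    """
    edges = []
    for src in s.subject.gene_symbols:
        for dst in s.object.gene_symbols:
            edges.append(
                SignedEdge(
                    source=src,
                    target=dst,
                    sign=s.sign,
                    direct=s.direct,
                    provenance=s.provenance,
                    evidence=(s.evidence,) if s.evidence else (),
                )
            )
    return edges


class BackboneGraph:
    """Signed directed functional-layer graph over gene symbols.

    Thin wrapper around a :class:`networkx.DiGraph` whose edges carry
    ``sign`` (+1/-1), ``direct``, ``provenance`` and ``evidence``
    attributes and whose nodes carry a ``role`` (MSG, TF or other).
    """

    def __init__(self, graph: nx.DiGraph | None = None):
        self.g = graph if graph is not None else nx.DiGraph()

    # -- construction -------------------------------------------------------
    def add_node(self, symbol: str, role: str = "other") -> None:
        self.g.add_node(symbol, role=role)

    def add_edge(self, edge: SignedEdge) -> None:
        """Add an edge, merging evidence with any identical existing edge."""
        if self.g.has_edge(edge.source, edge.target):
            data = self.g[edge.source][edge.target]
            if data["sign"] != edge.sign:
                raise ValueError(
                    f"conflicting signs for {edge.source} -> {edge.target}: "
                    f"existing evidence {data['evidence']}, new evidence {edge.evidence}"
                )
            data["evidence"] = data["evidence"] + edge.evidence
            data["direct"] = data["direct"] or edge.direct
        else:
            for n in (edge.source, edge.target):
                if n not in self.g:
                    self.g.add_node(n, role="other")
            self.g.add_edge(
                edge.source,
                edge.target,
                sign=edge.sign,
                direct=edge.direct,
                provenance=edge.provenance,
                evidence=edge.evidence,
            )

    # -- queries ------------------------------------------------------------
    @property
    def nodes(self) -> list[str]:
        return sorted(self.g.nodes)

    def role(self, symbol: str) -> str:
        return self.g.nodes[symbol].get("role", "other")

    def edges(self) -> list[SignedEdge]:
        out = []
        for u, v, d in sorted(self.g.edges(data=True)):
            out.append(
                SignedEdge(
                    source=u, target=v, sign=d["sign"], direct=d["direct"],
                    provenance=d.get("provenance", "curated"),
                    evidence=tuple(d.get("evidence", ())),
                )
            )
        return out

    def sign(self, u: str, v: str) -> int:
        return self.g[u][v]["sign"]

    def successors(self, u: str) -> list[tuple[str, int]]:
        return sorted((v, d["sign"]) for v, d in self.g[u].items())

    def copy(self) -> "BackboneGraph":
        return BackboneGraph(self.g.copy())

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.g

    def __len__(self) -> int:
        return self.g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.g.number_of_edges()

    def __repr__(self) -> str:
        return f"BackboneGraph({len(self)} nodes, {self.n_edges} edges)"

    # -- serialization ------------------------------------------------------
    def to_sif(self, path) -> None:
        """Write SIF: source <TAB> activates|represses <TAB> target."""
        with open(path, "w") as fh:
            for e in self.edges():
                rel = "activates" if e.sign > 0 else "represses"
                fh.write(f"{e.source}\t{rel}\t{e.target}\n")

    def to_graphml(self, path) -> None:
        g = self.g.copy()
        for _, _, d in g.edges(data=True):
            d["evidence"] = "|".join(d.get("evidence", ()))
        nx.write_graphml(g, path)

    @classmethod
    def from_sif(cls, path) -> "BackboneGraph":
        bg = cls()
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                src, rel, dst = line.rstrip("\n").split("\t")
                sign = +1 if rel == "activates" else -1
                bg.add_edge(SignedEdge(source=src, target=dst, sign=sign))
        return bg


def build_backbone(
    statements: Iterable[CausalStatement],
    roles: Mapping[str, str] | None = None,
    on_conflict: str = "error",
) -> BackboneGraph:
    """Compile statements into a deduplicated signed backbone.

    Duplicate assertions of the same ordered gene pair with the same sign
    merge into one edge with pooled evidence.  The same pair asserted with
    *both* signs is a curation conflict: ``on_conflict='error'`` (default)
    raises listing the evidence on each side; ``'keep_direct'`` keeps the
    sign backed by a direct (mechanistic) statement when exactly one side
    has one; ``'drop'`` removes the pair entirely.
    """
    statements = list(statements)
    if not statements:
        raise ValueError("no statements to build a backbone from")
    if on_conflict not in ("error", "keep_direct", "drop"):
        raise ValueError(f"unknown on_conflict policy {on_conflict!r}")

    by_pair: dict[tuple[str, str], list[SignedEdge]] = {}
    for s in statements:
        for e in statement_to_edges(s):
            by_pair.setdefault((e.source, e.target), []).append(e)

    bg = BackboneGraph()
    for (u, v), group in by_pair.items():
        signs = {e.sign for e in group}
        if len(signs) > 1:
            pos = [e for e in group if e.sign > 0]
            neg = [e for e in group if e.sign < 0]
            if on_conflict == "drop":
                continue
            if on_conflict == "keep_direct":
                direct_signs = {e.sign for e in group if e.direct}
                if len(direct_signs) == 1:
                    keep = direct_signs.pop()
                    group = [e for e in group if e.sign == keep]
                else:
                    raise ValueError(
                        f"unresolvable sign conflict for {u} -> {v}: "
                        f"+1 evidence {[e.evidence for e in pos]}, "
                        f"-1 evidence {[e.evidence for e in neg]}"
                    )
            else:
                raise ValueError(
                    f"conflicting signs for {u} -> {v}: "
                    f"+1 evidence {[e.evidence for e in pos]}, "
                    f"-1 evidence {[e.evidence for e in neg]}"
                )
        evidence = tuple(ref for e in group for ref in e.evidence)
        merged = SignedEdge(
            source=u,
            target=v,
            sign=group[0].sign,
            direct=any(e.direct for e in group),
            provenance=group[0].provenance,
            evidence=evidence,
        )
        bg.add_edge(merged)

    if roles:
        for n in bg.g.nodes:
            bg.g.nodes[n]["role"] = roles.get(n, "other")
    return bg
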