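"""Core domain types and plain-text I/O for protein-level knowledge graphs.

A knowledge graph here is a multigraph over proteins: each record is a
subject-predicate-object triple carrying a non-empty set of provenance
sources (the databases or literature extracts attesting the relationship).
The set of triples connecting an unordered protein pair constitutes the
*edge* between them; a pair may be linked by several predicates, each with
its own provenance. Direction is stored as written but connectivity is
treated as undirected throughout the package, since many protein-protein
predicates (complex formation, interaction) are symmetric and path
semantics never depend on orientation.

File dialects are deliberately plain: UTF-8 TSV, ``#`` comment lines,
``;``-separated provenance, ``|``-separated protein sets.
"""

from __future__ import annotations


from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

__all__ = [
    "ParseError",
    "ValidationError",
    "Triple",
    "KnowledgeGraph",
    "ProteinSet",
    "Combination",
    "read_triples",
    "write_triples",
    "read_reference_set",
    "write_reference_set",
    "write_feature_matrix",
    "read_feature_matrix",
]

COMMENT_CHAR = "#"
PROVENANCE_SEP = ";"
SET_SEP = "|"
VALID_LABELS = ("positive", "negative", "unlabeled")


class ParseError(ValueError):
    """A line of an input file could not be parsed."""


class ValidationError(ValueError):
    """An input violated a domain invariant."""


def _check_protein_id(token: str) -> str:
    if not token or any(c.isspace() for c in token):
        raise ValidationError(f"invalid protein id: {token!r}")
    return token


@dataclass(frozen=True)
class Triple:
    """One subject-predicate-object edge record with its provenance sources."""

    subject: str
    predicate: str
    object: str
    provenance: frozenset[str]

    def __post_init__(self) -> None:
        _check_protein_id(self.subject)
        _check_protein_id(self.object)
        if not self.predicate:
            raise ValidationError("empty predicate")
        object.__setattr__(self, "provenance", frozenset(self.provenance))
        if not self.provenance or any(not s for s in self.provenance):
            raise ValidationError(
                f"triple {self.subject}-{self.predicate}-{self.object}: "
                "provenance must be a non-empty set of non-empty source labels"
            )

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.subject, self.predicate, self.object)

    @property
    def pair(self) -> frozenset[str]:
        """Unordered endpoint pair (a singleton for self-relationships)."""
        return frozenset((self.subject, self.object))

    @property
    def is_self(self) -> bool:
        return self.subject == self.object

    def other(self, protein: str) -> str:
        if protein == self.subject:
            return self.object
        if protein == self.object:
            return self.subject
        raise KeyError(protein)


class KnowledgeGraph:
    """Indexed multi-edge protein graph.

    Duplicate ``(subject, predicate, object)`` records merge their provenance
    sets on construction. Predicate and source vocabularies default to the
    sorted distinct labels observed in the triples; supplied vocabularies
    must be supersets of the observed ones.
    """

    def __init__(
        self,
        triples: Iterable[Triple],
        proteins: Iterable[str] = (),
        predicate_vocabulary: Sequence[str] | None = None,
        source_vocabulary: Sequence[str] | None = None,
    ) -> None:
        merged: dict[tuple[str, str, str], set[str]] = {}
        for t in triples:
            merged.setdefault(t.key, set()).update(t.provenance)
        self._triples: tuple[Triple, ...] = tuple(
            Triple(s, p, o, frozenset(prov)) for (s, p, o), prov in merged.items()
        )

        prots: set[str] = {_check_protein_id(p) for p in proteins}
        for t in self._triples:
            prots.add(t.subject)
            prots.add(t.object)
        self._proteins = frozenset(prots)

        seen_preds = sorted({t.predicate for t in self._triples})
        seen_srcs = sorted({s for t in self._triples for s in t.provenance})
        if predicate_vocabulary is None:
            self._predicates = tuple(seen_preds)
        else:
            missing = set(seen_preds) - set(predicate_vocabulary)
            if missing:
                raise ValidationError(f"predicates outside vocabulary: {sorted(missing)}")
            self._predicates = tuple(predicate_vocabulary)
        if source_vocabulary is None:
            self._sources = tuple(seen_srcs)
        else:
            missing = set(seen_srcs) - set(source_vocabulary)
            if missing:
                raise ValidationError(f"sources outside vocabulary: {sorted(missing)}")
            self._sources = tuple(source_vocabulary)

        # adjacency: protein -> neighbour -> list of triples on that pair;
        # self-relationships sit at adj[p][p].
        adj: dict[str, dict[str, list[Triple]]] = {p: {} for p in self._proteins}
        for t in self._triples:
            adj[t.subject].setdefault(t.object, []).append(t)
            if not t.is_self:
                adj[t.object].setdefault(t.subject, []).append(t)
        self._adj = adj

    # ---- views -----------------------------------------------------------
    @property
    def proteins(self) -> frozenset[str]:
        return self._proteins

    @property
    def triples(self) -> tuple[Triple, ...]:
        return self._triples

    @property
    def predicate_vocabulary(self) -> tuple[str, ...]:
        return self._predicates

    @property
    def source_vocabulary(self) -> tuple[str, ...]:
        return self._sources

    @property
    def n_proteins(self) -> int:
        return len(self._proteins)

    @property
    def n_triples(self) -> int:
        return len(self._triples)

    @property
    def n_edges(self) -> int:
        """Number of distinct unordered connected protein pairs (incl. self)."""
        return len({t.pair for t in self._triples})

    # ---- queries ---------------------------------------------------------
    def neighbors(self, protein: str, include_self: bool = False) -> Iterator[str]:
        for q in self._adj.get(protein, ()):
            if include_self or q != protein:
                yield q

    def triples_between(self, a: str, b: str) -> tuple[Triple, ...]:
        """All triples joining the unordered pair (a, b), either orientation."""
        return tuple(self._adj.get(a, {}).get(b, ()))

    def self_triples(self, protein: str) -> tuple[Triple, ...]:
        return self.triples_between(protein, protein)

    def incident(self, protein: str) -> tuple[Triple, ...]:
        out: list[Triple] = []
        for ts in self._adj.get(protein, {}).values():
            out.extend(ts)
        return tuple(out)

    def degree(self, protein: str) -> int:
        """Simple-graph degree: number of distinct neighbours (self excluded)."""
        return sum(1 for _ in self.neighbors(protein))

    def to_networkx(self):
        """Simple undirected networkx view (self-loops dropped)."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self._proteins)
        g.add_edges_from(
            (t.subject, t.object) for t in self._triples if not t.is_self
        )
        return g

    def without_sole_source_triples(self, source: str) -> "KnowledgeGraph":
        """Copy of the graph with triples attested *only* by ``source`` removed.

        The source vocabulary is retained so downstream feature columns stay
        addressable; remaining triples keep their full provenance.
        """
        if source not in self._sources:
            raise ValidationError(f"unknown source: {source!r}")
        kept = [t for t in self._triples if t.provenance != frozenset((source,))]
        return KnowledgeGraph(
            kept,
            proteins=self._proteins,
            predicate_vocabulary=self._predicates,
            source_vocabulary=self._sources,
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"KnowledgeGraph({self.n_proteins} proteins, {self.n_triples} triples, "
            f"{len(self._predicates)} predicates, {len(self._sources)} sources)"
        )


@dataclass(frozen=True)
class ProteinSet:
    """A drug-target (DT) or disease-protein (DP) set; always non-empty."""

    members: frozenset[str]
    role: str  # "DT" | "DP"
    set_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        if not self.members:
            raise ValidationError(f"empty protein set (role {self.role})")
        if self.role not in ("DT", "DP"):
            raise ValidationError(f"invalid role: {self.role!r}")
        for p in self.members:
            _check_protein_id(p)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self.members))


@dataclass(frozen=True)
class Combination:
    """One classification unit: a drug-target set paired with a disease-protein set."""

    combo_id: str
    drug_targets: ProteinSet
    disease_proteins: ProteinSet
    label: str = "unlabeled"

    def __post_init__(self) -> None:
        if self.label not in VALID_LABELS:
            raise ValidationError(f"unknown label: {self.label!r}")
        if self.drug_targets.role != "DT" or self.disease_proteins.role != "DP":
            raise ValidationError("combination requires a DT set and a DP set")

    @property
    def n_targets(self) -> int:
        return len(self.drug_targets)

    @property
    def y(self) -> int:
        return 1 if self.label == "positive" else 0


# ---------------------------------------------------------------------------
# Triple-store I/O
# ---------------------------------------------------------------------------

def _data_lines(path: str | Path) -> Iterator[tuple[int, str]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith(COMMENT_CHAR):
                continue
            yield lineno, line


def read_triples(path: str | Path) -> KnowledgeGraph:
    """Load a 4-column TSV triple store into an indexed :class:`KnowledgeGraph`.

    Columns: subject, predicate, object, ``;``-joined provenance sources.
    Duplicate (subject, predicate, object) lines merge their provenance.
    ``#! protein|predicate|source <label>`` directive comments declare
    isolated proteins and vocabulary labels that no triple realizes, so a
    written graph reloads with identical counts; other parsers may skip
    them as ordinary comments.
    """
    triples: list[Triple] = []
    extra_proteins: list[str] = []
    extra_predicates: set[str] = set()
    extra_sources: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").strip()
            if line.startswith("#!"):
                parts = line[2:].split()
                if len(parts) != 2 or parts[0] not in ("protein", "predicate", "source"):
                    raise ParseError(f"{path}:{lineno}: malformed directive")
                {"protein": extra_proteins.append,
                 "predicate": extra_predicates.add,
                 "source": extra_sources.add}[parts[0]](parts[1])
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 4:
            raise ParseError(f"{path}:{lineno}: expected >=4 tab-separated fields")
        subject, predicate, obj, prov_field = fields[0], fields[1], fields[2], fields[3]
        sources = frozenset(s for s in prov_field.split(PROVENANCE_SEP) if s)
        if not sources:
            raise ValidationError(f"{path}:{lineno}: empty provenance field")
        try:
            triples.append(Triple(subject, predicate, obj, sources))
        except ValidationError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    seen_preds = {t.predicate for t in triples}
    seen_srcs = {s for t in triples for s in t.provenance}
    pred_vocab = sorted(seen_preds | extra_predicates) if extra_predicates else None
    src_vocab = sorted(seen_srcs | extra_sources) if extra_sources else None
    return KnowledgeGraph(
        triples,
        proteins=extra_proteins,
        predicate_vocabulary=pred_vocab,
        source_vocabulary=src_vocab,
    )


def write_triples(graph: KnowledgeGraph, path: str | Path) -> None:
    """Write the triple store in the same TSV dialect ``read_triples`` accepts."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# subject\tpredicate\tobject\tprovenance\n")
        connected = {p for t in graph.triples for p in (t.subject, t.object)}
        for p in sorted(graph.proteins - connected):
            fh.write(f"#! protein {p}\n")
        seen_preds = {t.predicate for t in graph.triples}
        for p in sorted(set(graph.predicate_vocabulary) - seen_preds):
            fh.write(f"#! predicate {p}\n")
        seen_srcs = {s for t in graph.triples for s in t.provenance}
        for s in sorted(set(graph.source_vocabulary) - seen_srcs):
            fh.write(f"#! source {s}\n")
        for t in sorted(graph.triples, key=lambda t: t.key):
            fh.write(
                f"{t.subject}\t{t.predicate}\t{t.object}\t"
                f"{PROVENANCE_SEP.join(sorted(t.provenance))}\n"
            )


# ---------------------------------------------------------------------------
# Reference-set I/O
# ---------------------------------------------------------------------------

def read_reference_set(
    path: str | Path, graph: KnowledgeGraph
) -> tuple[list[Combination], dict[str, frozenset[str]]]:
    """Load labelled drug-target / disease-protein combinations.

    Columns: combo_id, ``|``-joined drug targets, ``|``-joined disease
    proteins, label. Proteins absent from ``graph`` are retained (a
    combination is only unusable when none of its disease proteins has a
    qualifying path, which is an analysis-time decision, not a load-time
    one) but reported in the returned load report mapping
    combo_id -> missing proteins.
    """
    combos: list[Combination] = []
    report: dict[str, frozenset[str]] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 4:
            raise ParseError(f"{path}:{lineno}: expected 4 tab-separated fields")
        combo_id, dt_field, dp_field, label = fields[0], fields[1], fields[2], fields[3]
        dts = frozenset(p for p in dt_field.split(SET_SEP) if p)
        dps = frozenset(p for p in dp_field.split(SET_SEP) if p)
        if not dts or not dps:
            raise ValidationError(f"{path}:{lineno}: empty protein set")
        if label not in VALID_LABELS:
            raise ValidationError(f"{path}:{lineno}: unknown label {label!r}")
        combo = Combination(
            combo_id,
            ProteinSet(dts, "DT", set_id=f"{combo_id}:DT"),
            ProteinSet(dps, "DP", set_id=f"{combo_id}:DP"),
            label,
        )
        missing = (dts | dps) - graph.proteins
        if missing:
            report[combo_id] = frozenset(missing)
        combos.append(combo)
    return combos, report


def write_reference_set(combos: Iterable[Combination], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# combo_id\tdrug_targets\tdisease_proteins\tlabel\n")
        for c in combos:
            fh.write(
                f"{c.combo_id}\t{SET_SEP.join(sorted(c.drug_targets.members))}\t"
                f"{SET_SEP.join(sorted(c.disease_proteins.members))}\t{c.label}\n"
            )


# ---------------------------------------------------------------------------
# Feature-matrix I/O
# ---------------------------------------------------------------------------

def write_feature_matrix(combos, spec, vectors, path: str | Path) -> None:
    """Write a wide 0/1 TSV: combo_id, label, then one column per feature id."""
    combos = list(combos)
    vectors = list(vectors)
    if len(combos) != len(vectors):
        raise ValidationError(
            f"{len(combos)} combinations but {len(vectors)} feature vectors"
        )
    n_feat = len(spec.features)
    rows = []
    for combo, vec in zip(combos, vectors):
        bits = list(vec.bits)
        if len(bits) != n_feat:
            raise ValidationError(
                f"vector for {combo.combo_id} has {len(bits)} bits, spec has {n_feat}"
            )
        rows.append([combo.combo_id, combo.label] + [int(b) for b in bits])
    df = pd.DataFrame(rows, columns=["combo_id", "label"] + [str(f) for f in spec.features])
    df.to_csv(path, sep="\t", index=False)


def read_feature_matrix(path: str | Path) -> pd.DataFrame:
    """Read a matrix written by :func:`write_feature_matrix`.

    Returns a DataFrame indexed by combo_id with a ``label`` column and
    integer 0/1 feature columns.
    """
    df = pd.read_csv(path, sep="\t", dtype={"combo_id": str})
    return df.set_index("combo_id")
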