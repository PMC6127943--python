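"""Binary predicate/provenance feature tables over the three path scenarios.

Each combination of a drug-target set and a disease-protein set is encoded
as a fixed-length 0/1 vector. The feature space is the cross product of
path slots and vocabulary values:

* flag slots — ``OVERLAP_FLAG``, ``COOC_DIRECT``, ``COOC_INDIRECT``:
  scenario co-occurrence indicators carrying no predicate or provenance
  information;
* value slots — ``SELF`` (self-relationships of overlapping proteins),
  ``DIRECT`` (drug target to disease protein triples), ``DTIP`` and
  ``IPDP`` (the two steps of indirect paths), each crossed with every
  predicate label and/or every provenance source of the graph.

A feature is 1 iff its (slot, value) combination occurs in at least one
triple of that slot for the combination — presence, never counts.

Five variants of the space are used:

========== ==========================================================
baseline       the three flags only
predicate      OVERLAP_FLAG + value slots x predicates
provenance     OVERLAP_FLAG + value slots x sources
full           OVERLAP_FLAG + value slots x (predicates + sources)
indirect_only  full restricted to the DTIP/IPDP slots
========== ==========================================================

For a vocabulary of 45 predicates and 25 sources the full space has
1 + 4 x (45 + 25) = 281 features.

The primary implementation is the sklearn-style transformer
:class:`KGPathFeaturizer`; :func:`build_feature_space` and
:func:`extract_features` are thin functional wrappers around it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .kg_core import Combination, KnowledgeGraph, ValidationError
from . import pathfind
from .pathfind import STEP_DIRECT, STEP_DTIP, STEP_IPDP, STEP_SELF

__all__ = [
    "FLAG_SLOTS",
    "VALUE_SLOTS",
    "VARIANTS",
    "FeatureId",
    "FeatureSpec",
    "FeatureVector",
    "KGPathFeaturizer",
    "build_feature_space",
    "extract_features",
    "extract_matrix",
    "restrict_to_sources",
]

FLAG_SLOTS = ("OVERLAP_FLAG", "COOC_DIRECT", "COOC_INDIRECT")
VALUE_SLOTS = ("SELF", "DIRECT", "DTIP", "IPDP")
_SLOT_ORDER = FLAG_SLOTS + VALUE_SLOTS
_KIND_ORDER = ("flag", "predicate", "provenance")

VARIANTS = ("baseline", "predicate", "provenance", "full", "indirect_only")


@dataclass(frozen=True)
class FeatureId:
    """One column of the feature space: a slot, a kind, and a label value."""

    slot: str
    kind: str  # "flag" | "predicate" | "provenance"
    value: str = ""

    def __post_init__(self) -> None:
        if self.slot not in _SLOT_ORDER:
            raise ValidationError(f"unknown slot: {self.slot!r}")
        if self.kind not in _KIND_ORDER:
            raise ValidationError(f"unknown kind: {self.kind!r}")
        if self.kind == "flag" and (self.slot in VALUE_SLOTS or self.value):
            raise ValidationError("flag features carry no value and no value slot")
        if self.kind != "flag" and (self.slot in FLAG_SLOTS or not self.value):
            raise ValidationError("predicate/provenance features need a value slot and value")

    @property
    def sort_key(self) -> tuple[int, int, str]:
        return (_SLOT_ORDER.index(self.slot), _KIND_ORDER.index(self.kind), self.value)

    def __str__(self) -> str:
        return f"{self.slot}:{self.kind}:{self.value}"

    @classmethod
    def parse(cls, token: str) -> "FeatureId":
        slot, kind, value = token.split(":", 2)
        return cls(slot, kind, value)


@dataclass(frozen=True)
class FeatureSpec:
    """An ordered, deterministic feature space for one variant."""

    variant: str
    features: tuple[FeatureId, ...]

    def __len__(self) -> int:
        return len(self.features)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(str(f) for f in self.features)

    def index_of(self) -> dict[FeatureId, int]:
        return {f: i for i, f in enumerate(self.features)}


@dataclass(frozen=True)
class FeatureVector:
    """One combination's realization of a :class:`FeatureSpec`."""

    combo_id: str
    bits: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(b not in (0, 1) for b in self.bits):
            raise ValidationError("feature bits must be 0/1")


class KGPathFeaturizer(TransformerMixin, BaseEstimator):
    """Transform drug-disease combinations into binary path-feature vectors.

    Parameters
    ----------
    graph : KnowledgeGraph
        The triple store paths are extracted from. Its predicate and source
        vocabularies define the feature space; vocabulary derivation is
        label-free, so the space is built once from the whole graph and
        stays fixed across cross-validation splits.
    variant : str
        One of ``baseline``, ``predicate``, ``provenance``, ``full``,
        ``indirect_only``.

    Attributes
    ----------
    spec_ : FeatureSpec
        The ordered feature space, set by :meth:`fit`.
    feature_names_ : tuple of str
        Serialized feature ids (``SLOT:kind:value``), aligned to columns.
    """

    def __init__(self, graph: KnowledgeGraph | None = None, variant: str = "full"):
        self.graph = graph
        self.variant = variant

    # ---- fitting ---------------------------------------------------------
    def fit(self, X=None, y=None) -> "KGPathFeaturizer":
        graph = self.graph
        if graph is None and isinstance(X, KnowledgeGraph):
            graph = X
        if graph is None:
            raise ValidationError("a KnowledgeGraph is required (graph= or fit(X=graph))")
        if self.variant not in VARIANTS:
            raise ValidationError(
                f"unknown variant {self.variant!r}; expected one of {VARIANTS}"
            )
        self.graph_ = graph
        self.spec_ = self._build_spec(graph, self.variant)
        self.feature_names_ = self.spec_.names
        self.n_features_out_ = len(self.spec_)
        return self

    @staticmethod
    def _build_spec(graph: KnowledgeGraph, variant: str) -> FeatureSpec:
        if variant == "baseline":
            feats = [FeatureId(slot, "flag") for slot in FLAG_SLOTS]
            return FeatureSpec(variant, tuple(feats))

        kinds: list[tuple[str, tuple[str, ...]]] = []
        if variant in ("predicate", "full", "indirect_only"):
            kinds.append(("predicate", graph.predicate_vocabulary))
        if variant in ("provenance", "full", "indirect_only"):
            kinds.append(("provenance", graph.source_vocabulary))
        slots = ("DTIP", "IPDP") if variant == "indirect_only" else VALUE_SLOTS

        feats = []
        if variant != "indirect_only":
            feats.append(FeatureId("OVERLAP_FLAG", "flag"))
        for slot in slots:
            for kind, values in kinds:
                for v in sorted(values):
                    feats.append(FeatureId(slot, kind, v))
        feats.sort(key=lambda f: f.sort_key)
        return FeatureSpec(variant, tuple(feats))

    # ---- transforming ----------------------------------------------------
    def transform(self, X) -> np.ndarray:
        """Extract one row of 0/1 features per combination in ``X``."""
        self._check_fitted()
        index = self.spec_.index_of()
        rows = np.zeros((len(X), len(self.spec_)), dtype=np.uint8)
        for i, combo in enumerate(X):
            for fid in self._present_features(combo):
                j = index.get(fid)
                if j is not None:
                    rows[i, j] = 1
        return rows

    def transform_one(self, combo: Combination) -> FeatureVector:
        row = self.transform([combo])[0]
        return FeatureVector(combo.combo_id, tuple(int(b) for b in row))

    def get_feature_names_out(self, input_features=None):
        self._check_fitted()
        return np.asarray(self.feature_names_, dtype=object)

    def _check_fitted(self) -> None:
        if not hasattr(self, "spec_"):
            raise ValidationError("featurizer is not fitted; call fit() first")

    def _present_features(self, combo: Combination) -> set[FeatureId]:
        """All (slot, kind, value) features realized by the combo's paths."""
        graph = self.graph_
        present: set[FeatureId] = set()

        overlap = pathfind.find_overlap(combo, graph)
        if overlap:
            present.add(FeatureId("OVERLAP_FLAG", "flag"))
            for rec in overlap:
                self._add_triples(present, "SELF", rec.step_triples[STEP_SELF])

        direct = pathfind.find_direct(combo, graph)
        if direct:
            present.add(FeatureId("COOC_DIRECT", "flag"))
            for rec in direct:
                self._add_triples(present, "DIRECT", rec.step_triples[STEP_DIRECT])

        indirect = pathfind.find_indirect(combo, graph)
        if indirect:
            present.add(FeatureId("COOC_INDIRECT", "flag"))
            for rec in indirect:
                self._add_triples(present, "DTIP", rec.step_triples[STEP_DTIP])
                self._add_triples(present, "IPDP", rec.step_triples[STEP_IPDP])
        return present

    @staticmethod
    def _add_triples(present: set[FeatureId], slot: str, triples) -> None:
        for t in triples:
            present.add(FeatureId(slot, "predicate", t.predicate))
            for s in t.provenance:
                present.add(FeatureId(slot, "provenance", s))


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------

def build_feature_space(graph: KnowledgeGraph, variant: str) -> FeatureSpec:
    """Deterministic ordered feature space for a graph's vocabularies."""
    return KGPathFeaturizer(graph=graph, variant=variant).fit().spec_


def extract_features(
    combo: Combination, graph: KnowledgeGraph, spec: FeatureSpec
) -> FeatureVector:
    """Realize one combination against an existing spec.

    The spec must have been built from vocabularies compatible with
    ``graph`` (every value-feature label inside the graph's vocabularies).
    """
    _check_spec_compatible(spec, graph)
    feat = KGPathFeaturizer(graph=graph, variant=spec.variant).fit()
    feat.spec_ = spec
    feat.feature_names_ = spec.names
    return feat.transform_one(combo)


def extract_matrix(combos, graph: KnowledgeGraph, spec: FeatureSpec) -> np.ndarray:
    _check_spec_compatible(spec, graph)
    feat = KGPathFeaturizer(graph=graph, variant=spec.variant).fit()
    feat.spec_ = spec
    feat.feature_names_ = spec.names
    return feat.transform(list(combos))


def _check_spec_compatible(spec: FeatureSpec, graph: KnowledgeGraph) -> None:
    preds = set(graph.predicate_vocabulary)
    srcs = set(graph.source_vocabulary)
    for f in spec.features:
        if f.kind == "predicate" and f.value not in preds:
            raise ValidationError(f"spec predicate {f.value!r} not in graph vocabulary")
        if f.kind == "provenance" and f.value not in srcs:
            raise ValidationError(f"spec source {f.value!r} not in graph vocabulary")


def restrict_to_sources(
    spec: FeatureSpec,
    combos,
    graph: KnowledgeGraph,
    excluded_source: str,
) -> tuple[FeatureSpec, list[FeatureVector], KnowledgeGraph]:
    """Drop everything derivable only from one provenance source.

    Removes (i) the provenance columns of ``excluded_source`` and (ii) any
    predicate column whose label survives nowhere once triples attested
    *only* by that source are deleted; the remaining columns are
    re-extracted against the filtered graph, i.e. as if the sole-source
    triples were absent. Returns the restricted spec, the re-extracted
    vectors, and the filtered graph.
    """
    filtered = graph.without_sole_source_triples(excluded_source)
    surviving_predicates = {t.predicate for t in filtered.triples}
    kept = tuple(
        f
        for f in spec.features
        if not (f.kind == "provenance" and f.value == excluded_source)
        and not (f.kind == "predicate" and f.value not in surviving_predicates)
    )
    new_spec = FeatureSpec(spec.variant, kept)
    vectors = [extract_features(c, filtered, new_spec) for c in combos]
    return new_spec, vectors, filtered
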