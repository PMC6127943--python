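"""Synthetic knowledge graphs and reference sets with plantable class signal.

The commercial graph the screening method was developed on is not
redistributable, so every experiment in this package runs on synthetic
data shaped like it: thousands of proteins, a heavy-tailed degree
distribution, edges carrying 1-3 predicates each attested by 1-3 sources
(vocabulary cardinalities default to 45 predicates and 25 sources), and
reference sets whose drug-target and disease-protein set sizes follow
geometric distributions with medians 2 and 5.

Class signal is planted so the central claim — predicate and provenance
labels carry information beyond mere path co-occurrence — is a testable
property: positives and negatives receive planted paths through the same
scenario-mix process at the same rate (overlap / direct / indirect), but
only the triples on positive paths switch their predicate (with
probability ``predicate_effect``) or provenance (``provenance_effect``)
to designated signal labels. Co-occurrence rates are therefore matched
between classes by construction and the baseline flag features stay
uninformative at any effect size, while the value features separate the
classes in proportion to the effects. Setting both effects to zero yields
fully exchangeable classes.

``planted_sole_source`` stamps every planted path triple of *both*
classes with exactly that one source, making the planted evidence
removable by single-source ablation — symmetrically, so ablation returns
performance to chance instead of inverting the signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .kg_core import Combination, KnowledgeGraph, ProteinSet, Triple, ValidationError

__all__ = ["SynthConfig", "SynthBundle", "generate_graph", "generate_reference",
           "generate", "scenario_fixture"]

_SCENARIOS = ("overlap", "direct", "indirect")


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; defaults define the package's benchmark conditions."""

    n_proteins: int = 500
    n_predicates: int = 45
    n_sources: int = 25
    edge_density: float = 3.0          # expected background edges per protein
    degree_dist: str = "powerlaw"      # "powerlaw" | "uniform"
    n_pos: int = 100
    n_neg: int = 100
    dt_size_p: float = 0.35            # geometric; median set size 2
    dt_size_max: int = 51
    dp_size_p: float = 0.13            # geometric; median set size 5
    dp_size_max: int = 273
    n_signal_predicates: int = 3
    n_signal_sources: int = 2
    predicate_effect: float = 0.9
    provenance_effect: float = 0.6
    scenario_mix: tuple[float, float, float] = (0.15, 0.35, 0.50)
    paths_per_combo: int = 3
    planted_sole_source: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.predicate_effect, self.provenance_effect, self.dt_size_p,
                  self.dp_size_p, *self.scenario_mix):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"probability out of [0,1]: {p}")
        if min(self.n_proteins, self.n_predicates, self.n_sources,
               self.n_pos, self.n_neg, self.paths_per_combo) <= 0:
            raise ValidationError("counts must be positive")
        if self.n_predicates < self.n_signal_predicates:
            raise ValidationError("more signal predicates than predicates")
        if self.n_sources < self.n_signal_sources:
            raise ValidationError("more signal sources than sources")
        if abs(sum(self.scenario_mix) - 1.0) > 1e-9:
            raise ValidationError("scenario_mix must sum to 1")
        if self.degree_dist not in ("powerlaw", "uniform"):
            raise ValidationError(f"unknown degree_dist: {self.degree_dist!r}")

    # ---- derived vocabularies -------------------------------------------
    @property
    def proteins(self) -> tuple[str, ...]:
        return tuple(f"PR{i:04d}" for i in range(1, self.n_proteins + 1))

    @property
    def predicates(self) -> tuple[str, ...]:
        return tuple(f"P{i:02d}" for i in range(1, self.n_predicates + 1))

    @property
    def sources(self) -> tuple[str, ...]:
        return tuple(f"S{i:02d}" for i in range(1, self.n_sources + 1))

    @property
    def signal_predicates(self) -> tuple[str, ...]:
        # the rarest background labels: planted signal must not be swamped
        # by background paths that happen to carry the same labels
        return self.predicates[-self.n_signal_predicates:]

    @property
    def signal_sources(self) -> tuple[str, ...]:
        return self.sources[-self.n_signal_sources:]


@dataclass(frozen=True)
class SynthBundle:
    """A generated graph, its labelled combinations, and the planted truth."""

    graph: KnowledgeGraph
    combos: tuple[Combination, ...]
    truth: dict


def _zipf_probs(n: int) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1)
    return w / w.sum()


def generate_graph(config: SynthConfig) -> KnowledgeGraph:
    """Random background graph with multi-predicate, multi-source edges."""
    rng = np.random.default_rng([config.seed, 0])
    n = config.n_proteins
    proteins = config.proteins
    m = int(round(n * config.edge_density))
    if m > n * (n - 1) // 2:
        raise ValidationError(
            f"edge_density {config.edge_density} infeasible for {n} proteins"
        )
    if config.degree_dist == "powerlaw":
        w = 1.0 / np.arange(1, n + 1) ** 0.8
        node_p = w / w.sum()
    else:
        node_p = np.full(n, 1.0 / n)
    pred_p = _zipf_probs(config.n_predicates)
    src_p = _zipf_probs(config.n_sources)

    pairs: set[tuple[int, int]] = set()
    attempts = 0
    while len(pairs) < m and attempts < 100 * max(m, 1):
        a, b = rng.choice(n, size=2, p=node_p)
        attempts += 1
        if a == b:
            continue
        pairs.add((min(a, b), max(a, b)))
    if len(pairs) < m:
        warnings.warn(f"only placed {len(pairs)} of {m} requested edges")

    triples: list[Triple] = []
    for a, b in sorted(pairs):
        n_pred = int(rng.integers(1, 4))
        preds = rng.choice(config.n_predicates, size=n_pred, replace=False, p=pred_p)
        # random orientation per edge; path semantics are undirected anyway
        subj, obj = (proteins[a], proteins[b]) if rng.random() < 0.5 else (
            proteins[b], proteins[a])
        for k in preds:
            n_src = int(rng.integers(1, 4))
            srcs = rng.choice(config.n_sources, size=n_src, replace=False, p=src_p)
            triples.append(
                Triple(subj, config.predicates[int(k)], obj,
                       frozenset(config.sources[int(s)] for s in srcs))
            )
    return KnowledgeGraph(
        triples,
        proteins=proteins,
        predicate_vocabulary=config.predicates,
        source_vocabulary=config.sources,
    )


def _sample_size(rng: np.random.Generator, p: float, cap: int, n_proteins: int) -> int:
    size = int(rng.geometric(p))
    return max(1, min(size, cap, max(1, n_proteins // 4)))


def generate_reference(graph: KnowledgeGraph, config: SynthConfig) -> SynthBundle:
    """Labelled combinations with planted, class-symmetric path structure.

    Positives and negatives are built by the identical structural process;
    they differ only in the label distributions on planted path triples.
    The returned graph is the input graph plus the planted triples.
    """
    rng = np.random.default_rng([config.seed, 1])
    proteins = sorted(graph.proteins)
    n = len(proteins)
    if config.planted_sole_source is not None and (
        config.planted_sole_source not in graph.source_vocabulary
    ):
        raise ValidationError(
            f"planted_sole_source {config.planted_sole_source!r} not in vocabulary"
        )
    pred_p = _zipf_probs(len(graph.predicate_vocabulary))
    src_p = _zipf_probs(len(graph.source_vocabulary))
    all_preds = tuple(sorted(graph.predicate_vocabulary))
    all_srcs = tuple(sorted(graph.source_vocabulary))
    signal_preds = config.signal_predicates
    signal_srcs = config.signal_sources

    def pick_predicate(positive: bool) -> str:
        if positive and rng.random() < config.predicate_effect:
            return signal_preds[int(rng.integers(len(signal_preds)))]
        return all_preds[int(rng.choice(len(all_preds), p=pred_p))]

    def pick_provenance(positive: bool) -> frozenset[str]:
        if config.planted_sole_source is not None:
            return frozenset((config.planted_sole_source,))
        if positive and rng.random() < config.provenance_effect:
            return frozenset((signal_srcs[int(rng.integers(len(signal_srcs)))],))
        k = int(rng.integers(1, 3))
        idx = rng.choice(len(all_srcs), size=k, replace=False, p=src_p)
        return frozenset(all_srcs[int(i)] for i in idx)

    planted: list[Triple] = []
    combos: list[Combination] = []
    for label, count in (("positive", config.n_pos), ("negative", config.n_neg)):
        positive = label == "positive"
        for i in range(count):
            dt_size = _sample_size(rng, config.dt_size_p, config.dt_size_max, n)
            dp_size = _sample_size(rng, config.dp_size_p, config.dp_size_max, n)
            dt = set(
                proteins[int(j)]
                for j in rng.choice(n, size=dt_size, replace=False)
            )
            dp = set(
                proteins[int(j)]
                for j in rng.choice(n, size=dp_size, replace=False)
            )
            for _ in range(config.paths_per_combo):
                scenario = _SCENARIOS[int(rng.choice(3, p=config.scenario_mix))]
                t = sorted(dt)[int(rng.integers(len(dt)))]
                if scenario == "overlap":
                    dp.add(t)
                    planted.append(
                        Triple(t, pick_predicate(positive), t, pick_provenance(positive))
                    )
                    continue
                s_candidates = sorted(dp - {t}) or sorted(set(proteins) - {t})
                s = s_candidates[int(rng.integers(len(s_candidates)))]
                dp.add(s)
                if scenario == "direct":
                    planted.append(
                        Triple(t, pick_predicate(positive), s, pick_provenance(positive))
                    )
                else:
                    ip_candidates = sorted(set(proteins) - {t, s})
                    ip = ip_candidates[int(rng.integers(len(ip_candidates)))]
                    planted.append(
                        Triple(t, pick_predicate(positive), ip, pick_provenance(positive))
                    )
                    planted.append(
                        Triple(ip, pick_predicate(positive), s, pick_provenance(positive))
                    )
            cid = f"{'pos' if positive else 'neg'}{i:04d}"
            combos.append(
                Combination(
                    cid,
                    ProteinSet(frozenset(dt), "DT", set_id=f"{cid}:DT"),
                    ProteinSet(frozenset(dp), "DP", set_id=f"{cid}:DP"),
                    label,
                )
            )

    full_graph = KnowledgeGraph(
        tuple(graph.triples) + tuple(planted),
        proteins=graph.proteins,
        predicate_vocabulary=graph.predicate_vocabulary,
        source_vocabulary=graph.source_vocabulary,
    )
    informative = []
    if config.predicate_effect > 0:
        informative += [
            f"{slot}:predicate:{p}"
            for slot in ("SELF", "DIRECT", "DTIP", "IPDP")
            for p in signal_preds
        ]
    if config.provenance_effect > 0 and config.planted_sole_source is None:
        informative += [
            f"{slot}:provenance:{s}"
            for slot in ("SELF", "DIRECT", "DTIP", "IPDP")
            for s in signal_srcs
        ]
    truth = {
        "signal_predicates": list(signal_preds),
        "signal_sources": list(signal_srcs),
        "predicate_effect": config.predicate_effect,
        "provenance_effect": config.provenance_effect,
        "planted_sole_source": config.planted_sole_source,
        "scenario_mix": list(config.scenario_mix),
        "informative_features": informative,
        "n_planted_triples": len(planted),
    }
    return SynthBundle(full_graph, tuple(combos), truth)


def generate(config: SynthConfig) -> SynthBundle:
    """Background graph + reference set in one call."""
    return generate_reference(generate_graph(config), config)


def scenario_fixture() -> SynthBundle:
    """Hand-built eight-protein graph with one instance of each path scenario.

    * overlap — protein A is both drug target and disease protein and
      homodimerizes (a self-relationship triple);
    * direct — drug target B binds disease protein C (single triple,
      single source);
    * indirect — drug target D reaches disease protein F through the
      intermediate E (two steps with distinct predicates and sources).

    G and H carry an unrelated background edge.
    """
    triples = (
        Triple("A", "homodimerizes", "A", frozenset(("S1",))),
        Triple("B", "binds", "C", frozenset(("S2",))),
        Triple("D", "binds", "E", frozenset(("S1",))),
        Triple("E", "activates", "F", frozenset(("S2",))),
        Triple("G", "interacts", "H", frozenset(("S3",))),
    )
    graph = KnowledgeGraph(triples)
    combos = (
        Combination("c_overlap", ProteinSet(frozenset("A"), "DT"),
                    ProteinSet(frozenset("A"), "DP"), "positive"),
        Combination("c_direct", ProteinSet(frozenset("B"), "DT"),
                    ProteinSet(frozenset("C"), "DP"), "positive"),
        Combination("c_indirect", ProteinSet(frozenset("D"), "DT"),
                    ProteinSet(frozenset("F"), "DP"), "negative"),
    )
    truth = {
        "scenarios": {
            "c_overlap": "overlap",
            "c_direct": "direct",
            "c_indirect": "indirect",
        },
        "intermediate": {"c_indirect": "E"},
    }
    return SynthBundle(graph, combos, truth)
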