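"""Enumeration of the three path scenarios between drug targets and disease proteins.

Three scenarios relate a drug-target set (DT) to a disease-protein set (DP):

* OVERLAP — a protein is simultaneously a drug target and a disease
  protein; it may additionally carry self-relationship triples
  (e.g. homodimerization).
* DIRECT — a drug target and a distinct disease protein are joined by one
  or more triples.
* INDIRECT — a two-step path through exactly one intermediate protein
  (IP); the two steps are kept separate as DTIP (drug target to
  intermediate) and IPDP (intermediate to disease protein).

Paths longer than two steps are never produced. Matching is
orientation-insensitive: a triple joins a pair regardless of which member
is the subject. An intermediate may itself belong to DT or DP as long as
it differs from the two endpoints of its own path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .kg_core import Combination, KnowledgeGraph, Triple

__all__ = [
    "OVERLAP",
    "DIRECT",
    "INDIRECT",
    "STEP_SELF",
    "STEP_DIRECT",
    "STEP_DTIP",
    "STEP_IPDP",
    "PathRecord",
    "find_overlap",
    "find_direct",
    "find_indirect",
    "find_all",
    "has_qualifying_path",
]

OVERLAP = "OVERLAP"
DIRECT = "DIRECT"
INDIRECT = "INDIRECT"

STEP_SELF = "SELF"
STEP_DIRECT = "DIRECT"
STEP_DTIP = "DTIP"
STEP_IPDP = "IPDP"


@dataclass(frozen=True)
class PathRecord:
    """One enumerated path instance with the triples supporting each step."""

    scenario: str
    dt: str
    dp: str
    ip: str | None = None
    step_triples: Mapping[str, tuple[Triple, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scenario == OVERLAP:
            assert self.dt == self.dp and self.ip is None
        elif self.scenario == DIRECT:
            assert self.dt != self.dp and self.ip is None
            assert self.step_triples.get(STEP_DIRECT)
        elif self.scenario == INDIRECT:
            assert self.ip is not None and self.ip not in (self.dt, self.dp)
            assert self.step_triples.get(STEP_DTIP) and self.step_triples.get(STEP_IPDP)
        else:
            raise ValueError(f"unknown scenario: {self.scenario!r}")


def find_overlap(combo: Combination, graph: KnowledgeGraph) -> list[PathRecord]:
    """One OVERLAP record per protein in both sets.

    The record's SELF step holds that protein's self-relationship triples,
    which may be an empty bag — overlap alone is evidence even without a
    recorded self-relationship.
    """
    records = []
    shared = combo.drug_targets.members & combo.disease_proteins.members
    for p in sorted(shared):
        records.append(
            PathRecord(OVERLAP, p, p, step_triples={STEP_SELF: graph.self_triples(p)})
        )
    return records


def find_direct(combo: Combination, graph: KnowledgeGraph) -> list[PathRecord]:
    """One DIRECT record per connected (dt, dp) pair with dt != dp.

    Collects every triple joining the pair in either orientation; pairs
    where drug target and disease protein coincide belong to the OVERLAP
    scenario and are excluded here.
    """
    records = []
    dps = combo.disease_proteins.members
    for dt in sorted(combo.drug_targets.members):
        for dp in sorted(dps):
            if dt == dp:
                continue
            triples = graph.triples_between(dt, dp)
            if triples:
                records.append(
                    PathRecord(DIRECT, dt, dp, step_triples={STEP_DIRECT: triples})
                )
    return records


def find_indirect(combo: Combination, graph: KnowledgeGraph) -> list[PathRecord]:
    """One INDIRECT record per (dt, ip, dp) two-step path.

    The intermediate must differ from both endpoints of its path but may
    otherwise be any protein, including another drug target or disease
    protein of the combination. No paths longer than two steps exist by
    construction.
    """
    records = []
    dps = combo.disease_proteins.members
    for dt in sorted(combo.drug_targets.members):
        for ip in sorted(graph.neighbors(dt)):
            dtip = graph.triples_between(dt, ip)
            for dp in sorted(dps):
                if dp == dt or dp == ip:
                    continue
                ipdp = graph.triples_between(ip, dp)
                if ipdp:
                    records.append(
                        PathRecord(
                            INDIRECT,
                            dt,
                            dp,
                            ip=ip,
                            step_triples={STEP_DTIP: dtip, STEP_IPDP: ipdp},
                        )
                    )
    return records


def find_all(combo: Combination, graph: KnowledgeGraph) -> dict[str, list[PathRecord]]:
    return {
        OVERLAP: find_overlap(combo, graph),
        DIRECT: find_direct(combo, graph),
        INDIRECT: find_indirect(combo, graph),
    }


def has_qualifying_path(dp: str, combo: Combination, graph: KnowledgeGraph) -> bool:
    """Whether a disease protein is reachable from any drug target within two steps.

    Disease proteins failing this test contribute nothing to any feature
    and can be reported as unusable for the combination.
    """
    if dp not in combo.disease_proteins.members:
        raise KeyError(f"{dp} is not a disease protein of {combo.combo_id}")
    if dp in combo.drug_targets.members:
        return True
    for dt in combo.drug_targets.members:
        if dt == dp:
            continue
        if graph.triples_between(dt, dp):
            return True
        for ip in graph.neighbors(dt):
            if ip != dp and ip != dt and graph.triples_between(ip, dp):
                return True
    return False
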