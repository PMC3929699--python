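"""Core in-memory containers for the off-label usage pipeline.

The pipeline reasons about four kinds of objects: patient-level concept
mentions, a binary drug x indication known-usage relation, a concept
hierarchy used to normalize indications and to detect near-miss
predictions, and per-drug knowledge (attribute sets, adverse events,
unit costs) used for similarity features and for risk/cost triage.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

DRUG = "drug"
INDICATION = "indication"
CONCEPT_TYPES = frozenset({DRUG, INDICATION})


class HierarchyError(ValueError):
    """Raised when a concept hierarchy contains a cycle."""


@dataclass(frozen=True)
class MentionRecord:
    """One concept occurrence for one patient on one date."""

    patient_id: str
    note_id: str
    date: dt.date
    concept_id: str
    concept_type: str

    def __post_init__(self) -> None:
        if self.concept_type not in CONCEPT_TYPES:
            raise ValueError(
                f"concept_type must be one of {sorted(CONCEPT_TYPES)}, "
                f"got {self.concept_type!r}"
            )


class UsageMatrix:
    """Binary drug x indication known-usage relation.

    Each (drug, indication) pair carries an approval flag: ``approved``
    usages are on the drug's label, ``known`` usages are recognized but
    unapproved. Row profiles (a drug's binary indication vector) and
    column profiles (an indication's binary drug vector) drive the
    usage-profile similarity features.
    """

    def __init__(
        self,
        drugs: Iterable[str],
        indications: Iterable[str],
        pairs: Mapping[tuple[str, str], bool] | Iterable[tuple[str, str]] = (),
    ) -> None:
        self.drugs: tuple[str, ...] = tuple(dict.fromkeys(drugs))
        self.indications: tuple[str, ...] = tuple(dict.fromkeys(indications))
        self._drug_set = frozenset(self.drugs)
        self._ind_set = frozenset(self.indications)
        if isinstance(pairs, Mapping):
            items = dict(pairs)
        else:
            items = {pair: True for pair in pairs}
        for d, i in items:
            if d not in self._drug_set:
                raise ValueError(f"pair references unknown drug {d!r}")
            if i not in self._ind_set:
                raise ValueError(f"pair references unknown indication {i!r}")
        self._approved: dict[tuple[str, str], bool] = items

    # -- basic relation queries -------------------------------------------
    @property
    def pairs(self) -> frozenset[tuple[str, str]]:
        return frozenset(self._approved)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self._approved

    def __len__(self) -> int:
        return len(self._approved)

    def is_approved(self, drug: str, indication: str) -> bool:
        return self._approved.get((drug, indication), False)

    def treaters(self, indication: str) -> frozenset[str]:
        """Drugs known or approved to treat ``indication``."""
        return frozenset(d for (d, i) in self._approved if i == indication)

    def indications_of(self, drug: str) -> frozenset[str]:
        return frozenset(i for (d, i) in self._approved if d == drug)

    # -- set algebra -------------------------------------------------------
    def union(self, other: "UsageMatrix") -> "UsageMatrix":
        merged = dict(other._approved)
        merged.update(self._approved)  # self's approval flag wins on overlap
        return UsageMatrix(
            list(self.drugs) + [d for d in other.drugs if d not in self._drug_set],
            list(self.indications)
            + [i for i in other.indications if i not in self._ind_set],
            merged,
        )

    def without(self, pairs: Iterable[tuple[str, str]]) -> "UsageMatrix":
        drop = set(pairs)
        return UsageMatrix(
            self.drugs,
            self.indications,
            {p: a for p, a in self._approved.items() if p not in drop},
        )

    def to_records(self) -> list[tuple[str, str, str]]:
        return sorted(
            (d, i, "approved" if a else "known")
            for (d, i), a in self._approved.items()
        )


class ConceptHierarchy:
    """Directed acyclic is-a hierarchy over concepts (child -> parent edges).

    Multiple parents are allowed; cycles are rejected at construction.
    """

    def __init__(self, edges: Iterable[tuple[str, str]]) -> None:
        self.graph = nx.DiGraph()
        self.graph.add_edges_from(edges)  # edge child -> parent
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise HierarchyError(f"hierarchy contains a cycle: {cycle}")

    @property
    def edges(self) -> frozenset[tuple[str, str]]:
        return frozenset(self.graph.edges())

    def parents(self, concept: str) -> frozenset[str]:
        if concept not in self.graph:
            return frozenset()
        return frozenset(self.graph.successors(concept))

    def children(self, concept: str) -> frozenset[str]:
        if concept not in self.graph:
            return frozenset()
        return frozenset(self.graph.predecessors(concept))

    def ancestors(self, concept: str) -> frozenset[str]:
        """All transitive ancestors (parents, grandparents, ...)."""
        if concept not in self.graph:
            return frozenset()
        return frozenset(nx.descendants(self.graph, concept))

    def descendants(self, concept: str) -> frozenset[str]:
        """All transitive descendants (subtypes at any depth)."""
        if concept not in self.graph:
            return frozenset()
        return frozenset(nx.ancestors(self.graph, concept))


@dataclass(frozen=True)
class DrugAttributes:
    targets: frozenset[str] = frozenset()
    pathways: frozenset[str] = frozenset()
    categories: frozenset[str] = frozenset()


ATTRIBUTE_KINDS = ("targets", "pathways", "categories")


class DrugAttributeTable:
    """Per-drug attribute sets (molecular targets, pathways, categories).

    A drug absent from the table is distinguishable from a drug with
    empty attribute sets: ``get`` returns None for absent drugs.
    """

    def __init__(self, table: Mapping[str, DrugAttributes] | None = None) -> None:
        self._table: dict[str, DrugAttributes] = dict(table or {})

    def __contains__(self, drug: str) -> bool:
        return drug in self._table

    def __len__(self) -> int:
        return len(self._table)

    @property
    def drugs(self) -> frozenset[str]:
        return frozenset(self._table)

    def get(self, drug: str) -> DrugAttributes | None:
        return self._table.get(drug)

    def to_records(self) -> list[tuple[str, str, str]]:
        rows = []
        for drug, attrs in self._table.items():
            for kind in ATTRIBUTE_KINDS:
                for value in getattr(attrs, kind):
                    rows.append((drug, kind, value))
        return sorted(rows)

    @classmethod
    def from_records(cls, rows: Iterable[tuple[str, str, str]]) -> "DrugAttributeTable":
        acc: dict[str, dict[str, set[str]]] = {}
        for drug, kind, value in rows:
            if kind not in ATTRIBUTE_KINDS:
                raise ValueError(f"unknown attribute kind {kind!r}")
            acc.setdefault(drug, {k: set() for k in ATTRIBUTE_KINDS})[kind].add(value)
        return cls(
            {
                drug: DrugAttributes(
                    targets=frozenset(kinds["targets"]),
                    pathways=frozenset(kinds["pathways"]),
                    categories=frozenset(kinds["categories"]),
                )
                for drug, kinds in acc.items()
            }
        )


@dataclass(frozen=True)
class EvidenceBundle:
    """External evidence used to corroborate or veto predicted usages.

    ``report_links``: spontaneous case reports explicitly linking a drug
    to the indication it treated (report id, drug, indication).
    ``literature_links``: articles co-annotated with a drug and an
    indication in a therapy context (article id, drug, indication).
    ``side_effects``: (drug, event concept) pairs from a side-effect
    resource; predicted usages matching one are suspected adverse events.
    """

    report_links: frozenset[tuple[str, str, str]] = frozenset()
    literature_links: frozenset[tuple[str, str, str]] = frozenset()
    side_effects: frozenset[tuple[str, str]] = frozenset()


@dataclass(frozen=True)
class AdverseEvent:
    event_id: str
    severity: str
    frequency: str


@dataclass
class DrugEconSafetyProfile:
    """A drug's adverse-event associations and unit costs.

    Severity and frequency class vocabularies are configuration (closed
    enumerations supplied by the caller), not hard-coded.
    """

    adverse_events: list[AdverseEvent] = field(default_factory=list)
    unit_costs: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.unit_costs):
            raise ValueError("unit costs must be non-negative")
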