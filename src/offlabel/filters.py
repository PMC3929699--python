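"""Candidate filtering: from flagged predictions to novel off-label usages.

Flagged pairs pass through a fixed cascade: known-usage removal,
hierarchical near-miss removal, spontaneous-report support, literature
support, side-effect removal (with a manual-review whitelist), and an
explicit manual removal list. A :class:`FilterLedger` accounts for
every pair at every stage — n_in = n_pass + n_removed always — and
records exactly one primary removal reason per removed pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .containers import ConceptHierarchy, EvidenceBundle, UsageMatrix

Pair = tuple[str, str]

STAGE_ORDER = (
    "known-usage",
    "near-miss",
    "report-support",
    "literature-support",
    "side-effect",
    "manual-override",
)


@dataclass
class FilterStage:
    name: str
    n_in: int
    n_pass: int
    n_removed: int
    removed: dict[Pair, str] = field(default_factory=dict)
    flagged: dict[Pair, str] = field(default_factory=dict)  # notes, not removals


@dataclass
class FilterLedger:
    stages: list[FilterStage] = field(default_factory=list)

    def add(self, stage: FilterStage) -> None:
        if stage.n_in != stage.n_pass + stage.n_removed:
            raise ValueError(
                f"stage {stage.name!r} breaks conservation: "
                f"{stage.n_in} != {stage.n_pass} + {stage.n_removed}"
            )
        if self.stages and self.stages[-1].n_pass != stage.n_in:
            raise ValueError(
                f"stage {stage.name!r} n_in {stage.n_in} != previous n_pass "
                f"{self.stages[-1].n_pass}"
            )
        self.stages.append(stage)

    def verify(self) -> None:
        for k, stage in enumerate(self.stages):
            assert stage.n_in == stage.n_pass + stage.n_removed
            if k:
                assert self.stages[k - 1].n_pass == stage.n_in

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stage": s.name,
                    "n_in": s.n_in,
                    "n_pass": s.n_pass,
                    "n_removed": s.n_removed,
                }
                for s in self.stages
            ]
        )

    def removals_frame(self) -> pd.DataFrame:
        rows = [
            {"stage": s.name, "drug": d, "indication": i, "reason": reason}
            for s in self.stages
            for (d, i), reason in sorted(s.removed.items())
        ]
        return pd.DataFrame(rows, columns=["stage", "drug", "indication", "reason"])


def known_usage_filter(
    pairs: Iterable[Pair], usage_union: UsageMatrix
) -> tuple[list[Pair], dict[Pair, str]]:
    """Remove pairs present in the union of the known-usage KBs."""
    passed, removed = [], {}
    for pair in pairs:
        if pair in usage_union:
            removed[pair] = "known usage"
        else:
            passed.append(pair)
    return passed, removed


def near_miss_filter(
    pairs: Iterable[Pair],
    usage_union: UsageMatrix,
    hierarchy: ConceptHierarchy,
) -> tuple[list[Pair], dict[Pair, str]]:
    """Remove pairs whose indication is a near miss of a known usage.

    (d, i) is removed if i is a transitive descendant (subtype at any
    depth) of some known indication of d, or i is a *direct* parent of
    one. A grandparent is not a near miss: the parent rule is
    distance-1 only.
    """
    passed, removed = [], {}
    for d, i in pairs:
        known_inds = usage_union.indications_of(d)
        reason = None
        ancestors = hierarchy.ancestors(i)
        children = hierarchy.children(i)
        for j in known_inds:
            if j in ancestors:
                reason = f"subtype of known indication {j}"
                break
            if j in children:
                reason = f"direct parent of known indication {j}"
                break
        if reason:
            removed[(d, i)] = reason
        else:
            passed.append((d, i))
    return passed, removed


def report_support(pair: Pair, report_links: Iterable[tuple[str, str, str]]) -> int:
    """Distinct case reports linking the drug as treatment for the indication."""
    d, i = pair
    return len({rid for rid, rd, ri in report_links if rd == d and ri == i})


def literature_support(
    pair: Pair, literature_links: Iterable[tuple[str, str, str]]
) -> int:
    """Distinct articles co-annotated with the drug and the indication in a
    therapy context."""
    d, i = pair
    return len({aid for aid, ad, ai in literature_links if ad == d and ai == i})


def side_effect_filter(
    pairs: Iterable[Pair],
    side_effects: frozenset[Pair],
    whitelist: frozenset[Pair] = frozenset(),
) -> tuple[list[Pair], dict[Pair, str], dict[Pair, str]]:
    """Remove pairs matching a side-effect entry unless whitelisted.

    Every match is flagged in the third return value regardless of the
    whitelist, modeling the manual review of side-effect matches.
    """
    passed, removed, flagged = [], {}, {}
    for pair in pairs:
        if pair in side_effects:
            flagged[pair] = "matches side-effect entry"
            if pair in whitelist:
                passed.append(pair)
            else:
                removed[pair] = "listed as drug adverse event"
        else:
            passed.append(pair)
    return passed, removed, flagged


@dataclass(frozen=True)
class FilterConfig:
    report_threshold: int = 10
    literature_threshold: int = 3


def run_cascade(
    pairs: Iterable[Pair],
    evidence: EvidenceBundle,
    usage_union: UsageMatrix,
    hierarchy: ConceptHierarchy,
    config: FilterConfig | None = None,
    whitelist: frozenset[Pair] = frozenset(),
    removal_list: frozenset[Pair] = frozenset(),
) -> tuple[list[Pair], FilterLedger]:
    """Run the full filter cascade in canonical order with accounting.

    The stage order (known-usage, near-miss, report-support,
    literature-support, side-effect, manual-override) is canonical;
    the filters do not commute in general.
    """
    cfg = config or FilterConfig()
    ledger = FilterLedger()
    current = list(dict.fromkeys(pairs))

    passed, removed = known_usage_filter(current, usage_union)
    ledger.add(FilterStage("known-usage", len(current), len(passed), len(removed), removed))
    current = passed

    passed, removed = near_miss_filter(current, usage_union, hierarchy)
    ledger.add(FilterStage("near-miss", len(current), len(passed), len(removed), removed))
    current = passed

    # distinct-support counts, computed once per surviving pair
    report_counts = _support_counts(evidence.report_links)
    passed, removed = [], {}
    for pair in current:
        n = report_counts.get(pair, 0)
        if n >= cfg.report_threshold:
            passed.append(pair)
        else:
            removed[pair] = (
                f"only {n} supporting reports (< {cfg.report_threshold})"
            )
    ledger.add(FilterStage("report-support", len(current), len(passed), len(removed), removed))
    current = passed

    article_counts = _support_counts(evidence.literature_links)
    passed, removed = [], {}
    for pair in current:
        n = article_counts.get(pair, 0)
        if n >= cfg.literature_threshold:
            passed.append(pair)
        else:
            removed[pair] = (
                f"only {n} supporting articles (< {cfg.literature_threshold})"
            )
    ledger.add(
        FilterStage("literature-support", len(current), len(passed), len(removed), removed)
    )
    current = passed

    passed, removed, flagged = side_effect_filter(
        current, evidence.side_effects, whitelist
    )
    ledger.add(
        FilterStage(
            "side-effect", len(current), len(passed), len(removed), removed, flagged
        )
    )
    current = passed

    passed, removed = [], {}
    for pair in current:
        if pair in removal_list:
            removed[pair] = "manual review removal"
        else:
            passed.append(pair)
    ledger.add(
        FilterStage("manual-override", len(current), len(passed), len(removed), removed)
    )
    ledger.verify()
    return passed, ledger


def _support_counts(links: Iterable[tuple[str, str, str]]) -> dict[Pair, int]:
    seen: dict[Pair, set[str]] = {}
    for link_id, d, i in links:
        seen.setdefault((d, i), set()).add(link_id)
    return {pair: len(ids) for pair, ids in seen.items()}
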