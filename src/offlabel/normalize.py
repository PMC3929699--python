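"""Normalization of raw mentions into the target vocabularies.

Drug mentions are rewritten to active ingredients (a combination
product like Excedrin becomes three ingredient mentions); indication
mentions outside the target vocabulary are rolled up the concept
hierarchy to their nearest in-target ancestors. Mentions that cannot be
normalized are routed to a rejected-mentions report, never dropped
silently: over the ingredient-expanded record stream,
accepted + rejected = total.
"""

from __future__ import annotations

from collections import deque
from typing import Iterable, Mapping

import pandas as pd

from .containers import DRUG, INDICATION, ConceptHierarchy


class IngredientMap:
    """Product/brand drug id -> non-empty set of active-ingredient ids."""

    def __init__(self, mapping: Mapping[str, Iterable[str]]) -> None:
        self._map = {k: frozenset(v) for k, v in mapping.items()}
        for product, ingredients in self._map.items():
            if not ingredients:
                raise ValueError(f"product {product!r} maps to no ingredients")

    def __contains__(self, drug: str) -> bool:
        return drug in self._map

    def get(self, drug: str) -> frozenset[str] | None:
        return self._map.get(drug)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "IngredientMap":
        return cls(df.groupby("product")["ingredient"].apply(set).to_dict())


def expand_to_ingredients(
    concept_id: str, ingredient_map: IngredientMap, drug_vocabulary: frozenset[str]
) -> frozenset[str] | None:
    """Rewrite one drug concept to its active ingredients.

    Returns the ingredient set, a singleton if the concept is already an
    in-vocabulary ingredient, or None if the drug is neither mapped nor
    in the target vocabulary (the caller rejects it with a reason).
    """
    mapped = ingredient_map.get(concept_id)
    if mapped is not None:
        return mapped
    if concept_id in drug_vocabulary:
        return frozenset({concept_id})
    return None


def rollup_indication(
    concept_id: str, hierarchy: ConceptHierarchy, target: frozenset[str]
) -> frozenset[str]:
    """Nearest in-target ancestors of an indication concept.

    An in-target concept maps to itself. Otherwise we walk parents
    breadth-first, stopping each branch at its first in-target node;
    the union of those stopping points — the minimal in-target
    ancestors, i.e. those reachable by a path containing no other
    in-target node — is the result. Empty if no ancestor qualifies.
    """
    if concept_id in target:
        return frozenset({concept_id})
    found: set[str] = set()
    seen = {concept_id}
    frontier = deque([concept_id])
    while frontier:
        node = frontier.popleft()
        for parent in hierarchy.parents(node):
            if parent in seen:
                continue
            seen.add(parent)
            if parent in target:
                found.add(parent)  # branch stops here, never expanded
            else:
                frontier.append(parent)
    return frozenset(found)


def normalize_corpus(
    mentions: pd.DataFrame,
    ingredient_map: IngredientMap,
    hierarchy: ConceptHierarchy,
    drug_vocabulary: frozenset[str],
    indication_vocabulary: frozenset[str],
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Normalize a mention table; returns (normalized, rejected, stats).

    Output is deduplicated on (patient, date, concept) after rewriting.
    ``rejected`` lists every input record that could not be mapped, with
    a reason. ``stats`` carries the accounting identity over rewritten
    records: expanded = accepted + rejected, with the number removed by
    deduplication reported separately, so nothing is dropped silently.
    """
    accepted: list[dict] = []
    rejected: list[dict] = []
    for rec in mentions.to_dict("records"):
        if rec["concept_type"] == DRUG:
            ingredients = expand_to_ingredients(
                rec["concept_id"], ingredient_map, drug_vocabulary
            )
            if ingredients is None:
                rejected.append(
                    {**rec, "reason": "drug not mapped and not in target vocabulary"}
                )
                continue
            for ingredient in sorted(ingredients):
                accepted.append({**rec, "concept_id": ingredient})
        elif rec["concept_type"] == INDICATION:
            targets = rollup_indication(
                rec["concept_id"], hierarchy, indication_vocabulary
            )
            if not targets:
                rejected.append(
                    {**rec, "reason": "no in-vocabulary ancestor for indication"}
                )
                continue
            for target in sorted(targets):
                accepted.append({**rec, "concept_id": target})
        else:  # pragma: no cover - schema validation upstream
            rejected.append({**rec, "reason": "unknown concept type"})
    columns = list(mentions.columns)
    out = pd.DataFrame(accepted, columns=columns)
    if not out.empty:
        out = (
            out.sort_values(["patient_id", "concept_id", "date", "note_id"])
            .drop_duplicates(subset=["patient_id", "date", "concept_id"])
            .reset_index(drop=True)
        )
    rej = pd.DataFrame(rejected, columns=columns + ["reason"])
    stats = {
        "expanded": len(accepted) + len(rejected),
        "accepted": len(accepted),
        "rejected": len(rejected),
        "deduplicated": len(accepted) - len(out),
        "normalized": len(out),
    }
    return out, rej, stats


def expanded_record_count(
    mentions: pd.DataFrame,
    ingredient_map: IngredientMap,
    hierarchy: ConceptHierarchy,
    drug_vocabulary: frozenset[str],
    indication_vocabulary: frozenset[str],
) -> int:
    """Number of records after rewriting but before dedup/rejection split."""
    n = 0
    for rec in mentions.to_dict("records"):
        if rec["concept_type"] == DRUG:
            ing = expand_to_ingredients(rec["concept_id"], ingredient_map, drug_vocabulary)
            n += len(ing) if ing else 1
        else:
            roll = rollup_indication(rec["concept_id"], hierarchy, indication_vocabulary)
            n += len(roll) if roll else 1
    return n
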