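"""Shared fixtures: small synthetic worlds reused across test modules."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from offlabel.containers import (
    ConceptHierarchy,
    DrugAttributeTable,
    DrugEconSafetyProfile,
    UsageMatrix,
)
from offlabel.normalize import IngredientMap
from offlabel.simulate import SyntheticWorld, WorldConfig, generate_corpus, generate_world

SMALL_CONFIG = WorldConfig(
    n_drugs=30,
    n_indications=24,
    n_offlabel=6,
    n_drug_classes=6,
    n_products=4,
    n_raw_children=8,
    n_indication_subtypes=2,
)


@pytest.fixture(scope="session")
def small_world():
    return generate_world(SMALL_CONFIG, seed=11)


@pytest.fixture(scope="session")
def small_corpus(small_world):
    return generate_corpus(small_world, 400, seed=12)


def make_hand_world(
    drugs,
    indications,
    usage_pairs,
    prevalence,
    *,
    ae_links=None,
    comorbidity=None,
    config=None,
    offlabel=frozenset(),
    hierarchy_edges=(),
):
    """Construct a SyntheticWorld by hand for targeted corpus experiments."""
    usage = UsageMatrix(drugs, indications, usage_pairs)
    cfg = config or WorldConfig(n_drugs=len(drugs), n_indications=len(indications),
                                n_offlabel=0)
    return SyntheticWorld(
        config=cfg,
        seed=0,
        drugs=tuple(drugs),
        indications=tuple(indications),
        prevalence=dict(prevalence),
        usage_true=usage,
        usage_offlabel=frozenset(offlabel),
        usage_secondary=UsageMatrix(drugs, indications, {}),
        comorbidity_links=dict(comorbidity or {}),
        ae_links=dict(ae_links or {}),
        hierarchy=ConceptHierarchy(hierarchy_edges),
        attributes=DrugAttributeTable({}),
        econ_safety={d: DrugEconSafetyProfile() for d in drugs},
        ingredient_map=IngredientMap({}),
        raw_children={},
    )


def mentions_frame(rows):
    """rows: (patient, note, iso-date, concept, type) tuples -> mention frame."""
    return pd.DataFrame(
        [
            {
                "patient_id": p,
                "note_id": n,
                "date": dt.date.fromisoformat(d),
                "concept_id": c,
                "concept_type": t,
            }
            for p, n, d, c, t in rows
        ],
        columns=["patient_id", "note_id", "date", "concept_id", "concept_type"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
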