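"""Synthetic world generator with planted ground truth.

The real inputs of an off-label detection study — clinical-note mention
streams, a licensed known-usage compendium, a drug knowledge base,
spontaneous-report and literature evidence, a side-effect resource —
are proprietary or large. This module generates a self-consistent
synthetic stand-in for all of them, with planted off-label usages,
comorbidity confounders and adverse-event confounders, so that every
downstream stage can be tested against known ground truth.

Everything is deterministic under (config, seed).

Design notes
------------
* Indication prevalence follows a Zipf-like profile so that the
  frequency-matched negative sampling used to build the gold standard
  operates on a dense frequency ordering.
* Off-label pairs are planted by copying part of the usage profile and
  an attribute of an approved treater of the indication, emulating the
  clinical intuition that drugs are used off-label because they
  resemble a drug already approved for the indication.
* Confounders are explicit: comorbidity links inflate indication
  co-occurrence without any treatment relation (what the conditioned
  co-mention rule must suppress) and adverse-event links make a drug
  precede an indication it causes (what the side-effect filter must
  remove).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    AdverseEvent,
    ConceptHierarchy,
    DrugAttributes,
    DrugAttributeTable,
    DrugEconSafetyProfile,
    EvidenceBundle,
    UsageMatrix,
)
from .normalize import IngredientMap


class ConfigError(ValueError):
    """Infeasible or out-of-range generation parameters."""


EPOCH = dt.date(2010, 1, 1)

SEVERITY_CLASSES = ("mild", "moderate", "severe", "life-threatening")
FREQUENCY_CLASSES = ("rare", "infrequent", "common")


@dataclass(frozen=True)
class WorldConfig:
    """Generation parameters; the defaults are the shipped study conditions."""

    n_drugs: int = 60
    n_indications: int = 50
    n_offlabel: int = 12

    # known-usage relation, organized around drug classes: drugs in a
    # class treat (most of) the class's indication set, so treaters of
    # an indication share usage profiles, as in real compendia
    n_drug_classes: int = 12
    class_overlap: int = 1  # indications each class borrows from another
    class_membership_prob: float = 0.7  # chance a member is labeled per class indication
    extra_usage_prob: float = 0.3  # chance of one off-class usage per drug
    approved_prob: float = 0.7
    n_indication_subtypes: int = 4  # target indications that are children of others
    secondary_keep: float = 0.7  # fraction of primary usages echoed in the 2nd KB
    secondary_extra: int = 8  # spurious pairs unique to the 2nd KB

    # prevalence profile
    zipf_exponent: float = 0.7
    max_prevalence: float = 0.15
    min_prevalence: float = 0.02

    # confounders
    n_comorbidity: int = 5
    comorbidity_odds: float = 6.0
    n_ae_links: int = 5
    ae_incidence: float = 0.35

    # corpus dynamics
    treatment_prob: float = 0.85
    lag_days: tuple[int, int] = (1, 30)
    ae_lag_days: tuple[int, int] = (1, 60)
    observation_days: int = 365
    noise_drug_rate: float = 0.3  # expected spurious drug mentions / patient
    noise_indication_rate: float = 0.5
    product_swap_prob: float = 0.1  # drug mention recorded as a combination product
    child_swap_prob: float = 0.2  # indication recorded as an out-of-vocabulary subtype

    # vocabulary dressing
    n_products: int = 10
    product_ingredients: tuple[int, int] = (2, 3)
    n_raw_children: int = 20
    n_categories: int = 8

    # drug attributes
    n_targets: int = 40
    n_pathways: int = 15
    n_drug_categories: int = 12
    attr_counts: tuple[int, int] = (1, 4)
    shared_attr_prob: float = 0.7  # treaters of an indication share its signature target

    # evidence
    offlabel_report_range: tuple[int, int] = (10, 120)
    known_report_range: tuple[int, int] = (1, 120)
    report_coverage: float = 0.7
    offlabel_article_range: tuple[int, int] = (3, 40)
    known_article_range: tuple[int, int] = (0, 40)
    article_coverage: float = 0.7
    spurious_side_effect_fraction: float = 0.3

    # economics & safety
    ae_free_prob: float = 0.5  # drugs with no adverse-event associations
    mean_extra_aes: float = 2.0
    cost_log_mean: float = 1.0
    cost_log_sigma: float = 1.0

    def validate(self) -> None:
        if min(self.n_drugs, self.n_indications) < 1:
            raise ConfigError("world must have at least one drug and indication")
        if self.n_offlabel < 0:
            raise ConfigError("n_offlabel must be >= 0")
        if self.n_offlabel > self.n_drugs * self.n_indications:
            raise ConfigError("more planted off-label pairs than drug x indication cells")
        for p in (
            self.approved_prob,
            self.treatment_prob,
            self.ae_incidence,
            self.secondary_keep,
            self.report_coverage,
            self.article_coverage,
            self.spurious_side_effect_fraction,
            self.product_swap_prob,
            self.child_swap_prob,
            self.ae_free_prob,
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"probability {p} outside [0, 1]")


@dataclass
class SyntheticWorld:
    """A generated knowledge base plus planted ground truth."""

    config: WorldConfig
    seed: int
    drugs: tuple[str, ...]
    indications: tuple[str, ...]
    prevalence: dict[str, float]
    usage_true: UsageMatrix
    usage_offlabel: frozenset[tuple[str, str]]
    usage_secondary: UsageMatrix
    comorbidity_links: dict[tuple[str, str], float]
    ae_links: dict[tuple[str, str], float]
    hierarchy: ConceptHierarchy
    attributes: DrugAttributeTable
    econ_safety: dict[str, DrugEconSafetyProfile]
    ingredient_map: IngredientMap
    raw_children: dict[str, str] = field(default_factory=dict)  # raw concept -> target

    def known_union(self) -> UsageMatrix:
        """Union of both known-usage knowledge bases."""
        return self.usage_true.union(self.usage_secondary)

    def treated_relation(self) -> frozenset[tuple[str, str]]:
        """Pairs actually used to treat in the corpus (known + planted)."""
        return self.usage_true.pairs | self.usage_offlabel

    def confounder_triples(self) -> list[tuple[str, str, str]]:
        """(drug D, known indication A, comorbid indication B) triples where
        B co-occurs with A through comorbidity only and is never treated by D."""
        treated = self.treated_relation()
        triples = []
        for (a, b), _mult in sorted(self.comorbidity_links.items()):
            for d in sorted(self.usage_true.treaters(a)):
                if (d, b) not in treated and (d, b) not in self.usage_secondary:
                    triples.append((d, a, b))
        return triples


def _zipf_prevalence(cfg: WorldConfig, rng: np.random.Generator) -> np.ndarray:
    ranks = np.arange(1, cfg.n_indications + 1, dtype=float)
    p = cfg.max_prevalence * ranks ** (-cfg.zipf_exponent)
    p = np.maximum(p, cfg.min_prevalence)
    order = rng.permutation(cfg.n_indications)  # detach prevalence from id order
    return p[np.argsort(order)]


def generate_world(config: WorldConfig | None = None, seed: int = 0) -> SyntheticWorld:
    """Generate the knowledge-base half of the synthetic world."""
    cfg = config or WorldConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)

    drugs = tuple(f"drug{i:03d}" for i in range(cfg.n_drugs))
    indications = tuple(f"ind{i:03d}" for i in range(cfg.n_indications))
    prevalence = dict(zip(indications, _zipf_prevalence(cfg, rng)))

    # --- primary known-usage relation, via drug classes -------------------
    n_classes = max(1, min(cfg.n_drug_classes, cfg.n_drugs, cfg.n_indications))
    ind_deal = rng.permutation(cfg.n_indications)
    class_inds: list[list[str]] = [[] for _ in range(n_classes)]
    for k, ix in enumerate(ind_deal):
        class_inds[k % n_classes].append(indications[ix])
    for c in range(n_classes):  # borrowed indications create cross-class overlap
        other = (c + 1 + int(rng.integers(max(n_classes - 1, 1)))) % n_classes
        if other != c and class_inds[other]:
            donors = class_inds[other]
            for ind in rng.choice(donors, size=min(cfg.class_overlap, len(donors)),
                                  replace=False):
                if ind not in class_inds[c]:
                    class_inds[c].append(str(ind))
    drug_deal = rng.permutation(cfg.n_drugs)
    class_of: dict[str, int] = {}
    for k, dx in enumerate(drug_deal):
        class_of[drugs[dx]] = k % n_classes

    pairs: dict[tuple[str, str], bool] = {}
    for d in drugs:
        members = class_inds[class_of[d]]
        labeled = [i for i in members if rng.random() < cfg.class_membership_prob]
        if not labeled and members:
            labeled = [members[int(rng.integers(len(members)))]]
        for i in labeled:
            pairs[(d, i)] = bool(rng.random() < cfg.approved_prob)
        if rng.random() < cfg.extra_usage_prob:
            i = indications[int(rng.integers(cfg.n_indications))]
            if (d, i) not in pairs:
                pairs[(d, i)] = bool(rng.random() < cfg.approved_prob)
    # every indication gets at least one treater, and at least one approved one
    for ind in indications:
        treaters = [d for (d, i) in pairs if i == ind]
        if not treaters:
            members = [d for d in drugs
                       if ind in class_inds[class_of[d]]] or list(drugs)
            d = members[int(rng.integers(len(members)))]
            pairs[(d, ind)] = True
        elif not any(pairs[(d, ind)] for d in treaters):
            pairs[(treaters[int(rng.integers(len(treaters)))], ind)] = True

    # --- hierarchy: categories above, raw subtypes below ------------------
    edges: list[tuple[str, str]] = []
    categories = [f"cat{i:02d}" for i in range(cfg.n_categories)]
    for ind in indications:
        edges.append((ind, categories[int(rng.integers(cfg.n_categories))]))
    subtype_of: dict[str, str] = {}
    if cfg.n_indication_subtypes and cfg.n_indications >= 2:
        picks = rng.choice(cfg.n_indications, size=min(cfg.n_indication_subtypes,
                                                       cfg.n_indications // 2) * 2,
                           replace=False)
        for child_ix, parent_ix in zip(picks[::2], picks[1::2]):
            child, parent = indications[child_ix], indications[parent_ix]
            edges.append((child, parent))
            subtype_of[child] = parent
    raw_children: dict[str, str] = {}
    for r in range(cfg.n_raw_children):
        raw = f"raw{r:03d}"
        target = indications[int(rng.integers(cfg.n_indications))]
        raw_children[raw] = target
        edges.append((raw, target))
    hierarchy = ConceptHierarchy(edges)

    # --- drug attributes with per-indication signatures -------------------
    target_pool = [f"T{i:03d}" for i in range(cfg.n_targets)]
    pathway_pool = [f"P{i:03d}" for i in range(cfg.n_pathways)]
    category_pool = [f"C{i:03d}" for i in range(cfg.n_drug_categories)]
    signature_target = {
        ind: target_pool[int(rng.integers(cfg.n_targets))] for ind in indications
    }
    signature_category = {
        ind: category_pool[int(rng.integers(cfg.n_drug_categories))]
        for ind in indications
    }
    attrs: dict[str, dict[str, set[str]]] = {
        d: {"targets": set(), "pathways": set(), "categories": set()} for d in drugs
    }
    alo, ahi = cfg.attr_counts
    for d in drugs:
        attrs[d]["targets"].update(
            rng.choice(target_pool, size=int(rng.integers(alo, ahi + 1)), replace=False)
        )
        attrs[d]["pathways"].update(
            rng.choice(pathway_pool, size=int(rng.integers(1, 4)), replace=False)
        )
        attrs[d]["categories"].update(
            rng.choice(category_pool, size=int(rng.integers(1, 3)), replace=False)
        )
    for (d, ind) in sorted(pairs):
        if rng.random() < cfg.shared_attr_prob:
            attrs[d]["targets"].add(signature_target[ind])
            attrs[d]["categories"].add(signature_category[ind])

    # --- plant off-label pairs -------------------------------------------
    # Preferred mechanism: class-consistent holes. A drug whose class
    # treats an indication but that is itself not labeled for it is the
    # archetypal off-label candidate: it already shares usage profile
    # and attributes with the indication's approved treaters.
    usage = UsageMatrix(drugs, indications, pairs)
    hier_related = _near_miss_closure(usage, hierarchy)
    ind_by_prev = sorted(indications, key=lambda i: (-prevalence[i], i))
    offlabel: set[tuple[str, str]] = set()
    holes: list[tuple[str, str]] = []
    for d in drugs:
        for i in class_inds[class_of[d]]:
            if (d, i) in pairs or (d, i) in hier_related:
                continue
            approved = [
                t for t in usage.treaters(i) if usage.is_approved(t, i) and t != d
            ]
            if any(usage.indications_of(d) & usage.indications_of(t)
                   for t in approved):
                holes.append((d, i))
    # prefer prevalent indications so the planted signal is observable
    holes.sort(key=lambda p: (-prevalence[p[1]], p))
    pool = holes[: max(cfg.n_offlabel * 2, 10)]
    if pool:
        take = min(cfg.n_offlabel, len(pool))
        picks = rng.choice(len(pool), size=take, replace=False)
        offlabel.update(pool[k] for k in picks)
    # fallback: cross-class planting by explicit profile copying
    attempts = 0
    candidates_ind = [i for i in ind_by_prev if any(
        usage.is_approved(d, i) for d in usage.treaters(i))]
    while len(offlabel) < cfg.n_offlabel:
        attempts += 1
        if attempts > 10_000:
            raise ConfigError("could not plant the requested off-label pairs")
        ind = candidates_ind[int(rng.integers(min(len(candidates_ind),
                                                  max(cfg.n_offlabel * 2, 10))))]
        approved = sorted(d for d in usage.treaters(ind) if usage.is_approved(d, ind))
        treater = approved[int(rng.integers(len(approved)))]
        d = drugs[int(rng.integers(cfg.n_drugs))]
        if d == treater or (d, ind) in pairs or (d, ind) in offlabel:
            continue
        if (d, ind) in hier_related:
            continue  # would be removed as a near miss; not a useful plant
        shared = usage.indications_of(d) & usage.indications_of(treater)
        if not shared:
            planted_for_d = {i2 for (d2, i2) in offlabel if d2 == d} | {ind}
            donor_inds = sorted(
                j
                for j in usage.indications_of(treater) - {ind}
                if not planted_for_d
                & (
                    hierarchy.descendants(j)
                    | hierarchy.children(j)
                    | hierarchy.parents(j)
                    | {j}
                )
            )
            if not donor_inds:
                continue
            j = donor_inds[int(rng.integers(len(donor_inds)))]
            pairs[(d, j)] = bool(rng.random() < cfg.approved_prob)
            usage = UsageMatrix(drugs, indications, pairs)
            hier_related = _near_miss_closure(usage, hierarchy)
            if (d, ind) in hier_related:
                continue
        offlabel.add((d, ind))
        donor_targets = sorted(attrs[treater]["targets"])
        if donor_targets:
            attrs[d]["targets"].add(
                donor_targets[int(rng.integers(len(donor_targets)))])

    # planted drugs share the indication's attribute signature, like the
    # approved treaters they resemble
    for d, i in sorted(offlabel):
        attrs[d]["targets"].add(signature_target[i])
        attrs[d]["categories"].add(signature_category[i])

    usage = UsageMatrix(drugs, indications, pairs)
    offlabel -= usage.pairs  # profile copying must never legitimize a plant
    attributes = DrugAttributeTable(
        {
            d: DrugAttributes(
                frozenset(a["targets"]),
                frozenset(a["pathways"]),
                frozenset(a["categories"]),
            )
            for d, a in attrs.items()
        }
    )

    # --- secondary (attribute-source) usage KB ----------------------------
    secondary: dict[tuple[str, str], bool] = {
        p: a for p, a in pairs.items() if rng.random() < cfg.secondary_keep
    }
    extra = 0
    while extra < cfg.secondary_extra:
        d = drugs[int(rng.integers(cfg.n_drugs))]
        i = indications[int(rng.integers(cfg.n_indications))]
        if (d, i) in pairs or (d, i) in offlabel or (d, i) in secondary:
            continue
        secondary[(d, i)] = False
        extra += 1
    usage_secondary = UsageMatrix(drugs, indications, secondary)

    # --- confounders ------------------------------------------------------
    comorbidity: dict[tuple[str, str], float] = {}
    treated = usage.pairs | offlabel
    # first link is a guaranteed pure confounder: B comorbid with a treated
    # indication A of some drug D, with (D, B) never a treatment relation
    for a in ind_by_prev:
        ds = sorted(usage.treaters(a))
        if not ds:
            continue
        bs = [
            b
            for b in ind_by_prev
            if b != a
            and all((d, b) not in treated and (d, b) not in usage_secondary
                    for d in ds)
        ]
        if bs:
            comorbidity[(a, bs[0])] = cfg.comorbidity_odds
            break
    while len(comorbidity) < cfg.n_comorbidity:
        a = indications[int(rng.integers(cfg.n_indications))]
        b = indications[int(rng.integers(cfg.n_indications))]
        if a == b or (a, b) in comorbidity or (b, a) in comorbidity:
            continue
        comorbidity[(a, b)] = cfg.comorbidity_odds

    ae_links: dict[tuple[str, str], float] = {}
    while len(ae_links) < cfg.n_ae_links:
        d = drugs[int(rng.integers(cfg.n_drugs))]
        e = ind_by_prev[int(rng.integers(min(cfg.n_indications, 20)))]
        if (d, e) in treated or (d, e) in ae_links or (d, e) in usage_secondary:
            continue
        ae_links[(d, e)] = cfg.ae_incidence

    # --- economics and safety profiles ------------------------------------
    econ: dict[str, DrugEconSafetyProfile] = {}
    for d in drugs:
        events: list[AdverseEvent] = []
        if rng.random() >= cfg.ae_free_prob:
            n_ev = 1 + int(rng.poisson(cfg.mean_extra_aes))
            for k in range(n_ev):
                events.append(
                    AdverseEvent(
                        event_id=f"ae{int(rng.integers(100)):03d}",
                        severity=SEVERITY_CLASSES[int(rng.integers(len(SEVERITY_CLASSES)))],
                        frequency=FREQUENCY_CLASSES[int(rng.integers(len(FREQUENCY_CLASSES)))],
                    )
                )
        n_costs = int(rng.integers(1, 4))
        costs = np.round(
            rng.lognormal(cfg.cost_log_mean, cfg.cost_log_sigma, size=n_costs), 2
        )
        econ[d] = DrugEconSafetyProfile(events, [float(c) for c in costs])

    # --- combination products ---------------------------------------------
    plo, phi = cfg.product_ingredients
    products = {}
    for p in range(cfg.n_products):
        size = int(rng.integers(plo, phi + 1))
        members = rng.choice(cfg.n_drugs, size=size, replace=False)
        products[f"prod{p:03d}"] = {drugs[m] for m in members}
    ingredient_map = IngredientMap(products)

    return SyntheticWorld(
        config=cfg,
        seed=seed,
        drugs=drugs,
        indications=indications,
        prevalence=prevalence,
        usage_true=usage,
        usage_offlabel=frozenset(offlabel),
        usage_secondary=usage_secondary,
        comorbidity_links=comorbidity,
        ae_links=ae_links,
        hierarchy=hierarchy,
        attributes=attributes,
        econ_safety=econ,
        ingredient_map=ingredient_map,
        raw_children=raw_children,
    )


def _near_miss_closure(usage: UsageMatrix, hierarchy: ConceptHierarchy):
    """Pairs (d, i) hierarchically adjacent to a known usage of d."""
    related: set[tuple[str, str]] = set()
    for d in usage.drugs:
        for j in usage.indications_of(d):
            for i in hierarchy.descendants(j):
                related.add((d, i))
            for i in hierarchy.children(j):
                related.add((d, i))  # direct parent rule, seen from the child
            for i in hierarchy.parents(j):
                related.add((d, i))
    return related


def generate_corpus(
    world: SyntheticWorld, n_patients: int, seed: int = 0
) -> pd.DataFrame:
    """Generate the raw (pre-normalization) patient mention stream.

    Per patient: indications are drawn from prevalence with comorbidity
    odds multipliers; each drug treating a present indication (known or
    planted usage) is prescribed with the configured treatment
    probability and dated after the earliest treated indication; drug
    adverse events add indication mentions after the drug date; noise
    mentions are sprinkled at the configured rates. A fraction of drug
    mentions is recorded as a combination product and a fraction of
    indication mentions as an out-of-vocabulary subtype, exercising the
    normalization stage.
    """
    if n_patients <= 0:
        raise ConfigError("n_patients must be positive")
    cfg = world.config
    rng = np.random.default_rng(seed)
    treated = sorted(world.treated_relation())
    treaters_of: dict[str, list[str]] = {}
    for d, i in treated:
        treaters_of.setdefault(i, []).append(d)
    product_of: dict[str, list[str]] = {}
    for prod in sorted(world.ingredient_map._map):
        for d in world.ingredient_map.get(prod):
            product_of.setdefault(d, []).append(prod)
    children_of: dict[str, list[str]] = {}
    for raw, target in sorted(world.raw_children.items()):
        children_of.setdefault(target, []).append(raw)
    horizon = cfg.observation_days

    rows: list[tuple[str, str, dt.date, str, str]] = []

    def emit(pid: str, day: int, concept: str, ctype: str) -> None:
        day = int(min(max(day, 0), horizon))
        rows.append(
            (pid, f"note-{pid}-{len(rows)}", EPOCH + dt.timedelta(days=day), concept, ctype)
        )

    for p in range(n_patients):
        pid = f"pt{p:06d}"
        # indications: base prevalence, then comorbidity multipliers
        present: dict[str, int] = {}
        for ind in world.indications:
            if rng.random() < world.prevalence[ind]:
                present[ind] = int(rng.integers(0, max(horizon - cfg.lag_days[1], 1)))
        for (a, b), mult in sorted(world.comorbidity_links.items()):
            if a in present and b not in present:
                p_b = world.prevalence[b]
                odds = mult * p_b / (1.0 - p_b)
                if rng.random() < odds / (1.0 + odds):
                    present[b] = int(
                        rng.integers(0, max(horizon - cfg.lag_days[1], 1))
                    )
        # drugs given indications
        drug_dates: dict[str, int] = {}
        for ind, day in sorted(present.items()):
            for d in treaters_of.get(ind, ()):
                if rng.random() < cfg.treatment_prob:
                    lag = int(rng.integers(cfg.lag_days[0], cfg.lag_days[1] + 1))
                    start = day + lag
                    if d not in drug_dates or start < drug_dates[d]:
                        drug_dates[d] = start
        # adverse events after drug exposure
        for (d, e), incidence in sorted(world.ae_links.items()):
            if d in drug_dates and e not in present and rng.random() < incidence:
                lag = int(rng.integers(cfg.ae_lag_days[0], cfg.ae_lag_days[1] + 1))
                present[e] = drug_dates[d] + lag
        # noise
        for _ in range(int(rng.poisson(cfg.noise_drug_rate))):
            d = world.drugs[int(rng.integers(len(world.drugs)))]
            if d not in drug_dates:
                drug_dates[d] = int(rng.integers(0, horizon))
        for _ in range(int(rng.poisson(cfg.noise_indication_rate))):
            ind = world.indications[int(rng.integers(len(world.indications)))]
            if ind not in present:
                present[ind] = int(rng.integers(0, horizon))
        # emit, with product/subtype recording noise
        for ind, day in sorted(present.items()):
            concept = ind
            kids = children_of.get(ind)
            if kids and rng.random() < cfg.child_swap_prob:
                concept = kids[int(rng.integers(len(kids)))]
            emit(pid, day, concept, "indication")
        for d, day in sorted(drug_dates.items()):
            concept = d
            prods = product_of.get(d)
            if prods and rng.random() < cfg.product_swap_prob:
                concept = prods[int(rng.integers(len(prods)))]
            emit(pid, day, concept, "drug")

    df = pd.DataFrame(
        rows, columns=["patient_id", "note_id", "date", "concept_id", "concept_type"]
    )
    return df.drop_duplicates(subset=["patient_id", "date", "concept_id"]).reset_index(
        drop=True
    )


def generate_evidence(world: SyntheticWorld, seed: int = 0) -> EvidenceBundle:
    """Generate spontaneous-report, literature, and side-effect evidence.

    Report and article counts are drawn per treated pair (planted
    off-label pairs always get evidence; known usages with the
    configured coverage). Side effects are the true adverse-event links
    plus a configurable spurious fraction, emulating an uncurated
    side-effect resource.
    """
    cfg = world.config
    rng = np.random.default_rng(seed)
    reports: set[tuple[str, str, str]] = set()
    articles: set[tuple[str, str, str]] = set()
    r_seq = a_seq = 0
    for d, i in sorted(world.treated_relation()):
        planted = (d, i) in world.usage_offlabel
        if planted:
            n_rep = int(rng.integers(cfg.offlabel_report_range[0],
                                     cfg.offlabel_report_range[1] + 1))
            n_art = int(rng.integers(cfg.offlabel_article_range[0],
                                     cfg.offlabel_article_range[1] + 1))
        else:
            n_rep = (
                int(rng.integers(cfg.known_report_range[0],
                                 cfg.known_report_range[1] + 1))
                if rng.random() < cfg.report_coverage
                else 0
            )
            n_art = (
                int(rng.integers(cfg.known_article_range[0],
                                 cfg.known_article_range[1] + 1))
                if rng.random() < cfg.article_coverage
                else 0
            )
        for _ in range(n_rep):
            reports.add((f"R{r_seq:07d}", d, i))
            r_seq += 1
        for _ in range(n_art):
            articles.add((f"A{a_seq:07d}", d, i))
            a_seq += 1

    true_se = set(world.ae_links)
    frac = cfg.spurious_side_effect_fraction
    n_spurious = int(round(len(true_se) * frac / (1.0 - frac))) if frac < 1 else 0
    spurious: set[tuple[str, str]] = set()
    guard = 0
    while len(spurious) < n_spurious and guard < 10_000:
        guard += 1
        d = world.drugs[int(rng.integers(len(world.drugs)))]
        e = world.indications[int(rng.integers(len(world.indications)))]
        if (d, e) in true_se or (d, e) in spurious or (d, e) in world.usage_offlabel:
            continue
        spurious.add((d, e))
    return EvidenceBundle(
        report_links=frozenset(reports),
        literature_links=frozenset(articles),
        side_effects=frozenset(true_se | spurious),
    )


def config_from_dict(d: dict) -> WorldConfig:
    """Build a WorldConfig from a plain dict (e.g., parsed YAML)."""
    fields = {f.name for f in dataclasses.fields(WorldConfig)}
    unknown = set(d) - fields
    if unknown:
        raise ConfigError(f"unknown world config keys: {sorted(unknown)}")
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in d.items()
    }
    return WorldConfig(**coerced)
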