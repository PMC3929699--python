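"""The 25-dimensional feature vector for a drug-indication pair.

Nine empirical features summarize the pattern of patient-level mentions
of the drug and indication in the corpus; sixteen knowledge features
summarize the pair's standing in two knowledge bases (a known-usage
compendium and a drug attribute database).

The key empirical subtlety is the *conditioned co-mention rule*: a drug
and indication count as co-occurring for a patient only if the pair is
itself a known usage, or no other known indication of the drug appears
in that patient's record. This stops a drug from being associated with
a disease merely because the disease is a common comorbidity of the
drug's actual indication.
"""

from __future__ import annotations

import datetime as dt
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    ATTRIBUTE_KINDS,
    DRUG,
    INDICATION,
    DrugAttributeTable,
    UsageMatrix,
)

logger = logging.getLogger(__name__)

EMPIRICAL_FEATURES = (
    "n_drug",
    "n_ind",
    "n_co",
    "chi2",
    "odds_ratio",
    "p_drug_given_ind",
    "dff",
    "dff_adj_drug",
    "dff_adj_ind",
)
USAGE_KB_FEATURES = (
    "k_n_treaters",
    "k_frac_approved",
    "k_dd_cos",
    "k_dd_jac",
    "k_ii_cos",
    "k_ii_jac",
)
ATTRIBUTE_KB_FEATURES = (
    "k2_dd_cos",
    "k2_dd_jac",
    "k2_ii_cos",
    "k2_ii_jac",
    "k_target_cos",
    "k_target_jac",
    "k_pathway_cos",
    "k_pathway_jac",
    "k_category_cos",
    "k_category_jac",
)
FEATURE_NAMES = EMPIRICAL_FEATURES + USAGE_KB_FEATURES + ATTRIBUTE_KB_FEATURES
NAIVE_FEATURES = (
    "naive_n_co",
    "naive_chi2",
    "naive_odds_ratio",
    "naive_p_drug_given_ind",
    "naive_dff",
    "naive_dff_adj_drug",
    "naive_dff_adj_ind",
)
# heavy-tailed count-like features, log1p-transformed before scaling
COUNT_FEATURES = (
    "n_drug",
    "n_ind",
    "n_co",
    "chi2",
    "odds_ratio",
    "k_n_treaters",
    "naive_n_co",
    "naive_chi2",
    "naive_odds_ratio",
)


@dataclass(frozen=True)
class PatientProfile:
    """Per-patient first mention dates in the normalized vocabularies."""

    patient_id: str
    drug_first_dates: dict[str, dt.date] = field(default_factory=dict)
    indication_first_dates: dict[str, dt.date] = field(default_factory=dict)


@dataclass(frozen=True)
class KnowledgeBases:
    """The knowledge inputs to featurization.

    ``usage``: the primary known-usage compendium (with approval flags).
    ``usage_secondary``: the attribute database's own usage relation.
    ``attributes``: per-drug targets, pathways, categories.
    """

    usage: UsageMatrix
    usage_secondary: UsageMatrix
    attributes: DrugAttributeTable

    def known_union(self) -> UsageMatrix:
        return self.usage.union(self.usage_secondary)


def build_profiles(corpus: pd.DataFrame) -> list[PatientProfile]:
    """One profile per patient; dates are minima over the patient's records."""
    if corpus.empty:
        return []
    grouped = corpus.groupby(["patient_id", "concept_type", "concept_id"])[
        "date"
    ].min()
    acc: dict[str, dict[str, dict]] = {}
    for (pid, ctype, concept), first in grouped.items():
        slot = acc.setdefault(pid, {DRUG: {}, INDICATION: {}})
        slot[ctype][concept] = first
    return [
        PatientProfile(pid, dict(slots[DRUG]), dict(slots[INDICATION]))
        for pid, slots in sorted(acc.items())
    ]


def co_occurs(
    pair: tuple[str, str], profile: PatientProfile, known: UsageMatrix
) -> bool:
    """Conditioned co-mention predicate for one patient.

    True iff both concepts are present and either the pair is a known
    usage, or no *other* known indication of the drug is present.
    """
    d, i = pair
    if d not in profile.drug_first_dates or i not in profile.indication_first_dates:
        return False
    if (d, i) in known:
        return True
    known_inds = known.indications_of(d)
    return not any(
        i2 in profile.indication_first_dates for i2 in known_inds if i2 != i
    )


def contingency(
    pair: tuple[str, str],
    profiles: list[PatientProfile],
    known: UsageMatrix,
    conditioned: bool = True,
) -> tuple[int, int, int, int]:
    """2x2 patient counts (a, b, c, d) for a drug-indication pair.

    a is the (conditioned) co-mention count; b = n_drug - a;
    c = n_ind - a; d = N - a - b - c, clipped at zero if conditioning
    pushes it negative (logged; the margins stay interpretable).
    """
    d_id, i_id = pair
    n = len(profiles)
    n_drug = sum(1 for p in profiles if d_id in p.drug_first_dates)
    n_ind = sum(1 for p in profiles if i_id in p.indication_first_dates)
    if conditioned:
        a = sum(1 for p in profiles if co_occurs(pair, p, known))
    else:
        a = sum(
            1
            for p in profiles
            if d_id in p.drug_first_dates and i_id in p.indication_first_dates
        )
    b = n_drug - a
    c = n_ind - a
    d = n - a - b - c
    if d < 0:
        logger.warning("contingency cell d < 0 for %s; clipped to 0", pair)
        d = 0
    assert min(a, b, c) >= 0, "negative contingency cell"
    return a, b, c, d


def chi_squared(table: tuple[int, int, int, int]) -> float:
    """Pearson chi-squared for a 2x2 table, no continuity correction.

    Defined as 0 when any margin is zero (the statistic is then
    degenerate) and exactly 0 at independence.
    """
    a, b, c, d = (float(x) for x in table)
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0 or n == 0:
        return 0.0
    return n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)


def odds_ratio(table: tuple[int, int, int, int]) -> float:
    """(a*d)/(b*c), with Haldane-Anscombe +0.5 on all cells if any is zero."""
    a, b, c, d = (float(x) for x in table)
    if min(a, b, c, d) == 0.0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def p_drug_given_ind(table: tuple[int, int, int, int]) -> float:
    a, _, c, _ = table
    n_ind = a + c
    return a / n_ind if n_ind else 0.0


def drug_first_fraction(
    pair: tuple[str, str],
    profiles: list[PatientProfile],
    known: UsageMatrix,
    conditioned: bool = True,
) -> float:
    """Fraction of co-occurring patients whose drug mention comes first.

    Strictly earlier counts 1, equal dates count 0.5; with no
    co-occurring patients the fraction defaults to the uninformative 0.5.
    """
    d_id, i_id = pair
    scores = []
    for p in profiles:
        if conditioned:
            if not co_occurs(pair, p, known):
                continue
        elif d_id not in p.drug_first_dates or i_id not in p.indication_first_dates:
            continue
        dd = p.drug_first_dates[d_id]
        di = p.indication_first_dates[i_id]
        scores.append(1.0 if dd < di else 0.5 if dd == di else 0.0)
    return float(np.mean(scores)) if scores else 0.5


# -- set similarities ------------------------------------------------------

def binary_cosine(a: frozenset | set, b: frozenset | set) -> float:
    if not a or not b:
        return 0.0
    return len(a & b) / math.sqrt(len(a) * len(b))


def jaccard(a: frozenset | set, b: frozenset | set) -> float:
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def usage_similarity(
    drug: str,
    indication: str,
    usage: UsageMatrix,
    exclude: frozenset[tuple[str, str]] = frozenset(),
) -> tuple[float, float]:
    """Max usage-profile similarity of ``drug`` vs the indication's treaters.

    Profiles are binary indication vectors with the query indication's
    column removed from every profile, so a shared check on the query
    itself cannot create a trivial self-signal. ``exclude`` (e.g. the
    held-out test usages) is removed from the matrix before profiles or
    treater sets are formed.
    """
    u = usage.without(exclude) if exclude else usage
    treaters = sorted(u.treaters(indication) - {drug})
    if not treaters:
        return 0.0, 0.0
    profile_d = u.indications_of(drug) - {indication}
    best_cos = best_jac = 0.0
    for t in treaters:
        profile_t = u.indications_of(t) - {indication}
        best_cos = max(best_cos, binary_cosine(profile_d, profile_t))
        best_jac = max(best_jac, jaccard(profile_d, profile_t))
    return best_cos, best_jac


def indication_similarity(
    drug: str,
    indication: str,
    usage: UsageMatrix,
    exclude: frozenset[tuple[str, str]] = frozenset(),
) -> tuple[float, float]:
    """Transposed construction: the indication's drug-profile vs profiles
    of the other indications the drug is known to treat, with the query
    drug's row removed from every profile."""
    u = usage.without(exclude) if exclude else usage
    others = sorted(u.indications_of(drug) - {indication})
    if not others:
        return 0.0, 0.0
    profile_i = u.treaters(indication) - {drug}
    best_cos = best_jac = 0.0
    for j in others:
        profile_j = u.treaters(j) - {drug}
        best_cos = max(best_cos, binary_cosine(profile_i, profile_j))
        best_jac = max(best_jac, jaccard(profile_i, profile_j))
    return best_cos, best_jac


def attribute_similarity(
    drug: str,
    indication: str,
    attributes: DrugAttributeTable,
    usage: UsageMatrix,
    exclude: frozenset[tuple[str, str]] = frozenset(),
) -> dict[str, float]:
    """Max attribute-set similarity of ``drug`` vs the indication's treaters.

    One cosine and one Jaccard per attribute kind (targets, pathways,
    categories); a drug or treater with an empty or absent attribute
    set contributes 0.
    """
    u = usage.without(exclude) if exclude else usage
    treaters = sorted(u.treaters(indication) - {drug})
    mine = attributes.get(drug)
    out: dict[str, float] = {}
    for kind in ATTRIBUTE_KINDS:
        key = kind.rstrip("s") if kind != "categories" else "category"
        my_set = getattr(mine, kind) if mine is not None else frozenset()
        best_cos = best_jac = 0.0
        for t in treaters:
            theirs = attributes.get(t)
            if theirs is None:
                continue
            their_set = getattr(theirs, kind)
            best_cos = max(best_cos, binary_cosine(my_set, their_set))
            best_jac = max(best_jac, jaccard(my_set, their_set))
        out[f"k_{key}_cos"] = best_cos
        out[f"k_{key}_jac"] = best_jac
    return out


# -- vectorized corpus statistics ------------------------------------------

class CorpusStats:
    """Dense patient x concept presence/date matrices over a vocabulary.

    Precomputes the conditioned and naive co-mention count matrices and
    the drug-first-fraction matrices that featurization needs; built
    once per corpus and reused across pairs.
    """

    def __init__(
        self,
        corpus: pd.DataFrame,
        drugs: tuple[str, ...],
        indications: tuple[str, ...],
        known: UsageMatrix,
    ) -> None:
        self.drugs = tuple(drugs)
        self.indications = tuple(indications)
        self.d_index = {d: k for k, d in enumerate(self.drugs)}
        self.i_index = {i: k for k, i in enumerate(self.indications)}
        # every patient in the corpus counts toward N, even if none of
        # their mentions fall in the modeled vocabularies
        profiles = build_profiles(corpus)
        self.n_patients = len(profiles)
        P, D, I = self.n_patients, len(drugs), len(indications)
        present_d = np.zeros((P, D), dtype=bool)
        present_i = np.zeros((P, I), dtype=bool)
        day_d = np.full((P, D), np.nan)
        day_i = np.full((P, I), np.nan)
        for p, prof in enumerate(profiles):
            for d_id, date in prof.drug_first_dates.items():
                k = self.d_index.get(d_id)
                if k is not None:
                    present_d[p, k] = True
                    day_d[p, k] = date.toordinal()
            for i_id, date in prof.indication_first_dates.items():
                k = self.i_index.get(i_id)
                if k is not None:
                    present_i[p, k] = True
                    day_i[p, k] = date.toordinal()
        self.present_d, self.present_i = present_d, present_i
        self.n_drug = present_d.sum(axis=0).astype(int)
        self.n_ind = present_i.sum(axis=0).astype(int)

        K = np.zeros((D, I), dtype=bool)
        for d_id, i_id in known.pairs:
            kd, ki = self.d_index.get(d_id), self.i_index.get(i_id)
            if kd is not None and ki is not None:
                K[kd, ki] = True
        self.known_mask = K
        has_known = present_i @ K.T.astype(int) > 0  # (P, D)
        pdi = present_d.astype(int)
        pii = present_i.astype(int)
        self.co_naive = pdi.T @ pii
        allowed = (present_d & ~has_known).astype(int)
        co_cond_base = allowed.T @ pii
        self.co_cond = np.where(K, self.co_naive, co_cond_base)

        # drug-first fraction matrices (conditioned and naive)
        self.dff_cond = np.full((D, I), 0.5)
        self.dff_naive = np.full((D, I), 0.5)
        for kd in range(D):
            both = present_d[:, kd][:, None] & present_i  # (P, I)
            if not both.any():
                continue
            score = np.where(
                day_d[:, kd][:, None] < day_i,
                1.0,
                np.where(day_d[:, kd][:, None] == day_i, 0.5, 0.0),
            )
            mask_cond = both & (K[kd][None, :] | ~has_known[:, kd][:, None])
            for mask, out in ((mask_cond, self.dff_cond), (both, self.dff_naive)):
                counts = mask.sum(axis=0)
                with np.errstate(invalid="ignore"):
                    frac = np.where(
                        counts > 0,
                        (score * mask).sum(axis=0) / np.maximum(counts, 1),
                        0.5,
                    )
                out[kd] = frac

        self.dff_cond_adj_drug, self.dff_cond_adj_ind = _adjust_dff(
            self.dff_cond, self.co_cond
        )
        self.dff_naive_adj_drug, self.dff_naive_adj_ind = _adjust_dff(
            self.dff_naive, self.co_naive
        )

    def table(self, kd: int, ki: int, conditioned: bool = True):
        a = int((self.co_cond if conditioned else self.co_naive)[kd, ki])
        b = int(self.n_drug[kd]) - a
        c = int(self.n_ind[ki]) - a
        d = self.n_patients - a - b - c
        if d < 0:
            logger.warning(
                "contingency cell d < 0 for (%s, %s); clipped",
                self.drugs[kd],
                self.indications[ki],
            )
            d = 0
        return a, b, c, d


def _adjust_dff(dff: np.ndarray, co: np.ndarray):
    """Per-drug and per-indication mean-baseline adjustments of the
    drug-first fraction, over cells with at least one co-mention."""
    observed = co > 0
    with np.errstate(invalid="ignore"):
        drug_mean = np.where(
            observed.any(axis=1),
            np.nansum(np.where(observed, dff, np.nan), axis=1)
            / np.maximum(observed.sum(axis=1), 1),
            0.5,
        )
        ind_mean = np.where(
            observed.any(axis=0),
            np.nansum(np.where(observed, dff, np.nan), axis=0)
            / np.maximum(observed.sum(axis=0), 1),
            0.5,
        )
    return dff - drug_mean[:, None], dff - ind_mean[None, :]


def featurize(
    pairs,
    corpus: pd.DataFrame,
    kbs: KnowledgeBases,
    exclude: frozenset[tuple[str, str]] = frozenset(),
    include_naive: bool = True,
    stats: CorpusStats | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Feature vectors for a collection of (drug, indication) pairs.

    Returns ``(features, rejected)``; ``features`` has drug, indication
    and the 25 named feature columns (plus the naive unconditioned
    empirical variants used only for ablation, prefixed ``naive_``).
    Pairs referencing concepts outside the knowledge-base vocabularies
    are rejected with a reason. ``exclude`` lists known usages to be
    ignored when computing knowledge features (leakage control for
    held-out test pairs); the conditioning of co-mention counts always
    uses the full known-usage union.
    """
    usage = kbs.usage
    known = kbs.known_union()
    if stats is None:
        stats = CorpusStats(corpus, usage.drugs, usage.indications, known)
    u1 = usage.without(exclude) if exclude else usage
    u2 = kbs.usage_secondary.without(exclude) if exclude else kbs.usage_secondary

    rows: list[dict] = []
    rejected: list[dict] = []
    for d_id, i_id in pairs:
        kd = stats.d_index.get(d_id)
        ki = stats.i_index.get(i_id)
        if kd is None or ki is None:
            rejected.append(
                {
                    "drug": d_id,
                    "indication": i_id,
                    "reason": "concept outside the knowledge-base vocabulary",
                }
            )
            continue
        row: dict = {"drug": d_id, "indication": i_id}
        tab = stats.table(kd, ki, conditioned=True)
        row["n_drug"] = tab[0] + tab[1]
        row["n_ind"] = tab[0] + tab[2]
        row["n_co"] = tab[0]
        row["chi2"] = chi_squared(tab)
        row["odds_ratio"] = odds_ratio(tab)
        row["p_drug_given_ind"] = p_drug_given_ind(tab)
        row["dff"] = float(stats.dff_cond[kd, ki])
        row["dff_adj_drug"] = float(stats.dff_cond_adj_drug[kd, ki])
        row["dff_adj_ind"] = float(stats.dff_cond_adj_ind[kd, ki])

        treaters = u1.treaters(i_id)
        row["k_n_treaters"] = len(treaters)
        row["k_frac_approved"] = (
            sum(u1.is_approved(t, i_id) for t in treaters) / len(treaters)
            if treaters
            else 0.0
        )
        row["k_dd_cos"], row["k_dd_jac"] = usage_similarity(d_id, i_id, u1)
        row["k_ii_cos"], row["k_ii_jac"] = indication_similarity(d_id, i_id, u1)
        row["k2_dd_cos"], row["k2_dd_jac"] = usage_similarity(d_id, i_id, u2)
        row["k2_ii_cos"], row["k2_ii_jac"] = indication_similarity(d_id, i_id, u2)
        row.update(attribute_similarity(d_id, i_id, kbs.attributes, u2))

        if include_naive:
            ntab = stats.table(kd, ki, conditioned=False)
            row["naive_n_co"] = ntab[0]
            row["naive_chi2"] = chi_squared(ntab)
            row["naive_odds_ratio"] = odds_ratio(ntab)
            row["naive_p_drug_given_ind"] = p_drug_given_ind(ntab)
            row["naive_dff"] = float(stats.dff_naive[kd, ki])
            row["naive_dff_adj_drug"] = float(stats.dff_naive_adj_drug[kd, ki])
            row["naive_dff_adj_ind"] = float(stats.dff_naive_adj_ind[kd, ki])
        rows.append(row)

    columns = ["drug", "indication"] + list(FEATURE_NAMES)
    if include_naive:
        columns += list(NAIVE_FEATURES)
    features = pd.DataFrame(rows, columns=columns)
    rejected_df = pd.DataFrame(rejected, columns=["drug", "indication", "reason"])
    return features, rejected_df
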