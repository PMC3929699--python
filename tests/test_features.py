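"""Feature construction: conditioning, association stats, similarities."""

import dataclasses
import itertools

import numpy as np
import pandas as pd
import pytest

from offlabel.containers import DrugAttributes, DrugAttributeTable, UsageMatrix
from offlabel.features import (
    CorpusStats,
    KnowledgeBases,
    PatientProfile,
    attribute_similarity,
    binary_cosine,
    build_profiles,
    chi_squared,
    co_occurs,
    contingency,
    drug_first_fraction,
    featurize,
    indication_similarity,
    jaccard,
    odds_ratio,
    usage_similarity,
    FEATURE_NAMES,
)
from offlabel.simulate import WorldConfig, generate_corpus, generate_world

from conftest import SMALL_CONFIG, make_hand_world, mentions_frame


# ---------------------------------------------------------------- profiles
def test_first_dates_are_minima():
    corpus = mentions_frame(
        [
            ("p1", "n1", "2011-01-03", "d1", "drug"),
            ("p1", "n2", "2011-01-01", "d1", "drug"),
        ]
    )
    (profile,) = build_profiles(corpus)
    assert profile.drug_first_dates["d1"].day == 1


def test_profiles_match_brute_force_group_by(small_corpus):
    profiles = {p.patient_id: p for p in build_profiles(small_corpus)}
    for pid, group in small_corpus.groupby("patient_id"):
        p = profiles[pid]
        for r in group.itertuples():
            slot = (
                p.drug_first_dates
                if r.concept_type == "drug"
                else p.indication_first_dates
            )
            assert slot[r.concept_id] <= r.date


# ------------------------------------------------------------- conditioning
def test_comorbidity_is_not_counted_but_known_usage_is():
    """A drug co-mentioned with its known indication and a comorbidity is
    associated with the indication, not the comorbidity."""
    known = UsageMatrix(["lisinopril"], ["hypertension", "diabetes"],
                        {("lisinopril", "hypertension"): True})
    import datetime as dt

    day = dt.date(2011, 1, 1)
    profile = PatientProfile(
        "p1",
        {"lisinopril": day},
        {"hypertension": day, "diabetes": day},
    )
    assert co_occurs(("lisinopril", "hypertension"), profile, known)
    assert not co_occurs(("lisinopril", "diabetes"), profile, known)


def test_drug_only_patient_co_occurs_with_nothing():
    import datetime as dt

    profile = PatientProfile("p1", {"d1": dt.date(2011, 1, 1)}, {})
    known = UsageMatrix(["d1"], ["i1"], {})
    assert not co_occurs(("d1", "i1"), profile, known)


def test_co_occurs_matches_exhaustive_truth_table():
    """Brute-force enumeration over every subset of present indications and
    every known-usage configuration for a 3-indication vocabulary."""
    import datetime as dt

    inds = ["i1", "i2", "i3"]
    day = dt.date(2011, 1, 1)
    for present in itertools.chain.from_iterable(
        itertools.combinations(inds, r) for r in range(4)
    ):
        for known_set in itertools.chain.from_iterable(
            itertools.combinations(inds, r) for r in range(4)
        ):
            known = UsageMatrix(
                ["d"], inds, {("d", i): True for i in known_set}
            )
            profile = PatientProfile(
                "p", {"d": day}, {i: day for i in present}
            )
            for query in inds:
                got = co_occurs(("d", query), profile, known)
                # the spec predicate, evaluated literally
                expected = (
                    query in present
                    and (
                        query in known_set
                        or not any(
                            i in present for i in known_set if i != query
                        )
                    )
                )
                assert got == expected, (present, known_set, query)


def test_contingency_matches_hand_count():
    known = UsageMatrix(["d"], ["i", "j"], {("d", "j"): True})
    rows = []
    # 20 patients: 6 with (d,i) cleanly, 3 with (d,i,j) [conditioned away],
    # 4 with d only, 3 with i only, 4 with neither
    for k in range(6):
        rows += [(f"a{k}", "n", "2011-01-01", "d", "drug"),
                 (f"a{k}", "n", "2011-01-02", "i", "indication")]
    for k in range(3):
        rows += [(f"b{k}", "n", "2011-01-01", "d", "drug"),
                 (f"b{k}", "n", "2011-01-02", "i", "indication"),
                 (f"b{k}", "n", "2011-01-03", "j", "indication")]
    for k in range(4):
        rows += [(f"c{k}", "n", "2011-01-01", "d", "drug")]
    for k in range(3):
        rows += [(f"e{k}", "n", "2011-01-01", "i", "indication")]
    for k in range(4):
        rows += [(f"f{k}", "n", "2011-01-01", "i2", "indication")]
    corpus = mentions_frame(rows)
    profiles = build_profiles(corpus)
    a, b, c, d = contingency(("d", "i"), profiles, known)
    assert (a, b, c, d) == (6, 7, 6, 1)
    a_raw, *_ = contingency(("d", "i"), profiles, known, conditioned=False)
    assert a_raw == 9


def test_absent_drug_gives_empty_cells():
    known = UsageMatrix(["d"], ["i"], {})
    corpus = mentions_frame([("p1", "n", "2011-01-01", "i", "indication")])
    a, b, c, d = contingency(("d", "i"), build_profiles(corpus), known)
    assert (a, b) == (0, 0)


# ------------------------------------------------------- association stats
def test_chi_squared_closed_forms():
    assert chi_squared((25, 25, 25, 25)) == 0.0
    assert chi_squared((10, 0, 0, 10)) == pytest.approx(20.0)
    assert chi_squared((5, 0, 3, 0)) == 0.0  # zero margin


def test_chi_squared_matches_textbook_formula(rng):
    for _ in range(300):
        a, b, c, d = (int(x) for x in rng.integers(0, 40, size=4))
        n = a + b + c + d
        if n == 0:
            continue
        table = np.array([[a, b], [c, d]], dtype=float)
        rows, cols = table.sum(1), table.sum(0)
        if rows.min() == 0 or cols.min() == 0:
            expected = 0.0
        else:
            expected = sum(
                (table[i, j] - rows[i] * cols[j] / n) ** 2 / (rows[i] * cols[j] / n)
                for i in range(2)
                for j in range(2)
            )
        assert chi_squared((a, b, c, d)) == pytest.approx(expected)


def test_odds_ratio_closed_forms(rng):
    assert odds_ratio((10, 10, 10, 10)) == 1.0
    assert odds_ratio((10, 0, 0, 10)) == pytest.approx(441.0)
    for _ in range(200):
        a, b, c, d = (int(x) for x in rng.integers(1, 40, size=4))
        assert odds_ratio((a, b, c, d)) == pytest.approx(a * d / (b * c))


# -------------------------------------------------------------------- dff
def test_drug_first_fraction_cases():
    import datetime as dt

    known = UsageMatrix(["d"], ["i"], {})
    d1, d2 = dt.date(2011, 1, 1), dt.date(2011, 2, 1)
    strictly_first = [
        PatientProfile(f"p{k}", {"d": d1}, {"i": d2}) for k in range(3)
    ]
    assert drug_first_fraction(("d", "i"), strictly_first, known) == 1.0
    assert drug_first_fraction(("d", "i"), [], known) == 0.5
    equal_dates = [PatientProfile("p", {"d": d1}, {"i": d1})]
    assert drug_first_fraction(("d", "i"), equal_dates, known) == 0.5


def test_treatment_lag_puts_dff_below_half():
    """When drugs are generated after their indications, planted true pairs
    have drug-first fractions below the neutral 0.5."""
    cfg = dataclasses.replace(SMALL_CONFIG, noise_drug_rate=0.0, n_ae_links=0)
    world = generate_world(cfg, seed=21)
    corpus = generate_corpus(world, 400, seed=22)
    known = world.known_union()
    profiles = build_profiles(corpus)
    pair = sorted(world.usage_offlabel)[0]
    assert drug_first_fraction(pair, profiles, known) < 0.5


# ------------------------------------------------------------ similarities
@pytest.fixture
def epilepsy_fixture():
    """Usage matrix mirroring the lamotrigine/topiramate narrative: the
    query drug shares two seizure indications with a migraine treater."""
    drugs = ["lamotrigine", "topiramate", "rituximab"]
    inds = ["tonic-clonic", "myoclonic", "migraine", "nhl"]
    pairs = {
        ("lamotrigine", "tonic-clonic"): True,
        ("lamotrigine", "myoclonic"): True,
        ("lamotrigine", "nhl"): False,
        ("topiramate", "tonic-clonic"): True,
        ("topiramate", "myoclonic"): True,
        ("topiramate", "migraine"): True,
        ("rituximab", "nhl"): True,
    }
    return UsageMatrix(drugs, inds, pairs)


def test_usage_similarity_on_epilepsy_fixture(epilepsy_fixture):
    cos, jac = usage_similarity("lamotrigine", "migraine", epilepsy_fixture)
    # profiles with the migraine column removed: {tc, myo, nhl} vs {tc, myo}
    assert jac == pytest.approx(2 / 3)
    assert cos == pytest.approx(2 / np.sqrt(3 * 2))


def test_usage_similarity_no_treaters_is_zero(epilepsy_fixture):
    u = epilepsy_fixture.without([("topiramate", "migraine")])
    assert usage_similarity("lamotrigine", "migraine", u) == (0.0, 0.0)


def test_indication_similarity_transpose_symmetry(epilepsy_fixture):
    """Transposing the usage matrix swaps the roles of the two similarity
    constructions, so results coincide on the transposed fixture."""
    transposed = UsageMatrix(
        epilepsy_fixture.indications,
        epilepsy_fixture.drugs,
        {(i, d): True for (d, i) in epilepsy_fixture.pairs},
    )
    assert indication_similarity(
        "migraine", "lamotrigine", transposed
    ) == pytest.approx(usage_similarity("lamotrigine", "migraine", epilepsy_fixture))


def test_indication_similarity_no_known_indications():
    u = UsageMatrix(["d1", "d2"], ["i1"], {("d2", "i1"): True})
    assert indication_similarity("d1", "i1", u) == (0.0, 0.0)


def _brute_max_sim(profile, others):
    best_cos = best_jac = 0.0
    for other in others:
        inter = len(profile & other)
        if profile and other:
            best_cos = max(best_cos, inter / np.sqrt(len(profile) * len(other)))
        if profile | other:
            best_jac = max(best_jac, inter / len(profile | other))
    return best_cos, best_jac


def test_similarities_match_brute_force_on_random_matrices(rng):
    for trial in range(25):
        D, I = 12, 9
        drugs = [f"d{k}" for k in range(D)]
        inds = [f"i{k}" for k in range(I)]
        mask = rng.random((D, I)) < 0.25
        usage = UsageMatrix(
            drugs, inds,
            {(drugs[a], inds[b]): True for a, b in zip(*np.nonzero(mask))},
        )
        d = drugs[int(rng.integers(D))]
        i = inds[int(rng.integers(I))]
        # drug-drug, via brute-force set construction
        prof = usage.indications_of(d) - {i}
        others = [
            usage.indications_of(t) - {i}
            for t in usage.treaters(i)
            if t != d
        ]
        assert usage_similarity(d, i, usage) == pytest.approx(
            _brute_max_sim(prof, others)
        )
        # indication-indication
        prof_i = usage.treaters(i) - {d}
        others_i = [
            usage.treaters(j) - {d}
            for j in usage.indications_of(d)
            if j != i
        ]
        assert indication_similarity(d, i, usage) == pytest.approx(
            _brute_max_sim(prof_i, others_i)
        )


def test_attribute_similarity_identical_and_disjoint(rng):
    drugs = ["d1", "d2", "d3"]
    usage = UsageMatrix(drugs, ["i1"], {("d2", "i1"): True, ("d3", "i1"): True})
    attrs = DrugAttributeTable(
        {
            "d1": DrugAttributes(frozenset({"T1", "T2"}), frozenset({"P1"}), frozenset()),
            "d2": DrugAttributes(frozenset({"T1", "T2"}), frozenset({"P9"}), frozenset()),
            "d3": DrugAttributes(frozenset({"T9"}), frozenset(), frozenset({"C1"})),
        }
    )
    out = attribute_similarity("d1", "i1", attrs, usage)
    assert out["k_target_cos"] == 1.0 and out["k_target_jac"] == 1.0
    assert out["k_pathway_cos"] == 0.0 and out["k_pathway_jac"] == 0.0
    assert out["k_category_cos"] == 0.0  # empty set contributes zero


def test_jaccard_is_one_only_for_identical_nonempty_sets(rng):
    for _ in range(100):
        a = frozenset(rng.choice(10, size=rng.integers(0, 6), replace=False))
        b = frozenset(rng.choice(10, size=rng.integers(0, 6), replace=False))
        j = jaccard(a, b)
        assert 0.0 <= j <= 1.0 and 0.0 <= binary_cosine(a, b) <= 1.0
        if j == 1.0:
            assert a == b and a


def test_excluding_the_pair_never_increases_its_similarity(rng, epilepsy_fixture):
    for d, i in [("lamotrigine", "migraine"), ("rituximab", "migraine")]:
        excluded = usage_similarity(d, i, epilepsy_fixture, exclude=frozenset({(d, i)}))
        included = usage_similarity(d, i, epilepsy_fixture)
        assert excluded[0] <= included[0] + 1e-12
        assert excluded[1] <= included[1] + 1e-12


# ---------------------------------------------------------------- featurize
@pytest.fixture(scope="module")
def small_kbs():
    world = generate_world(SMALL_CONFIG, seed=11)
    return world, KnowledgeBases(world.usage_true, world.usage_secondary, world.attributes)


def test_featurize_schema_and_rejection(small_kbs, small_corpus):
    world, kbs = small_kbs
    pairs = sorted(world.usage_offlabel) + [("nonexistent", "ind000")]
    feats, rejected = featurize(pairs, small_corpus, kbs)
    assert len(feats) == len(pairs) - 1
    assert list(feats.columns[2 : 2 + 25]) == list(FEATURE_NAMES)
    assert len(rejected) == 1 and "vocabulary" in rejected.iloc[0]["reason"]
    sim_cols = [c for c in FEATURE_NAMES if "cos" in c or "jac" in c or c == "k_frac_approved"]
    assert ((feats[sim_cols] >= 0) & (feats[sim_cols] <= 1)).all().all()
    assert (feats["n_co"] <= feats[["n_drug", "n_ind"]].min(axis=1)).all()


def test_absent_drug_has_neutral_empirical_but_live_knowledge(small_kbs):
    world, kbs = small_kbs
    corpus = mentions_frame([("p1", "n", "2011-01-01", world.indications[0], "indication")])
    d = world.drugs[0]
    i = sorted(world.usage_true.indications_of(d))[0]
    feats, _ = featurize([(d, i)], corpus, kbs)
    row = feats.iloc[0]
    assert row["n_drug"] == 0 and row["n_co"] == 0 and row["dff"] == 0.5
    assert row["k_n_treaters"] >= 1  # knowledge features still computed


def test_vectorized_stats_agree_with_scalar_path(small_kbs, small_corpus):
    """Dual-route check: the matrix co-mention counts equal the per-pair
    predicate evaluated patient by patient."""
    world, kbs = small_kbs
    known = kbs.known_union()
    stats = CorpusStats(small_corpus, world.drugs, world.indications, known)
    profiles = build_profiles(small_corpus)
    rng = np.random.default_rng(0)
    for _ in range(25):
        d = world.drugs[int(rng.integers(len(world.drugs)))]
        i = world.indications[int(rng.integers(len(world.indications)))]
        table = contingency((d, i), profiles, known)
        kd, ki = stats.d_index[d], stats.i_index[i]
        assert stats.table(kd, ki) == table
        assert drug_first_fraction((d, i), profiles, known) == pytest.approx(
            stats.dff_cond[kd, ki]
        )


def test_conditioning_strictly_reduces_confounded_co_counts():
    """For a pure comorbidity confounder (D, B), the conditioned co-count is
    strictly below the raw co-count and the chi-squared drops with it."""
    cfg = WorldConfig(
        n_drugs=6, n_indications=6, n_offlabel=0, n_drug_classes=3,
        comorbidity_odds=20.0, n_comorbidity=1, n_ae_links=0,
        noise_drug_rate=0.0, noise_indication_rate=0.0,
        product_swap_prob=0.0, child_swap_prob=0.0,
        max_prevalence=0.4, min_prevalence=0.1,
    )
    world = generate_world(cfg, seed=31)
    corpus = generate_corpus(world, 1500, seed=32)
    d, a, b = world.confounder_triples()[0]
    known = world.known_union()
    stats = CorpusStats(corpus, world.drugs, world.indications, known)
    kd, kb = stats.d_index[d], stats.i_index[b]
    assert stats.co_cond[kd, kb] < stats.co_naive[kd, kb]
    # conditioning flips the apparent association: the raw pair looks
    # positively associated, the conditioned pair does not
    cond_or = odds_ratio(stats.table(kd, kb, conditioned=True))
    naive_or = odds_ratio(stats.table(kd, kb, conditioned=False))
    assert cond_or < naive_or
    assert naive_or > 1.0 > cond_or


def test_planted_pairs_separate_from_random_negatives(small_kbs, small_corpus):
    world, kbs = small_kbs
    planted = sorted(world.usage_offlabel)
    rng = np.random.default_rng(7)
    treated = world.treated_relation()
    negatives = []
    while len(negatives) < 30:
        d = world.drugs[int(rng.integers(len(world.drugs)))]
        i = world.indications[int(rng.integers(len(world.indications)))]
        if (d, i) not in treated:
            negatives.append((d, i))
    f_pos, _ = featurize(planted, small_corpus, kbs)
    f_neg, _ = featurize(negatives, small_corpus, kbs)
    assert f_pos["chi2"].mean() > f_neg["chi2"].mean()
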