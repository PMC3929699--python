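"""Filter cascade: set semantics, hierarchy near-misses, support counts,
side-effect vetoes, and ledger conservation."""

import numpy as np
import pytest

from offlabel.containers import ConceptHierarchy, EvidenceBundle, UsageMatrix
from offlabel.filters import (
    FilterConfig,
    FilterLedger,
    FilterStage,
    known_usage_filter,
    literature_support,
    near_miss_filter,
    report_support,
    run_cascade,
    side_effect_filter,
)


def _usage(pairs, drugs=None, inds=None):
    drugs = drugs or sorted({d for d, _ in pairs})
    inds = inds or sorted({i for _, i in pairs})
    return UsageMatrix(drugs, inds, {p: True for p in pairs})


def test_known_usage_union_semantics():
    u1 = _usage([("d1", "i1")], ["d1", "d2"], ["i1", "i2"])
    u2 = _usage([("d2", "i2")], ["d1", "d2"], ["i1", "i2"])
    union = u1.union(u2)
    passed, removed = known_usage_filter(
        [("d1", "i1"), ("d2", "i2"), ("d1", "i2")], union
    )
    assert passed == [("d1", "i2")]
    assert set(removed) == {("d1", "i1"), ("d2", "i2")}


def test_known_usage_equals_set_difference_on_random_pairs(rng):
    drugs = [f"d{k}" for k in range(15)]
    inds = [f"i{k}" for k in range(10)]
    for _ in range(30):
        known = {
            (drugs[a], inds[b])
            for a, b in zip(rng.integers(0, 15, 20), rng.integers(0, 10, 20))
        }
        candidates = [
            (drugs[a], inds[b])
            for a, b in zip(rng.integers(0, 15, 40), rng.integers(0, 10, 40))
        ]
        u = UsageMatrix(drugs, inds, {p: True for p in known})
        passed, removed = known_usage_filter(dict.fromkeys(candidates), u)
        assert set(passed) == set(candidates) - known
        assert set(removed) == set(candidates) & known


def test_near_miss_subtype_removed_grandparent_passes():
    # open-angle glaucoma is a subtype of glaucoma; eye-disease is the
    # grandparent of open-angle via glaucoma
    h = ConceptHierarchy(
        [("open-angle", "glaucoma"), ("glaucoma", "eye-disease")]
    )
    usage = _usage([("drug", "glaucoma")], ["drug"],
                   ["glaucoma", "open-angle", "eye-disease"])
    passed, removed = near_miss_filter(
        [("drug", "open-angle"), ("drug", "eye-disease")], usage, h
    )
    # subtype of a known indication: removed
    assert ("drug", "open-angle") in removed
    # direct parent of a known indication: removed; grandparents pass
    assert passed == []
    usage2 = _usage([("drug", "open-angle")], ["drug"],
                    ["glaucoma", "open-angle", "eye-disease"])
    passed2, removed2 = near_miss_filter(
        [("drug", "glaucoma"), ("drug", "eye-disease")], usage2, h
    )
    assert ("drug", "glaucoma") in removed2  # direct parent
    assert passed2 == [("drug", "eye-disease")]  # distance-2 ancestor passes


def test_near_miss_matches_brute_force_on_random_dags(rng):
    for trial in range(20):
        n = 20
        inds = [f"i{k}" for k in range(n)]
        edges = []
        for k in range(1, n):
            for p in rng.choice(k, size=min(k, int(rng.integers(1, 3))), replace=False):
                edges.append((inds[k], inds[int(p)]))
        h = ConceptHierarchy(edges)
        parents = {}
        children = {}
        for c, p in edges:
            parents.setdefault(c, set()).add(p)
            children.setdefault(p, set()).add(c)

        def all_ancestors(node):
            out, stack = set(), [node]
            while stack:
                for p in parents.get(stack.pop(), ()):
                    if p not in out:
                        out.add(p)
                        stack.append(p)
            return out

        known = {inds[int(k)] for k in rng.choice(n, size=5, replace=False)}
        usage = UsageMatrix(["d"], inds, {("d", i): True for i in known})
        candidates = [("d", i) for i in inds if i not in known]
        passed, removed = near_miss_filter(candidates, usage, h)
        for d, i in candidates:
            is_subtype = any(j in all_ancestors(i) for j in known)
            is_direct_parent = any(i in parents.get(j, ()) for j in known)
            if is_subtype or is_direct_parent:
                assert (d, i) in removed
            else:
                assert (d, i) in passed


def test_support_counts_distinct_ids_only(rng):
    links = {("r1", "d", "i"), ("r2", "d", "i"), ("r2", "d", "i"), ("r3", "d", "j")}
    assert report_support(("d", "i"), links) == 2
    assert literature_support(("d", "j"), links) == 1
    # brute force on random bundles
    for _ in range(20):
        bundle = {
            (f"r{int(rng.integers(6))}", f"d{int(rng.integers(3))}", f"i{int(rng.integers(3))}")
            for _ in range(30)
        }
        for d in ("d0", "d1", "d2"):
            for i in ("i0", "i1", "i2"):
                expected = len({r for r, dd, ii in bundle if dd == d and ii == i})
                assert report_support((d, i), bundle) == expected


def test_side_effect_filter_whitelist_passes_but_flags():
    side_effects = frozenset({("d1", "i1"), ("d2", "i2")})
    passed, removed, flagged = side_effect_filter(
        [("d1", "i1"), ("d2", "i2"), ("d3", "i3")],
        side_effects,
        whitelist=frozenset({("d1", "i1")}),
    )
    assert ("d1", "i1") in passed and ("d1", "i1") in flagged
    assert ("d2", "i2") in removed and ("d2", "i2") in flagged
    assert ("d3", "i3") in passed and ("d3", "i3") not in flagged


def test_cascade_on_empty_input():
    usage = _usage([("d", "i")])
    survivors, ledger = run_cascade(
        [], EvidenceBundle(), usage, ConceptHierarchy([])
    )
    assert survivors == []
    assert all(s.n_in == 0 and s.n_pass == 0 for s in ledger.stages)


def test_cascade_stage_accounting_on_engineered_fixture():
    """Stages remove 2, 1, 3, 0, 1 of 10 candidates; 3 survive."""
    drugs = [f"d{k}" for k in range(10)]
    inds = [f"i{k}" for k in range(10)] + ["iparent"]
    candidates = [(f"d{k}", f"i{k}") for k in range(10)]
    usage_pairs = {("d0", "i0"): True, ("d1", "i1"): True, ("d2", "iparent"): True}
    usage = UsageMatrix(drugs, inds, usage_pairs)
    hierarchy = ConceptHierarchy([("i2", "iparent")])  # i2 subtype of known iparent
    # pairs d3..d9 survive known+near-miss; give reports to all but d3, d4, d5
    reports = frozenset(
        (f"r{k}-{n}", f"d{k}", f"i{k}") for k in range(6, 10) for n in range(10)
    )
    articles = frozenset(
        (f"a{k}-{n}", f"d{k}", f"i{k}") for k in range(6, 10) for n in range(3)
    )
    side_effects = frozenset({("d6", "i6")})
    evidence = EvidenceBundle(reports, articles, side_effects)
    survivors, ledger = run_cascade(candidates, evidence, usage, hierarchy)
    assert [s.n_removed for s in ledger.stages] == [2, 1, 3, 0, 1, 0]
    assert survivors == [(f"d{k}", f"i{k}") for k in (7, 8, 9)]
    frame = ledger.to_frame()
    assert (frame["n_in"] == frame["n_pass"] + frame["n_removed"]).all()
    reasons = ledger.removals_frame()
    assert len(reasons) == 7  # every removed pair carries exactly one reason


def test_published_funnel_counts_satisfy_conservation():
    """The printed candidate funnel (14,174 flagged through 403 surviving)
    forms a conservation-consistent ledger."""
    counts = [14174, 6142, 766, 537, 466, 403]
    names = ["known+near-miss", "report-support", "literature-support",
             "side-effect", "manual-override"]
    ledger = FilterLedger()
    for name, n_in, n_pass in zip(names, counts[:-1], counts[1:]):
        ledger.add(FilterStage(name, n_in, n_pass, n_in - n_pass))
    ledger.verify()
    frame = ledger.to_frame()
    assert (frame["n_in"] == frame["n_pass"] + frame["n_removed"]).all()
    assert (frame["n_pass"].diff().dropna() <= 0).all()
    assert frame.iloc[-1]["n_pass"] == 403


def test_ledger_rejects_broken_conservation():
    ledger = FilterLedger()
    with pytest.raises(ValueError, match="conservation"):
        ledger.add(FilterStage("bad", 10, 5, 4))
    ledger.add(FilterStage("ok", 10, 6, 4))
    with pytest.raises(ValueError, match="n_in"):
        ledger.add(FilterStage("mismatched", 7, 6, 1))


def test_thresholds_are_configurable():
    usage = UsageMatrix(["d"], ["i"], {})
    reports = frozenset((f"r{n}", "d", "i") for n in range(5))
    articles = frozenset((f"a{n}", "d", "i") for n in range(2))
    evidence = EvidenceBundle(reports, articles, frozenset())
    survivors, _ = run_cascade(
        [("d", "i")], evidence, usage, ConceptHierarchy([]),
        FilterConfig(report_threshold=5, literature_threshold=2),
    )
    assert survivors == [("d", "i")]
    survivors, _ = run_cascade(
        [("d", "i")], evidence, usage, ConceptHierarchy([]),
        FilterConfig(report_threshold=6, literature_threshold=2),
    )
    assert survivors == []
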