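"""Gold-standard construction: KB positives, frequency-matched negatives.

Positives are the known-usage pairs whose drug and indication are each
observed at least once in the corpus. Negatives are built by sampling
positives with replacement and replacing both the drug and the
indication with concepts of roughly the same corpus frequency (drawn
uniformly from the ranks flanking the original in a frequency-sorted
list). Sampled pairs that collide with a known usage are discarded and
not replaced, so the final negative count may fall slightly below
ratio x positives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import DRUG, INDICATION, UsageMatrix


class GoldStandardError(ValueError):
    """No positives are observable in the corpus."""


@dataclass(frozen=True)
class LabeledPair:
    drug: str
    indication: str
    label: str  # "positive" | "negative"
    origin: str  # "kb" | "sampled"


def patient_frequencies(corpus: pd.DataFrame, concept_type: str) -> dict[str, int]:
    """Patient-level mention frequency (distinct patients) per concept."""
    sub = corpus[corpus["concept_type"] == concept_type]
    return sub.groupby("concept_id")["patient_id"].nunique().to_dict()


def frequency_rank(ids, frequencies: dict[str, int]) -> list[str]:
    """Concepts ordered by descending patient frequency, ties lexicographic."""
    return sorted(ids, key=lambda c: (-frequencies.get(c, 0), c))


def sample_negative(
    positive: tuple[str, str],
    drug_ranks: list[str],
    indication_ranks: list[str],
    window: int,
    rng: np.random.Generator,
) -> tuple[str, str]:
    """Perturb both members of a positive within a frequency-rank window.

    The replacement drug is drawn uniformly from the up-to-2*window
    ranks flanking the positive's drug (the drug itself excluded);
    likewise for the indication. Windows are truncated at list bounds.
    """
    if window < 1:
        raise ValueError("window must be >= 1")

    def draw(ranks: list[str], item: str) -> str:
        r = ranks.index(item)
        lo, hi = max(0, r - window), min(len(ranks) - 1, r + window)
        candidates = [ranks[k] for k in range(lo, hi + 1) if k != r]
        if not candidates:
            return item
        return candidates[int(rng.integers(len(candidates)))]

    d, i = positive
    return draw(drug_ranks, d), draw(indication_ranks, i)


def build_gold_standard(
    usage: UsageMatrix,
    corpus: pd.DataFrame,
    ratio: int = 4,
    window: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Labeled (drug, indication) pairs: KB positives + sampled negatives.

    Returns a frame with columns drug/indication/label/origin. Negatives
    are deduplicated; negatives colliding with a known usage are
    discarded without resampling.
    """
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    rng = np.random.default_rng(seed)
    drug_freq = patient_frequencies(corpus, DRUG)
    ind_freq = patient_frequencies(corpus, INDICATION)
    positives = sorted(
        (d, i)
        for (d, i) in usage.pairs
        if drug_freq.get(d, 0) >= 1 and ind_freq.get(i, 0) >= 1
    )
    if not positives:
        raise GoldStandardError(
            "no known-usage pair has both members observed in the corpus"
        )
    drug_ranks = frequency_rank(usage.drugs, drug_freq)
    ind_ranks = frequency_rank(usage.indications, ind_freq)

    negatives: set[tuple[str, str]] = set()
    n_draws = ratio * len(positives)
    for _ in range(n_draws):
        pos = positives[int(rng.integers(len(positives)))]
        neg = sample_negative(pos, drug_ranks, ind_ranks, window, rng)
        if neg in usage:
            continue  # inadvertent known usage: discard, do not resample
        negatives.add(neg)
    negatives -= set(positives)

    rows = [
        {"drug": d, "indication": i, "label": "positive", "origin": "kb"}
        for d, i in positives
    ] + [
        {"drug": d, "indication": i, "label": "negative", "origin": "sampled"}
        for d, i in sorted(negatives)
    ]
    return pd.DataFrame(rows, columns=["drug", "indication", "label", "origin"])


def split(
    gold: pd.DataFrame, train_fraction: float = 0.8, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic, label-stratified train/test split."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    for _, group in gold.groupby("label", sort=True):
        perm = rng.permutation(len(group))
        n_train = int(round(train_fraction * len(group)))
        idx = group.index.to_numpy()[perm]
        train_parts.append(gold.loc[idx[:n_train]])
        test_parts.append(gold.loc[idx[n_train:]])
    train = pd.concat(train_parts).sort_index().reset_index(drop=True)
    test = pd.concat(test_parts).sort_index().reset_index(drop=True)
    return train, test
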