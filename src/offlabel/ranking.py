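"""Risk and cost indices and triage binning of surviving usages.

A drug's *risk index* is its rank-normalized expected disutility: the
sum over its adverse events of a severity weight times a frequency
probability. Drugs with no adverse-event associations sit at exactly 0.
The *cost index* is the rank-normalized mean unit cost. Both indices
live in [0, 1] with the riskiest / most expensive drug at 1. Surviving
usages are binned against empirical quantiles of the index values over
the surviving set itself (default quartiles): high-risk-high-cost if
both indices reach the upper threshold, low-risk-low-cost if both are
at or below the lower one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import DrugEconSafetyProfile

# Reconstruction defaults: severity weights are relative disutilities on
# [0, 1]; frequency probabilities are class midpoints of typical
# labeling bands (rare <0.1%, infrequent 0.1-1%, common >1%).
DEFAULT_SEVERITY_WEIGHTS = {
    "mild": 0.05,
    "moderate": 0.2,
    "severe": 0.5,
    "life-threatening": 1.0,
}
DEFAULT_FREQUENCY_PROBS = {
    "rare": 0.0005,
    "infrequent": 0.005,
    "common": 0.05,
}


class RankingConfigError(ValueError):
    pass


@dataclass(frozen=True)
class TriagedUsage:
    drug: str
    indication: str
    report_support: int
    literature_support: int
    risk_index: float | None
    cost_index: float | None
    bin: str  # high-risk-high-cost | low-risk-low-cost | other


def expected_disutility(
    profile: DrugEconSafetyProfile,
    severity_weights: Mapping[str, float] | None = None,
    frequency_probs: Mapping[str, float] | None = None,
) -> float:
    """Severity-weighted, probability-weighted sum over adverse events."""
    weights = severity_weights or DEFAULT_SEVERITY_WEIGHTS
    probs = frequency_probs or DEFAULT_FREQUENCY_PROBS
    total = 0.0
    for event in profile.adverse_events:
        if event.severity not in weights:
            raise RankingConfigError(f"unknown severity class {event.severity!r}")
        if event.frequency not in probs:
            raise RankingConfigError(f"unknown frequency class {event.frequency!r}")
        total += weights[event.severity] * probs[event.frequency]
    return total


def rank_normalize(
    values: Mapping[str, float], zero_floor: bool = False
) -> dict[str, float]:
    """Map raw values to average ranks scaled to (0, 1], ties averaged.

    With ``zero_floor``, drugs at raw value 0 map to exactly 0 and are
    excluded from the rank denominator (so the index reflects ranking
    among drugs that have any signal at all).
    """
    if not values:
        raise ValueError("rank_normalize needs at least one value")
    keys = sorted(values)
    raw = np.array([values[k] for k in keys], dtype=float)
    out: dict[str, float] = {}
    if zero_floor:
        nonzero = raw > 0
        for k, is_nz in zip(keys, nonzero):
            if not is_nz:
                out[k] = 0.0
        if not nonzero.any():
            return out
        ranks = rankdata(raw[nonzero], method="average")
        denom = ranks.max()
        for k, r in zip([k for k, nz in zip(keys, nonzero) if nz], ranks):
            out[k] = float(r / denom)
        return out
    ranks = rankdata(raw, method="average")
    denom = ranks.max()
    return {k: float(r / denom) for k, r in zip(keys, ranks)}


def risk_index(
    profiles: Mapping[str, DrugEconSafetyProfile],
    severity_weights: Mapping[str, float] | None = None,
    frequency_probs: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Rank-normalized expected disutility per drug; AE-free drugs at 0."""
    raw = {
        d: expected_disutility(p, severity_weights, frequency_probs)
        for d, p in profiles.items()
    }
    return rank_normalize(raw, zero_floor=True)


def cost_index(profiles: Mapping[str, DrugEconSafetyProfile]) -> dict[str, float]:
    """Rank-normalized mean unit cost; drugs with no cost data are absent."""
    raw = {
        d: float(np.mean(p.unit_costs))
        for d, p in profiles.items()
        if p.unit_costs
    }
    if not raw:
        return {}
    return rank_normalize(raw, zero_floor=False)


def bin_usages(
    usages: Iterable[tuple[str, str]],
    risk: Mapping[str, float],
    cost: Mapping[str, float],
    report_counts: Mapping[tuple[str, str], int] | None = None,
    literature_counts: Mapping[tuple[str, str], int] | None = None,
    lower_q: float = 0.25,
    upper_q: float = 0.75,
) -> pd.DataFrame:
    """Bin surviving usages by risk/cost quantile thresholds.

    Thresholds are empirical quantiles (linear interpolation) of the
    index values over the surviving usage set itself, not over all
    drugs. Comparisons are inclusive, so ties at a threshold fall into
    the extreme bins. Usages whose drug lacks an index are kept with
    bin "other" and flagged. Output is sorted within bin by report
    support descending.
    """
    usages = list(usages)
    if len(usages) < 4:
        raise RankingConfigError(
            f"quantile thresholds undefined for {len(usages)} usages (< 4)"
        )
    report_counts = report_counts or {}
    literature_counts = literature_counts or {}
    risks = [risk[d] for d, _ in usages if d in risk]
    costs = [cost[d] for d, _ in usages if d in cost]
    if not risks or not costs:
        raise RankingConfigError("no usage has both risk and cost data")
    risk_lo, risk_hi = np.quantile(risks, [lower_q, upper_q])
    cost_lo, cost_hi = np.quantile(costs, [lower_q, upper_q])

    rows = []
    for d, i in usages:
        r = risk.get(d)
        c = cost.get(d)
        if r is None or c is None:
            bin_name, flagged = "other", True
        else:
            flagged = False
            if r >= risk_hi and c >= cost_hi:
                bin_name = "high-risk-high-cost"
            elif r <= risk_lo and c <= cost_lo:
                bin_name = "low-risk-low-cost"
            else:
                bin_name = "other"
        rows.append(
            {
                "drug": d,
                "indication": i,
                "report_support": int(report_counts.get((d, i), 0)),
                "literature_support": int(literature_counts.get((d, i), 0)),
                "risk_index": r,
                "cost_index": c,
                "bin": bin_name,
                "missing_index": flagged,
            }
        )
    df = pd.DataFrame(rows)
    bin_order = {"high-risk-high-cost": 0, "low-risk-low-cost": 1, "other": 2}
    df["_bin_order"] = df["bin"].map(bin_order)
    df = (
        df.sort_values(
            ["_bin_order", "report_support", "drug", "indication"],
            ascending=[True, False, True, True],
        )
        .drop(columns="_bin_order")
        .reset_index(drop=True)
    )
    return df
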