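"""End-to-end orchestration: config, staged execution, reports.

A run starts from either a synthetic world (``world`` section in the
config) or a directory of input tables (``paths`` section), executes
normalize -> gold standard -> features -> classifier -> prediction ->
filter cascade -> triage, writes every stage's output before the next
begins, and finishes with a manifest recording seeds, the config hash,
and the funnel counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .containers import DRUG, INDICATION, AdverseEvent, DrugEconSafetyProfile, EvidenceBundle
from .features import FEATURE_NAMES, NAIVE_FEATURES, KnowledgeBases, featurize
from .filters import FilterConfig, run_cascade, _support_counts
from .gold import build_gold_standard, split
from .model import ABLATION_ROWS, UsedToTreatModel, ablate
from .normalize import IngredientMap, normalize_corpus
from .ranking import (
    DEFAULT_FREQUENCY_PROBS,
    DEFAULT_SEVERITY_WEIGHTS,
    bin_usages,
    cost_index,
    risk_index,
)
from .simulate import (
    SyntheticWorld,
    WorldConfig,
    config_from_dict,
    generate_corpus,
    generate_evidence,
    generate_world,
)


class PipelineConfigError(ValueError):
    pass


@dataclass(frozen=True)
class Thresholds:
    probability: float = 0.99
    report_support: int = 10
    literature_support: int = 3
    negative_ratio: int = 4
    rank_window: int = 10
    train_fraction: float = 0.8
    lower_quantile: float = 0.25
    upper_quantile: float = 0.75
    cv_folds: int = 10

    def validate(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise PipelineConfigError("probability threshold outside [0, 1]")
        if self.report_support < 0 or self.literature_support < 0:
            raise PipelineConfigError("support thresholds must be non-negative")
        if self.negative_ratio < 1:
            raise PipelineConfigError("negative_ratio must be >= 1")
        if self.rank_window < 1:
            raise PipelineConfigError("rank_window must be >= 1")
        if not 0.0 < self.train_fraction < 1.0:
            raise PipelineConfigError("train_fraction must lie in (0, 1)")
        if not 0.0 <= self.lower_quantile < self.upper_quantile <= 1.0:
            raise PipelineConfigError("quantiles must satisfy 0 <= lo < hi <= 1")


_KNOWN_KEYS = {
    "seed",
    "n_patients",
    "thresholds",
    "world",
    "paths",
    "ablation",
    "severity_weights",
    "frequency_probs",
}


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    n_patients: int = 2000
    thresholds: Thresholds = field(default_factory=Thresholds)
    world: WorldConfig | None = field(default_factory=WorldConfig)
    paths: dict | None = None
    ablation: bool = False
    severity_weights: dict = field(
        default_factory=lambda: dict(DEFAULT_SEVERITY_WEIGHTS)
    )
    frequency_probs: dict = field(
        default_factory=lambda: dict(DEFAULT_FREQUENCY_PROBS)
    )

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise PipelineConfigError(f"unknown config keys: {sorted(unknown)}")
        thresholds = Thresholds(**raw.get("thresholds", {}))
        thresholds.validate()
        world = None
        if raw.get("world") is not None or raw.get("paths") is None:
            world = config_from_dict(raw.get("world") or {})
        return cls(
            seed=int(raw.get("seed", 0)),
            n_patients=int(raw.get("n_patients", 2000)),
            thresholds=thresholds,
            world=world,
            paths=raw.get("paths"),
            ablation=bool(raw.get("ablation", False)),
            severity_weights=raw.get("severity_weights", dict(DEFAULT_SEVERITY_WEIGHTS)),
            frequency_probs=raw.get("frequency_probs", dict(DEFAULT_FREQUENCY_PROBS)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open("r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "n_patients": self.n_patients,
            "thresholds": dataclasses.asdict(self.thresholds),
            "world": dataclasses.asdict(self.world) if self.world else None,
            "paths": self.paths,
            "ablation": self.ablation,
            "severity_weights": self.severity_weights,
            "frequency_probs": self.frequency_probs,
        }
        return d

    def digest(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _subseed(seed: int, offset: int) -> int:
    return (seed * 1000 + offset) % (2**31 - 1)


def write_world_tables(world: SyntheticWorld, corpus: pd.DataFrame,
                       evidence: EvidenceBundle, outdir: Path) -> None:
    """Emit the full input TSV set plus the planted ground truth."""
    outdir.mkdir(parents=True, exist_ok=True)
    tio.write_table(corpus, outdir / "mentions.tsv", tio.MENTIONS)
    tio.write_table(tio.usage_to_frame(world.usage_true), outdir / "usage.tsv", tio.USAGE)
    tio.write_table(
        tio.usage_to_frame(world.usage_secondary), outdir / "usage_secondary.tsv", tio.USAGE
    )
    tio.write_table(
        pd.DataFrame(sorted(world.hierarchy.edges), columns=["child", "parent"]),
        outdir / "hierarchy.tsv",
        tio.HIERARCHY,
    )
    tio.write_table(
        pd.DataFrame(
            [
                {"product": p, "ingredient": ing}
                for p in sorted(world.ingredient_map._map)
                for ing in sorted(world.ingredient_map.get(p))
            ],
            columns=["product", "ingredient"],
        ),
        outdir / "ingredients.tsv",
        tio.INGREDIENTS,
    )
    tio.write_table(
        pd.DataFrame(world.attributes.to_records(), columns=["drug", "kind", "value"]),
        outdir / "attributes.tsv",
        tio.ATTRIBUTES,
    )
    tio.write_table(
        pd.DataFrame(sorted(evidence.report_links), columns=["report_id", "drug", "indication"]),
        outdir / "reports.tsv",
        tio.REPORTS,
    )
    tio.write_table(
        pd.DataFrame(
            sorted(evidence.literature_links), columns=["article_id", "drug", "indication"]
        ),
        outdir / "literature.tsv",
        tio.LITERATURE,
    )
    tio.write_table(
        pd.DataFrame(sorted(evidence.side_effects), columns=["drug", "event"]),
        outdir / "side_effects.tsv",
        tio.SIDE_EFFECTS,
    )
    tio.write_table(
        pd.DataFrame(
            [
                {"drug": d, "event": e.event_id, "severity": e.severity,
                 "frequency": e.frequency}
                for d, prof in sorted(world.econ_safety.items())
                for e in prof.adverse_events
            ],
            columns=["drug", "event", "severity", "frequency"],
        ),
        outdir / "adverse_events.tsv",
        tio.ADVERSE_EVENTS,
    )
    tio.write_table(
        pd.DataFrame(
            [
                {"drug": d, "unit_cost": c}
                for d, prof in sorted(world.econ_safety.items())
                for c in prof.unit_costs
            ],
            columns=["drug", "unit_cost"],
        ),
        outdir / "costs.tsv",
        tio.COSTS,
    )
    tio.write_table(
        pd.DataFrame(sorted(world.usage_offlabel), columns=["drug", "indication"]),
        outdir / "ground_truth_offlabel.tsv",
        tio.PAIRS,
    )


@dataclass
class PipelineRun:
    """Handles to the artifacts of a completed run."""

    outdir: Path
    config: PipelineConfig
    world: SyntheticWorld | None
    evaluation: dict
    ablation: pd.DataFrame | None
    predictions: pd.DataFrame
    survivors: list[tuple[str, str]]
    ledger_frame: pd.DataFrame
    triage: pd.DataFrame
    manifest: dict


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> PipelineRun:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    thr = config.thresholds
    seed = config.seed

    # ---- stage 0: inputs -------------------------------------------------
    world = None
    if config.paths is None:
        world = generate_world(config.world, seed=_subseed(seed, 1))
        corpus = generate_corpus(world, config.n_patients, seed=_subseed(seed, 2))
        evidence = generate_evidence(world, seed=_subseed(seed, 3))
        usage = world.usage_true
        usage_secondary = world.usage_secondary
        hierarchy = world.hierarchy
        attributes = world.attributes
        ingredient_map = world.ingredient_map
        econ = world.econ_safety
        whitelist: frozenset = frozenset()
        removal_list: frozenset = frozenset()
        write_world_tables(world, corpus, evidence, outdir / "inputs")
    else:
        p = {k: Path(v) for k, v in config.paths.items()}
        corpus = tio.read_table(p["mentions"], tio.MENTIONS)
        usage = tio.frame_to_usage(tio.read_table(p["usage"], tio.USAGE))
        usage_secondary = tio.frame_to_usage(
            tio.read_table(p["usage_secondary"], tio.USAGE),
            drugs=usage.drugs,
            indications=usage.indications,
        )
        from .containers import ConceptHierarchy, DrugAttributeTable

        hier_df = tio.read_table(p["hierarchy"], tio.HIERARCHY)
        hierarchy = ConceptHierarchy(
            list(hier_df.itertuples(index=False, name=None))
        )
        attributes = DrugAttributeTable.from_records(
            tio.read_table(p["attributes"], tio.ATTRIBUTES).itertuples(
                index=False, name=None
            )
        )
        ingredient_map = IngredientMap.from_frame(
            tio.read_table(p["ingredients"], tio.INGREDIENTS)
        )
        reports = tio.read_table(p["reports"], tio.REPORTS)
        literature = tio.read_table(p["literature"], tio.LITERATURE)
        side_effects = tio.read_table(p["side_effects"], tio.SIDE_EFFECTS)
        evidence = EvidenceBundle(
            report_links=frozenset(reports.itertuples(index=False, name=None)),
            literature_links=frozenset(literature.itertuples(index=False, name=None)),
            side_effects=frozenset(side_effects.itertuples(index=False, name=None)),
        )
        ae_df = tio.read_table(p["adverse_events"], tio.ADVERSE_EVENTS)
        cost_df = tio.read_table(p["costs"], tio.COSTS)
        econ = {}
        for d in usage.drugs:
            events = [
                AdverseEvent(r.event, r.severity, r.frequency)
                for r in ae_df[ae_df["drug"] == d].itertuples()
            ]
            costs = list(cost_df[cost_df["drug"] == d]["unit_cost"])
            econ[d] = DrugEconSafetyProfile(events, costs)
        whitelist = _read_pairs(p.get("whitelist"))
        removal_list = _read_pairs(p.get("removal_list"))

    # ---- stage 1: normalize ---------------------------------------------
    drug_vocab = frozenset(usage.drugs)
    ind_vocab = frozenset(usage.indications)
    normalized, rejected, norm_stats = normalize_corpus(
        corpus, ingredient_map, hierarchy, drug_vocab, ind_vocab
    )
    tio.write_table(normalized, outdir / "normalized_mentions.tsv", tio.MENTIONS)

    # ---- stage 2: gold standard -----------------------------------------
    gold = build_gold_standard(
        usage,
        normalized,
        ratio=thr.negative_ratio,
        window=thr.rank_window,
        seed=_subseed(seed, 4),
    )
    train_df, test_df = split(gold, thr.train_fraction, seed=_subseed(seed, 5))
    tio.write_table(gold, outdir / "gold_standard.tsv", tio.LABELED_PAIRS)

    # ---- stage 3: features ----------------------------------------------
    kbs = KnowledgeBases(usage, usage_secondary, attributes)
    test_positives = frozenset(
        (r.drug, r.indication)
        for r in test_df.itertuples()
        if r.label == "positive"
    )
    gold_pairs = [(r.drug, r.indication) for r in gold.itertuples()]
    gold_features, _ = featurize(gold_pairs, normalized, kbs, exclude=test_positives)
    gold_features = gold_features.merge(
        gold, on=["drug", "indication"], how="left"
    )
    _write_features(gold_features, outdir / "gold_features.tsv")

    train_feat = gold_features.merge(
        train_df[["drug", "indication"]], on=["drug", "indication"]
    )
    test_feat = gold_features.merge(
        test_df[["drug", "indication"]], on=["drug", "indication"]
    )

    # ---- stage 4: classifier --------------------------------------------
    results = UsedToTreatModel.from_dataframe(train_feat).fit(
        folds=thr.cv_folds, seed=_subseed(seed, 6)
    )
    results.save(outdir / "model.pkl")
    test_labels = (test_feat["label"] == "positive").astype(int).to_numpy()
    report = results.evaluate(test_feat, test_labels, threshold=0.5)
    evaluation = {"feature_set": "all", "threshold": 0.5, **report.as_dict()}
    pd.DataFrame([evaluation]).to_csv(outdir / "evaluation.tsv", sep="\t", index=False)

    ablation_df = None
    if config.ablation:
        ablation_df = ablate(
            train_feat, test_feat, ABLATION_ROWS,
            folds=thr.cv_folds, seed=_subseed(seed, 6),
        )
        ablation_df.to_csv(outdir / "ablation.tsv", sep="\t", index=False)

    # ---- stage 5: predict all pairs -------------------------------------
    # The final model is trained on the whole gold standard with the full
    # knowledge bases: the test-usage exclusion above exists only to keep
    # the hold-out evaluation honest, and predictions on all pairs use
    # full-KB features, so the final training features must match.
    gold_features_full, _ = featurize(gold_pairs, normalized, kbs)
    gold_features_full = gold_features_full.merge(
        gold, on=["drug", "indication"], how="left"
    )
    final = UsedToTreatModel.from_dataframe(gold_features_full).fit(
        folds=thr.cv_folds, seed=_subseed(seed, 7)
    )
    all_pairs = [(d, i) for d in usage.drugs for i in usage.indications]
    all_features, _ = featurize(all_pairs, normalized, kbs)
    predictions = final.predict(all_features, threshold=thr.probability)
    predictions.to_csv(
        outdir / "predictions.tsv", sep="\t", index=False,
        float_format="%.10g",
    )
    flagged = [
        (r.drug, r.indication) for r in predictions[predictions["flag"]].itertuples()
    ]

    # ---- stage 6: filter cascade ----------------------------------------
    usage_union = usage.union(usage_secondary)
    survivors, ledger = run_cascade(
        flagged,
        evidence,
        usage_union,
        hierarchy,
        FilterConfig(thr.report_support, thr.literature_support),
        whitelist=whitelist,
        removal_list=removal_list,
    )
    ledger_frame = ledger.to_frame()
    ledger_frame.to_csv(outdir / "ledger.tsv", sep="\t", index=False)
    ledger.removals_frame().to_csv(outdir / "removals.tsv", sep="\t", index=False)

    # ---- stage 7: triage -------------------------------------------------
    risk = risk_index(econ, config.severity_weights, config.frequency_probs)
    cost = cost_index(econ)
    report_counts = _support_counts(evidence.report_links)
    article_counts = _support_counts(evidence.literature_links)
    if len(survivors) >= 4:
        triage = bin_usages(
            survivors, risk, cost, report_counts, article_counts,
            thr.lower_quantile, thr.upper_quantile,
        )
    else:
        triage = pd.DataFrame(
            [
                {
                    "drug": d,
                    "indication": i,
                    "report_support": report_counts.get((d, i), 0),
                    "literature_support": article_counts.get((d, i), 0),
                    "risk_index": risk.get(d),
                    "cost_index": cost.get(d),
                    "bin": "other",
                    "missing_index": False,
                }
                for d, i in survivors
            ],
            columns=[
                "drug", "indication", "report_support", "literature_support",
                "risk_index", "cost_index", "bin", "missing_index",
            ],
        )
    triage.to_csv(outdir / "triage.tsv", sep="\t", index=False, float_format="%.10g")

    # ---- manifest ---------------------------------------------------------
    funnel = [
        {"stage": "all-pairs", "count": len(all_pairs)},
        {"stage": "flagged", "count": len(flagged)},
    ] + [
        {"stage": s["stage"], "count": s["n_pass"]}
        for s in ledger_frame.to_dict("records")
    ]
    manifest = {
        "config_digest": config.digest(),
        "seed": seed,
        "n_patients": config.n_patients,
        "normalization": norm_stats,
        "gold": {
            "positives": int((gold["label"] == "positive").sum()),
            "negatives": int((gold["label"] == "negative").sum()),
            "train": len(train_df),
            "test": len(test_df),
        },
        "classifier": {
            "cost": results.cost,
            "gamma": results.gamma,
            "evaluation": evaluation,
        },
        "funnel": funnel,
        "survivors": len(survivors),
        "triage_bins": triage["bin"].value_counts().to_dict() if len(triage) else {},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return PipelineRun(
        outdir=outdir,
        config=config,
        world=world,
        evaluation=evaluation,
        ablation=ablation_df,
        predictions=predictions,
        survivors=survivors,
        ledger_frame=ledger_frame,
        triage=triage,
        manifest=manifest,
    )


def _read_pairs(path: Path | None) -> frozenset:
    if path is None:
        return frozenset()
    df = tio.read_table(path, tio.PAIRS)
    return frozenset((r.drug, r.indication) for r in df.itertuples())


def _write_features(features: pd.DataFrame, path: Path) -> None:
    cols = ["drug", "indication"] + [
        c for c in features.columns
        if c in FEATURE_NAMES or c in NAIVE_FEATURES or c in ("label", "origin")
    ]
    features[cols].to_csv(path, sep="\t", index=False, float_format="%.10g")


def report(run_dir: str | Path) -> str:
    """Human-readable funnel and metric summary for a completed run."""
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"missing artifact: {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    lines = [
        "Off-label usage detection run",
        "=" * 40,
        f"config digest : {manifest['config_digest']}",
        f"seed          : {manifest['seed']}",
        f"patients      : {manifest['n_patients']}",
        "",
        "candidate funnel:",
    ]
    for item in manifest["funnel"]:
        lines.append(f"  {item['stage']:<20} {item['count']:>8}")
    ev = manifest["classifier"]["evaluation"]
    lines += [
        "",
        "hold-out evaluation (threshold 0.5):",
        f"  PPV {ev['ppv']:.3f}  specificity {ev['specificity']:.3f}  "
        f"sensitivity {ev['sensitivity']:.3f}  F1 {ev['f1']:.3f}",
    ]
    ablation_path = run_dir / "ablation.tsv"
    if ablation_path.exists():
        abl = pd.read_csv(ablation_path, sep="\t")
        lines += ["", "feature ablation (threshold 0.5):", abl.to_string(index=False)]
    lines += ["", f"surviving novel usages: {manifest['survivors']}"]
    if manifest.get("triage_bins"):
        lines.append(f"triage bins: {manifest['triage_bins']}")
    return "\n".join(lines)
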