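"""End-to-end pipeline driver: simulate/load -> preprocess -> explore
-> baselines -> Bayesian network -> rules -> validate -> report.

Every stage persists its artifact as a plain file (CSV/JSON/DOT) under
the output directory, with a manifest recording the config, seeds and
stage products, so a run is reproducible and each stage independently
inspectable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .baselines import (
    SplitSpec,
    default_classifiers,
    default_regressors,
    fit_classifiers,
    fit_regressors,
    leaderboard,
    split_dataset,
)
from .bayesnet import (
    BayesNet,
    ConstraintSet,
    asina_constraints,
    fit_cpts,
    learn_structure_hillclimb,
    predict_class,
)
from .eda import association_matrix, mapper_graph, skewness
from .metrics import MetricsReport, classification_metrics
from .preprocessing import (
    BinnedDataset,
    FINAL_CATEGORICAL,
    FINAL_NUMERIC,
    OneHotMap,
    apply_bins,
    finalize_features,
    fit_quantile_bins,
    interpolate_strata,
    iterative_impute,
    smote_oversample,
)
from .rules import (
    ExtractionLog,
    enumerate_rules,
    filter_rules,
    format_rule,
    merge_over,
    rules_to_frame,
    rules_to_json,
)
from .schema import Dataset, read_dataset, write_dataset
from .synthetic import GeneratorConfig, generate_dataset


@dataclass
class RunConfig:
    """Pipeline configuration with one explicit seed per stochastic
    stage."""

    source: str = "synthetic"  # "synthetic" or a file path
    generator_seed: int = 42
    impute_seed: int = 1
    split_seed: int = 2
    smote_seed: int = 3
    model_seed: int = 4
    structure_seed: int = 5
    train_fraction: float = 0.8
    score: str = "bdeu"
    ess: float = 1.0
    max_parents: int = 6
    pseudocount: float = 0.5
    smote_for_bn: bool = True
    run_mapper: bool = True
    run_baselines: bool = True
    rule_top_k: int = 5
    output_dir: str = "nanohazard_run"

    KNOWN = None  # filled after class creation

    @classmethod
    def from_dict(cls, obj: Mapping) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(obj) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**obj)

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)


def _hash(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def _with_viability(final: Dataset, viability: pd.Series) -> Dataset:
    df = final.frame.copy()
    df["viability"] = viability.to_numpy()
    roles = dict(final.roles)
    roles["viability"] = "dropped"
    return Dataset(df, roles)


def _strip_dropped(ds: Dataset) -> pd.DataFrame:
    keep = [c for c in ds.frame.columns if ds.roles.get(c) != "dropped"]
    return ds.frame[keep]


def _binned_with_states(frame: pd.DataFrame, dmap, cat_states: dict) -> BinnedDataset:
    binned = apply_bins(frame, dmap)
    for col, states in cat_states.items():
        if col in binned.states:
            binned.states[col] = list(states)
    return binned


def bn_test_metrics(bn: BayesNet, binned_test: BinnedDataset,
                    outcome: str = "hazard") -> MetricsReport:
    """Classify every test record with the network's posterior argmax
    and score with the shared classification metric suite."""
    inputs = [c for c in binned_test.frame.columns if c != outcome]
    preds = [
        predict_class(bn, {c: row[c] for c in inputs}, target=outcome)
        for _, row in binned_test.frame.iterrows()
    ]
    return classification_metrics(
        binned_test.frame[outcome], preds, classes=bn.states[outcome]
    )


def compare_structures(
    binned_train: BinnedDataset,
    binned_test: BinnedDataset,
    constraints: ConstraintSet,
    score: str = "bdeu",
    ess: float = 1.0,
    max_parents: int = 6,
    pseudocount: float = 0.5,
    seed: int = 0,
) -> dict:
    """Learn constrained and unconstrained structures on the same
    training data, fit CPTs, and validate both on the same test rows."""
    out = {}
    for label, cons in (("constrained", constraints), ("unconstrained", None)):
        struct = learn_structure_hillclimb(
            binned_train, score=score, constraints=cons,
            max_parents=max_parents, ess=ess, seed=seed,
        )
        bn = fit_cpts(struct, binned_train, pseudocount=pseudocount)
        out[label] = {
            "bn": bn,
            "train_score": struct.score,
            "metrics": bn_test_metrics(bn, binned_test),
        }
    return out


def run_pipeline(config: RunConfig, generator: GeneratorConfig | None = None) -> dict:
    """Execute every stage in order and persist the artifacts.

    Returns the manifest (also written to ``manifest.json``).
    Re-running with the same config reproduces identical JSON outputs.
    """
    cfg = config
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": json.loads(cfg.to_json()),
        "config_hash": _hash(cfg.to_json()),
        "stages": {},
    }

    def record(stage: str, path: Path | None, **extra):
        manifest["stages"][stage] = {
            "artifact": str(path.name) if path else None, **extra
        }

    # 1. simulate / load
    if cfg.source == "synthetic":
        gen = generator or GeneratorConfig(seed=cfg.generator_seed)
        dataset = generate_dataset(gen)
    else:
        dataset = read_dataset(cfg.source)
    raw_path = outdir / "dataset_raw.csv"
    write_dataset(dataset, raw_path)
    record("simulate", raw_path, rows=len(dataset))

    # 2. preprocess: interpolate, impute, finalize
    interp = interpolate_strata(dataset)
    imputed = iterative_impute(interp, seed=cfg.impute_seed)
    imp_path = outdir / "dataset_imputed.csv"
    write_dataset(imputed, imp_path)
    final = finalize_features(imputed)
    modeling = _with_viability(final, imputed.frame["viability"])
    record(
        "preprocess", imp_path, rows=len(imputed),
        imputed_cells=int(dataset.frame.isna().sum().sum()),
    )

    # 3. explore
    assoc = association_matrix(final)
    assoc_path = outdir / "association_matrix.csv"
    assoc.to_csv(assoc_path)
    skew = {c: skewness(final.frame[c]) for c in FINAL_NUMERIC}
    (outdir / "skewness.json").write_text(json.dumps(skew, indent=2, sort_keys=True))
    if cfg.run_mapper:
        mg = mapper_graph(
            final.frame[FINAL_NUMERIC].to_numpy(dtype=float),
            lens=imputed.frame["viability"].to_numpy(dtype=float),
            n_intervals=8,
            overlap=0.3,
            linkage_threshold=0.6,
        )
        (outdir / "mapper.dot").write_text(mg.to_dot())
    record("eda", assoc_path, mapper=cfg.run_mapper)

    # 4. split and discretize
    train, test = split_dataset(modeling, SplitSpec(cfg.train_fraction, True, cfg.split_seed))
    dmap = fit_quantile_bins(_strip_dropped(train), columns=FINAL_NUMERIC)
    dmap_path = outdir / "discretization_map.json"
    dmap_path.write_text(dmap.to_json())
    cat_states = {
        c: sorted(modeling.frame[c].astype(str).unique())
        for c in FINAL_CATEGORICAL + ["hazard"]
    }
    record("discretize", dmap_path, train_rows=len(train), test_rows=len(test))

    # 5. baselines
    if cfg.run_baselines:
        enc = OneHotMap.fit(modeling.frame, FINAL_CATEGORICAL)
        Xtr = enc.transform(train.frame[FINAL_NUMERIC + FINAL_CATEGORICAL])
        Xte = enc.transform(test.frame[FINAL_NUMERIC + FINAL_CATEGORICAL])
        reg = fit_regressors(
            Xtr, train.frame["viability"], Xte, test.frame["viability"],
            default_regressors(cfg.model_seed), seed=cfg.model_seed,
        )
        clf = fit_classifiers(
            Xtr, train.frame["hazard"], Xte, test.frame["hazard"],
            default_classifiers(cfg.model_seed),
            smote=True, smote_seed=cfg.smote_seed, seed=cfg.model_seed,
        )
        board = pd.concat(
            [leaderboard(reg).assign(task="regression"),
             leaderboard(clf).assign(task="classification")],
            ignore_index=True,
        )
        board_path = outdir / "baseline_leaderboard.csv"
        board.to_csv(board_path, index=False)
        record("baselines", board_path, models=sorted(reg) + sorted(clf))
    else:
        record("baselines", None, skipped=True)

    # 6. Bayesian network (constrained vs unconstrained)
    train_features = train.frame[FINAL_NUMERIC + FINAL_CATEGORICAL + ["hazard"]]
    if cfg.smote_for_bn:
        enc_bn = OneHotMap.fit(modeling.frame, FINAL_CATEGORICAL)
        Xs, ys = smote_oversample(
            enc_bn.transform(train_features.drop(columns=["hazard"])),
            train_features["hazard"],
            seed=cfg.smote_seed,
        )
        bn_train_frame = enc_bn.inverse(Xs)
        bn_train_frame["hazard"] = ys.to_numpy()
    else:
        bn_train_frame = train_features.copy()
    binned_train = _binned_with_states(bn_train_frame, dmap, cat_states)
    binned_test = _binned_with_states(
        test.frame[FINAL_NUMERIC + FINAL_CATEGORICAL + ["hazard"]], dmap, cat_states
    )
    constraints = asina_constraints(nodes=list(binned_train.frame.columns))
    comparison = compare_structures(
        binned_train, binned_test, constraints,
        score=cfg.score, ess=cfg.ess, max_parents=cfg.max_parents,
        pseudocount=cfg.pseudocount, seed=cfg.structure_seed,
    )
    bn = comparison["constrained"]["bn"]
    (outdir / "bn_constrained.dot").write_text(bn.to_dot())
    (outdir / "bn_unconstrained.dot").write_text(
        comparison["unconstrained"]["bn"].to_dot()
    )
    (outdir / "bn_constrained_cpts.json").write_text(bn.cpts_json())
    record(
        "bn", outdir / "bn_constrained.dot",
        constrained_score=comparison["constrained"]["train_score"],
        unconstrained_score=comparison["unconstrained"]["train_score"],
        smote_rows=len(binned_train),
    )

    # 7. rules
    log = ExtractionLog()
    rules = enumerate_rules(bn, target="hazard", data=binned_train, log=log)
    rules_path = outdir / "rules.json"
    rules_path.write_text(rules_to_json(rules))
    rules_to_frame(rules).to_csv(outdir / "rules.csv", index=False)
    top_lines = []
    for cls in bn.states["hazard"]:
        for r in filter_rules(
            merge_over([x for x in rules if x.consequent == cls], "dose"),
            cls, cfg.rule_top_k,
        ):
            top_lines.append(format_rule(r, dmap))
    (outdir / "rules_top.txt").write_text("\n".join(top_lines) + "\n")
    record(
        "rules", rules_path, n_rules=len(rules), n_configs=log.n_configs,
        zero_probability_configs=log.zero_probability_configs,
        discarded_infinite_cf=log.discarded_infinite_cf,
    )

    # 8. validate + report
    validation = {
        label: {
            "train_score": comparison[label]["train_score"],
            **comparison[label]["metrics"].to_dict(),
        }
        for label in ("constrained", "unconstrained")
    }
    val_path = outdir / "validation.json"
    val_path.write_text(json.dumps(validation, indent=2, sort_keys=True))
    record("validate", val_path,
           constrained_balanced_accuracy=validation["constrained"]["balanced_accuracy"])

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
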