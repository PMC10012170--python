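import numpy as np
import pandas as pd
import pytest

from nanohazard.baselines import SplitSpec, split_dataset
from nanohazard.pipeline import (
    _binned_with_states,
    _strip_dropped,
    _with_viability,
)
from nanohazard.preprocessing import (
    FINAL_CATEGORICAL,
    FINAL_NUMERIC,
    finalize_features,
    fit_quantile_bins,
    interpolate_strata,
    iterative_impute,
)
from nanohazard.synthetic import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The generator's default 900-row study design (seed 42)."""
    return generate_dataset(GeneratorConfig(seed=42))


@pytest.fixture(scope="session")
def small_dataset():
    """A small, fully observed table for fast unit tests."""
    cfg = GeneratorConfig(
        seed=7,
        dose_grid=(0.1, 1.0, 10.0, 50.0, 100.0),
        replicates=2,
        missing_rates={},
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def prepared_split(default_dataset):
    """Imputed, finalized, stratified-split view of the default data,
    with fitted tercile bins and binned train/test tables."""
    imputed = iterative_impute(interpolate_strata(default_dataset), seed=1)
    final = finalize_features(imputed)
    modeling = _with_viability(final, imputed.frame["viability"])
    train, test = split_dataset(modeling, SplitSpec(0.8, True, 2))
    dmap = fit_quantile_bins(_strip_dropped(train), columns=FINAL_NUMERIC)
    cat_states = {
        c: sorted(modeling.frame[c].astype(str).unique())
        for c in FINAL_CATEGORICAL + ["hazard"]
    }
    cols = FINAL_NUMERIC + FINAL_CATEGORICAL + ["hazard"]
    binned_train = _binned_with_states(train.frame[cols], dmap, cat_states)
    binned_test = _binned_with_states(test.frame[cols], dmap, cat_states)
    return {
        "imputed": imputed,
        "modeling": modeling,
        "train": train,
        "test": test,
        "dmap": dmap,
        "binned_train": binned_train,
        "binned_test": binned_test,
        "cat_states": cat_states,
    }


@pytest.fixture(scope="session")
def trained_bn(prepared_split):
    """Constrained network trained as the pipeline trains it: SMOTE on
    the training split, hill climbing under the expert constraints
    (6-parent limit), CPTs smoothed with pseudocount 0.5."""
    from nanohazard.bayesnet import asina_constraints, fit_cpts, learn_structure_hillclimb
    from nanohazard.preprocessing import OneHotMap, smote_oversample

    train = prepared_split["train"]
    modeling = prepared_split["modeling"]
    dmap = prepared_split["dmap"]
    cols = FINAL_NUMERIC + FINAL_CATEGORICAL
    enc = OneHotMap.fit(modeling.frame, FINAL_CATEGORICAL)
    Xs, ys = smote_oversample(
        enc.transform(train.frame[cols]), train.frame["hazard"], seed=3
    )
    frame = enc.inverse(Xs)
    frame["hazard"] = ys.to_numpy()
    binned = _binned_with_states(frame, dmap, prepared_split["cat_states"])
    cons = asina_constraints()
    struct = learn_structure_hillclimb(binned, constraints=cons, max_parents=6)
    bn = fit_cpts(struct, binned, pseudocount=0.5)
    return {"bn": bn, "binned_smote_train": binned, "constraints": cons}
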