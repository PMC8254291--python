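"""Reference synthetic study: one assay, directional QSAR test, mixin scan.

This module fixes the study conditions used throughout the package's
analyses: a multi-series Free-Wilson assay of 110 independent 2x2 blocks
(440 compounds, 110 designed double-transformation cycles), 10% of the
series carrying one interaction term of 2.0 log units, and measurement
noise of 0.3 log units. On that assay it runs

* the *directional* experiment — a regressor trained on additive compounds
  only, evaluated on the additive hold-out versus the nonadditive hold-out —
  and
* the *mixin* experiment — blending 0.6% / 1.3% / 2.6% nonadditive
  compounds into training and scoring the dichotomized additive test by MCC.

The hyperparameter search here uses a deliberately compact random-forest
space and a small trial budget; spaces and budgets are arguments, so the
full-width search in :mod:`nadd.mlstudy` remains available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import randint

from . import mlstudy, pipeline, simulate

# study conditions (see docs/methods.md)
N_SERIES = 110
INJECTED_FRACTION = 0.10
DELTA = 2.0
SIGMA = 0.3

#: compact RF space used by the study drivers
FAST_RF_SPACE = {
    "n_estimators": randint(100, 300),
    "max_depth": [None, 10, 20],
    "max_features": ["sqrt", 0.3],
}
FAST_BUDGET = 4
CV_FOLDS = 5


@dataclass
class StudyAssay:
    labeled: list[mlstudy.LabeledCompound]
    cycles: list
    pacts: dict[str, float]
    X: np.ndarray
    index: dict[str, int]
    result: pipeline.AssayResult = None
    truths: list = field(default_factory=list)

    def xy(self, ids):
        rows = [self.index[c] for c in ids]
        return self.X[rows], np.array([self.pacts[c] for c in ids])


def build_study_assay(
    seed: int,
    n_series: int = N_SERIES,
    injected_fraction: float = INJECTED_FRACTION,
    delta: float = DELTA,
    sigma: float = SIGMA,
    n_bits: int = 2048,
) -> StudyAssay:
    """Generate, curate and analyze the synthetic study assay end to end."""
    rng = np.random.default_rng(seed)
    mols, truths = simulate.sample_series_library(
        n_series, rng, injected_fraction=injected_fraction, delta=delta)
    records = simulate.measure(
        mols, simulate.MeasurementSpec(sigma=sigma, seed=seed + 1), assay_id="STUDY")
    res = pipeline.analyze_assay(records, pipeline.PipelineConfig(sigma_exp=sigma))
    if res.assay is None:
        raise RuntimeError("study assay did not survive curation")
    compounds = {e.compound_id: (e.smiles, e.pact) for e in res.assay.entries}
    labeled = mlstudy.label_compounds(res.profiles, compounds)
    ids = sorted(compounds)
    X = mlstudy.featurize([compounds[c][0] for c in ids], n_bits=n_bits)
    return StudyAssay(
        labeled=labeled,
        cycles=res.cycles,
        pacts={c: compounds[c][1] for c in ids},
        X=X,
        index={c: i for i, c in enumerate(ids)},
        result=res,
        truths=truths,
    )


def train_and_evaluate(
    assay: StudyAssay,
    train_ids: list[str],
    test_sets: dict[str, list[str]],
    seed: int,
    algorithm: str = "random_forest",
    budget: int = FAST_BUDGET,
) -> mlstudy.EvalReport:
    Xtr, ytr = assay.xy(train_ids)
    space = FAST_RF_SPACE if algorithm == "random_forest" else None
    model = mlstudy.train_model(Xtr, ytr, algorithm, budget=budget,
                                folds=CV_FOLDS, seed=seed, search_space=space)
    return mlstudy.evaluate(
        model.best_estimator_,
        {name: assay.xy(ids) for name, ids in test_sets.items()},
        r2_train_cv=float(model.best_score_),
    )


def directional_experiment(
    assay: StudyAssay, seeds: tuple[int, ...] = (0, 1, 2, 3, 4),
    strategy: str = "dtc_split",
) -> pd.DataFrame:
    """Additive-trained model scored on additive vs nonadditive hold-outs."""
    rows = []
    for seed in seeds:
        split = mlstudy.make_split(assay.labeled, mlstudy.SplitSpec(strategy, seed=seed),
                                   assay.cycles)
        rep = train_and_evaluate(assay, split.train, split.test_sets, seed)
        add = rep.per_set.get("additive") or rep.per_set.get("additive_ab")
        na = rep.per_set.get("nonadditive") or rep.per_set.get("nonadditive_ab")
        rows.append({
            "seed": seed, "cv_r2": rep.r2_train_cv,
            "r2_additive": add.r2, "rmse_additive": add.rmse, "mcc_additive": add.mcc,
            "r2_nonadditive": na.r2, "rmse_nonadditive": na.rmse,
        })
    return pd.DataFrame(rows)


def mixin_experiment(
    assay: StudyAssay,
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4),
    fractions: dict[str, float] | None = None,
) -> pd.DataFrame:
    """MCC on the fixed additive test set for each mixin fraction and seed.

    For a given seed the additive test set and the NA hold-out are identical
    across fractions, so rows are directly comparable.
    """
    fractions = dict(fractions or {"Q0": 0.0, **mlstudy.MIXIN_FRACTIONS})
    na_pool = sorted(c.compound_id for c in assay.labeled if c.na_label == "nonadditive")
    rows = []
    for seed in seeds:
        split = mlstudy.make_split(assay.labeled, mlstudy.SplitSpec("dtc_split", seed=seed))
        for name, frac in fractions.items():
            train_ids, holdout = mlstudy.mixin(split.train, na_pool, frac, seed, assay.pacts)
            rep = train_and_evaluate(
                assay, train_ids,
                {"additive": split.test_sets["additive"], "na_holdout": holdout},
                seed,
            )
            m = rep.per_set["additive"]
            h = rep.per_set["na_holdout"]
            rows.append({
                "seed": seed, "fraction_name": name, "fraction": frac,
                "n_train": len(train_ids),
                "mcc_additive": m.mcc, "r2_additive": m.r2, "rmse_additive": m.rmse,
                "r2_holdout": h.r2, "rmse_holdout": h.rmse, "mcc_holdout": h.mcc,
            })
    return pd.DataFrame(rows)


def mixin_flatness(mixin_df: pd.DataFrame) -> dict:
    """Summarize the mixin scan: per-fraction mean MCC shift vs the Q0 model.

    Returns the largest |mean paired MCC difference| across nonzero
    fractions and the across-seed standard deviation of those differences;
    the shift is called flat when the former does not exceed the latter.
    """
    wide = mixin_df.pivot(index="seed", columns="fraction_name", values="mcc_additive")
    deltas = wide.drop(columns="Q0").sub(wide["Q0"], axis=0)
    max_abs_mean = float(deltas.mean().abs().max())
    std = float(deltas.stack().std(ddof=1))
    return {
        "max_abs_mean_delta_mcc": max_abs_mean,
        "across_seed_std": std,
        "flat": bool(max_abs_mean <= std + 1e-12),
    }
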