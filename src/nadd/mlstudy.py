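"""Additivity-aware QSAR study: splits, fingerprints, models, evaluation.

The study asks how regression models behave on compounds whose SAR is
nonadditive. Compounds are labelled from the per-compound nonadditivity
profiles (additive / nonadditive / no_dtc), split by one of three
strategies, featurized as ECFP6-style substructure counts (Morgan radius 3,
folded counts), and modelled with random forest, RBF-SVM or PLS regression
under randomized hyperparameter search with cross-validation. Evaluation
reports R^2 and RMSE on each test set plus a dichotomized view (active at
pActivity > 5) scored with the Matthews correlation coefficient.

Split strategies:

* ``dtc_split`` — only compounds occurring in DTCs; additive ones are
  stratified 80/20 into train / additive-test, nonadditive ones form an
  NA hold-out that is never trained on.
* ``all_split`` — as above but compounds without DTC membership are assumed
  additive and pooled in.
* ``ab_split`` — leverages cycle structure: singly-transformed corners (the
  A and B compounds, plus the parent) go to training, doubly-transformed
  corners (AB) to test, assigned greedily from a seed-chosen starting
  compound; the AB test set is reported separately for its additive and
  nonadditive members.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from scipy.stats import loguniform, randint
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import confusion_matrix, matthews_corrcoef, r2_score
from sklearn.model_selection import KFold, RandomizedSearchCV, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .cycles import AssayNASummary, CompoundNAProfile, DoubleTransformationCycle

ACTIVITY_CLASS_THRESHOLD = 5.0  # pActivity; class 1 iff pact > 5


@dataclass(frozen=True)
class LabeledCompound:
    compound_id: str
    smiles: str
    pact: float
    na_label: str          # additive | nonadditive | no_dtc
    in_dtc: bool


@dataclass(frozen=True)
class SplitSpec:
    strategy: str                  # dtc_split | all_split | ab_split
    seed: int
    train_fraction: float = 0.8
    include_non_dtc: bool = False


@dataclass
class DataSplit:
    train: list[str]
    test_sets: dict[str, list[str]] = field(default_factory=dict)

    def validate(self) -> None:
        train = set(self.train)
        for name, ids in self.test_sets.items():
            overlap = train & set(ids)
            if overlap:
                raise RuntimeError(f"train/test overlap in {name}: {sorted(overlap)[:5]}")


def label_compounds(
    profiles: Sequence[CompoundNAProfile],
    compounds: Mapping[str, tuple[str, float]],
) -> list[LabeledCompound]:
    """Attach additive/nonadditive/no_dtc labels to ``{id: (smiles, pact)}``."""
    by_id = {p.compound_id: p for p in profiles}
    out = []
    for cid in sorted(compounds):
        smiles, pact = compounds[cid]
        p = by_id.get(cid)
        if p is None:
            label, in_dtc = "no_dtc", False
        elif p.significant:
            label, in_dtc = "nonadditive", True
        else:
            label, in_dtc = "additive", True
        out.append(LabeledCompound(cid, smiles, pact, label, in_dtc))
    return out


def select_assays(summaries: Iterable[AssayNASummary],
                  min_compounds: int = 200, min_cycles: int = 25) -> list[str]:
    """Assays eligible for QSAR modelling: NA output present, > 200 compounds,
    > 25 double-transformation cycles."""
    return [s.assay_id for s in summaries
            if s.n_cycles > min_cycles and s.n_compounds > min_compounds and s.n_cycles >= 1]


# ---------------------------------------------------------------------------
# featurization

def featurize(smiles_list: Sequence[str], n_bits: int = 2048, radius: int = 3) -> np.ndarray:
    """Folded Morgan count fingerprints (ECFP6-style substructure counts)."""
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    X = np.zeros((len(smiles_list), n_bits), dtype=np.float64)
    for i, smi in enumerate(smiles_list):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparseable structure: {smi!r}")
        fp = gen.GetCountFingerprint(mol)
        for bit, count in fp.GetNonzeroElements().items():
            X[i, bit] = count
    return X


def tanimoto_counts(a: np.ndarray, b: np.ndarray) -> float:
    """Count-based (minmax) Tanimoto similarity of two count vectors."""
    denom = np.minimum(a, b).sum(), np.maximum(a, b).sum()
    return float(denom[0] / denom[1]) if denom[1] > 0 else 0.0


def similarity_overlap(X_query: np.ndarray, X_ref: np.ndarray,
                       same_set: bool = False) -> np.ndarray:
    """Per-query max Tanimoto similarity to the reference set, self excluded.

    With ``same_set=True`` the i-th query is compared against all reference
    rows except index i. An empty effective reference yields NaN.
    """
    mins = None
    out = np.full(len(X_query), np.nan)
    for i, q in enumerate(X_query):
        sims = []
        for j, r in enumerate(X_ref):
            if same_set and i == j:
                continue
            sims.append(tanimoto_counts(q, r))
        if sims:
            out[i] = max(sims)
    return out


# ---------------------------------------------------------------------------
# splitting

def _stratify_bins(pacts: Sequence[float], n_bins: int = 10) -> np.ndarray:
    """Pact-decile labels for stratified splitting (degenerate bins merged)."""
    s = pd.Series(pacts)
    try:
        bins = pd.qcut(s, q=n_bins, labels=False, duplicates="drop")
    except ValueError:
        return np.zeros(len(s), dtype=int)
    # merge singleton strata so sklearn's stratified splitter accepts them
    counts = bins.value_counts()
    lonely = counts[counts < 2].index
    if len(lonely):
        bins = bins.replace({b: -1 for b in lonely})
    return bins.to_numpy()


def _stratified_80_20(ids: list[str], pacts: Mapping[str, float],
                      seed: int, train_fraction: float) -> tuple[list[str], list[str]]:
    strata = _stratify_bins([pacts[c] for c in ids])
    train, test = train_test_split(
        ids, train_size=train_fraction, random_state=seed,
        stratify=strata if len(set(strata)) > 1 else None, shuffle=True,
    )
    return sorted(train), sorted(test)


def make_split(
    compounds: Sequence[LabeledCompound],
    spec: SplitSpec,
    cycles: Sequence[DoubleTransformationCycle] | None = None,
) -> DataSplit:
    """Build train/test compound-id sets for one strategy (see module doc)."""
    pacts = {c.compound_id: c.pact for c in compounds}
    additive = sorted(c.compound_id for c in compounds if c.na_label == "additive")
    nonadditive = sorted(c.compound_id for c in compounds if c.na_label == "nonadditive")
    no_dtc = sorted(c.compound_id for c in compounds if c.na_label == "no_dtc")

    if spec.strategy == "dtc_split":
        train, add_test = _stratified_80_20(additive, pacts, spec.seed, spec.train_fraction)
        split = DataSplit(train, {"additive": add_test, "nonadditive": nonadditive})
    elif spec.strategy == "all_split":
        pool = sorted(additive + no_dtc)
        train, add_test = _stratified_80_20(pool, pacts, spec.seed, spec.train_fraction)
        split = DataSplit(train, {"additive": add_test, "nonadditive": nonadditive})
    elif spec.strategy == "ab_split":
        if cycles is None:
            raise ValueError("ab_split requires the cycle list")
        split = _ab_split(compounds, cycles, spec)
    else:
        raise ValueError(f"unknown strategy {spec.strategy!r}")
    split.validate()
    return split


def _ab_split(
    compounds: Sequence[LabeledCompound],
    cycles: Sequence[DoubleTransformationCycle],
    spec: SplitSpec,
) -> DataSplit:
    """Greedy A-B-AB assignment over cycles from a seeded starting compound.

    Per cycle, corners c1 (parent), c2 and c4 (single transformations) are
    training candidates and c3 (the doubly-transformed AB compound) a test
    candidate. Cycles are visited in a seed-shuffled order beginning with the
    cycles of a randomly chosen starting compound; once a compound holds a
    role it keeps it, and cycles that would conflict are skipped.
    """
    rng = np.random.default_rng(spec.seed)
    labels = {c.compound_id: c.na_label for c in compounds}
    pacts = {c.compound_id: c.pact for c in compounds}
    order = list(cycles)
    rng.shuffle(order)
    members = sorted({cid for cyc in cycles for cid in cyc.compounds})
    start = members[rng.integers(len(members))]
    order.sort(key=lambda cyc: 0 if start in cyc.compounds else 1)

    role: dict[str, str] = {}
    for cyc in order:
        c1, c2, c3, c4 = cyc.compounds
        wanted = {c1: "train", c2: "train", c4: "train", c3: "test"}
        if any(role.get(cid, w) != w for cid, w in wanted.items()):
            continue
        role.update(wanted)

    train = sorted(c for c, r in role.items() if r == "train")
    ab_test = sorted(c for c, r in role.items() if r == "test")
    add_ab = [c for c in ab_test if labels.get(c) == "additive"]
    na_ab = [c for c in ab_test if labels.get(c) == "nonadditive"]
    remaining_na = sorted(
        c.compound_id for c in compounds
        if c.na_label == "nonadditive" and c.compound_id not in role
    )
    test_sets = {"additive_ab": add_ab, "nonadditive_ab": na_ab,
                 "nonadditive_rest": remaining_na}
    if spec.include_non_dtc:
        no_dtc = sorted(c.compound_id for c in compounds if c.na_label == "no_dtc")
        if len(no_dtc) >= 5:
            extra_train, extra_test = _stratified_80_20(
                no_dtc, pacts, spec.seed, spec.train_fraction)
        else:
            extra_train, extra_test = no_dtc, []
        train = sorted(train + extra_train)
        test_sets["non_dtc"] = extra_test
    return DataSplit(train, test_sets)


# ---------------------------------------------------------------------------
# models

def _search_space(algorithm: str, n_samples: int, n_features: int):
    if algorithm == "random_forest":
        est = RandomForestRegressor(random_state=0, n_jobs=1)
        space = {
            "n_estimators": randint(100, 1000),
            "max_depth": [None, 5, 10, 15, 20, 30],
            "max_features": ["sqrt", "log2", 0.1, 0.3, 0.5],
        }
    elif algorithm == "svm_rbf":
        est = Pipeline([("scale", StandardScaler()), ("svr", SVR(kernel="rbf"))])
        space = {
            "svr__C": loguniform(1e-2, 1e3),
            "svr__gamma": loguniform(1e-4, 1e1),
        }
    elif algorithm == "pls":
        max_comp = max(2, min(50, n_features, n_samples - 1))
        est = Pipeline([("scale", StandardScaler()), ("pls", PLSRegression())])
        space = {"pls__n_components": randint(2, max_comp + 1)}
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    return est, space


def train_model(
    X: np.ndarray,
    y: np.ndarray,
    algorithm: str = "random_forest",
    budget: int = 500,
    folds: int = 5,
    seed: int = 0,
    search_space: dict | None = None,
):
    """Randomized hyperparameter search (CV R^2) followed by a full-train refit.

    ``search_space`` overrides the default hyperparameter distributions
    (which are deliberately wide); the study drivers pass narrower spaces
    with smaller budgets. Returns the fitted search object;
    ``.best_estimator_`` is the final model refit on all training data with
    the best hyperparameters and ``.best_score_`` the mean cross-validated
    R^2.
    """
    y = np.asarray(y, float)
    if len(y) < folds or float(np.var(y)) == 0.0:
        raise ValueError("degenerate training response (too small or zero variance)")
    est, space = _search_space(algorithm, len(y), X.shape[1])
    if search_space is not None:
        space = search_space
    search = RandomizedSearchCV(
        est,
        space,
        n_iter=budget,
        scoring="r2",
        cv=KFold(n_splits=folds, shuffle=True, random_state=seed),
        random_state=seed,
        refit=True,
        n_jobs=1,
        error_score="raise",
    )
    search.fit(X, y)
    return search


# ---------------------------------------------------------------------------
# evaluation

@dataclass
class TestSetMetrics:
    n: int
    r2: float
    rmse: float
    mcc: float                   # NaN when truth has a single class
    mcc_defined: bool
    confusion: np.ndarray        # 2x2, labels (0, 1)


@dataclass
class EvalReport:
    r2_train_cv: float
    per_set: dict[str, TestSetMetrics] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"test_set": name, "n": m.n, "r2": m.r2, "rmse": m.rmse,
             "mcc": m.mcc, "mcc_defined": m.mcc_defined}
            for name, m in self.per_set.items()
        ]
        return pd.DataFrame(rows)


def binarize(pacts: np.ndarray, threshold: float = ACTIVITY_CLASS_THRESHOLD) -> np.ndarray:
    """Class 1 iff pActivity strictly exceeds the threshold (ties -> class 0)."""
    return (np.asarray(pacts) > threshold).astype(int)


def evaluate(model, test_sets: Mapping[str, tuple[np.ndarray, np.ndarray]],
             r2_train_cv: float = float("nan")) -> EvalReport:
    """R^2 / RMSE on continuous predictions plus dichotomized MCC per test set."""
    report = EvalReport(r2_train_cv=r2_train_cv)
    for name, (X, y) in test_sets.items():
        y = np.asarray(y, float)
        if len(y) == 0:
            report.per_set[name] = TestSetMetrics(0, float("nan"), float("nan"),
                                                  float("nan"), False,
                                                  np.zeros((2, 2), int))
            continue
        pred = np.asarray(model.predict(X), float).ravel()
        r2 = r2_score(y, pred) if len(y) >= 2 and np.var(y) > 0 else float("nan")
        rmse = float(np.sqrt(np.mean((y - pred) ** 2)))
        yc, pc = binarize(y), binarize(pred)
        cm = confusion_matrix(yc, pc, labels=[0, 1])
        defined = len(np.unique(yc)) > 1
        mcc = float(matthews_corrcoef(yc, pc)) if defined else float("nan")
        report.per_set[name] = TestSetMetrics(len(y), float(r2), rmse, mcc, defined, cm)
    return report


# ---------------------------------------------------------------------------
# mixin experiments

def stratified_order(ids: Sequence[str], pacts: Mapping[str, float],
                     seed: int, n_bins: int = 10) -> list[str]:
    """Seeded stratified ordering: round-robin over shuffled pact-decile bins.

    Any prefix of the returned ordering is an (approximately) stratified
    draw, so nested prefixes give nested stratified subsets.
    """
    rng = np.random.default_rng(seed)
    ids = list(ids)
    bins = _stratify_bins([pacts[c] for c in ids], n_bins)
    buckets: dict[int, list[str]] = {}
    for cid, b in zip(ids, bins):
        buckets.setdefault(int(b), []).append(cid)
    for b in buckets.values():
        rng.shuffle(b)
    keys = list(buckets)
    rng.shuffle(keys)
    out, k = [], 0
    while any(buckets.values()):
        key = keys[k % len(keys)]
        if buckets[key]:
            out.append(buckets[key].pop())
        k += 1
    return out


MIXIN_FRACTIONS = {"Q1": 0.006, "median": 0.013, "Q3": 0.026}


def mixin(
    train: Sequence[str],
    na_pool: Sequence[str],
    fraction: float,
    seed: int,
    pacts: Mapping[str, float],
    holdout_fraction: float = MIXIN_FRACTIONS["Q3"],
) -> tuple[list[str], list[str]]:
    """Blend a stratified fraction of nonadditive compounds into training.

    ``fraction`` (and the hold-out construction) are relative to the training
    set size. The hold-out is the complement of the largest (Q3) draw and is
    identical across all fractions for a given seed, so every mixin model is
    evaluated on the same compounds. Draws are nested: the Q1 mix is a prefix
    of the median mix is a prefix of the Q3 mix.
    """
    if not 0.0 <= fraction <= holdout_fraction:
        raise ValueError("fraction must lie in [0, holdout_fraction]")
    n_q3 = int(round(holdout_fraction * len(train)))
    n_f = int(round(fraction * len(train)))
    if n_q3 > len(na_pool):
        raise ValueError(
            f"nonadditive pool ({len(na_pool)}) too small for hold-out draw ({n_q3})"
        )
    order = stratified_order(sorted(na_pool), pacts, seed)
    q3_draw = order[:n_q3]
    holdout = sorted(set(na_pool) - set(q3_draw))
    augmented = sorted(list(train) + q3_draw[:n_f])
    return augmented, holdout
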