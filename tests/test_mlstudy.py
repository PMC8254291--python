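"""QSAR study machinery: featurization, splits, models, mixin, similarity."""

import numpy as np
import pytest

from nadd import mlstudy, simulate
from nadd.cycles import AssayNASummary, NoiseModel, assemble_cycles, compound_profiles
from nadd import mmp
from nadd.mlstudy import (
    LabeledCompound,
    SplitSpec,
    binarize,
    evaluate,
    featurize,
    label_compounds,
    make_split,
    mixin,
    select_assays,
    similarity_overlap,
    tanimoto_counts,
    train_model,
)


def summary(assay_id, n_compounds, n_cycles):
    return AssayNASummary(assay_id, n_compounds, 0, n_cycles, 0, 0, 0,
                          0.0, 0.0, 0.0, 0.0, 0.0, 1.0)


class TestSelectAssays:
    def test_three_criteria(self):
        summaries = [
            summary("small", 150, 50),        # too few compounds
            summary("few_cycles", 300, 10),   # too few cycles
            summary("ok", 400, 120),
        ]
        assert select_assays(summaries) == ["ok"]


class TestFeaturize:
    def test_methane_single_environment(self):
        X = featurize(["C"])
        assert X.sum() == 1.0  # one heavy atom, radius-0 environment only

    def test_identical_molecules_identical_vectors(self):
        X = featurize(["CCO", "OCC"])
        assert np.array_equal(X[0], X[1])

    def test_counts_not_bits(self):
        X = featurize(["CCCCCCCC"])
        assert X.max() > 1  # repeated chain environments are counted

    def test_hexane_vs_benzene_distinct(self):
        X = featurize(["CCCCCC", "c1ccccc1"])
        assert not np.array_equal(X[0], X[1])
        assert tanimoto_counts(X[0], X[1]) < 1.0


class TestSimilarityOverlap:
    def test_duplicate_across_sets_gives_unity(self):
        X = featurize(["CCO", "CCN"])
        ref = featurize(["CCO", "c1ccccc1"])
        sims = similarity_overlap(X, ref)
        assert sims[0] == pytest.approx(1.0)

    def test_self_excluded_within_one_set(self):
        X = featurize(["CCO", "CCN", "CCCO"])
        sims = similarity_overlap(X, X, same_set=True)
        assert all(s < 1.0 for s in sims)

    def test_empty_reference_flagged(self):
        X = featurize(["CCO"])
        assert np.isnan(similarity_overlap(X, X, same_set=True)[0])

    def test_mmp_related_set_closer_than_unrelated_decoy_series(self):
        """Nonadditive compounds, being MMP neighbours of the additive set,
        overlap it more than an unrelated decoy series does."""
        spec = simulate.default_library_spec(2, 4)
        mols = simulate.enumerate_library(spec)
        additive = featurize([m.smiles for m in mols[:12]])
        related = featurize([m.smiles for m in mols[12:]])  # same series
        decoy_spec = simulate.FreeWilsonSpec(
            scaffold=simulate._series_core(50),
            sites=(
                simulate.Site(1, (simulate.Substituent("methyl", "C", 0.1),
                                  simulate.Substituent("bromo", "Br", 0.2))),
                simulate.Site(2, (simulate.Substituent("cyano", "C#N", 0.0),
                                  simulate.Substituent("amino", "N", -0.1))),
            ),
            baseline=6.0, series_id="DECOY",
        )
        decoy = featurize([m.smiles for m in simulate.enumerate_library(decoy_spec)])
        rel = np.median(similarity_overlap(related, additive))
        dec = np.median(similarity_overlap(decoy, additive))
        assert rel > dec


def toy_compounds(n_add=100, n_na=20, n_free=30, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_add):
        out.append(LabeledCompound(f"a{i:03d}", "CCO", float(rng.uniform(4, 9)),
                                   "additive", True))
    for i in range(n_na):
        out.append(LabeledCompound(f"n{i:03d}", "CCN", float(rng.uniform(4, 9)),
                                   "nonadditive", True))
    for i in range(n_free):
        out.append(LabeledCompound(f"f{i:03d}", "CCC", float(rng.uniform(4, 9)),
                                   "no_dtc", False))
    return out


class TestMakeSplit:
    def test_dtc_split_sizes_and_holdout(self):
        comps = toy_compounds()
        split = make_split(comps, SplitSpec("dtc_split", seed=4))
        assert len(split.train) == 80
        assert len(split.test_sets["additive"]) == 20
        assert len(split.test_sets["nonadditive"]) == 20
        assert set(split.test_sets["nonadditive"]) == {c.compound_id for c in comps
                                                       if c.na_label == "nonadditive"}

    def test_all_split_pools_non_dtc_as_additive(self):
        comps = toy_compounds()
        split = make_split(comps, SplitSpec("all_split", seed=4))
        assert len(split.train) == 104  # 80% of 130
        assert len(split.test_sets["additive"]) == 26

    def test_stratification_preserves_activity_deciles(self):
        comps = toy_compounds(n_add=200, n_na=0, n_free=0)
        split = make_split(comps, SplitSpec("dtc_split", seed=4))
        pacts = {c.compound_id: c.pact for c in comps}
        import pandas as pd
        bins = pd.qcut([pacts[c] for c in pacts], 10, labels=False)
        by_id = dict(zip(pacts, bins))
        for b in range(10):
            n_train = sum(1 for c in split.train if by_id[c] == b)
            n_test = sum(1 for c in split.test_sets["additive"] if by_id[c] == b)
            assert abs(n_train - 4 * n_test) <= 4  # 80/20 per decile, 1-compound slack

    def test_same_seed_reproducible_distinct_seeds_differ(self):
        comps = toy_compounds()
        s1 = make_split(comps, SplitSpec("dtc_split", seed=4))
        s2 = make_split(comps, SplitSpec("dtc_split", seed=4))
        s3 = make_split(comps, SplitSpec("dtc_split", seed=7))
        assert s1.train == s2.train
        assert s1.train != s3.train

    def test_train_test_disjoint_all_strategies(self, study_assay):
        for strategy in ("dtc_split", "all_split", "ab_split"):
            for seed in (4, 7):
                split = make_split(study_assay.labeled, SplitSpec(strategy, seed=seed),
                                   study_assay.cycles)
                train = set(split.train)
                for name, ids in split.test_sets.items():
                    assert not train & set(ids), (strategy, seed, name)

    def test_ab_split_roles_on_free_wilson_block(self):
        """No AB (c3-role) test compound in train; each tested AB compound
        has its A and B neighbours in training."""
        spec = simulate.default_library_spec(2, 5)
        mols = simulate.enumerate_library(spec)
        pairs = mmp.index_pairs({m.compound_id: m.smiles for m in mols})
        cycles = assemble_cycles(pairs, {m.compound_id: m.true_pact for m in mols})
        profiles = compound_profiles(cycles, NoiseModel(0.3))
        labeled = label_compounds(profiles, {m.compound_id: (m.smiles, m.true_pact)
                                             for m in mols})
        split = make_split(labeled, SplitSpec("ab_split", seed=4), cycles)
        train = set(split.train)
        tested = set(split.test_sets["additive_ab"]) | set(split.test_sets["nonadditive_ab"])
        assert tested and not train & tested
        for cyc in cycles:
            c1, c2, c3, c4 = cyc.compounds
            if c3 in tested and c2 in train and c4 in train:
                break
        else:
            pytest.fail("no tested AB compound with both neighbours in train")


class TestTrainEvaluate:
    def test_pls_on_noiseless_linear_response(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 5))
        y = 2.0 * X[:, 0] + 5.0
        m = train_model(X, y, "pls", budget=5, folds=5, seed=0)
        assert m.best_score_ > 0.99

    def test_pure_noise_response_has_no_cv_skill(self):
        rng = np.random.default_rng(1)
        scores = []
        for rep in range(5):
            X = rng.normal(size=(60, 10))
            y = rng.normal(size=60)
            m = train_model(X, y, "pls", budget=3, folds=5, seed=rep)
            scores.append(m.best_score_)
        assert np.mean(scores) <= 0.05

    def test_degenerate_response_aborts(self):
        X = np.ones((20, 3))
        with pytest.raises(ValueError, match="degenerate"):
            train_model(X, np.full(20, 5.0), "pls")

    def test_perfect_predictions(self):
        class Identity:
            def predict(self, X):
                return X[:, 0]

        y = np.array([4.0, 5.5, 6.0, 7.0])
        rep = evaluate(Identity(), {"t": (y.reshape(-1, 1), y)})
        m = rep.per_set["t"]
        assert m.r2 == pytest.approx(1.0)
        assert m.rmse == pytest.approx(0.0)
        assert m.mcc == pytest.approx(1.0)

    def test_constant_prediction_r2_zero(self):
        class Mean:
            def predict(self, X):
                return np.full(len(X), 5.625)

        y = np.array([4.0, 5.5, 6.0, 7.0])
        m = evaluate(Mean(), {"t": (np.zeros((4, 1)), y)}).per_set["t"]
        assert m.r2 == pytest.approx(0.0)

    def test_anticorrelated_binarization_mcc_minus_one(self):
        class Flip:
            def predict(self, X):
                return X[:, 0]

        y_true = np.array([4.0, 4.5, 6.0, 7.0])
        X = np.array([[6.0], [7.0], [4.0], [4.5]])
        m = evaluate(Flip(), {"t": (X, y_true)}).per_set["t"]
        assert m.mcc == pytest.approx(-1.0)

    def test_single_class_truth_flagged(self):
        class Zero:
            def predict(self, X):
                return np.full(len(X), 4.0)

        y = np.array([4.0, 4.2, 4.4])
        m = evaluate(Zero(), {"t": (np.zeros((3, 1)), y)}).per_set["t"]
        assert not m.mcc_defined and np.isnan(m.mcc)

    def test_binarization_boundary_goes_to_class_zero(self):
        assert binarize(np.array([4.9, 5.0, 5.1])).tolist() == [0, 0, 1]


class TestMixin:
    def test_fraction_zero_keeps_training_unchanged(self):
        comps = toy_compounds(n_add=500, n_na=60)
        pacts = {c.compound_id: c.pact for c in comps}
        train = [c.compound_id for c in comps if c.na_label == "additive"][:400]
        pool = [c.compound_id for c in comps if c.na_label == "nonadditive"]
        aug, hold = mixin(train, pool, 0.0, seed=4, pacts=pacts)
        assert aug == sorted(train)

    def test_fraction_arithmetic(self):
        comps = toy_compounds(n_add=1200, n_na=60)
        pacts = {c.compound_id: c.pact for c in comps}
        train = [c.compound_id for c in comps if c.na_label == "additive"][:1000]
        pool = [c.compound_id for c in comps if c.na_label == "nonadditive"]
        aug, _ = mixin(train, pool, 0.026, seed=4, pacts=pacts)
        assert len(aug) == 1026

    def test_holdout_identical_across_fractions(self):
        comps = toy_compounds(n_add=500, n_na=60)
        pacts = {c.compound_id: c.pact for c in comps}
        train = [c.compound_id for c in comps if c.na_label == "additive"][:400]
        pool = [c.compound_id for c in comps if c.na_label == "nonadditive"]
        holds = [mixin(train, pool, f, seed=4, pacts=pacts)[1]
                 for f in (0.0, 0.006, 0.013, 0.026)]
        assert all(h == holds[0] for h in holds)
        # nested draws: smaller mixes are subsets of larger ones
        augs = [set(mixin(train, pool, f, seed=4, pacts=pacts)[0])
                for f in (0.006, 0.013, 0.026)]
        assert augs[0] <= augs[1] <= augs[2]

    def test_mixed_in_never_in_holdout(self):
        comps = toy_compounds(n_add=500, n_na=60)
        pacts = {c.compound_id: c.pact for c in comps}
        train = [c.compound_id for c in comps if c.na_label == "additive"][:400]
        pool = [c.compound_id for c in comps if c.na_label == "nonadditive"]
        aug, hold = mixin(train, pool, 0.026, seed=4, pacts=pacts)
        assert not (set(aug) - set(train)) & set(hold)

    def test_pool_too_small_aborts(self):
        comps = toy_compounds(n_add=500, n_na=5)
        pacts = {c.compound_id: c.pact for c in comps}
        train = [c.compound_id for c in comps if c.na_label == "additive"][:400]
        with pytest.raises(ValueError, match="too small"):
            mixin(train, [c.compound_id for c in comps if c.na_label == "nonadditive"],
                  0.026, seed=4, pacts=pacts)
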