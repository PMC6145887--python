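"""Synthetic cohort generator: planted structure and determinism."""

import numpy as np
import pandas as pd
import pytest

import growthmicro as gm
from growthmicro.errors import InvalidArgumentError
from growthmicro.synthetic import sibling_leaf_pairs


class TestGenTree:
    def test_bifurcating_node_count(self):
        tree = gm.gen_tree(4, seed=1)
        tips = list(tree.root.tips())
        internal = [n for n in tree.root.traverse(include_self=True)
                    if not n.is_tip()]
        assert len(tips) == 4
        assert len(internal) == 3
        assert all(len(n.children) == 2 for n in internal)

    def test_every_leaf_has_one_phylum(self):
        tree = gm.gen_tree(75, seed=7)
        assert len(tree.leaf_names) == 75
        phyla = {leaf: tree.phylum_of(leaf) for leaf in tree.leaf_names}
        assert all(isinstance(p, str) and p for p in phyla.values())
        assert {"Firmicutes", "Bacteroidetes"} <= set(phyla.values())

    def test_deterministic_newick(self):
        assert gm.gen_tree(20, seed=5).to_newick() == gm.gen_tree(20, seed=5).to_newick()

    def test_too_few_genera_rejected(self):
        with pytest.raises(InvalidArgumentError):
            gm.gen_tree(3, seed=0)


class TestGenAbundances:
    def test_planted_rarity_fraction(self):
        tree = gm.gen_tree(4, seed=1)
        table = gm.gen_abundances(tree, 50, 10_000, 0.5, [], seed=2)
        counts = table.counts.to_numpy()
        rare = ((counts < 5).sum(axis=0) > 0.9 * 50).sum()
        assert rare == 2

    def test_no_sparsity_no_rare(self):
        tree = gm.gen_tree(6, seed=1)
        table = gm.gen_abundances(tree, 60, 10_000, 0.0, [], seed=3)
        counts = table.counts.to_numpy()
        assert ((counts < 5).sum(axis=0) > 0.9 * 60).sum() == 0

    def test_multinomial_closure(self):
        tree = gm.gen_tree(4, seed=1)
        table = gm.gen_abundances(tree, 20, 10_000, 0.25, [], seed=4)
        assert (table.counts.sum(axis=1) == 10_000).all()

    def test_sibling_pair_strongly_correlated(self):
        tree = gm.gen_tree(20, seed=3)
        pairs = sibling_leaf_pairs(tree)[:1]
        table = gm.gen_abundances(tree, 250, 50_000, 0.3, pairs, seed=5)
        a, b = pairs[0]
        r = np.corrcoef(table.counts[a], table.counts[b])[0, 1]
        assert r > 0.8

    def test_non_sibling_corr_block_rejected(self):
        tree = gm.gen_tree(8, seed=2)
        leaves = tree.leaf_names
        # find two leaves that are not siblings
        sibs = set(map(frozenset, sibling_leaf_pairs(tree)))
        pair = next(
            (x, y) for x in leaves for y in leaves
            if x != y and frozenset((x, y)) not in sibs
        )
        with pytest.raises(InvalidArgumentError):
            gm.gen_abundances(tree, 10, 1000, 0.0, [pair], seed=1)

    def test_rare_fraction_binomial_error(self):
        # emitted rare fraction tracks sparsity_frac at n_samples >= 100
        tree = gm.gen_tree(40, seed=11)
        table = gm.gen_abundances(tree, 120, 20_000, 0.3, [], seed=12)
        counts = table.counts.to_numpy()
        rare_frac = ((counts < 5).sum(axis=0) > 0.9 * 120).mean()
        se = np.sqrt(0.3 * 0.7 / 40)
        assert abs(rare_frac - 0.3) <= 3 * se + 1 / 40

    def test_determinism(self):
        tree = gm.gen_tree(10, seed=2)
        t1 = gm.gen_abundances(tree, 30, 5000, 0.2, [], seed=9)
        t2 = gm.gen_abundances(tree, 30, 5000, 0.2, [], seed=9)
        pd.testing.assert_frame_equal(t1.counts, t2.counts)


class TestGenReference:
    def test_exact_grid_lookup_and_monotone_median(self):
        ref = gm.gen_reference((0, 182, 730))
        L, M, S = ref.lms("male", "weight", 100.0)
        assert 0 < S < 0.3 and -2 <= L <= 2
        grid = np.arange(0, 731)
        medians = np.array([ref.lms("female", "length", float(a))[1] for a in grid])
        assert np.all(np.diff(medians) >= 0)

    def test_zscore_zero_at_median(self):
        ref = gm.gen_reference((0, 365, 730))
        for age in (0.0, 100.0, 365.5, 730.0):
            _, M, _ = ref.lms("male", "weight", age)
            assert gm.lms_zscore(M, age, "male", ref, "weight") == pytest.approx(0.0, abs=1e-12)


class TestGenCovariates:
    def test_deterministic(self):
        a = gm.gen_covariates(50, seed=8).frame
        b = gm.gen_covariates(50, seed=8).frame
        pd.testing.assert_frame_equal(a, b)

    def test_planted_collinearity(self):
        frame = gm.gen_covariates(150, seed=2).frame
        assert np.corrcoef(frame["milk"], frame["dairy"])[0, 1] > 0.7
        assert np.corrcoef(frame["vegetables"],
                           frame["vegetables_no_potato"])[0, 1] > 0.7

    def test_diet_frequencies_bounded(self):
        cov = gm.gen_covariates(80, seed=3)
        diet = cov.diet.to_numpy()
        assert diet.min() >= 0 and diet.max() <= 42


class TestGenGrowth:
    def test_null_effects_independent_of_predictors(self):
        cfg = gm.SyntheticConfig(n_children=30, seed=1, effect_map=())
        feats = pd.DataFrame({"oral_inverse_simpson": np.arange(30.0)})
        _, truth = gm.gen_growth(cfg, feats)
        assert truth.effects == {}
        cfg0 = gm.SyntheticConfig(
            n_children=30, seed=1,
            effect_map=(("oral_inverse_simpson", "sin", 0.0),))
        _, truth0 = gm.gen_growth(cfg0, feats)
        np.testing.assert_allclose(truth0.curves, truth.curves)

    def test_no_missing_gives_all_visits(self):
        cfg = gm.SyntheticConfig(n_children=15, seed=2, missing_rate=0.0,
                                 effect_map=())
        records, _ = gm.gen_growth(cfg, None)
        assert all(len(r.visits) == 7 for r in records)

    def test_birth_never_missing(self):
        cfg = gm.SyntheticConfig(n_children=40, seed=3, missing_rate=0.6,
                                 effect_map=())
        records, _ = gm.gen_growth(cfg, None)
        assert all(r.visits[0].age_days == 0 for r in records)

    def test_zero_noise_zero_effects_reproduces_mean(self):
        cfg = gm.SyntheticConfig(n_children=12, seed=4, effect_map=(),
                                 noise_sd=0.0, pc_sds=(0.0, 0.0),
                                 missing_rate=0.0)
        records, truth = gm.gen_growth(cfg, None)
        for rec in records:
            for v in rec.visits:
                assert v.weight_kg / v.length_cm == pytest.approx(
                    truth.mean[v.age_days], abs=1e-12)

    def test_unknown_effect_predictor_rejected(self):
        cfg = gm.SyntheticConfig(n_children=12, seed=1,
                                 effect_map=(("nope", "sin", 0.1),))
        feats = pd.DataFrame({"oral_inverse_simpson": np.arange(12.0)})
        with pytest.raises(InvalidArgumentError):
            gm.gen_growth(cfg, feats)

    def test_fosr_on_true_curves_recovers_effect_sign(self):
        # planted positive effect on oral diversity, fit on noiseless curves
        rng = np.random.default_rng(6)
        n = 200
        feats = pd.DataFrame({"oral_inverse_simpson": rng.normal(size=n)})
        cfg = gm.SyntheticConfig(
            n_children=n, seed=6, noise_sd=0.0,
            effect_map=(("oral_inverse_simpson", "sin", 0.005),))
        _, truth = gm.gen_growth(cfg, feats)
        fit = gm.fit_fosr((truth.grid, truth.curves), truth.design,
                          lambda_s=0.0, compute_pvalues=False)
        beta = fit.coefficient("oral_inverse_simpson")
        interior = beta[30:-30]
        assert (interior > 0).mean() > 0.99

    def test_weight_backsolve_consistency(self):
        cfg = gm.SyntheticConfig(n_children=12, seed=7, effect_map=())
        records, _ = gm.gen_growth(cfg, None)
        for rec in records:
            for v in rec.visits:
                assert v.weight_kg > 0 and v.length_cm > 0


def test_simulate_cohort_roundtrip(tmp_path):
    cfg = gm.SyntheticConfig(n_children=15, n_genera=8, seed=5)
    cohort = gm.simulate_cohort(cfg)
    paths = cohort.write(tmp_path)
    from growthmicro.anthro import read_anthropometry
    from growthmicro.diversity import read_counts

    table = read_counts(paths["counts_oral"])
    pd.testing.assert_frame_equal(table.counts, cohort.tables["oral"].counts)
    assert table.taxonomy  # lineage strings parsed back
    records = read_anthropometry(paths["anthropometry"])
    assert len(records) == 15
    tree2 = gm.TaxTree.read(paths["tree"])
    assert tree2.leaf_names == cohort.tree.leaf_names
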