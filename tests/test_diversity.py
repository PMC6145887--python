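"""Count-table I/O, rarefaction, diversity summaries and group tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import growthmicro as gm
from growthmicro.diversity import (
    AbundanceTable,
    alpha_diversity,
    bray_curtis,
    fb_ratio,
    mw_one_tailed,
    phylum_proportion_tests,
    rarefy,
    read_counts,
    write_counts,
)
from growthmicro.errors import (
    ConfigurationError,
    FormatError,
    InvalidArgumentError,
    UndefinedDiversityError,
)


class TestIO:
    def test_roundtrip(self, toy_table, tmp_path):
        path = tmp_path / "counts.tsv"
        write_counts(toy_table, path)
        back = read_counts(path)
        pd.testing.assert_frame_equal(back.counts, toy_table.counts)
        assert back.taxonomy == toy_table.taxonomy

    def test_duplicate_taxon_column(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("sample_id\tA\tA\ns1\t1\t2\n")
        with pytest.raises(FormatError):
            read_counts(path)

    def test_empty_table(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("sample_id\tA\n")
        with pytest.raises(FormatError):
            read_counts(path)

    def test_non_integer_cell_reports_position(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("sample_id\tA\tB\ns1\t1\t2.5\n")
        with pytest.raises(FormatError, match="B"):
            read_counts(path)


class TestRarefy:
    def test_rows_sum_to_depth(self, toy_table):
        out = rarefy(toy_table, 50, seed=1)
        assert (out.counts.sum(axis=1) == 50).all()

    def test_full_depth_identity(self, toy_table):
        totals = toy_table.counts.sum(axis=1)
        depth = int(totals.min())
        out = rarefy(toy_table, depth, seed=2)
        kept = toy_table.counts.loc[out.counts.index]
        row = out.counts.loc[totals.idxmin()]
        pd.testing.assert_series_equal(row, kept.loc[totals.idxmin()])

    def test_deterministic(self, toy_table):
        a = rarefy(toy_table, 40, seed=7).counts
        b = rarefy(toy_table, 40, seed=7).counts
        pd.testing.assert_frame_equal(a, b)

    def test_nonpositive_depth_rejected(self, toy_table):
        with pytest.raises(InvalidArgumentError):
            rarefy(toy_table, 0, seed=1)

    def test_shallow_samples_dropped_with_audit(self, toy_table):
        out = rarefy(toy_table, 95, seed=3)
        assert out.meta["rarefaction_dropped"]
        assert out.counts.shape[0] < toy_table.counts.shape[0]

    def test_expected_proportions_preserved(self, toy_table):
        # mean subsampled proportion stays within binomial CI over 200 seeds
        depth = 50
        props = []
        for seed in range(200):
            out = rarefy(toy_table, depth, seed=seed)
            props.append(out.counts["B"].to_numpy() / depth)
        mean_prop = float(np.mean(props))
        p0 = float((toy_table.counts["B"] / toy_table.counts.sum(axis=1)).mean())
        se = np.sqrt(p0 * (1 - p0) / (depth * 200 * 10))
        assert abs(mean_prop - p0) < 4 * se


class TestAlphaDiversity:
    def test_uniform_four_phyla(self):
        tree = gm.TaxTree.from_newick(
            "(((a:1)p__P1:1,(b:1)p__P2:1)n1:1,((c:1)p__P3:1,(d:1)p__P4:1)n2:1)root;"
        )
        counts = pd.DataFrame({"a": [25], "b": [25], "c": [25], "d": [25]},
                              index=["s"])
        table = AbundanceTable(counts=counts, taxonomy=tree.taxonomy())
        div = alpha_diversity(table)
        assert div.loc["s", "inverse_simpson"] == pytest.approx(4.0)

    def test_single_phylum(self, toy_table):
        div = alpha_diversity(toy_table)  # all four genera share one phylum
        assert np.allclose(div["inverse_simpson"], 1.0)
        assert np.allclose(div["shannon"], 0.0)

    def test_hand_computed_composition(self):
        tree = gm.TaxTree.from_newick(
            "(((a:1)p__P1:1,(b:1)p__P2:1,(c:1)p__P3:1)n0:1)root;"
        )
        counts = pd.DataFrame({"a": [50], "b": [25], "c": [25]}, index=["s"])
        table = AbundanceTable(counts=counts, taxonomy=tree.taxonomy())
        div = alpha_diversity(table)
        assert div.loc["s", "simpson"] == pytest.approx(0.375)
        assert div.loc["s", "inverse_simpson"] == pytest.approx(8.0 / 3.0)

    def test_matches_skbio_at_genus_level(self, toy_table):
        from skbio.diversity.alpha import inv_simpson, shannon

        div = alpha_diversity(toy_table, level="genus")
        for sid in toy_table.sample_ids[:3]:
            row = toy_table.counts.loc[sid].to_numpy()
            assert div.loc[sid, "inverse_simpson"] == pytest.approx(
                inv_simpson(row))
            assert div.loc[sid, "shannon"] == pytest.approx(
                shannon(row, base=np.e))

    def test_all_zero_sample_rejected(self, toy_tree):
        counts = pd.DataFrame({"A": [0], "B": [0], "C": [0], "D": [0]},
                              index=["s"])
        table = AbundanceTable(counts=counts, taxonomy=toy_tree.taxonomy())
        with pytest.raises(UndefinedDiversityError):
            alpha_diversity(table)

    def test_uniform_maximizes_inverse_simpson(self):
        # enumeration over small compositional grids of 3 phyla
        best = 0.0
        for a in range(1, 11):
            for b in range(1, 11 - a):
                c = 12 - a - b
                if c < 1:
                    continue
                p = np.array([a, b, c]) / 12
                best = max(best, 1.0 / (p ** 2).sum())
        assert best == pytest.approx(3.0)  # attained only at (4,4,4)


class TestFBRatio:
    def test_basic_and_zero_cases(self, two_phylum_table):
        ratio = fb_ratio(two_phylum_table)
        assert ratio["s1"] == pytest.approx(200 / 100)
        assert ratio["s2"] == pytest.approx(200 / 200)
        assert np.isnan(ratio["s3"])  # zero Bacteroidetes: undefined, not inf
        assert two_phylum_table.meta["fb_undefined"] == ["s3"]

    def test_zero_firmicutes_is_zero(self):
        tree = gm.TaxTree.from_newick(
            "((F1:1)p__Firmicutes:1,(B1:1)p__Bacteroidetes:1)root;"
        )
        counts = pd.DataFrame({"F1": [0], "B1": [100]}, index=["s"])
        table = AbundanceTable(counts=counts, taxonomy=tree.taxonomy())
        assert fb_ratio(table)["s"] == 0.0

    def test_missing_phylum_configuration_error(self, toy_table):
        with pytest.raises(ConfigurationError):
            fb_ratio(toy_table)


class TestProportionTests:
    def _table(self, phylum_counts, n):
        tree = gm.TaxTree.from_newick(
            "((a:1)p__P1:1,(b:1)p__P2:1)root;"
        )
        counts = pd.DataFrame(
            {"a": [phylum_counts] * n, "b": [100 - phylum_counts] * n},
            index=[f"s{i}" for i in range(n)],
        )
        return AbundanceTable(counts=counts, taxonomy=tree.taxonomy())

    def test_identical_groups_p_one(self):
        t = self._table(40, 50)
        res = phylum_proportion_tests({"g1": t, "g2": t})
        assert (res["p_bonferroni"] == 1.0).all()

    def test_strong_difference_significant(self):
        res = phylum_proportion_tests(
            {"g1": self._table(90, 100), "g2": self._table(10, 100)},
            phyla=["P1"], m_tests=24,
        )
        assert res["p_bonferroni"].iloc[0] < 0.001

    def test_m_tests_one_returns_raw(self):
        res1 = phylum_proportion_tests(
            {"g1": self._table(60, 40), "g2": self._table(45, 40)}, m_tests=1)
        assert (res1["p_bonferroni"] == res1["p_raw"]).all()

    def test_matches_textbook_chi_squared(self):
        # hand-built 2x2: successes 30/100 vs 50/100
        res = phylum_proportion_tests(
            {"g1": self._table(30, 100), "g2": self._table(50, 100)},
            phyla=["P1"], m_tests=1)
        expected = stats.chi2_contingency(
            np.array([[30, 70], [50, 50]]), correction=True)[1]
        assert res["p_raw"].iloc[0] == pytest.approx(expected)

    def test_single_group_rejected(self):
        with pytest.raises(InvalidArgumentError):
            phylum_proportion_tests({"g1": self._table(10, 5)})


class TestMannWhitney:
    def test_exact_small_sample(self):
        assert mw_one_tailed([1, 2, 3], [4, 5, 6], "less") == pytest.approx(0.05)

    def test_identical_samples_half(self):
        p = mw_one_tailed([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0], "greater")
        assert p == pytest.approx(0.5, abs=0.05)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=12), rng.normal(1.0, 1.0, size=15)
        assert mw_one_tailed(a, b, "less") == pytest.approx(
            mw_one_tailed(b, a, "greater"))

    def test_direction_required(self):
        with pytest.raises(InvalidArgumentError):
            mw_one_tailed([1, 2], [3, 4], "two-sided")


class TestBrayCurtis:
    def test_identities(self, toy_tree):
        counts = pd.DataFrame(
            {"A": [6, 2, 5, 0], "B": [0, 4, 5, 0], "C": [0, 0, 0, 3],
             "D": [0, 0, 0, 2]},
            index=["x", "y", "z", "w"],
        )
        table = AbundanceTable(counts=counts, taxonomy=toy_tree.taxonomy())
        d = bray_curtis(table)
        assert d.loc["x", "x"] == 0.0
        assert d.loc["x", "w"] == 1.0  # disjoint supports
        assert d.loc["x", "y"] == pytest.approx(2.0 / 3.0)  # hand example
        assert np.allclose(d, d.T)
        vals = d.to_numpy()[np.isfinite(d.to_numpy())]
        assert vals.min() >= 0.0 and vals.max() <= 1.0

    def test_zero_sum_pair_flagged(self, toy_tree):
        counts = pd.DataFrame({"A": [0, 0], "B": [0, 0], "C": [0, 0],
                               "D": [0, 0]}, index=["u", "v"])
        table = AbundanceTable(counts=counts, taxonomy=toy_tree.taxonomy())
        d = bray_curtis(table)
        assert np.isnan(d.loc["u", "v"])
        assert table.meta["bray_curtis_undefined_pairs"] == [("u", "v")]
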