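"""Defined-community quantification: matching, propagation, statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sp_stats

from invertiscan import (
    ASVRecord,
    ConfigError,
    DataError,
    StrainReferenceDB,
    community_ko_abundance,
    detection_prevalence,
    differential_features,
    match_asv_to_strains,
    ora_enrichment,
    relative_abundance_table,
)
from invertiscan.simulate import simulate_community_profiles

from oracles import hypergeom_upper_tail, welch_from_formula


@pytest.fixture
def db():
    return StrainReferenceDB(
        {
            "S1": "ACGTACGTACGTACGTACGTACGTACGTACGT",
            "S2": "TTTTACGTACGTACGTACGTACGTACGTAAAA",
            # S3 and S4 are indistinguishable by this region
            "S3": "GGGGACGTACGTACGTACGTACGTACGTCCCC",
            "S4": "GGGGACGTACGTACGTACGTACGTACGTCCCC",
        }
    )


class TestMatchASVToStrains:
    def test_unique_match(self, db):
        asv = ASVRecord("a", db.sequences["S1"], {"x": 1})
        m = match_asv_to_strains(asv, db)
        assert m.status == "unique"
        assert m.matched_strains == frozenset({"S1"})

    def test_identical_references_form_ambiguity_group(self, db):
        asv = ASVRecord("a", db.sequences["S3"], {"x": 1})
        m = match_asv_to_strains(asv, db)
        assert m.status == "ambiguous_group"
        assert m.matched_strains == frozenset({"S3", "S4"})

    def test_one_mismatch_tolerated_two_rejected(self, db):
        one = db.sequences["S1"][:-1] + "C"  # one substitution
        m = match_asv_to_strains(ASVRecord("a", one, {"x": 1}), db)
        assert m.status == "unique"
        two = "TG" + db.sequences["S1"][2:]  # two substitutions
        m = match_asv_to_strains(ASVRecord("b", two, {"x": 1}), db)
        assert m.status == "unassigned"

    def test_indel_counts_as_one_mismatch(self, db):
        deleted = db.sequences["S1"][1:]
        m = match_asv_to_strains(ASVRecord("a", deleted, {"x": 1}), db)
        assert "S1" in m.matched_strains


class TestRelativeAbundanceTable:
    def _asvs(self, db):
        return [
            ASVRecord("a1", db.sequences["S1"], {"s1": 600}),
            ASVRecord("a2", db.sequences["S2"], {"s1": 400}),
        ]

    def test_fractions(self, db):
        asvs = self._asvs(db)
        matches = [match_asv_to_strains(a, db) for a in asvs]
        table, unmapped = relative_abundance_table(asvs, matches)
        assert table.loc["S1", "s1"] == pytest.approx(0.6)
        assert table.loc["S2", "s1"] == pytest.approx(0.4)
        assert unmapped["s1"] == 0.0

    def test_ambiguity_group_row(self, db):
        asvs = [ASVRecord("a", db.sequences["S3"], {"s1": 10})]
        matches = [match_asv_to_strains(a, db) for a in asvs]
        table, _ = relative_abundance_table(asvs, matches)
        assert "S3+S4" in table.index

    def test_all_unassigned(self, db):
        asvs = [ASVRecord("a", "A" * 32, {"s1": 10})]
        matches = [match_asv_to_strains(a, db) for a in asvs]
        table, unmapped = relative_abundance_table(asvs, matches)
        assert table.empty
        assert unmapped["s1"] == 1.0

    def test_order_invariance(self, db):
        asvs = self._asvs(db)
        matches = [match_asv_to_strains(a, db) for a in asvs]
        t1, _ = relative_abundance_table(asvs, matches)
        t2, _ = relative_abundance_table(asvs[::-1], matches[::-1])
        pd.testing.assert_frame_equal(t1, t2)


class TestCommunityKOAbundance:
    def test_worked_micro_example(self):
        """Two strains at 2.0 and 3.0 with copies 1 and 2 give 2*1 + 3*2 = 8."""
        abund = pd.DataFrame({"m1": [2.0, 3.0]}, index=["S1", "S2"])
        copies = pd.DataFrame({"K1": [1, 2]}, index=["S1", "S2"])
        ko = community_ko_abundance(abund, copies)
        assert ko.loc["K1", "m1"] == pytest.approx(8.0)

    def test_zero_abundance_contributes_nothing(self):
        abund = pd.DataFrame({"m1": [0.0, 3.0]}, index=["S1", "S2"])
        copies = pd.DataFrame({"K1": [99, 2]}, index=["S1", "S2"])
        assert community_ko_abundance(abund, copies).loc["K1", "m1"] == 6.0

    def test_absent_ko_is_zero(self):
        abund = pd.DataFrame({"m1": [2.0, 3.0]}, index=["S1", "S2"])
        copies = pd.DataFrame({"K1": [0, 0]}, index=["S1", "S2"])
        assert community_ko_abundance(abund, copies).loc["K1", "m1"] == 0.0

    def test_disjoint_strains_error(self):
        abund = pd.DataFrame({"m1": [2.0]}, index=["S1"])
        copies = pd.DataFrame({"K1": [1]}, index=["S9"])
        with pytest.raises(ConfigError):
            community_ko_abundance(abund, copies)

    def test_linearity_and_additivity(self):
        rng = np.random.default_rng(0)
        abund = pd.DataFrame(
            rng.uniform(0, 10, (5, 3)), index=[f"S{i}" for i in range(5)],
            columns=["m1", "m2", "m3"],
        )
        copies = pd.DataFrame(
            rng.integers(0, 4, (5, 8)), index=abund.index,
            columns=[f"K{i}" for i in range(8)],
        )
        ko = community_ko_abundance(abund, copies)
        pd.testing.assert_frame_equal(
            community_ko_abundance(3.0 * abund, copies), 3.0 * ko
        )
        # additive over a strain partition
        part = community_ko_abundance(abund.iloc[:2], copies.iloc[:2]).add(
            community_ko_abundance(abund.iloc[2:], copies.iloc[2:]), fill_value=0
        )
        pd.testing.assert_frame_equal(part.sort_index(), ko.sort_index())


class TestDifferentialFeatures:
    def _table(self, a, b):
        data = {f"a{i}": [v] for i, v in enumerate(a)}
        data.update({f"b{i}": [v] for i, v in enumerate(b)})
        return pd.DataFrame(data, index=["f1"])

    def _groups(self, a, b):
        return {f"a{i}": "A" for i in range(len(a))} | {f"b{i}": "B" for i in range(len(b))}

    def test_matches_textbook_formula_and_scipy(self):
        a = [3.0, 3.1, 2.9, 3.0]
        b = [4.0, 4.1, 3.9, 4.0]
        res = differential_features(
            self._table(a, b), self._groups(a, b), log2_transform=False
        ).loc["f1"]
        t_o, df_o, p_o = welch_from_formula(a, b)
        assert res["t_statistic"] == pytest.approx(t_o, abs=1e-6)
        assert res["df"] == pytest.approx(df_o, abs=1e-6)
        assert res["p_value"] == pytest.approx(p_o, abs=1e-6)
        sp = sp_stats.ttest_ind(a, b, equal_var=False)
        assert res["t_statistic"] == pytest.approx(sp.statistic, abs=1e-9)
        assert res["p_value"] == pytest.approx(sp.pvalue, abs=1e-9)

    def test_identical_groups_p_one(self):
        a = [1.0, 2.0, 3.0]
        res = differential_features(
            self._table(a, a), self._groups(a, a), log2_transform=False
        ).loc["f1"]
        assert res["p_value"] == pytest.approx(1.0)

    def test_zero_variance_equal_means(self):
        res = differential_features(
            self._table([2.0, 2.0], [2.0, 2.0]), self._groups([0, 0], [0, 0]),
            log2_transform=False,
        ).loc["f1"]
        assert res["t_statistic"] == 0.0
        assert res["p_value"] == 1.0

    def test_label_swap_negates_t(self):
        a = [3.0, 3.1, 2.9]
        b = [4.0, 4.2, 3.9]
        groups = self._groups(a, b)
        swapped = {k: ("A" if v == "B" else "B") for k, v in groups.items()}
        r1 = differential_features(self._table(a, b), groups, log2_transform=False)
        r2 = differential_features(self._table(a, b), swapped, log2_transform=False)
        assert r1.loc["f1", "t_statistic"] == pytest.approx(-r2.loc["f1", "t_statistic"])
        assert r1.loc["f1", "p_value"] == pytest.approx(r2.loc["f1", "p_value"])

    def test_small_group_rejected(self):
        table = pd.DataFrame({"a0": [1.0], "b0": [2.0], "b1": [3.0]}, index=["f1"])
        with pytest.raises(ConfigError, match="A"):
            differential_features(table, {"a0": "A", "b0": "B", "b1": "B"})

    def test_pseudocount_default_handles_zeros(self):
        table = pd.DataFrame(
            {"a0": [0.0], "a1": [4.0], "b0": [8.0], "b1": [16.0]}, index=["f1"]
        )
        res = differential_features(table, {"a0": "A", "a1": "A", "b0": "B", "b1": "B"})
        assert res.attrs["pseudocount"] == pytest.approx(2.0)  # half of min nonzero
        assert np.isfinite(res.loc["f1", "t_statistic"])

    def test_planted_fold_change_recovered(self):
        """All 10 planted 4-fold KOs detected; null false positives under 5%."""
        com = simulate_community_profiles(seed=9)
        ko = community_ko_abundance(com.abundance, com.ko_copies)
        res = differential_features(ko, com.groups)
        planted = com.truth["planted_kos"]
        assert res.loc[planted, "significant"].all()
        nulls = res.drop(index=planted)
        assert nulls["significant"].mean() <= 0.05

    def test_type_i_error_controlled_without_effects(self):
        """With no planted effect the significant fraction averages near alpha."""
        rates = []
        for seed in range(8):
            com = simulate_community_profiles(seed=100 + seed, n_planted=0)
            ko = community_ko_abundance(com.abundance, com.ko_copies)
            res = differential_features(ko, com.groups)
            rates.append(res["significant"].mean())
        assert np.mean(rates) <= 0.08


class TestORAEnrichment:
    def test_zero_overlap_p_is_one(self):
        res = ora_enrichment(
            {"K1"}, {"K1", "K2", "K3", "K4"}, {"p": ["K2", "K3"]}
        )
        assert res.loc["p", "k"] == 0
        assert res.loc["p", "p_value"] == pytest.approx(1.0)

    def test_pathway_spanning_background_p_is_one(self):
        bg = {f"K{i}" for i in range(10)}
        res = ora_enrichment({"K1", "K2"}, bg, {"p": bg})
        assert res.loc["p", "p_value"] == pytest.approx(1.0)

    def test_matches_combinatorial_oracle(self):
        bg = [f"K{i:03d}" for i in range(100)]
        pathway = bg[:10]
        sig = pathway[:5] + bg[50:55]  # k=5, n=10
        res = ora_enrichment(sig, bg, {"p": pathway})
        expected = hypergeom_upper_tail(5, 100, 10, 10)
        assert res.loc["p", "p_value"] == pytest.approx(expected, abs=1e-12)

    def test_bh_is_monotone_step_up(self):
        rng = np.random.default_rng(1)
        bg = [f"K{i:03d}" for i in range(200)]
        sig = set(rng.choice(bg, 40, replace=False))
        pathways = {
            f"p{j}": list(rng.choice(bg, 20, replace=False)) for j in range(15)
        }
        res = ora_enrichment(sig, bg, pathways).sort_values("p_value")
        qs = res["q_value"].to_numpy()
        assert (np.diff(qs) >= -1e-15).all()
        assert (res["q_value"] >= res["p_value"] - 1e-15).all()

    def test_empty_pathways_skipped(self):
        res = ora_enrichment({"K1"}, {"K1", "K2"}, {"p": ["K9"]})
        assert res.empty

    def test_significant_outside_background_rejected(self):
        with pytest.raises(DataError):
            ora_enrichment({"K9"}, {"K1"}, {"p": ["K1"]})


class TestDetectionPrevalence:
    @pytest.mark.parametrize(
        "k,n,pct,rounded",
        [(249, 2758, 100 * 249 / 2758, 9), (0, 100, 0.0, 0), (100, 100, 100.0, 100)],
    )
    def test_values(self, k, n, pct, rounded):
        raw, r = detection_prevalence(k, n)
        assert raw == pytest.approx(pct)
        assert r == rounded

    def test_zero_total_rejected(self):
        with pytest.raises(ConfigError):
            detection_prevalence(0, 0)
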