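"""Spectra, simulated-P chi-squared, Weir-Cockerham Fst, divergence."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from demeseed.core import ConfigError, DemeseedError, SampleFrame
from demeseed.popstats import (
    chisq_simulated_p,
    expected_polymorphic_sites,
    haplotype_spectrum,
    hierarchical_fst,
    pairwise_divergence,
    weir_cockerham_fst,
)
from demeseed.haplocall import HaplotypeCatalog

from conftest import make_matrix


def _frame(sample_meta, ind_map):
    samples = pd.DataFrame(
        sample_meta,
        columns=["sample_id", "location", "date", "substrate", "x_m", "y_m"],
    )
    individuals = pd.DataFrame(ind_map, columns=["individual_id", "sample_id"])
    return SampleFrame(samples=samples, individuals=individuals)


def _assign(rows):
    return pd.DataFrame(rows).reindex(
        columns=["individual_id", "kind", "haplotype", "h1", "h2"]
    )


class TestHaplotypeSpectrum:
    @staticmethod
    def _fixture():
        frame = _frame(
            [("S1", "Orsay", "2011-10-01", "fruit", 0, 0),
             ("S2", "Orsay", "2011-10-01", "fruit", 1, 0)],
            [("a", "S1"), ("b", "S1"), ("c", "S2"), ("d", "S2")],
        )
        table = _assign(
            [dict(individual_id="a", kind="haplotype", haplotype="HO1"),
             dict(individual_id="b", kind="haplotype", haplotype="HO2"),
             dict(individual_id="c", kind="haplotype", haplotype="HO1"),
             dict(individual_id="d", kind="haplotype", haplotype="HO2")]
        )
        return frame, table

    def test_individual_proportions_sum_to_one(self):
        frame, table = self._fixture()
        spec = haplotype_spectrum(table, frame, by="individuals")
        assert spec.groupby("location")["proportion"].sum().tolist() == [1.0]

    def test_sample_proportions_can_exceed_one(self):
        frame, table = self._fixture()
        spec = haplotype_spectrum(table, frame, by="samples")
        # both haplotypes present in both samples: proportion 1.0 each
        assert spec["proportion"].tolist() == [1.0, 1.0]
        assert spec["proportion"].sum() == 2.0

    def test_single_haplotype(self):
        frame, _ = self._fixture()
        table = _assign(
            [dict(individual_id=i, kind="haplotype", haplotype="HO1")
             for i in "abcd"]
        )
        spec = haplotype_spectrum(table, frame)
        assert len(spec) == 1 and spec["proportion"].iloc[0] == 1.0

    def test_f1_counted_as_own_category(self):
        frame, _ = self._fixture()
        table = _assign(
            [dict(individual_id="a", kind="haplotype", haplotype="HO1"),
             dict(individual_id="b", kind="F1", h1="HO1", h2="HO2"),
             dict(individual_id="c", kind="haplotype", haplotype="HO1"),
             dict(individual_id="d", kind="haplotype", haplotype="HO2")]
        )
        spec = haplotype_spectrum(table, frame)
        assert "F1(HO1,HO2)" in set(spec["haplotype"])
        assert spec["proportion"].sum() == pytest.approx(1.0)


class TestChisqSimulatedP:
    def test_independent_table_large_counts(self):
        tbl = np.array([[100, 200], [50, 100]])  # exactly proportional rows
        res = chisq_simulated_p(tbl, n_sim=2000, seed=0)
        assert res.p_value > 0.5

    def test_matches_asymptotic_tail(self):
        for tbl, df in [
            (np.array([[5060, 4940], [4940, 5060]]), 1),
            (np.array([[530, 470, 500], [470, 530, 500]]), 2),
        ]:
            res = chisq_simulated_p(tbl, n_sim=100_000, seed=1)
            asym = stats.chi2.sf(res.statistic, df)
            assert res.p_value == pytest.approx(asym, abs=0.005)

    def test_deterministic_given_seed(self):
        tbl = np.array([[30, 20], [20, 30]])
        a = chisq_simulated_p(tbl, n_sim=5000, seed=7)
        b = chisq_simulated_p(tbl, n_sim=5000, seed=7)
        assert a.p_value == b.p_value

    def test_permutation_invariance_within_mc_error(self):
        tbl = np.array([[40, 25, 10], [15, 30, 35]])
        n = 50_000
        p1 = chisq_simulated_p(tbl, n_sim=n, seed=2).p_value
        p2 = chisq_simulated_p(tbl[:, ::-1], n_sim=n, seed=2).p_value
        p3 = chisq_simulated_p(tbl[::-1], n_sim=n, seed=2).p_value
        se = np.sqrt(p1 * (1 - p1) / n)
        assert abs(p1 - p2) < 4 * se + 1e-4
        assert abs(p1 - p3) < 4 * se + 1e-4

    def test_p_floor_is_add_one(self):
        tbl = np.array([[50, 0], [0, 50]])
        res = chisq_simulated_p(tbl, n_sim=1000, seed=3)
        assert res.p_value >= 1 / 1001

    def test_zero_margin_dropped_with_warning(self):
        tbl = np.array([[10, 0, 5], [8, 0, 7], [0, 0, 0]])
        with pytest.warns(UserWarning):
            res = chisq_simulated_p(tbl, n_sim=500, seed=4)
        assert res.observed.shape == (2, 2)

    def test_invalid_table(self):
        with pytest.raises(ConfigError):
            chisq_simulated_p(np.array([[1.5, 2.0], [1.0, 2.0]]))


class TestWeirCockerham:
    def test_components_match_anova_oracle_equal_sizes(self):
        # frozen from an independent mean-squares nested-ANOVA computation
        # deme A dosages [0,0,1], deme B [2,2,1] at locus 1; fixed 0 vs 2
        # at locus 2
        m = make_matrix(
            [[0, 0], [0, 0], [1, 0], [2, 2], [2, 2], [1, 2]]
        )
        res = weir_cockerham_fst(m, ["A"] * 3 + ["B"] * 3)
        comp = res.components.set_index("site")
        assert comp.loc[0, "a"] == pytest.approx(0.194444444444, abs=1e-12)
        assert comp.loc[0, "b"] == pytest.approx(0.0, abs=1e-12)
        assert comp.loc[0, "c"] == pytest.approx(1 / 6, abs=1e-12)
        assert comp.loc[1, "a"] == pytest.approx(0.5, abs=1e-12)
        assert comp.loc[1, ["b", "c"]].tolist() == pytest.approx([0.0, 0.0], abs=1e-12)
        assert res.estimates["fst"] == pytest.approx(0.806451612903, abs=1e-12)

    def test_components_match_anova_oracle_unequal_sizes(self):
        # deme A (n=2) dosages [0,1], deme B (n=4) [1,2,2,2]
        m = make_matrix([[0], [1], [1], [2], [2], [2]])
        res = weir_cockerham_fst(m, ["A"] * 2 + ["B"] * 4)
        comp = res.components.iloc[0]
        assert comp["a"] == pytest.approx(0.166015625, abs=1e-12)
        assert comp["b"] == pytest.approx(-0.005208333333333, abs=1e-12)
        assert comp["c"] == pytest.approx(1 / 6, abs=1e-12)

    def test_fixed_differences_give_fst_one(self):
        m = make_matrix([[0, 0, 0]] * 4 + [[2, 2, 2]] * 4)
        res = weir_cockerham_fst(m, ["A"] * 4 + ["B"] * 4)
        assert res.estimates["fst"] == pytest.approx(1.0)

    def test_panmictic_split_has_fst_near_zero(self):
        rng = np.random.default_rng(5)
        fsts = []
        for _ in range(30):
            calls = rng.choice([0, 2], size=(40, 25), p=[0.6, 0.4])
            m = make_matrix(calls)
            groups = rng.permutation(["A"] * 20 + ["B"] * 20)
            fsts.append(weir_cockerham_fst(m, list(groups)).estimates["fst"])
        fsts = np.asarray(fsts)
        se = fsts.std(ddof=1) / np.sqrt(len(fsts))
        assert abs(fsts.mean()) < 3 * se

    def test_monomorphic_rejected(self):
        m = make_matrix([[0, 0]] * 6)
        with pytest.raises(DemeseedError):
            weir_cockerham_fst(m, ["A"] * 3 + ["B"] * 3)


class TestHierarchicalFst:
    @staticmethod
    def _nested_fixture(between_fixed: bool):
        rng = np.random.default_rng(6)
        rows, meta, imap = [], [], []
        for li, loc in enumerate(["Orsay", "Santeuil"]):
            for sj in range(2):
                sid = f"{loc}-{sj}"
                meta.append((sid, loc, "2010-10-01", "stem", sj, li * 100))
                for k in range(3):
                    imap.append((f"ind{len(rows)}", sid))
                    if between_fixed:
                        rows.append([0, 0, 0] if li == 0 else [2, 2, 2])
                    else:
                        rows.append(list(rng.choice([0, 2], 3)))
        frame = _frame(meta, imap)
        m = make_matrix(rows)
        m.individuals = [i for i, _ in imap]
        return m, frame

    def test_location_fixed_differences(self):
        m, frame = self._nested_fixture(between_fixed=True)
        res = hierarchical_fst(m, frame)
        assert res.estimates["fst_location"] == pytest.approx(1.0)

    def test_needs_two_groups_per_level(self):
        m, frame = self._nested_fixture(between_fixed=True)
        frame.samples["location"] = "Orsay"
        with pytest.raises(ConfigError):
            hierarchical_fst(m, frame)


class TestDivergence:
    @staticmethod
    def _catalog(vectors):
        entries = {f"H{i+1}": np.asarray(v, dtype=np.int8)
                   for i, v in enumerate(vectors)}
        return HaplotypeCatalog(
            entries=entries, majors=list(entries),
            n_individuals={k: 2 for k in entries},
        )

    def test_identical_haplotypes_zero(self):
        cat = self._catalog([[0, 2, 0], [0, 2, 0]])
        mat, mean = pairwise_divergence(cat)
        assert mean == 0.0

    def test_printed_arithmetic_75_sites(self):
        v1 = [0] * 75 + [0] * 25
        v2 = [2] * 75 + [0] * 25
        cat = self._catalog([v1, v2])
        _, mean = pairwise_divergence(cat, surveyed_bp=30 * 7760)
        assert mean == pytest.approx(3.22e-4, abs=5e-7)

    def test_hand_counted_matrix(self):
        cat = self._catalog([[0, 0, 0, 0], [2, 0, 0, 0], [2, 2, 2, 0]])
        mat, mean = pairwise_divergence(cat, surveyed_bp=100)
        assert mat.loc["H1", "H2"] == pytest.approx(0.01)
        assert mat.loc["H1", "H3"] == pytest.approx(0.03)
        assert mat.loc["H2", "H3"] == pytest.approx(0.02)
        assert np.allclose(mat.to_numpy(), mat.to_numpy().T)
        assert np.allclose(np.diag(mat.to_numpy()), 0.0)
        assert mean == pytest.approx(0.02)

    def test_missing_consensus_sites_skipped(self):
        cat = self._catalog([[0, -1, 2], [2, 2, 2]])
        mat, _ = pairwise_divergence(cat, surveyed_bp=10)
        assert mat.loc["H1", "H2"] == pytest.approx(0.1)


class TestExpectedPolymorphicSites:
    def test_printed_arithmetic(self):
        res = expected_polymorphic_sites(7760, 30, 1e-3)
        assert res.value == pytest.approx(232.8)
        assert res.display == 233

    def test_zero_diversity(self):
        assert expected_polymorphic_sites(7760, 30, 0.0).value == 0.0

    def test_simple_product(self):
        assert expected_polymorphic_sites(100, 36, 1e-2).value == pytest.approx(36.0)
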