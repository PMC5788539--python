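"""Site filtering, in-phase collapsing, haplotype clustering and the
heterozygote / recombinant classifiers."""

import numpy as np
import pytest

from demeseed.core import ConfigError, HET, HOM_ALT, HOM_REF, MISSING
from demeseed.haplocall import (
    call_haplotypes,
    classify_heterozygotes,
    cluster_haplotypes,
    collapse_in_phase,
    detect_recombinants,
    filter_sites,
)
from demeseed.sim import SimConfig, simulate_metapopulation

from conftest import make_matrix

N = MISSING


class TestFilterSites:
    def test_low_call_rate_site_removed(self):
        # 6/10 calls present (60%) < 70% threshold
        col = [0, 0, 0, 2, 2, 2, N, N, N, N]
        m = make_matrix(np.column_stack([col, [0] * 10]))
        out = filter_sites(m, min_call_rate=0.7)
        assert out.n_sites == 1 and out.sites["pos"].tolist() == [2]

    def test_mostly_het_site_removed(self):
        col = [1, 1, 1, 1, 1, 1, 1, 1, 0, 2]  # 8/10 het
        m = make_matrix(np.column_stack([col, [0] * 10]))
        out = filter_sites(m, max_het_fraction=0.5)
        assert out.sites["pos"].tolist() == [2]

    def test_clean_matrix_unchanged(self):
        m = make_matrix([[0, 2, 0], [2, 0, 2], [0, 2, 2]])
        assert filter_sites(m) == m

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.choice([N, 0, 1, 2], size=(12, 30), p=[0.2, 0.35, 0.1, 0.35]))
        once = filter_sites(m)
        assert filter_sites(once) == once

    def test_empty_matrix_warns(self):
        m = make_matrix(np.empty((0, 0), dtype=np.int8))
        with pytest.warns(UserWarning):
            out = filter_sites(m)
        assert out.n_sites == 0

    def test_invalid_fraction(self):
        m = make_matrix([[0, 2]])
        with pytest.raises(ConfigError):
            filter_sites(m, min_call_rate=0.0)


class TestCollapseInPhase:
    def test_identical_columns_same_locus_collapse_to_first(self):
        calls = np.array([[0, 0], [0, 0], [2, 2], [2, 2]])
        m = make_matrix(calls, loci=["R1", "R1"])
        out = collapse_in_phase(m)
        assert out.sites["pos"].tolist() == [1]

    def test_antiphase_columns_also_collapse(self):
        # swapped coding still defines the same partition of individuals
        calls = np.array([[0, 2], [0, 2], [2, 0], [2, 0]])
        m = make_matrix(calls, loci=["R1", "R1"])
        assert collapse_in_phase(m).n_sites == 1

    def test_discordant_columns_kept(self):
        calls = np.array([[0, 0], [0, 2], [2, 2], [2, 2]])
        m = make_matrix(calls, loci=["R1", "R1"])
        assert collapse_in_phase(m).n_sites == 2

    def test_distinct_loci_untouched(self):
        calls = np.array([[0, 0], [0, 0], [2, 2]])
        m = make_matrix(calls)  # each site its own locus
        assert collapse_in_phase(m) == m

    def test_never_changes_retained_calls(self):
        rng = np.random.default_rng(1)
        calls = rng.choice([N, 0, 2], size=(10, 12))
        m = make_matrix(calls, loci=[f"R{j // 3}" for j in range(12)])
        out = collapse_in_phase(m)
        assert out.n_sites <= m.n_sites
        kept = m.sites["pos"].isin(out.sites["pos"]).to_numpy()
        assert np.array_equal(out.calls, m.calls[:, kept])


class TestClusterHaplotypes:
    def test_all_identical_is_one_haplotype(self):
        m = make_matrix([[0, 2, 0]] * 5)
        catalog, table = cluster_haplotypes(m, location_code="O")
        assert catalog.majors == ["HO1"]
        assert (table["kind"] == "haplotype").all()

    def test_one_snp_singleton_is_minor_variant(self):
        base = [0, 2, 0, 2, 0, 2, 0, 2]
        variant = list(base)
        variant[0] = 2
        m = make_matrix([base] * 4 + [variant])
        catalog, table = cluster_haplotypes(m, minor_variant_max_diff=2,
                                            location_code="O")
        assert catalog.majors == ["HO1"]
        row = table[table["individual_id"] == "ind4"].iloc[0]
        assert row["kind"] == "minor_variant"
        assert row["haplotype"] == "HO1" and row["entry"] == "HO1-1"
        assert row["k_diffs"] == 1

    def test_distant_singleton_becomes_major(self):
        base = [0] * 10
        far = [2] * 10
        m = make_matrix([base] * 3 + [far])
        catalog, _ = cluster_haplotypes(m, location_code="O")
        assert catalog.majors == ["HO1", "HO2"]
        assert catalog.n_individuals["HO2"] == 1

    def test_low_overlap_individual_unassigned(self):
        base = [0, 2, 0, 2, 0, 2, 0, 2, 0, 2]
        sparse = [0] + [N] * 9
        m = make_matrix([base] * 3 + [sparse])
        _, table = cluster_haplotypes(m, min_overlap=0.5)
        assert table[table["individual_id"] == "ind3"]["kind"].iloc[0] == "unassigned"

    def test_recovers_simulated_partition_exactly(self, small_layout):
        pytest.importorskip("sklearn")
        from sklearn.metrics import adjusted_rand_score

        cfg = SimConfig(
            n_demes=30, outcross_rate=0.0, recombinant_rate=0.0, error_rate=0.0,
            missing_rate=0.0, n_sites=12, chromosome_layout=small_layout, seed=21,
        )
        matrix, _, truth = simulate_metapopulation(cfg)
        _, table = cluster_haplotypes(matrix)
        merged = table.merge(
            truth.labels, on="individual_id", suffixes=("_call", "_true")
        )
        ari = adjusted_rand_score(merged["h1_true"], merged["haplotype"])
        assert ari == 1.0

    def test_major_naming_follows_descending_count(self):
        a, b = [0] * 8, [2] * 8
        m = make_matrix([b] * 2 + [a] * 5)
        catalog, _ = cluster_haplotypes(m, location_code="S")
        assert catalog.n_individuals["HS1"] == 5
        assert catalog.n_individuals["HS2"] == 2


class TestClassifyHeterozygotes:
    @staticmethod
    def _catalog():
        h1 = np.array([0, 0, 0, 0, 2, 2, 2, 2], dtype=np.int8)
        h2 = np.array([0, 0, 0, 0, 0, 0, 0, 0], dtype=np.int8)
        m = make_matrix([h1] * 3 + [h2] * 3)
        catalog, _ = cluster_haplotypes(m, location_code="S")
        return catalog

    def test_full_heterozygote_is_f1(self):
        cat = self._catalog()
        calls = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=np.int8)
        res = classify_heterozygotes(calls, cat)
        assert res["kind"] == "F1"
        assert {res["h1"], res["h2"]} == {"HS1", "HS2"}

    def test_partial_heterozygosity_is_contamination(self):
        cat = self._catalog()
        calls = np.array([0, 0, 0, 0, 1, 2, 2, 2], dtype=np.int8)  # 25% of diag
        res = classify_heterozygotes(calls, cat, f1_min_het_fraction=0.9)
        assert res["kind"] == "contaminated"

    def test_homozygote_rejected(self):
        cat = self._catalog()
        with pytest.raises(ConfigError):
            classify_heterozygotes(np.zeros(8, dtype=np.int8), cat)

    def test_simulated_f1s_all_recovered_with_correct_parents(self, small_layout):
        cfg = SimConfig(
            n_demes=60, lambda_founders=8.0, outcross_rate=0.15,
            recombinant_rate=0.0, error_rate=0.0, missing_rate=0.0,
            pool_frequencies=(1 / 3, 1 / 3, 1 / 3), n_sites=12,
            chromosome_layout=small_layout, seed=22,
        )
        matrix, _, truth = simulate_metapopulation(cfg)
        catalog, table = call_haplotypes(matrix, location_code="S")
        # map catalog names back to simulator pool indices via consensus
        name_of = {}
        for name in catalog.majors:
            for h in range(cfg.n_haplotypes):
                if np.array_equal(catalog.consensus(name), truth.haplotype_calls[h]):
                    name_of[h] = name
        true_f1 = truth.labels[truth.labels["kind"] == "F1"]
        assert len(true_f1) > 0
        called = table.set_index("individual_id")
        for row in true_f1.itertuples():
            got = called.loc[row.individual_id]
            assert got["kind"] == "F1"
            assert {got["h1"], got["h2"]} == {name_of[row.h1], name_of[row.h2]}

    def test_f1_fraction_tracks_outcross_rate(self, small_layout):
        cfg = SimConfig(
            n_demes=150, lambda_founders=8.0, outcross_rate=0.10,
            recombinant_rate=0.0, error_rate=0.0, missing_rate=0.0,
            pool_frequencies=(1 / 3, 1 / 3, 1 / 3), n_sites=12,
            chromosome_layout=small_layout, seed=23,
        )
        matrix, _, _ = simulate_metapopulation(cfg)
        _, table = call_haplotypes(matrix, location_code="S")
        frac = (table["kind"] == "F1").mean()
        se = np.sqrt(0.10 * 0.90 / len(table))
        # slight deficit possible: outcrossing needs two distinct founder
        # genotypes in the deme, near-certain at lambda = 8 with 3 haplotypes
        assert abs(frac - 0.10) < 3 * se + 0.01


class TestDetectRecombinants:
    @staticmethod
    def _setup():
        rng = np.random.default_rng(5)
        h1 = rng.choice([0, 2], size=20).astype(np.int8)
        h2 = (2 - h1).astype(np.int8)  # diagnostic at every site
        chroms = ["I"] * 8 + ["V"] * 12
        m = make_matrix([h1] * 3 + [h2] * 3, chroms=chroms,
                        positions=list(range(1, 9)) + list(range(1, 13)))
        catalog, _ = cluster_haplotypes(m, location_code="S")
        return m, catalog, h1, h2

    def test_terminal_block_called_recombinant(self):
        m, catalog, h1, h2 = self._setup()
        mosaic = h1.copy()
        mosaic[-6:] = h2[-6:]  # right tip of chromosome V
        res = detect_recombinants(mosaic, m.sites, catalog, min_block_sites=3)
        assert res is not None and res["kind"] == "recombinant"
        assert res["haplotype"] == "HS1"
        (seg,) = res["segments"]
        assert seg["chrom"] == "V" and seg["n_sites"] == 6

    def test_pure_haplotype_is_not_recombinant(self):
        m, catalog, h1, _ = self._setup()
        assert detect_recombinants(h1.copy(), m.sites, catalog) is None

    def test_isolated_discordance_falls_through(self):
        m, catalog, h1, h2 = self._setup()
        variant = h1.copy()
        variant[10] = h2[10]
        assert detect_recombinants(variant, m.sites, catalog, min_block_sites=3) is None

    def test_small_catalog_unassigned(self):
        m, _, h1, _ = self._setup()
        from demeseed.haplocall import HaplotypeCatalog

        solo = HaplotypeCatalog(entries={"HS1": h1}, majors=["HS1"],
                                n_individuals={"HS1": 3})
        res = detect_recombinants(h1.copy(), m.sites, solo)
        assert res["kind"] == "unassigned"

    def test_pipeline_reclassifies_mosaic_singleton(self):
        m, catalog, h1, h2 = self._setup()
        mosaic = h1.copy()
        mosaic[-6:] = h2[-6:]
        stacked = make_matrix(
            np.vstack([m.calls, mosaic]),
            chroms=m.sites["chrom"].tolist(),
            positions=m.sites["pos"].tolist(),
            loci=m.sites["rad_locus"].tolist(),
        )
        cat, table = call_haplotypes(stacked, location_code="S")
        rec = table[table["kind"] == "recombinant"]
        assert len(rec) == 1
        assert rec.iloc[0]["segments"].startswith("V:")
        assert len(cat.majors) == 2  # the mosaic did not found its own major

    def test_isolated_discordance_stays_minor_variant(self):
        m, catalog, h1, h2 = self._setup()
        variant = h1.copy()
        variant[10] = h2[10]
        stacked = make_matrix(
            np.vstack([m.calls, variant]),
            chroms=m.sites["chrom"].tolist(),
            positions=m.sites["pos"].tolist(),
            loci=m.sites["rad_locus"].tolist(),
        )
        _, table = call_haplotypes(stacked, location_code="S")
        last = table.iloc[-1]
        assert last["kind"] == "minor_variant" and last["k_diffs"] == 1
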