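import numpy as np
import pandas as pd
import pytest

from fourfold.bootstrap import bootstrap_deficit, build_pair_index
from fourfold.simulate import GeneratorConfig, generate_sites
from fourfold.sites import filter_and_resample
from fourfold.strata import (
    PreferenceTable,
    RateBins,
    annotate_positional_features,
    bin_by_substitutions,
    classify_preference,
    group_and_estimate,
    polarize,
    rank_genes_surrogate,
    tertiles,
)

from conftest import make_sites


class TestRateBins:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (0.0, "b1"),
            (0.01, "b2"),
            (1.4, "b2"),
            (1.41, "b3"),
            (1.92, "b3"),
            (3.10, "b4"),
            (4.40, "b5"),
            (6.20, "b6"),
            (9.299, "b7"),
            (9.30, "b8"),
            (12.0, "b8"),
        ],
    )
    def test_boundary_assignment(self, value, expected):
        assert RateBins().assign(np.array([value]))[0] == expected

    def test_uniform_draws_partition(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 12, 5000)
        labels = RateBins().assign(x)
        assert set(labels) <= set(RateBins().labels)
        assert len(labels) == 5000  # every site assigned exactly once

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            RateBins().assign(np.array([-0.1]))

    def test_bin_by_substitutions_groups(self):
        df = make_sites(
            [{"subst_count": v} for v in (0.0, 0.5, 2.0, 10.0)]
        )
        groups = bin_by_substitutions(df)
        assert {k: len(v) for k, v in groups.items()} == {
            "b1": 1, "b2": 1, "b4": 1, "b8": 1
        }


class TestPreference:
    @pytest.mark.parametrize(
        "codon,expected",
        [("GCC", "P"), ("GGC", "P"), ("CCC", "P"), ("ACC", "P"), ("GTG", "P"),
         ("CCA", "U"), ("CCG", "U"), ("GGA", "U"), ("GTT", "U")],
    )
    def test_optimal_codon_table(self, codon, expected):
        assert classify_preference(codon) == expected

    def test_non_fourfold_codon_rejected(self):
        with pytest.raises(ValueError, match="four-fold"):
            classify_preference("ATG")

    def test_custom_table_validated(self):
        with pytest.raises(ValueError):
            PreferenceTable({"A": "GGC"})  # GGC encodes Gly, not Ala


class TestPolarize:
    def test_outgroup_matches_major(self):
        assert polarize("C", "T", "C") == ("C", "PARSIMONY")

    def test_outgroup_matches_minor(self):
        assert polarize("C", "T", "T") == ("T", "PARSIMONY")

    def test_major_fallback_keeps_site(self):
        assert polarize("C", "T", "G") == ("C", "MAJOR_FALLBACK")

    def test_monomorphic_ten_species(self):
        assert polarize("A", None, "A", context="ten_species") == ("A", "PARSIMONY")

    def test_ten_species_mismatch_unpolarized(self):
        anc, method = polarize("C", "T", "G", context="ten_species")
        assert anc == "UNPOLARIZED" and method == "MISMATCH"

    def test_missing_outgroup_is_error_in_single_mode(self):
        with pytest.raises(ValueError, match="outgroup"):
            polarize("C", "T", None)


class TestTertiles:
    @pytest.mark.parametrize("k", [9, 10, 11, 12, 100])
    def test_group_sizes_differ_by_at_most_one(self, k):
        s = pd.Series(np.arange(k, dtype=float), index=[f"g{i}" for i in range(k)])
        labels = tertiles(s)
        sizes = labels.value_counts()
        assert sizes.max() - sizes.min() <= 1

    def test_ties_broken_deterministically(self):
        s = pd.Series([1.0] * 6, index=list("abcdef"))
        assert (tertiles(s) == tertiles(s.copy())).all()


class TestPositionalFeatures:
    @pytest.fixture
    def gene_models(self):
        return pd.DataFrame(
            [
                {
                    "gene_id": "gA", "chrom": "2L", "strand": "+",
                    "exon_starts": "1000;1300", "exon_ends": "1149;1449",
                    "cds_length": 300, "gene_length": 450,
                },
                {
                    "gene_id": "gB", "chrom": "X", "strand": "+",
                    "exon_starts": "5000", "exon_ends": "5149",
                    "cds_length": 150, "gene_length": 150,
                },
            ]
        )

    def test_near_start_boundary(self, gene_models):
        sites = make_sites(
            [
                {"pos": 1030, "gene_id": "gA"},   # cds_pos 31
                {"pos": 1075, "gene_id": "gA"},   # cds_pos 76 -> not near start
                {"pos": 1448, "gene_id": "gA"},   # near stop
            ]
        )
        out = annotate_positional_features(sites, gene_models)
        assert out["attr:near_start_75"].tolist() == [True, False, False]
        assert out["attr:near_stop_75"].tolist() == [False, False, True]

    def test_splice_distance_and_single_exon(self, gene_models):
        sites = make_sites(
            [
                {"pos": 1140, "gene_id": "gA"},  # 9 bp from exon1 end
                {"pos": 5075, "gene_id": "gB", "chrom": "X"},  # single exon
            ]
        )
        out = annotate_positional_features(sites, gene_models)
        assert out["attr:near_splice_48"].tolist() == [True, False]
        assert out["attr:single_exon"].tolist() == [False, True]
        assert out["attr:x_linked"].tolist() == [False, True]

    def test_unknown_gene_warns_and_counts(self, gene_models):
        sites = make_sites([{"pos": 99999, "gene_id": "gZ"}])
        with pytest.warns(UserWarning, match="not in any supplied gene model"):
            out = annotate_positional_features(sites, gene_models)
        assert out.attrs["n_unmatched"] == 1
        assert pd.isna(out["attr:near_start_75"].iloc[0])


class TestGroupAndEstimate:
    def _cohort(self, f_strong, n, seed):
        cfg = GeneratorConfig(n_4d_sites=n, n_si_sites=n, f_strong=f_strong)
        sites = generate_sites(cfg, seed=seed)
        filt = filter_and_resample(sites, rng=seed + 1)
        return (
            filt[filt["site_class"] == "4D"],
            filt[filt["site_class"] == "SI"],
        )

    def test_groups_with_different_selection_are_ordered(self):
        test_a, ref_a = self._cohort(0.3, 100_000, seed=41)
        test_b, ref_b = self._cohort(0.1, 100_000, seed=43)
        # common reference pool; group B shifted to distinct coordinates
        test_b = test_b.assign(pos=test_b["pos"] + 50_000_000)
        ref_b = ref_b.assign(pos=ref_b["pos"] + 50_000_000)
        ests = group_and_estimate(
            {"A": test_a, "B": test_b},
            pd.concat([ref_a, ref_b], ignore_index=True),
            n_boot=10,
            seed=45,
        )
        a, b = ests["A"], ests["B"]
        assert a.mean_deficit - 2 * a.se > b.mean_deficit + 2 * b.se

    def test_single_group_matches_global_bootstrap(self):
        test, ref = self._cohort(0.2, 30_000, seed=47)
        ests = group_and_estimate({"all": test}, ref, n_boot=10, seed=48)
        direct = bootstrap_deficit(build_pair_index(test, ref), n_boot=10, seed=49)
        assert ests["all"].mean_deficit == pytest.approx(
            direct.mean_deficit, abs=3 * direct.se
        )

    def test_unpairable_group_skipped_with_warning(self):
        test, ref = self._cohort(0.2, 5_000, seed=51)
        orphan = test.head(10).assign(chrom="4")
        with pytest.warns(UserWarning, match="skipped"):
            ests = group_and_estimate({"ok": test, "orphan": orphan}, ref,
                                      n_boot=2, seed=52)
        assert "orphan" not in ests and "ok" in ests

    def test_negative_deficit_reported_unclamped(self):
        rng = np.random.default_rng(53)
        rows_t, rows_r = [], []
        for i in range(4000):
            seg_t = rng.random() < 0.3   # test denser than reference
            seg_r = rng.random() < 0.1
            rows_t.append({"pos": 10_000 * i, "major_allele": "G",
                           "minor_allele": "A" if seg_t else None,
                           "minor_count": int(seg_t), "n_alleles": 1 + seg_t})
            rows_r.append({"pos": 10_000 * i + 100, "major_allele": "G",
                           "site_class": "SI",
                           "minor_allele": "A" if seg_r else None,
                           "minor_count": int(seg_r), "n_alleles": 1 + seg_r})
        ests = group_and_estimate({"x": make_sites(rows_t)}, make_sites(rows_r),
                                  n_boot=5, seed=54)
        assert ests["x"].mean_deficit < -1.0


class TestGeneRanking:
    def _sites(self):
        rows = []
        # gene g1: 10 conserved-AA SNP-free sites, 4 unpreferred+conserved
        for i in range(10):
            rows.append(
                {"pos": i, "gene_id": "g1", "preference": "U" if i < 4 else "P",
                 "subst_count": 0.0 if i < 4 else 2.0, "codon_anc": "GCC"}
            )
        # gene g2: only 1 of 10 sites in a conserved amino acid -> ineligible
        for i in range(10):
            rows.append(
                {"pos": 100 + i, "gene_id": "g2", "preference": "P",
                 "subst_count": 1.0}
            )
        df = make_sites(rows)
        df["attr:conserved_aa"] = df["gene_id"].eq("g1") | (df["pos"] == 100)
        return df

    def test_score_arithmetic(self):
        ranking = rank_genes_surrogate(self._sites(), min_conserved_frac=0.2)
        assert ranking.scores.loc["g1"] == pytest.approx(0.4)

    def test_low_conservation_gene_ineligible(self):
        ranking = rank_genes_surrogate(self._sites(), min_conserved_frac=0.2)
        assert "g2" not in ranking.scores.index
        assert ranking.n_eligible == 1

    def test_top_fraction_size(self):
        rows = []
        rng = np.random.default_rng(7)
        for g in range(12):
            for i in range(10):
                rows.append(
                    {"pos": 1000 * g + i, "gene_id": f"g{g:02d}",
                     "preference": "U" if rng.random() < 0.5 else "P",
                     "subst_count": float(rng.random() < 0.5)}
                )
        df = make_sites(rows)
        df["attr:conserved_aa"] = True
        ranking = rank_genes_surrogate(df, top_frac=1 / 6)
        assert ranking.n_eligible == 12 and len(ranking.top_genes) == 2

    def test_snp_sites_excluded_from_score(self):
        df = self._sites()
        # add SNPs at unpreferred-conserved sites of g1: score must drop
        df.loc[df["gene_id"].eq("g1") & (df["pos"] < 2), "minor_count"] = 3
        df.loc[df["gene_id"].eq("g1") & (df["pos"] < 2), "minor_allele"] = "T"
        ranking = rank_genes_surrogate(df)
        assert ranking.scores.loc["g1"] == pytest.approx(2 / 8)

    def test_no_eligible_genes_is_error(self):
        df = self._sites()
        df["attr:conserved_aa"] = False
        with pytest.raises(ValueError, match="no eligible genes"):
            rank_genes_surrogate(df)
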