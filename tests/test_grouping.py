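"""Functional-group clustering, LDA verification and trait contrasts."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import traitsoil as ts
from traitsoil.grouping import TRAIT_NAMES


def _constantish_traits(n, rng):
    """Traits carrying no group signal: one jittered column, rest constant."""
    return pd.DataFrame({
        "species_id": [f"s{i:03d}" for i in range(n)],
        "height": 10.0 + rng.normal(0, 1e-6, n),
        "perenniality": 3, "sla": 20.0, "root_architecture": 4,
        "root_depth": 2, "mycorrhizal_affinity": 2,
    })


class TestClusterSpecies:
    def test_recovers_three_generated_syndromes(self, three_syndrome_traits):
        traits, truth = three_syndrome_traits
        out = ts.cluster_species(traits, k=3)
        ari = adjusted_rand_score(truth.loc[out.table["species_id"]],
                                  out.table["group"])
        assert ari == 1.0

    def test_k1_puts_everything_in_group_1(self, tiny_traits):
        out = ts.cluster_species(tiny_traits, k=1)
        assert (out.table["group"] == 1).all()

    def test_two_distinct_species_forced_apart(self, tiny_traits):
        out = ts.cluster_species(tiny_traits.iloc[:2], k=2)
        assert sorted(out.table["group"]) == [1, 2]

    def test_fewer_species_than_k_errors(self, tiny_traits):
        with pytest.raises(ValueError, match="insufficient species"):
            ts.cluster_species(tiny_traits, k=10)

    def test_identical_rows_error(self):
        traits = pd.DataFrame({
            "species_id": ["a", "b", "c"], "height": 5.0, "perenniality": 3,
            "sla": 20.0, "root_architecture": 4, "root_depth": 2,
            "mycorrhizal_affinity": 2,
        })
        with pytest.raises(ValueError, match="degenerate trait matrix"):
            ts.cluster_species(traits, k=2)

    def test_partition_is_row_order_invariant(self, three_syndrome_traits):
        traits, _ = three_syndrome_traits
        shuffled = traits.sample(frac=1, random_state=7).reset_index(drop=True)
        a = ts.cluster_species(traits, k=3).groups
        b = ts.cluster_species(shuffled, k=3).groups
        pd.testing.assert_series_equal(a.sort_index(), b.sort_index())

    def test_diana_separates_clean_syndromes(self, three_syndrome_traits):
        traits, truth = three_syndrome_traits
        out = ts.cluster_species(traits, k=3, method="diana")
        ari = adjusted_rand_score(truth.loc[out.table["species_id"]],
                                  out.table["group"])
        assert ari == 1.0

    def test_labels_ordered_by_group_size(self, three_syndrome_traits):
        traits, _ = three_syndrome_traits
        # drop some species from one generated group to break the size tie
        keep = traits["species_id"].str.startswith("sp_g1_0") | \
            ~traits["species_id"].str.startswith("sp_g1")
        out = ts.cluster_species(traits[keep], k=3)
        sizes = [out.group_sizes()[g] for g in sorted(out.group_sizes())]
        assert sizes == sorted(sizes, reverse=True)

    def test_duplicate_species_rejected(self, tiny_traits):
        dup = pd.concat([tiny_traits, tiny_traits.iloc[:1]])
        with pytest.raises(ValueError, match="duplicate species_id"):
            ts.cluster_species(dup, k=2)

    def test_median_imputation_of_sparse_missingness(self, three_syndrome_traits):
        traits, truth = three_syndrome_traits
        holey = traits.copy()
        holey.loc[holey.index[:3], "sla"] = np.nan
        out = ts.cluster_species(holey, k=3)
        assert len(out.table) == len(traits)

    def test_excessive_missingness_errors(self, three_syndrome_traits):
        traits, _ = three_syndrome_traits
        holey = traits.copy()
        holey.loc[holey.index[: int(0.5 * len(holey))], "sla"] = np.nan
        with pytest.raises(ValueError, match="cannot impute"):
            ts.cluster_species(holey, k=3)


class TestVerifyLda:
    def test_clean_syndromes_agree_fully(self, three_syndrome_traits):
        traits, _ = three_syndrome_traits
        assignment = ts.cluster_species(traits, k=3)
        out = ts.verify_lda(traits, assignment)
        assert out.agreement_pct == 100.0
        assert set(out.table.columns) >= {"species_id", "group",
                                          "lda_predicted_group"}

    def test_two_groups_separable_on_one_trait(self):
        traits = pd.DataFrame({
            "species_id": [f"s{i}" for i in range(8)],
            "height": [10.0, 11.0, 12.0, 13.0, 30.0, 31.0, 32.0, 33.0],
            "perenniality": 3, "sla": 20.0, "root_architecture": 4,
            "root_depth": 2, "mycorrhizal_affinity": 2,
        })
        assignment = ts.cluster_species(traits, k=2)
        out = ts.verify_lda(traits, assignment)
        assert out.agreement_pct == 100.0

    def test_chance_level_on_uninformative_traits(self):
        """With no trait signal, LDA agreement sits near 100/k percent."""
        agreements = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            traits = _constantish_traits(60, rng)
            labels = pd.Series(rng.permutation(np.repeat([1, 2, 3], 20)),
                               index=traits["species_id"])
            assignment = ts.GroupAssignment(
                table=labels.rename("group").reset_index(), k=3)
            out = ts.verify_lda(traits, assignment)
            agreements.append(out.agreement_pct)
        assert abs(np.mean(agreements) - 100 / 3) < 15

    def test_singleton_group_rejected(self, tiny_traits):
        labels = pd.DataFrame({"species_id": tiny_traits["species_id"],
                               "group": [1, 1, 1, 2]})
        assignment = ts.GroupAssignment(table=labels, k=2)
        with pytest.raises(ValueError, match="group too small"):
            ts.verify_lda(tiny_traits, assignment)

    def test_leave_one_out_option_runs(self, three_syndrome_traits):
        traits, _ = three_syndrome_traits
        assignment = ts.cluster_species(traits, k=3)
        out = ts.verify_lda(traits, assignment, cross_validate=True)
        assert out.agreement_pct >= 93.8


class TestGroupTraitContrast:
    def test_identical_groups_give_f_zero(self):
        traits = pd.DataFrame({
            "species_id": [f"s{i}" for i in range(8)],
            "height": [1.0, 2.0, 3.0, 4.0] * 2,
            "perenniality": 3, "sla": 20.0, "root_architecture": 4,
            "root_depth": 2, "mycorrhizal_affinity": 2,
        })
        labels = pd.DataFrame({"species_id": traits["species_id"],
                               "group": [1] * 4 + [2] * 4})
        res = ts.group_trait_contrast(traits, ts.GroupAssignment(labels, 2),
                                      "height")
        assert res.f_statistic == pytest.approx(0.0)

    def test_generated_depth_contrast_is_strong(self, three_syndrome_traits):
        traits, _ = three_syndrome_traits
        assignment = ts.cluster_species(traits, k=3)
        res = ts.group_trait_contrast(traits, assignment, "root_depth")
        assert res.p_value < 0.001
        assert res.df1 == 2 and res.df2 == len(traits) - 3

    def test_df_convention_three_groups_83_species(self):
        """k=3 on 83 species reports (2, 80) degrees of freedom."""
        rng = np.random.default_rng(0)
        n = 83
        traits = pd.DataFrame({
            "species_id": [f"s{i:03d}" for i in range(n)],
            "height": rng.uniform(5, 50, n),
            "perenniality": rng.integers(1, 6, n),
            "sla": rng.uniform(5, 30, n),
            "root_architecture": rng.integers(1, 9, n),
            "root_depth": rng.integers(1, 4, n),
            "mycorrhizal_affinity": rng.integers(1, 4, n),
        })
        assignment = ts.cluster_species(traits, k=3)
        res = ts.group_trait_contrast(traits, assignment, "height")
        assert (res.df1, res.df2) == (2, 80)

    def test_f_invariant_to_affine_trait_rescaling(self, three_syndrome_traits):
        traits, _ = three_syndrome_traits
        assignment = ts.cluster_species(traits, k=3)
        base = ts.group_trait_contrast(traits, assignment, "height")
        scaled = traits.copy()
        scaled["height"] = scaled["height"] * 100 + 7
        res = ts.group_trait_contrast(scaled, assignment, "height")
        assert res.f_statistic == pytest.approx(base.f_statistic, rel=1e-9)

    def test_no_residual_variance_errors(self):
        traits = pd.DataFrame({
            "species_id": ["a", "b", "c", "d"],
            "height": [1.0, 1.0, 2.0, 2.0],
            "perenniality": 3, "sla": 20.0, "root_architecture": 4,
            "root_depth": 2, "mycorrhizal_affinity": 2,
        })
        labels = pd.DataFrame({"species_id": traits["species_id"],
                               "group": [1, 1, 2, 2]})
        with pytest.raises(ValueError, match="no residual variance"):
            ts.group_trait_contrast(traits, ts.GroupAssignment(labels, 2),
                                    "height")
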