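import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import jensenshannon
from sklearn.metrics import adjusted_rand_score

from ervkit import (
    BulkSimSpec,
    cluster_fc_analysis,
    cluster_stage_genes,
    log2fc,
    ltr_class_test,
    minmax_normalize,
    score_profiles,
    simulate_bulk,
    specificity_score,
    stage_profiles,
    tpm,
)
from ervkit.stage import specificity_scores


def _pipeline(seed=1, **spec_kw):
    counts, features, sheet, truth = simulate_bulk(BulkSimSpec(seed=seed, **spec_kw))
    expr = tpm(counts, features)
    genes = features.table.index[features.table["feature_class"] == "gene"]
    gene_expr = expr.subset(genes)
    profiles = stage_profiles(gene_expr, sheet)
    scores = score_profiles(profiles)
    return counts, features, sheet, truth, expr, gene_expr, profiles, scores


class TestSpecificityScore:
    def test_point_mass_scores_one(self):
        for s in range(4):
            profile = np.zeros(4)
            profile[s] = 7.5
            score, argmax = specificity_score(profile)
            assert score == pytest.approx(1.0)
            assert argmax == s

    def test_uniform_profile_matches_jsd_oracle(self):
        """The uniform 10-stage profile scores 1 - sqrt(JSD(u, e_s)),
        cross-checked against scipy's Jensen-Shannon distance."""
        score, argmax = specificity_score(np.ones(10))
        u = np.ones(10) / 10
        e = np.eye(10)[0]
        assert score == pytest.approx(1 - jensenshannon(u, e, base=2), abs=1e-12)
        assert score == pytest.approx(0.1292, abs=1e-3)
        assert argmax == 0  # tie resolves to the earliest stage

    def test_random_profiles_match_jsd_oracle(self, rng):
        profiles = rng.random((50, 6)) + 1e-9
        res = specificity_scores(profiles)
        for g in range(50):
            p = profiles[g] / profiles[g].sum()
            per_stage = [1 - jensenshannon(p, np.eye(6)[s], base=2) for s in range(6)]
            assert res["score"][g] == pytest.approx(max(per_stage), abs=1e-9)
            assert res["argmax_stage"][g] == int(np.argmax(per_stage))

    def test_permutation_invariance(self, rng):
        profile = rng.random(8)
        base, arg = specificity_score(profile)
        perm = rng.permutation(8)
        score, arg_p = specificity_score(profile[perm])
        assert score == pytest.approx(base, abs=1e-12)
        assert perm[arg_p] == arg

    def test_scores_bounded_and_spreading_decreases(self, rng):
        profiles = rng.random((2000, 10))
        res = specificity_scores(profiles + 1e-12)
        assert ((res["score"] >= 0) & (res["score"] <= 1 + 1e-12)).all()
        one_stage, _ = specificity_score([1, 0, 0, 0])
        two_stage, _ = specificity_score([1, 1, 0, 0])
        assert one_stage > two_stage

    def test_uniform_profile_scores_decrease_with_stages(self):
        """A perfectly uniform profile scores lower the more stages there
        are, and falls below the 0.2 staging threshold from S = 6 on (at
        S = 3..5 a uniform profile still scores 0.22-0.32)."""
        scores = [specificity_score(np.ones(s))[0] for s in range(3, 21)]
        assert (np.diff(scores) < 0).all()
        for s, score in zip(range(3, 21), scores):
            if s >= 6:
                assert score < 0.2
            else:
                assert score > 0.2

    def test_all_zero_rejected_but_flagged_in_table(self):
        with pytest.raises(ValueError, match="all-zero"):
            specificity_score(np.zeros(5))
        profiles = pd.DataFrame([[0, 0, 0], [1, 0, 0]], index=["dead", "live"],
                                columns=["a", "b", "c"])
        table = score_profiles(profiles)
        assert not table.loc["dead", "scored"]
        assert table.loc["live", "score"] == pytest.approx(1.0)


class TestClusterStageGenes:
    def test_noiseless_blocks_recovered_exactly(self):
        _, _, _, truth, _, _, profiles, scores = _pipeline(noiseless=True)
        clustering = cluster_stage_genes(profiles, scores, threshold=0.2, k=5, seed=1)
        assigned = clustering.table[clustering.table["cluster"] > 0]
        ari = adjusted_rand_score(
            truth.loc[assigned.index, "cluster"], assigned["cluster"]
        )
        assert ari == pytest.approx(1.0)

    def test_noisy_blocks_recovered(self):
        _, _, _, truth, _, _, profiles, scores = _pipeline()
        clustering = cluster_stage_genes(profiles, scores, threshold=0.2, k=5, seed=1)
        assigned = clustering.table[clustering.table["cluster"] > 0]
        ari = adjusted_rand_score(
            truth.loc[assigned.index, "cluster"], assigned["cluster"]
        )
        assert ari >= 0.9

    def test_labels_ordered_by_centroid_peak_and_deterministic(self):
        _, _, _, _, _, _, profiles, scores = _pipeline()
        c1 = cluster_stage_genes(profiles, scores, threshold=0.2, k=5, seed=1)
        c2 = cluster_stage_genes(profiles, scores, threshold=0.2, k=5, seed=1)
        assert c1.table["cluster"].equals(c2.table["cluster"])
        peaks = c1.centroids.to_numpy().argmax(axis=1)
        assert (np.diff(peaks) >= 0).all()

    def test_k_one_puts_all_passing_in_cluster_one(self):
        _, _, _, _, _, _, profiles, scores = _pipeline()
        clustering = cluster_stage_genes(profiles, scores, threshold=0.2, k=1, seed=1)
        assigned = clustering.table[clustering.table["cluster"] > 0]
        assert (assigned["cluster"] == 1).all()

    def test_too_few_passing_genes_rejected(self):
        profiles = pd.DataFrame(np.eye(3), columns=["a", "b", "c"])
        scores = score_profiles(profiles)
        with pytest.raises(ValueError, match="pass the threshold"):
            cluster_stage_genes(profiles, scores, threshold=0.2, k=5, seed=0)


class TestClusterFC:
    @pytest.fixture(scope="class")
    @staticmethod
    def fitted():
        counts, features, sheet, truth, expr, gene_expr, profiles, scores = _pipeline()
        clustering = cluster_stage_genes(profiles, scores, threshold=0.2, k=5, seed=1)
        lfc = log2fc(
            gene_expr,
            sheet.samples_where(condition="WT"),
            sheet.samples_where(condition="KO"),
        )
        return clustering, lfc, truth

    def test_planted_direction_recovered(self, fitted):
        """The 2C-stage cluster shows positive median KO/WT fold change and
        the ribosomal-gene cluster negative, both strongly significant."""
        clustering, lfc, _ = fitted
        stats = cluster_fc_analysis(clustering, lfc)
        assert stats.loc[1, "median_lfc"] > 0
        assert stats.loc[1, "p_value"] < 0.01
        assert stats.loc[5, "median_lfc"] < 0
        assert stats.loc[5, "p_value"] < 0.01

    def test_null_lfc_gives_null_stats(self, fitted):
        clustering, lfc, _ = fitted
        zero = pd.Series(0.0, index=lfc.index)
        stats = cluster_fc_analysis(clustering, zero)
        assert (stats["median_lfc"] == 0).all()
        assert (stats["p_value"] == 1.0).all()

    def test_rank_invariance_under_scaling(self, fitted):
        clustering, lfc, _ = fitted
        s1 = cluster_fc_analysis(clustering, lfc)
        s2 = cluster_fc_analysis(clustering, 2.0 * lfc)
        assert np.allclose(s2["median_lfc"], 2 * s1["median_lfc"])
        assert np.allclose(s2["p_value"], s1["p_value"])


class TestLtrClassTest:
    @pytest.fixture(scope="class")
    @staticmethod
    def norm_setup():
        counts, features, sheet, truth = simulate_bulk(BulkSimSpec(seed=1))
        expr = tpm(counts, features)
        repeats = features.table.index[features.table["feature_class"] == "repeat"]
        norm = minmax_normalize(expr.subset(repeats))
        return norm, features.families.loc[repeats], sheet

    def test_planted_family_shift_detected(self, norm_setup):
        norm, families, sheet = norm_setup
        tests = ltr_class_test(norm, families, sheet, side="greater")
        assert tests.loc["MERVL-int", "p_value"] < 0.01
        assert tests.loc["MT2_Mm", "p_value"] < 0.01
        null_families = [f for f in tests.index if f not in ("MERVL-int", "MT2_Mm")]
        assert (tests.loc[null_families, "p_value"] > 0.05).all()

    def test_equal_conditions_are_null(self, norm_setup):
        """Relabeling replicates of the same condition as pseudo-KO leaves
        the paired deltas exchangeable noise for every family."""
        from ervkit import ExpressionMatrix, SampleSheet

        norm, families, sheet = norm_setup
        wt_only = sheet.table[sheet.table["condition"] == "WT"].copy()
        wt_only["condition"] = np.where(wt_only["replicate"] == 1, "KO", "WT")
        sub = ExpressionMatrix(norm.values[wt_only.index.tolist()], unit=norm.unit)
        tests = ltr_class_test(sub, families, SampleSheet(wt_only))
        assert (tests["p_value"] > 1e-3).all()

    def test_constant_shift_invariance(self):
        from ervkit import ExpressionMatrix, SampleSheet

        vals = pd.DataFrame(
            {"w1": [0.1, 0.2, 0.3], "k1": [0.2, 0.4, 0.3]},
            index=["m1", "m2", "m3"],
        )
        fam = pd.Series("ERVL", index=vals.index)
        sheet = SampleSheet(
            pd.DataFrame(
                {"condition": ["WT", "KO"], "stage": ["", ""], "replicate": [1, 1]},
                index=["w1", "k1"],
            )
        )
        base = ltr_class_test(ExpressionMatrix(vals, unit="normalized01"), fam, sheet)
        shifted = ltr_class_test(
            ExpressionMatrix(vals * 0.5 + 0.2, unit="normalized01"), fam, sheet
        )
        # paired signed-rank depends only on within-member deltas' ranks
        assert base.loc["ERVL", "p_value"] == shifted.loc["ERVL", "p_value"]
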