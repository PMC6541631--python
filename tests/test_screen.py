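import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cytoscreen as cs
from cytoscreen.screen import (
    combined_rank,
    dichotomize_mean,
    dual_marker_groups,
    iterative_km,
    joint_stratify,
    screen_genes,
    select_joint_cells,
    stratify_zscore,
    zygosity_groups,
)


class TestDichotomizeMean:
    def test_tie_at_mean_goes_low(self):
        labels = dichotomize_mean(pd.Series([1.0, 2.0, 3.0], index=list("abc")))
        assert labels.tolist() == ["low", "low", "high"]

    def test_symmetric_pair_splits_evenly(self):
        labels = dichotomize_mean(pd.Series([-1.0, 1.0]))
        assert sorted(labels) == ["high", "low"]

    def test_partition_covers_all_non_missing(self):
        rng = np.random.default_rng(1)
        v = pd.Series(rng.standard_normal(50))
        v.iloc[:7] = np.nan
        labels = dichotomize_mean(v)
        assert len(labels) == 43
        assert ((labels == "high").sum() + (labels == "low").sum()) == 43

    def test_too_few_values_is_error(self):
        with pytest.raises(ValueError):
            dichotomize_mean(pd.Series([1.0, np.nan]))


class TestStratifyZscore:
    def test_threshold_band(self, normalized_null):
        expr = normalized_null
        gene = expr.gene_ids[0]
        z = expr.gene(gene)
        labels = stratify_zscore(expr, gene)
        assert (z[labels[labels == "high"].index] > 0.25).all()
        assert (z[labels[labels == "low"].index] < -0.25).all()
        excluded = z.index.difference(labels.index)
        assert z[excluded].between(-0.25, 0.25).all()

    def test_equal_thresholds_rejected(self, normalized_null):
        with pytest.raises(ValueError):
            stratify_zscore(normalized_null, normalized_null.gene_ids[0], 0.0, 0.0)

    def test_exclusion_fraction_matches_normal_band(self):
        # standard-normal z: P(-0.25 <= Z <= 0.25) ~ 0.1974
        cohort = cs.simulate_cohort(cs.SyntheticCohortConfig(
            n_samples=5000, n_genes=3, rng_seed=77))
        expr = cs.zscore_normalize(cohort.expression)
        labels = stratify_zscore(expr, expr.gene_ids[0])
        excluded_frac = 1 - len(labels) / 5000
        expected = stats.norm.cdf(0.25) - stats.norm.cdf(-0.25)
        assert excluded_frac == pytest.approx(expected, abs=0.03)

    def test_requires_normalized(self, null_cohort):
        with pytest.raises(ValueError):
            stratify_zscore(null_cohort.expression, null_cohort.expression.gene_ids[0])


class TestDualMarker:
    def test_discordant_patients_excluded(self):
        df = pd.DataFrame(
            [[2.0, 2.0, 0.0, 0.0], [2.0, 0.0, 2.0, 0.0]],
            index=pd.Index(["A", "B"], name="gene"),
            columns=["s1", "s2", "s3", "s4"],
        )
        expr = cs.ExpressionMatrix(values=df)
        labels = dual_marker_groups(expr, "A", "B")
        assert labels.to_dict() == {"s1": "both_high", "s4": "both_low"}

    def test_identical_genes_no_exclusions(self, normalized_null):
        expr = normalized_null
        g = expr.gene_ids[0]
        dual = dual_marker_groups(expr, g, g)
        single = dichotomize_mean(expr.gene(g))
        assert len(dual) == len(single)
        assert (dual == single.map({"high": "both_high", "low": "both_low"})).all()

    def test_correlated_harmful_pair_is_directionally_harmful(self, pair_cohort):
        expr = cs.zscore_normalize(pair_cohort.expression)
        labels = dual_marker_groups(expr, "LIG_TRUE", "REC_TRUE")
        surv = pair_cohort.clinical.endpoint("OS").loc[labels.index]
        fit = cs.cox_fit_binary(surv["time"], surv["event"], labels)
        hr_high = fit.hazard_ratio if fit.groups[1] == "both_high" else 1 / fit.hazard_ratio
        assert hr_high > 1.0

    def test_empty_group_is_named(self):
        df = pd.DataFrame(
            [[2.0, 1.9, 0.0, 0.1], [0.0, 0.1, 2.0, 1.9]],
            index=pd.Index(["A", "B"], name="gene"),
            columns=["s1", "s2", "s3", "s4"],
        )
        expr = cs.ExpressionMatrix(values=df)
        with pytest.raises(ValueError, match="both_high"):
            dual_marker_groups(expr, "A", "B")


class TestZygosity:
    def test_code_map_and_frequencies(self):
        df = pd.DataFrame([[0, -1, -1, 0]], index=pd.Index(["SIRT1"], name="gene"),
                          columns=["s1", "s2", "s3", "s4"])
        labels, freqs = zygosity_groups(cs.CopyNumberTable(calls=df), "SIRT1")
        assert labels.tolist() == ["diploid", "hetloss", "hetloss", "diploid"]
        assert freqs == {"diploid": 0.5, "hetloss": 0.5}

    def test_amplification_code(self):
        df = pd.DataFrame([[2, -2]], index=pd.Index(["RELB"], name="gene"),
                          columns=["s1", "s2"])
        labels, _ = zygosity_groups(cs.CopyNumberTable(calls=df), "RELB")
        assert labels.tolist() == ["amplification", "deep_deletion"]

    def test_hetloss_effect_shortens_km_median(self):
        cfg = cs.SyntheticCohortConfig(
            n_samples=400, n_genes=5,
            copy_number=(cs.CopyNumberSpec(
                gene="SUPPRESSOR", state_probs={-1: 0.5, 0: 0.5},
                state_log_hazard={-1: 1.0}),),
            censor_horizon=200.0, dropout_rate=0.0, rng_seed=88,
        )
        cohort = cs.simulate_cohort(cfg)
        labels, _ = zygosity_groups(cohort.copy_number, "SUPPRESSOR")
        surv = cohort.clinical.endpoint("OS")
        medians = {}
        for grp in ("diploid", "hetloss"):
            idx = labels[labels == grp].index
            medians[grp] = cs.km_estimate(
                surv.loc[idx, "time"], surv.loc[idx, "event"]).median_survival
        assert medians["hetloss"] < medians["diploid"]


class TestJointStratify:
    def test_cell_shares_match_independent_normals(self):
        cohort = cs.simulate_cohort(cs.SyntheticCohortConfig(
            n_samples=4000, n_genes=4, rng_seed=5))
        expr = cs.zscore_normalize(cohort.expression)
        labels = joint_stratify(expr, expr.gene_ids[0], expr.gene_ids[1])
        p_hi = stats.norm.sf(0.25)
        share = (labels == "high/high").sum() / 4000
        assert share == pytest.approx(p_hi**2, abs=0.03)

    def test_anticorrelated_genes_empty_concordant_cell(self):
        rng = np.random.default_rng(2)
        z = rng.standard_normal(100)
        df = pd.DataFrame([z, -z], index=pd.Index(["A", "B"], name="gene"),
                          columns=[f"s{i}" for i in range(100)])
        expr = cs.zscore_normalize(cs.ExpressionMatrix(values=df))
        labels = joint_stratify(expr, "A", "B")
        assert (labels == "high/high").sum() == 0

    def test_selected_cells_are_disjoint_partition(self, normalized_null):
        expr = normalized_null
        labels = joint_stratify(expr, expr.gene_ids[0], expr.gene_ids[1])
        picked = select_joint_cells(labels, {"high/low"}, {"low/high"})
        assert set(picked.unique()) == {"group_a", "group_b"}
        assert picked[picked == "group_a"].index.intersection(
            picked[picked == "group_b"].index).empty

    def test_empty_selection_is_error(self, normalized_null):
        expr = normalized_null
        labels = joint_stratify(expr, expr.gene_ids[0], expr.gene_ids[0])
        # a gene crossed with itself has no discordant cells
        with pytest.raises(ValueError):
            select_joint_cells(labels, {"high/low"}, {"low/high"})


class TestScreenGenes:
    def test_planted_gene_attains_rank_one(self, planted_cohort):
        expr = cs.zscore_normalize(planted_cohort.expression)
        res = screen_genes(expr, planted_cohort.clinical)
        assert res.rank_of("PLANTED") == 1.0

    def test_null_pvalues_are_uniform(self, normalized_null, null_cohort):
        res = screen_genes(normalized_null, null_cohort.clinical)
        ks = stats.kstest(res.table["p_value"], "uniform")
        assert ks.pvalue > 0.01

    def test_gene_order_does_not_change_pvalues(self, normalized_pair, pair_cohort):
        res1 = screen_genes(normalized_pair, pair_cohort.clinical)
        shuffled = list(reversed(normalized_pair.gene_ids))
        res2 = screen_genes(normalized_pair, pair_cohort.clinical, shuffled)
        m1 = dict(zip(res1.table["gene"], res1.table["p_value"]))
        m2 = dict(zip(res2.table["gene"], res2.table["p_value"]))
        assert m1 == m2

    def test_missing_genes_reported(self, normalized_null, null_cohort):
        model = cs.SurvivalScreen(normalized_null, null_cohort.clinical,
                                  genes=["NOT_A_GENE"] + normalized_null.gene_ids[:3])
        assert model.missing_genes == ["NOT_A_GENE"]
        assert model.fit().n_genes == 3

    def test_ranks_are_permutation(self, normalized_null, null_cohort):
        res = screen_genes(normalized_null, null_cohort.clinical)
        ranks = np.sort(res.table["rank"].to_numpy())
        np.testing.assert_allclose(ranks, np.arange(1, len(ranks) + 1))

    def test_dfs_endpoint_runs(self, normalized_pair, pair_cohort):
        res = screen_genes(normalized_pair, pair_cohort.clinical, endpoint="DFS")
        assert res.endpoint == "DFS"
        assert res.rank_of("LIG_TRUE") <= 3

    def test_summary_is_printable(self, normalized_null, null_cohort):
        res = screen_genes(normalized_null, null_cohort.clinical)
        s = res.summary()
        assert "genes tested" in s


class TestIterativeKM:
    def test_alpha_one_returns_all_testable(self, normalized_null, null_cohort):
        full = screen_genes(normalized_null, null_cohort.clinical)
        it = iterative_km(normalized_null, null_cohort.clinical, alpha=1.0)
        assert len(it.table) == len(full.table)

    def test_planted_harmful_gene_labeled_poor(self, planted_cohort):
        expr = cs.zscore_normalize(planted_cohort.expression)
        it = iterative_km(expr, planted_cohort.clinical)
        row = it.table[it.table["gene"] == "PLANTED"]
        assert len(row) == 1
        assert row["direction"].iloc[0] == "poor"

    def test_null_false_positive_rate_near_alpha(self):
        hits = 0
        n_genes = 100
        reps = 5
        for seed in range(reps):
            cohort = cs.simulate_cohort(cs.SyntheticCohortConfig(
                n_samples=150, n_genes=n_genes, rng_seed=900 + seed))
            expr = cs.zscore_normalize(cohort.expression)
            it = iterative_km(expr, cohort.clinical, alpha=0.05)
            hits += len(it.table)
        rate = hits / (n_genes * reps)
        # binomial(500, 0.05): 3 s.d. ~ 0.03
        assert rate == pytest.approx(0.05, abs=0.035)


def combined_rank_bruteforce(rank_map, pairing_entries, agg):
    """Exhaustive recomputation of the combined ranking from the rank table."""
    aggf = {"mean": np.mean, "sum": np.sum, "best": np.min}[agg]
    rows = []
    for ligand, receptors in pairing_entries:
        if ligand not in rank_map:
            continue
        rec = [rank_map[r] for r in receptors if r in rank_map]
        if not rec:
            continue
        rr = float(aggf(rec))
        rows.append((float(aggf([rank_map[ligand], rr])), ligand, rank_map[ligand], rr))
    rows.sort()
    return rows


class TestCombinedRank:
    def test_mean_arithmetic(self):
        table = pd.DataFrame({
            "gene": ["L1", "R1"], "rank": [1.0, 3.0], "p_value": [0.01, 0.03],
        })
        screen = cs.ScreenResults(table=table)
        pairing = cs.PairingMap(entries=(("L1", ("R1",)),))
        res = combined_rank(screen, pairing, "mean")
        assert res.table.iloc[0]["combined_score"] == 2.0

    def test_multi_receptor_aggregates_first(self):
        table = pd.DataFrame({
            "gene": ["L1", "R1", "R2"], "rank": [2.0, 2.0, 6.0],
            "p_value": [0.01, 0.01, 0.05],
        })
        screen = cs.ScreenResults(table=table)
        pairing = cs.PairingMap(entries=(("L1", ("R1", "R2")),))
        res = combined_rank(screen, pairing, "mean")
        assert res.table.iloc[0]["receptor_rank"] == 4.0
        assert res.table.iloc[0]["combined_score"] == 3.0

    def test_unscreened_receptor_excluded_with_reason(self):
        table = pd.DataFrame({"gene": ["L1"], "rank": [1.0], "p_value": [0.01]})
        screen = cs.ScreenResults(table=table)
        pairing = cs.PairingMap(entries=(("L1", ("R_MISSING",)),))
        res = combined_rank(screen, pairing)
        assert res.excluded == {"L1": "no screened receptor"}
        assert len(res.table) == 0

    @pytest.mark.parametrize("agg", ["mean", "sum", "best"])
    def test_matches_bruteforce_on_random_instances(self, agg):
        rng = np.random.default_rng(14)
        for _ in range(20):
            n_pairs = int(rng.integers(2, 12))
            genes = [f"L{i}" for i in range(n_pairs)] + [f"R{i}" for i in range(n_pairs)]
            ranks = rng.permutation(len(genes)).astype(float) + 1
            table = pd.DataFrame({"gene": genes, "rank": ranks,
                                  "p_value": ranks / (len(genes) + 1)})
            entries = tuple(
                (f"L{i}", tuple(f"R{j}" for j in rng.choice(n_pairs, size=rng.integers(1, 3), replace=False)))
                for i in range(n_pairs)
            )
            res = combined_rank(cs.ScreenResults(table=table), cs.PairingMap(entries=entries), agg)
            brute = combined_rank_bruteforce(dict(zip(genes, ranks)), entries, agg)
            assert res.table["ligand"].tolist() == [b[1] for b in brute]
            np.testing.assert_allclose(res.table["combined_score"], [b[0] for b in brute])

    def test_planted_pair_tops_combined_rank(self, normalized_pair, pair_cohort):
        screen = screen_genes(normalized_pair, pair_cohort.clinical)
        nulls = [g for g in normalized_pair.gene_ids if not g.endswith("_TRUE")]
        entries = [("LIG_TRUE", ("REC_TRUE",))]
        for i in range(0, len(nulls) - 1, 2):
            entries.append((nulls[i], (nulls[i + 1],)))
        res = combined_rank(screen, cs.PairingMap(entries=tuple(entries)))
        assert res.table.iloc[0]["ligand"] == "LIG_TRUE"


class TestGroupingInvariants:
    def test_every_grouping_partitions_samples(self, normalized_null):
        expr = normalized_null
        n = len(expr.sample_ids)
        g0, g1 = expr.gene_ids[0], expr.gene_ids[1]
        for labels in (
            dichotomize_mean(expr.gene(g0)),
            stratify_zscore(expr, g0),
            dual_marker_groups(expr, g0, g1),
            joint_stratify(expr, g0, g1),
        ):
            assert labels.index.is_unique
            assert len(labels) <= n
            assert set(labels.index) <= set(expr.sample_ids)
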