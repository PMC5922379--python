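"""Risk-score construction: multivariate pruning, count-based grouping with
log-rank merging, frozen application, and Cox covariate comparisons."""

import warnings

import numpy as np
import pandas as pd
import pytest

import episcore as ep
from episcore.io import GeneRule
from episcore.synthetic import generate_grouped_cohort


def median_rules(cohort, probes=None):
    probes = probes if probes is not None else list(cohort.expression.index)
    return [
        GeneRule(p, float(np.median(cohort.expression.loc[p])), 0.0, 1)
        for p in probes
    ]


class TestPruneMultivariate:
    def test_drops_noisy_copy_keeps_independent_genes(self):
        spec = ep.SyntheticCohortSpec(
            n_patients=800, n_genes=3,
            planted_genes=(
                ep.PlantedGene(0, float(np.log(2.5)), 0.5),
                ep.PlantedGene(1, float(np.log(2.5)), 0.5),
            ),
            seed=3,
        )
        expr, clin, _ = ep.generate_cohort(spec)
        # make gene 2 a noisy copy of gene 0 (r ~ 0.95 on the log scale)
        rng = np.random.default_rng(4)
        z0 = np.log2(expr.iloc[0].to_numpy())
        expr.iloc[2] = 2 ** (7 + 0.95 * (z0 - 7) + np.sqrt(1 - 0.95**2) * rng.normal(0, 1, 800))
        cohort = ep.align_cohort(expr, clin)
        retained, fit = ep.prune_multivariate(median_rules(cohort), cohort)
        assert [g.probe_id for g in retained] == ["probe_0000", "probe_0001"]
        assert fit.p_value("probe_0002") > 0.05

    def test_single_gene_equals_univariate(self, small_cohort):
        cohort, truth = small_cohort
        rules = median_rules(cohort, [truth[0]["probe_id"]])
        retained, fit = ep.prune_multivariate(rules, cohort)
        uni = ep.cox_fit(
            pd.DataFrame(
                {"g": rules[0].risk_indicator(
                    cohort.expression.loc[rules[0].probe_id].to_numpy())}
            ),
            cohort.times, cohort.events,
        )
        assert fit.beta(rules[0].probe_id) == pytest.approx(uni.beta("g"), abs=1e-8)
        assert len(retained) == 1

    def test_null_genes_rarely_retained(self):
        kept = 0
        reps = 10
        for rep in range(reps):
            spec = ep.SyntheticCohortSpec(n_patients=200, n_genes=4, seed=300 + rep)
            expr, clin, _ = ep.generate_cohort(spec)
            cohort = ep.align_cohort(expr, clin)
            retained, _ = ep.prune_multivariate(median_rules(cohort), cohort)
            kept += len(retained) > 0
        assert kept <= 2  # ~5% per gene under the null


class TestBuildModel:
    def test_merges_indistinct_top_groups(self):
        # groups for counts 2 and 3 share one survival law -> exactly that
        # pair is merged, leaving three ordered risk groups
        cohort, rules = generate_grouped_cohort(
            [0.01, 0.03, 0.09, 0.09], 150, seed=5
        )
        model, groups = ep.build_model(rules, cohort)
        assert model.merge_map == {0: 0, 1: 1, 2: 2, 3: 2}
        assert model.n_groups == 3

    def test_identical_laws_collapse_to_one_group(self):
        cohort, rules = generate_grouped_cohort([0.03] * 4, 150, seed=6)
        model, _ = ep.build_model(rules, cohort)
        assert model.n_groups == 1

    def test_strong_separation_keeps_all_groups_ordered(self):
        cohort, rules = generate_grouped_cohort(
            [0.02 * 4**c for c in range(4)], 500, seed=7
        )
        model, groups = ep.build_model(rules, cohort)
        assert model.merge_map == {0: 0, 1: 1, 2: 2, 3: 3}
        medians = []
        for g in range(4):
            mask = (groups["group"] == g).to_numpy()
            medians.append(
                ep.kaplan_meier(cohort.times[mask], cohort.events[mask]).median_survival
            )
        assert all(a > b for a, b in zip(medians, medians[1:]))

    def test_score_monotone_in_count_for_positive_betas(self):
        cohort, rules = generate_grouped_cohort(
            [0.01, 0.03, 0.09, 0.2], 80, seed=8
        )
        rules = [GeneRule(r.probe_id, r.cutoff, b, r.direction)
                 for r, b in zip(rules, (0.5, 0.9, 1.3))]
        _, groups = ep.build_model(rules, cohort)
        by_count = groups.groupby("high_count")["score"].mean()
        assert by_count.is_monotonic_increasing
        # merged labels non-decreasing in the score
        ordered = groups.sort_values("score")["group"].to_numpy()
        assert (np.diff(ordered) >= 0).all()

    def test_single_populated_group_warns(self):
        cohort, rules = generate_grouped_cohort(
            [0.02, 0.05], (30, 0), seed=9
        )
        with pytest.warns(UserWarning, match="single-group|single group|fewer than 2"):
            model, groups = ep.build_model(rules, cohort)
        assert model.n_groups == 1


class TestApplyModel:
    @pytest.fixture()
    def trained(self):
        cohort, rules = generate_grouped_cohort(
            [0.01, 0.03, 0.09, 0.09], 150, seed=5
        )
        model, groups = ep.build_model(rules, cohort)
        return cohort, model, groups

    def test_training_cohort_idempotence(self, trained):
        cohort, model, groups = trained
        applied, res = ep.apply_model(model, cohort)
        pd.testing.assert_frame_equal(applied, groups)
        assert res is not None and res.p_value < 0.01

    def test_freeze_round_trip_bit_exact(self, trained, tmp_path):
        cohort, model, groups = trained
        ep.write_model(model, tmp_path / "m.json")
        thawed = ep.read_model(tmp_path / "m.json")
        applied, _ = ep.apply_model(thawed, cohort)
        pd.testing.assert_frame_equal(applied, groups)

    def test_generalizes_to_fresh_cohort_from_same_law(self, trained):
        _, model, _ = trained
        valid, _ = generate_grouped_cohort(
            [0.01, 0.03, 0.09, 0.09], 75, seed=55
        )
        applied, res = ep.apply_model(model, valid)
        assert res.p_value < 0.01
        medians = []
        for g in sorted(applied["group"].unique()):
            mask = (applied["group"] == g).to_numpy()
            medians.append(
                ep.kaplan_meier(valid.times[mask], valid.events[mask]).median_survival
            )
        assert all(a >= b for a, b in zip(medians, medians[1:]))

    def test_missing_probe_error(self, trained):
        cohort, model, _ = trained
        pruned = ep.io.Cohort(
            expression=cohort.expression.iloc[1:], clinical=cohort.clinical
        )
        with pytest.raises(KeyError, match="gene_0"):
            ep.apply_model(model, pruned)

    def test_all_below_cutoffs_single_group_warning(self, trained):
        cohort, model, _ = trained
        low = ep.io.Cohort(
            expression=cohort.expression * 0.0 - 1.0,  # every gene low side
            clinical=cohort.clinical,
        )
        with pytest.warns(UserWarning, match="single risk group"):
            applied, res = ep.apply_model(model, low)
        assert res is None
        assert (applied["group"] == 0).all()


class TestCompareCovariates:
    @staticmethod
    def _mediated_setup(seed=5, n=600):
        rng = np.random.default_rng(seed)
        w = rng.normal(0, 1, n)
        t = rng.exponential(1 / (0.02 * np.exp(1.0 * w)))
        c = rng.uniform(0, 120, n)
        x = w + rng.normal(0, 0.3, n)
        ids = [f"PT{i:04d}" for i in range(n)]
        expr = pd.DataFrame([x], index=["gene_w"], columns=ids)
        clin = pd.DataFrame({
            "patient_id": ids,
            "os_months": np.minimum(t, c),
            "os_event": (t <= c).astype(int),
            "w": w,
            "noise": rng.normal(size=n),
        })
        cohort = ep.align_cohort(expr, clin)
        rule = GeneRule("gene_w", float(np.median(x)), 1.0, 1)
        model, assignment = ep.build_model([rule], cohort)
        return cohort, assignment

    def test_noise_covariate_leaves_score_significant(self):
        cohort, assignment = self._mediated_setup()
        table = ep.compare_covariates(assignment, cohort, ["noise"], "pairwise")
        uni = table.query("model == 'univariate'").iloc[0]
        biv = table.query("model == 'episcore+noise' and term == 'episcore'").iloc[0]
        noise = table.query("term == 'noise'").iloc[0]
        assert biv["p"] < 2 * max(uni["p"], 1e-300) or biv["p"] < 1e-10
        assert noise["p"] > 0.05

    def test_mediating_covariate_absorbs_the_effect(self):
        cohort, assignment = self._mediated_setup()
        table = ep.compare_covariates(assignment, cohort, ["w"], "pairwise")
        uni = table.query("model == 'univariate'").iloc[0]
        biv = table.query("model == 'episcore+w' and term == 'episcore'").iloc[0]
        assert uni["p"] < 1e-6
        assert biv["p"] > 0.05

    def test_collinear_covariate_flagged(self):
        cohort, assignment = self._mediated_setup()
        clin = cohort.clinical.copy()
        clin["copy"] = assignment["group"].to_numpy(dtype=float)
        cohort2 = ep.io.Cohort(expression=cohort.expression, clinical=clin)
        with pytest.raises((ep.survival.CoxConvergenceError, ValueError)):
            ep.compare_covariates(assignment, cohort2, ["copy"], "joint")

    def test_degenerate_covariate_excluded(self):
        cohort, assignment = self._mediated_setup()
        clin = cohort.clinical.copy()
        clin["const"] = 1.0
        cohort2 = ep.io.Cohort(expression=cohort.expression, clinical=clin)
        with pytest.warns(UserWarning, match="degenerate"):
            table = ep.compare_covariates(assignment, cohort2, ["const"], "pairwise")
        assert not (table["term"] == "const").any()
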