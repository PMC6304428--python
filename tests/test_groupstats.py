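import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

from fracnet import covnet, groupstats as gs, synthdata as sd
from fracnet.covnet import CohortTable, ThresholdRule


def small_cohorts(seed=0, loading_b=None, n_regions=12, n_subjects=20):
    spec = sd.CohortSpec(
        n_regions=n_regions,
        n_subjects_per_group=n_subjects,
        blocks=[
            sd.BlockSpec(list(range(0, 4)), 0.8, loading_b if loading_b is not None else 0.8),
            sd.BlockSpec(list(range(4, 8)), 0.8, loading_b if loading_b is not None else 0.8),
        ],
        global_loading_a=0.4,
        global_loading_b=0.4 if loading_b is None else 0.4 * loading_b / 0.8,
        noise_sd=0.5,
        seed=seed,
    )
    return sd.make_cohort(spec)


class TestSweep:
    def test_identical_groups_identical_curves(self):
        a, _ = small_cohorts(seed=1)
        res = gs.sweep(a, a, thresholds=(0.05, 0.01), rule_mode="p_value")
        wide = res.table.pivot_table(
            index=["alpha", "metric"], columns="group", values="value"
        )
        assert wide["A"].to_numpy() == pytest.approx(wide["B"].to_numpy(), nan_ok=True)

    def test_density_non_increasing_as_alpha_tightens(self):
        a, b = small_cohorts(seed=2)
        res = gs.sweep(a, b, thresholds=(0.05, 0.02, 0.01, 0.005, 0.001))
        for group in ("A", "B"):
            dens = (
                res.table.query("group == @group and metric == 'density_pct'")
                .sort_values("alpha", ascending=False)["value"]
                .to_numpy()
            )
            assert (np.diff(dens) <= 1e-12).all()

    def test_weakened_group_has_lower_lcs_over_seeds(self):
        wins = []
        for seed in range(20):
            a, b = small_cohorts(seed=seed, loading_b=0.3)
            res = gs.sweep(a, b, thresholds=(0.01, 0.005, 0.001))
            wide = res.table.query("metric == 'LCS'").pivot_table(
                index="alpha", columns="group", values="value"
            )
            wins.append((wide["A"] >= wide["B"]).all())
        assert np.mean(wins) >= 0.9

    def test_mismatched_regions_rejected(self):
        a, b = small_cohorts()
        b2 = CohortTable(b.values.iloc[:-1], b.covariates)
        with pytest.raises(ValueError, match="region set"):
            gs.sweep(a, b2)


class TestPermutationTest:
    def test_copy_of_group_not_significant(self):
        a, _ = small_cohorts(seed=3)
        res = gs.permutation_test(
            a, a, "density", ThresholdRule("p_value", 0.05), n_perm=100, seed=0
        )
        assert res.observed_diff == pytest.approx(0.0)
        assert not res.significant

    def test_planted_effect_detected(self):
        a, b = small_cohorts(seed=4, loading_b=0.15, n_subjects=40)
        res = gs.permutation_test(
            a, b, "density", ThresholdRule("p_value", 0.05), n_perm=200, seed=0
        )
        assert res.observed_diff > 0
        assert res.significant

    def test_sampled_null_matches_exhaustive_split_enumeration(self):
        # 3+3 subjects: only C(6,3) = 20 distinct label splits exist
        spec = sd.CohortSpec(
            n_regions=6,
            n_subjects_per_group=3,
            blocks=[sd.BlockSpec([0, 1, 2], 0.9, 0.9)],
            noise_sd=0.4,
            seed=5,
        )
        a, b = sd.make_cohort(spec)
        rule = ThresholdRule("p_value", 0.5)
        # residualizing inside a 3-subject group saturates the 3-column
        # design, so residualize once on the pooled table
        res = gs.permutation_test(
            a, b, "density", rule, n_perm=400, seed=1, residualize_mode="once"
        )

        values, covs, n_a, _ = gs._pooled(a, b)
        from fracnet.covnet import residualize_values

        values = residualize_values(values, covs)
        exhaustive = set()
        for combo in itertools.combinations(range(6), 3):
            sel = np.array(list(combo) + [i for i in range(6) if i not in combo])
            d_a = gs.GLOBAL_METRICS["density"](
                gs._network_mask(values[:, sel[:3]], covs[sel[:3]], rule, False).astype(np.int8)
            )
            d_b = gs.GLOBAL_METRICS["density"](
                gs._network_mask(values[:, sel[3:]], covs[sel[3:]], rule, False).astype(np.int8)
            )
            exhaustive.add(round(d_a - d_b, 9))
        sampled = {round(v, 9) for v in res.null_diffs}
        assert sampled <= exhaustive
        # 400 draws should hit most of the 20 splits
        assert len(sampled) >= 0.7 * len(exhaustive)

    def test_direction_less_uses_fifth_percentile(self):
        a, b = small_cohorts(seed=6)
        res = gs.permutation_test(
            a, b, "char_path_length", ThresholdRule("p_value", 0.05),
            n_perm=100, seed=2,
        )
        assert res.direction == "less"
        assert res.critical_value == pytest.approx(
            np.percentile(res.null_diffs[~np.isnan(res.null_diffs)], 5)
        )

    def test_reproducible_from_seed(self):
        a, b = small_cohorts(seed=7)
        r1 = gs.permutation_test(a, b, "density", n_perm=100, seed=3)
        r2 = gs.permutation_test(a, b, "density", n_perm=100, seed=3)
        assert r1.null_diffs == pytest.approx(r2.null_diffs)

    def test_unknown_metric_rejected(self):
        a, b = small_cohorts()
        with pytest.raises(ValueError, match="unknown metric"):
            gs.permutation_test(a, b, "assortativity", n_perm=100)

    def test_undefined_metric_aborts_with_diagnostic(self):
        # alpha so strict that networks are empty -> L_p undefined
        a, b = small_cohorts(seed=8)
        with pytest.raises(ValueError, match="undefined"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gs.permutation_test(
                    a, b, "char_path_length", ThresholdRule("p_value", 1e-12),
                    n_perm=100, seed=0,
                )


class TestNodalBetweenness:
    def test_identical_groups_nothing_significant(self):
        a, _ = small_cohorts(seed=9)
        with pytest.warns(UserWarning, match="significant"):
            out = gs.nodal_betweenness_decrease(
                a, a, n_perm=100, top_k=5, p_cut=0.02, seed=0
            )
        assert len(out) == 0

    @staticmethod
    def _hub_cohorts(seed, n_subjects=40, ablated=True):
        """Region 0 bridges three otherwise-uncorrelated spoke blocks in
        group A (high betweenness); group B severs its cross-links."""
        rng = np.random.default_rng(seed)

        def build(hub_connected, sub_rng, group):
            factors = sub_rng.standard_normal((3, n_subjects))
            vals = np.empty((13, n_subjects))
            hub_signal = factors.sum(axis=0) / np.sqrt(3)
            vals[0] = (1.0 * hub_signal if hub_connected else 0.0)
            for k in range(3):
                vals[1 + 4 * k : 5 + 4 * k] = 0.9 * factors[k]
            vals += sub_rng.normal(0, 0.3, size=vals.shape)
            subjects = [f"{group}{j}" for j in range(n_subjects)]
            return CohortTable(
                pd.DataFrame(vals, index=[f"R{i:03d}" for i in range(13)],
                             columns=subjects),
                pd.DataFrame(
                    {"age": sub_rng.uniform(30, 70, n_subjects),
                     "sex": sub_rng.integers(0, 2, n_subjects).astype(float)},
                    index=subjects,
                ),
            )

        return (
            build(True, np.random.default_rng(rng.integers(2**31)), "A"),
            build(not ablated, np.random.default_rng(rng.integers(2**31)), "B"),
        )

    def test_ablated_hub_ranked_first(self):
        hits = 0
        for seed in range(10):
            a, b = self._hub_cohorts(seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out = gs.nodal_betweenness_decrease(
                    a, b, ThresholdRule("p_value", 0.05), n_perm=150,
                    top_k=3, p_cut=0.1, seed=seed,
                )
            if len(out) and out.index[0] == "R000":
                hits += 1
        assert hits >= 6

    def test_result_sorted_and_capped(self):
        a, b = small_cohorts(seed=10, loading_b=0.05, n_subjects=30)
        out = gs.nodal_betweenness_decrease(
            a, b, ThresholdRule("p_value", 0.2), n_perm=100,
            top_k=5, p_cut=0.5, seed=1,
        )
        assert len(out) <= 5
        dec = out["decrease"].to_numpy()
        assert (np.diff(dec) <= 1e-12).all()


class TestBhFdr:
    def test_single_small_p_retained(self):
        cutoff, kept = gs.bh_fdr([0.001], 0.05)
        assert kept.tolist() == [True]
        assert cutoff == pytest.approx(0.001)

    def test_all_equal_p_all_retained(self):
        cutoff, kept = gs.bh_fdr([0.01] * 8, 0.05)
        assert kept.all()

    def test_hand_worked_example(self):
        cutoff, kept = gs.bh_fdr([0.01, 0.02, 0.04, 0.9], 0.05)
        assert kept.tolist() == [True, True, False, False]
        assert cutoff == pytest.approx(0.02)

    def test_empty_input(self):
        cutoff, kept = gs.bh_fdr([], 0.05)
        assert kept.size == 0

    def test_between_bonferroni_and_uncorrected(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            p = rng.uniform(0, 1, 30) ** 2
            q = 0.05
            _, kept = gs.bh_fdr(p, q)
            bonf = p <= q / len(p)
            unc = p <= q
            assert np.all(kept >= bonf)
            assert np.all(kept <= unc)

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(13)
        for _ in range(10):
            p = rng.uniform(0, 0.2, 25)
            _, kept = gs.bh_fdr(p, 0.05)
            reject, *_ = multipletests(p, 0.05, method="fdr_bh")
            assert np.array_equal(kept, reject)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            gs.bh_fdr([0.5], 1.5)
        with pytest.raises(ValueError):
            gs.bh_fdr([1.2], 0.05)


def test_power_on_strong_planted_effect():
    """A strong planted covariance deficit is detected in the planted
    direction in >80% of replicate cohorts."""
    detections = []
    for seed in range(50):
        a, b = small_cohorts(seed=seed, loading_b=0.15, n_subjects=40)
        res = gs.permutation_test(
            a, b, "density", ThresholdRule("p_value", 0.05),
            n_perm=150, seed=seed,
        )
        detections.append(res.significant and res.observed_diff > 0)
    assert np.mean(detections) > 0.8


def test_null_rank_uniformity():
    """Under no group effect the permutation p-value is ~uniform: its
    empirical quartiles over replicates sit near (0.25, 0.5, 0.75)."""
    pvals = []
    for i, ss in enumerate(np.random.SeedSequence(99).spawn(60)):
        s = ss.generate_state(2) % (2**31)
        a, b = sd.make_cohort(sd.null_cohort_spec(seed=int(s[0]), n_regions=15))
        res = gs.permutation_test(
            a, b, "density", ThresholdRule("p_value", 0.05),
            n_perm=100, seed=int(s[1]),
        )
        pvals.append(res.p_value)
    q = np.quantile(pvals, [0.25, 0.5, 0.75])
    assert q == pytest.approx([0.25, 0.5, 0.75], abs=0.15)
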