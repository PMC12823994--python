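"""Constructive generator: exact metric targets, cohort structure,
subsampling, and replicate noise."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tcrdiv import (
    ConfigError,
    FeasibilityError,
    MetricTriple,
    SimulationParams,
    compute_metrics,
    construct_clone_table,
    is_feasible,
    project_to_feasible,
    random_feasible_triple,
    simulate_cohort,
    simulate_replicates,
    subsample_repertoire,
)
from conftest import make_table


def roundtrip(triple: MetricTriple, **kwargs):
    m = compute_metrics(construct_clone_table(triple, **kwargs), [triple.k])
    return (m.S, m.D, m.S_k[triple.k])


class TestConstructCloneTable:
    @pytest.mark.parametrize("profile", ["even", "geometric"])
    def test_examples_round_trip(self, profile):
        for t in [
            MetricTriple(S=10, D=3, S_k=8, k=2),
            MetricTriple(S=7, D=7, S_k=7, k=7),
            MetricTriple(S=1000, D=100, S_k=500, k=10),
            MetricTriple(S=2_000_000, D=300_000, S_k=200_000, k=1000),
        ]:
            assert roundtrip(t, profile=profile) == (t.S, t.D, t.S_k)

    @pytest.mark.parametrize(
        "S, D, S_k, k, msg",
        [
            (7, 8, 7, 2, "template"),       # D > S
            (10, 3, 1, 2, "top clone"),     # S_k < k
            (10, 5, 9, 2, "tail mass"),     # tail cannot cover tail clones
            (12, 4, 4, 2, "rank inversion"),  # top avg 2 < tail avg 4
            (10, 2, 8, 2, "S_k=S"),         # k == D forces S_k == S
        ],
    )
    def test_infeasible_targets_rejected(self, S, D, S_k, k, msg):
        with pytest.raises(FeasibilityError, match=msg):
            MetricTriple(S=S, D=D, S_k=S_k, k=k)

    def test_exhaustive_small_grid(self):
        """Round trip is the identity on every feasible triple with S <= 18."""
        checked = 0
        for S in range(1, 19):
            for D in range(1, S + 1):
                for k in range(1, D + 1):
                    for S_k in range(k, S - (D - k) + 1):
                        if not is_feasible(S, D, S_k, k):
                            continue
                        t = MetricTriple(S=S, D=D, S_k=S_k, k=k)
                        assert roundtrip(t) == (S, D, S_k)
                        checked += 1
        assert checked > 1000

    @pytest.mark.parametrize("profile", ["even", "geometric"])
    def test_randomized_round_trip(self, profile):
        rng = np.random.default_rng(7)
        for _ in range(300):
            t = random_feasible_triple(rng, s_max=200)
            assert roundtrip(t, profile=profile) == (t.S, t.D, t.S_k)

    def test_geometric_profile_has_heavier_head(self):
        t = MetricTriple(S=100_000, D=5_000, S_k=30_000, k=100)
        even = construct_clone_table(t, profile="even")
        geo = construct_clone_table(t, profile="geometric", geometric_decay=0.95)
        assert even.templates.max() < geo.templates.max()


class TestProjection:
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.integers(1, 5000), st.integers(1, 5000), st.integers(0, 5000), st.integers(1, 50)
    )
    def test_projection_always_feasible(self, S, D, S_k, k):
        s, d, sk, _ = project_to_feasible(S, D, S_k, k)
        k_eff = min(k, d)
        assert is_feasible(s, d, sk, k_eff)

    def test_feasible_input_unchanged(self):
        assert project_to_feasible(10, 3, 8, 2) == (10, 3, 8, False)


class TestSimulateCohort:
    def test_determinism(self):
        p = SimulationParams(n_subjects=50, seed=42)
        a = simulate_cohort(p, materialize=True)
        b = simulate_cohort(p, materialize=True)
        pd.testing.assert_frame_equal(a.metrics, b.metrics)
        for ta, tb in zip(a.clone_tables, b.clone_tables):
            assert np.array_equal(ta.templates, tb.templates)

    def test_materialized_tables_match_metrics(self):
        sim = simulate_cohort(SimulationParams(n_subjects=5, seed=3, k=100), materialize=True)
        for table, (_, row) in zip(sim.clone_tables, sim.metrics.iterrows()):
            m = compute_metrics(table, [10, 100])
            assert m.S == row["S"] and m.D == row["D"] and m.S_k[100] == row["S_100"]

    def test_degenerate_generator_identical_subjects(self):
        p = SimulationParams(
            n_subjects=20, seed=0,
            log10_s_sd=0.0, age_slope_log10_s=0.0, male_offset_log10_s=0.0,
            cmv_offset_log10_s=0.0, p_k_age_slope=0.0, p_k_female_offset=0.0,
            p_k_cmv_offset=0.0, p_k_noise_sd=0.0, intrinsic_noise_sd=0.0,
            measurement_noise_sd=0.0,
        )
        m = simulate_cohort(p, materialize=False).metrics
        assert m["S"].nunique() == 1 and m["D"].nunique() == 1 and m["S_1000"].nunique() == 1

    def test_age_slope_recovery_lognormal_mode(self):
        """Decade-binned medians of log10 D recover the generative age slope."""
        slope = -0.005
        p = SimulationParams(
            n_subjects=5000, seed=5, d_link="lognormal",
            age_slope_log10_d=slope, male_offset_log10_d=0.0, cmv_offset_log10_d=0.0,
            measurement_noise_sd=0.0,
        )
        m = simulate_cohort(p, materialize=False).metrics
        centers, medians = [], []
        for lo in range(20, 80, 10):
            sel = (m["age"] >= lo) & (m["age"] < lo + 10)
            centers.append(lo + 5)
            medians.append(np.median(np.log10(m.loc[sel, "D"])))
        fitted = np.polyfit(centers, medians, 1)[0]
        # sd of the binned-median slope ~ sd_D/sqrt(n_bin)/spread ~ 2e-4
        assert fitted == pytest.approx(slope, abs=1e-3)

    def test_fig1_style_covariate_orderings(self, default_cohort):
        """CMV+ subjects have larger S and higher P_1000 in every
        well-populated age decade; males have higher clonality per decade
        and hence lower diversity cohort-wide (the sex effect on D is small
        relative to within-decade scatter, so D is compared pooled)."""
        m = default_cohort
        for lo in range(20, 80, 10):
            sel = (m["age"] >= lo) & (m["age"] < lo + 10)
            sub = m[sel]
            male = sub[sub["sex"] == "male"]
            female = sub[sub["sex"] == "female"]
            if min(len(male), len(female)) >= 100:
                assert male["P_1000"].median() > female["P_1000"].median()
            pos = sub[sub["cmv_status"] == "positive"]
            neg = sub[sub["cmv_status"] == "negative"]
            if min(len(pos), len(neg)) >= 100:
                assert pos["S"].median() > neg["S"].median()
                assert pos["P_1000"].median() > neg["P_1000"].median()
        # pooled sex effect on D (mediated through clonality)
        male_d = np.log10(m.loc[m["sex"] == "male", "D"])
        female_d = np.log10(m.loc[m["sex"] == "female", "D"])
        assert male_d.median() < female_d.median()

    def test_p1000_rises_with_age(self, default_cohort):
        m = default_cohort
        young = m[m["age"] < 30]["P_1000"].median()
        old = m[m["age"] >= 70]["P_1000"].median()
        assert 5 < young < 15 and 25 < old < 35

    def test_inconsistent_params_raise_config_error(self):
        # a diversity scale above the size scale forces D > S for most subjects
        p = SimulationParams(
            n_subjects=100, seed=0, d_link="lognormal",
            log10_d_median=SimulationParams.log10_s_median + 1.0,
        )
        with pytest.raises(ConfigError, match="projection"):
            simulate_cohort(p, materialize=False)

    def test_param_validation(self):
        with pytest.raises(ConfigError):
            SimulationParams(log10_s_sd=-0.1).validate()
        with pytest.raises(ConfigError):
            SimulationParams(s_d_correlation=1.5).validate()
        with pytest.raises(ConfigError):
            SimulationParams(depth=0).validate()
        with pytest.raises(ConfigError):
            SimulationParams(d_link="other").validate()


class TestSubsampling:
    def test_without_replacement_exhaustive_draw(self, toy_table):
        out = subsample_repertoire(toy_table, depth=10, seed=0, replace=False)
        assert sorted(out.templates) == sorted(toy_table.templates)

    def test_depth_one(self, toy_table):
        out = subsample_repertoire(toy_table, depth=1, seed=0)
        assert out.total_templates == 1 and out.n_clones == 1

    def test_output_total_equals_depth(self, toy_table):
        for depth in (2, 5, 50):
            out = subsample_repertoire(toy_table, depth=depth, seed=1)
            assert out.total_templates == depth

    def test_depth_exceeding_total_without_replacement(self, toy_table):
        with pytest.raises(ValueError, match="exceeds total"):
            subsample_repertoire(toy_table, depth=11, replace=False)

    def test_richness_never_exceeds_truth_and_grows_with_depth(self):
        table = make_table([50, 20, 10, 5, 5, 5, 2, 1, 1, 1])
        rng = np.random.default_rng(0)
        mean_d = []
        for depth in (2, 10, 40):
            ds = [
                subsample_repertoire(table, depth, seed=int(rng.integers(2**31))).n_clones
                for _ in range(200)
            ]
            assert max(ds) <= table.n_clones
            mean_d.append(np.mean(ds))
        assert mean_d[0] < mean_d[1] < mean_d[2]

    def test_expected_richness_matches_enumeration(self):
        """Exact enumeration over the 3^2 ordered outcomes for counts (2,1,1)
        at depth 2 gives E[D] = 2 - sum p_i^2 = 1.625."""
        probs = np.array([2, 1, 1]) / 4
        exact = sum(
            pi * pj * len({i, j})
            for i, pi in enumerate(probs)
            for j, pj in enumerate(probs)
        )
        assert exact == pytest.approx(2 - np.sum(probs**2)) == pytest.approx(1.625)
        table = make_table([2, 1, 1])
        rng = np.random.default_rng(123)
        draws = rng.multinomial(2, probs, size=20_000)
        mc = np.mean((draws > 0).sum(axis=1))
        se = np.std((draws > 0).sum(axis=1)) / np.sqrt(20_000)
        assert abs(mc - exact) < 3 * se
        # and the implementation agrees with the enumeration on average
        ds = [
            subsample_repertoire(table, 2, seed=s).n_clones for s in range(5000)
        ]
        assert abs(np.mean(ds) - exact) < 3 * np.std(ds) / np.sqrt(len(ds))


class TestReplicates:
    def test_zero_noise_identical_pairs(self, default_cohort):
        reps = simulate_replicates(default_cohort.head(50), noise_sd=0.0, seed=1)
        assert (reps["D_1"] == reps["D_2"]).all()
        assert (reps["S_1"] == reps["S_2"]).all()

    def test_pair_difference_sd_scaling(self, default_cohort):
        """Independent per-measurement noise sd=0.02 gives pair-difference
        sd 0.02*sqrt(2)."""
        reps = simulate_replicates(default_cohort, noise_sd=0.02, seed=2)
        diffs = np.log10(reps["D_1"] / reps["S_1"]) - np.log10(reps["D_2"] / reps["S_2"])
        target = 0.02 * np.sqrt(2)
        assert np.std(diffs, ddof=1) == pytest.approx(target, rel=0.05)

    def test_reproducible(self, default_cohort):
        a = simulate_replicates(default_cohort, noise_sd=0.01, seed=9)
        b = simulate_replicates(default_cohort, noise_sd=0.01, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_accepts_clone_tables(self):
        sim = simulate_cohort(SimulationParams(n_subjects=4, seed=2, k=50), materialize=True)
        reps = simulate_replicates(sim.clone_tables, noise_sd=0.0, seed=0)
        assert list(reps["D_1"]) == [t.n_clones for t in sim.clone_tables]
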