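"""Synthetic-data generator: mixtures, droplet partitioning, trajectories, cohorts."""

import math

import pytest
from scipy import stats as sps

from ddtcf.cohort import Alteration
from ddtcf.errors import ValidationError
from ddtcf.monitoring import Medium, Outcome, Stage, classify_outcome, milestone_table, relative_change
from ddtcf.quant import Channel
from ddtcf.simulate import (
    MixtureSpec,
    SimConfig,
    TrajectoryParams,
    mixture_concentrations,
    simulate_cohort,
    simulate_trajectory,
    simulate_well,
)
from ddtcf.stats import pearson_correlation
from ddtcf.tcf import TCFAssay


class TestMixtureConcentrations:
    def test_pure_normal_duplication_ratio_is_one(self):
        c = mixture_concentrations(MixtureSpec(tcf_true=0.0, assay=TCFAssay.DUPLICATION))
        assert c[Channel.TARGET_EXON14] == pytest.approx(c[Channel.REF_EXON3])

    def test_pure_tumor_mutation_has_equal_alleles(self):
        c = mixture_concentrations(MixtureSpec(tcf_true=1.0, assay=TCFAssay.MUTATION))
        assert c[Channel.MUT_V600E] == pytest.approx(c[Channel.WT_BRAF])

    def test_half_tumor_mutation_ratio_is_one_third(self):
        c = mixture_concentrations(MixtureSpec(tcf_true=0.5, assay=TCFAssay.MUTATION))
        assert c[Channel.MUT_V600E] / c[Channel.WT_BRAF] == pytest.approx(1 / 3)

    @pytest.mark.parametrize("f", [0.1, 0.45, 0.9])
    def test_duplication_ratio_formula(self, f):
        c = mixture_concentrations(MixtureSpec(tcf_true=f, assay=TCFAssay.DUPLICATION))
        assert c[Channel.TARGET_EXON14] / c[Channel.REF_EXON3] == pytest.approx((2 + f) / 2)


class TestSimulateWell:
    def test_zero_concentration_gives_zero_positives(self):
        cfg = SimConfig(seed=1)
        well = simulate_well({Channel.MUT_V600E: 0.0, Channel.WT_BRAF: 100.0}, cfg)
        assert well.channel_counts[Channel.MUT_V600E][0] == 0

    def test_deterministic_given_seed(self):
        concs = mixture_concentrations(MixtureSpec(tcf_true=0.4, assay=TCFAssay.MUTATION))
        a = simulate_well(concs, SimConfig(seed=7))
        b = simulate_well(concs, SimConfig(seed=7))
        assert a == b

    def test_occupancy_matches_binomial_moments(self):
        # lambda = c*v = 0.10536... -> positive probability 0.1
        lam = -math.log(0.9)
        cfg = SimConfig(seed=13, n_droplets=20000)
        c = lam / cfg.droplet_volume_ul
        well = simulate_well({Channel.MUT_V600E: c, Channel.WT_BRAF: c}, cfg)
        k, n = well.channel_counts[Channel.MUT_V600E]
        sd = math.sqrt(0.1 * 0.9 / n)
        assert abs(k / n - 0.1) < 3 * sd


class TestSimulateTrajectory:
    def test_absorbing_states(self):
        cfg = SimConfig(seed=2)
        for f0 in (0.0, 1.0):
            traj = simulate_trajectory(
                TrajectoryParams(f0=f0, fitness_tumor=1.2, n_passages=10), cfg
            )
            assert all(f == f0 for _, f, _ in traj)

    def test_fitness_advantage_increases_monotonically_toward_one(self):
        cfg = SimConfig(seed=3)
        params = TrajectoryParams(
            f0=0.55, fitness_tumor=1.1, transduction_boost=1.2, n_passages=20
        )
        fs = [f for _, f, _ in simulate_trajectory(params, cfg)]
        assert all(b > a for a, b in zip(fs, fs[1:]))
        assert fs[-1] > 0.95

    def test_fitness_deficit_decreases_monotonically_toward_zero(self):
        cfg = SimConfig(seed=3)
        params = TrajectoryParams(
            f0=0.55, fitness_tumor=0.8, transduction_boost=1.05, n_passages=20
        )
        fs = [f for _, f, _ in simulate_trajectory(params, cfg)]
        assert all(b < a for a, b in zip(fs, fs[1:]))
        assert fs[-1] < 0.05

    def test_emits_one_well_per_passage(self):
        cfg = SimConfig(seed=4)
        traj = simulate_trajectory(TrajectoryParams(f0=0.5, n_passages=5), cfg)
        assert len(traj) == 6
        assert all(w is not None for _, _, w in traj)


class TestSimulateCohort:
    def test_single_sample_gives_one_record_and_both_arms(self):
        records, trajs = simulate_cohort(1, config=SimConfig(seed=5))
        assert len(records) == 1
        assert {t.medium for t in trajs} == {Medium.ABM, Medium.NSM}

    def test_bit_reproducible(self):
        a = simulate_cohort(10, config=SimConfig(seed=6))
        b = simulate_cohort(10, config=SimConfig(seed=6))
        assert a[0] == b[0]
        assert milestone_table(a[1]).equals(milestone_table(b[1]))

    def test_alteration_counts_within_multinomial_band(self):
        records, _ = simulate_cohort(18, config=SimConfig(seed=8))
        fusion = sum(r.alteration is Alteration.KIAA1549_BRAF_FUSION for r in records)
        v600e = sum(r.alteration is Alteration.BRAF_V600E for r in records)
        other = 18 - fusion - v600e
        # two-sided 95% binomial bands around expected (11, 3, 4) of 18
        for count, p in ((fusion, 11 / 18), (v600e, 3 / 18), (other, 4 / 18)):
            lo, hi = sps.binom.ppf([0.025, 0.975], 18, p)
            assert lo <= count <= hi

    def test_milestone_monotonicity_across_cohort(self):
        _, trajs = simulate_cohort(50, config=SimConfig(seed=9))
        table = milestone_table(trajs)
        assert ((~table["transduced"]) | table["viable_at_p1"]).all()
        assert ((~table["line_established"]) | table["transduced"]).all()

    def test_nsm_arms_are_never_transduced(self):
        _, trajs = simulate_cohort(40, config=SimConfig(seed=10))
        assert not any(t.milestones.transduced for t in trajs if t.medium is Medium.NSM)

    def test_age_negatively_correlated_with_tcf_change(self):
        records, trajs = simulate_cohort(200, config=SimConfig(seed=11))
        by_id = {r.sample_id: r for r in records}
        ages, changes = [], []
        for t in trajs:
            if t.medium is not Medium.ABM:
                continue
            p0, p1 = t.timepoint(Stage.P0), t.timepoint(Stage.P1)
            if p0 and p1 and p0.tcf and p1.tcf is not None:
                ages.append(by_id[t.sample_id].age_years)
                changes.append(relative_change(p0.tcf, p1.tcf))
        res = pearson_correlation(ages, changes)
        assert res.statistic < 0
        assert res.p_value < 0.01

    def test_transduced_trackable_cultures_reach_a_terminal_state(self):
        _, trajs = simulate_cohort(60, config=SimConfig(seed=12))
        outcomes = []
        for t in trajs:
            final = t.timepoint(Stage.FINAL)
            if t.medium is Medium.ABM and final is not None and final.tcf is not None:
                outcomes.append(classify_outcome(t).outcome)
        assert outcomes, "expected transduced trackable cultures in a 60-sample cohort"
        terminal = sum(o in (Outcome.ESTABLISHED, Outcome.FAILED) for o in outcomes)
        # the growth-competition map is bimodal: nearly all runs hit 0 or 1
        assert terminal / len(outcomes) > 0.8
        assert any(o is Outcome.ESTABLISHED for o in outcomes)
        assert any(o is Outcome.FAILED for o in outcomes)

    def test_invalid_n_rejected(self):
        with pytest.raises(ValidationError):
            simulate_cohort(0, config=SimConfig(seed=1))
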