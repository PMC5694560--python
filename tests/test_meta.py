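"""Weighted Gaussian clustering, model selection and meta-QTL assembly."""

import numpy as np
import pytest
from conftest import exhaustive_best_loglik
from hypothesis import given, settings
from hypothesis import strategies as st

from mqtlkit import (
    AnalysisError,
    QTLRecord,
    ValidationError,
    consensus_interval,
    fit_k_clusters,
    run_meta_analysis,
    select_model,
    split_segments,
    std_from_ci,
)
from mqtlkit.meta import QTLObservation, information_criterion
from mqtlkit.qtl import ProjectedQTL


def obs_list(xs, ss=None, pops=None):
    if ss is None:
        ss = [1.0] * len(xs)
    if pops is None:
        pops = [f"P{i}" for i in range(len(xs))]
    return [
        QTLObservation(x=float(x), s=float(s), qtl_id=f"q{i}", population_id=p)
        for i, (x, s, p) in enumerate(zip(xs, ss, pops))
    ]


class TestStdFromCI:
    def test_gaussian_95_convention(self):
        assert std_from_ci(8.04, 11.96) == pytest.approx(1.0)
        assert std_from_ci(0.0, 7.84) == pytest.approx(2.0)

    def test_degenerate_interval_rejected(self):
        with pytest.raises(ValidationError):
            std_from_ci(5.0, 5.0)


class TestFitKClusters:
    def test_single_cluster_symmetric_mean(self):
        model = fit_k_clusters(obs_list([10, 20]), K=1)
        assert model.mu[0] == pytest.approx(15.0)

    def test_weighted_mean_downweights_wide_ci(self):
        model = fit_k_clusters(obs_list([0, 10], ss=[1, 3]), K=1)
        assert model.mu[0] == pytest.approx(1.0)  # (0*1 + 10/9) / (1 + 1/9)

    def test_two_clear_clusters_split_correctly(self):
        model = fit_k_clusters(obs_list([10, 10.5, 50, 50.5]), K=2)
        assert model.assignment == [[0, 1], [2, 3]]
        assert model.mu == pytest.approx([10.25, 50.25])

    def test_invalid_k_rejected(self):
        obs = obs_list([1, 2])
        with pytest.raises(AnalysisError):
            fit_k_clusters(obs, 0)
        with pytest.raises(AnalysisError):
            fit_k_clusters(obs, 3)

    @given(
        st.integers(2, 10),
        st.integers(1, 4),
        st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=60, deadline=None)
    def test_dp_equals_exhaustive_enumeration(self, n, K, seed):
        """DP log-likelihood equals brute force over all contiguous partitions."""
        K = min(K, n)
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 100, n)
        s = rng.uniform(0.5, 5, n)
        model = fit_k_clusters(obs_list(x, s), K)
        assert model.logL == pytest.approx(exhaustive_best_loglik(x, s, K), abs=1e-8)

    def test_loglik_monotone_in_k(self, rng):
        x = rng.uniform(0, 120, 10)
        s = rng.uniform(0.5, 3, 10)
        obs = obs_list(x, s)
        logls = [fit_k_clusters(obs, K).logL for K in range(1, 11)]
        assert all(b >= a - 1e-9 for a, b in zip(logls, logls[1:]))

    def test_cluster_variance_is_pooled_precision(self):
        model = fit_k_clusters(obs_list([10, 11], ss=[1, 2]), K=1)
        assert model.cluster_var[0] == pytest.approx(1 / (1 + 0.25))


class TestSelectModel:
    def test_single_observation_is_its_own_mqtl_model(self):
        model = select_model(obs_list([42.0]))
        assert model.K == 1 and model.mu[0] == 42.0

    def test_tight_group_selects_one_cluster(self):
        model = select_model(obs_list([10, 10.2, 10.4]))
        assert model.K == 1

    def test_two_separated_pairs_select_two_clusters(self):
        model = select_model(obs_list([10, 10.5, 50, 50.5]))
        assert model.K == 2
        assert model.mu == pytest.approx([10.25, 50.25])

    @pytest.mark.parametrize("criterion", ["awe", "maic", "aic", "aicc", "bic"])
    def test_all_criteria_agree_on_obvious_structure(self, criterion):
        model = select_model(obs_list([10, 10.5, 80, 80.5]), criterion=criterion)
        assert model.K == 2

    def test_unknown_criterion_rejected(self):
        with pytest.raises(AnalysisError):
            select_model(obs_list([1.0]), criterion="cake")

    def test_empty_observations_rejected(self):
        with pytest.raises(AnalysisError):
            select_model([])

    def test_permutation_invariance(self, rng):
        x = rng.uniform(0, 150, 12)
        s = rng.uniform(0.5, 3, 12)
        obs = obs_list(x, s)
        ref = select_model(obs)
        for _ in range(5):
            perm = list(rng.permutation(len(obs)))
            shuffled = [obs[i] for i in perm]
            model = select_model(shuffled)
            assert model.K == ref.K
            assert model.mu == pytest.approx(ref.mu)

    def test_criterion_penalises_breakpoints(self):
        # one extra cluster costs 2 extra parameters (position + breakpoint)
        n = 10
        c1 = information_criterion(0.0, 1, n, "awe")
        c2 = information_criterion(0.0, 2, n, "awe")
        assert c2 - c1 == pytest.approx(2 * (3 + 2 * np.log(n)))


class TestSegments:
    def test_gap_splits_components(self):
        obs = [
            QTLObservation(x=5, s=1, qtl_id="a", ci_left=0, ci_right=10),
            QTLObservation(x=10, s=1, qtl_id="b", ci_left=5, ci_right=15),
            QTLObservation(x=45, s=1, qtl_id="c", ci_left=40, ci_right=50),
        ]
        segs = split_segments(obs, "1A")
        assert [(s.left, s.right) for s in segs] == [(0, 15), (40, 50)]
        assert [len(s.observations) for s in segs] == [2, 1]

    def test_touching_intervals_merge(self):
        obs = [
            QTLObservation(x=5, s=1, qtl_id="a", ci_left=0, ci_right=10),
            QTLObservation(x=15, s=1, qtl_id="b", ci_left=10, ci_right=20),
        ]
        segs = split_segments(obs)
        assert len(segs) == 1
        assert (segs[0].left, segs[0].right) == (0, 20)

    def test_empty_observations(self):
        assert split_segments([]) == []


class TestConsensusInterval:
    def test_single_member_recovers_own_ci(self):
        mu, (lo, hi) = consensus_interval([QTLObservation(x=10, s=2, qtl_id="a")])
        assert (hi - lo) / 2 == pytest.approx(3.92)

    def test_two_equal_members_shrink_by_sqrt2(self):
        obs = obs_list([10, 10], ss=[1, 1])
        mu, (lo, hi) = consensus_interval(obs)
        assert (hi - lo) / 2 == pytest.approx(1.96 / np.sqrt(2))

    def test_precise_member_dominates(self):
        obs = obs_list([10, 500], ss=[1, 1000])
        mu, (lo, hi) = consensus_interval(obs)
        assert mu == pytest.approx(10, abs=0.01)
        assert (hi - lo) / 2 == pytest.approx(1.96, rel=1e-5)

    @given(st.lists(st.tuples(st.floats(0, 100), st.floats(0.1, 10)), min_size=1, max_size=8))
    @settings(max_examples=60, deadline=None)
    def test_pooled_variance_never_exceeds_best_member(self, items):
        obs = obs_list([x for x, _ in items], [s for _, s in items])
        _, (lo, hi) = consensus_interval(obs)
        best_member_half = 1.96 * min(s for _, s in items)
        assert (hi - lo) / 2 <= best_member_half + 1e-9


def _projected(x, ci, pop, qtl_id, trait="GY", chrom="1A", comp="TKW"):
    rec = QTLRecord(
        qtl_id=qtl_id, population_id=pop, trait_class=trait, trait_component=comp,
        chromosome=chrom, peak=x, ci_left=ci[0], ci_right=ci[1],
    )
    return ProjectedQTL(rec, source_map="sim")


class TestRunMetaAnalysis:
    def test_two_planted_clusters_recovered(self, rng):
        projected = []
        for t, mu in enumerate([20.0, 60.0]):
            for j in range(4):
                x = float(rng.normal(mu, 1.0))
                projected.append(
                    _projected(x, (x - 4, x + 4), pop=f"P{j}", qtl_id=f"q{t}{j}")
                )
        result = run_meta_analysis(projected)
        assert len(result.mqtls) == 2
        for m, mu in zip(result.mqtls, [20.0, 60.0]):
            assert m.position == pytest.approx(mu, abs=2.0)
            assert m.n_populations == 4

    def test_single_population_cluster_stays_unresolved(self):
        projected = [
            _projected(30.0 + 0.1 * j, (25.0, 35.0), pop="P1", qtl_id=f"q{j}")
            for j in range(3)
        ]
        result = run_meta_analysis(projected)
        assert result.mqtls == []
        assert set(result.audit["status"]) == {"unresolved"}
        assert (result.audit["detail"] == "members from a single population").all()

    def test_every_qtl_accounted_exactly_once(self, rng):
        projected = []
        for j in range(12):
            x = float(rng.uniform(0, 150))
            projected.append(
                _projected(x, (x - 5, x + 5), pop=f"P{j % 3}", qtl_id=f"q{j}")
            )
        result = run_meta_analysis(projected)
        assert sorted(result.audit["qtl_id"]) == sorted(f"q{j}" for j in range(12))
        member_ids = [q for m in result.mqtls for q in m.member_qtls]
        in_mqtl = result.audit[result.audit["status"] == "mqtl_member"]["qtl_id"]
        assert sorted(member_ids) == sorted(in_mqtl)

    def test_large_group_segmented_at_gaps(self, rng):
        # 30 observations in two well-separated blobs force segment recursion
        projected = []
        for t, mu in enumerate([20.0, 120.0]):
            for j in range(15):
                x = float(rng.normal(mu, 1.5))
                projected.append(
                    _projected(x, (x - 5, x + 5), pop=f"P{j % 4}", qtl_id=f"q{t}_{j}")
                )
        result = run_meta_analysis(projected)
        assert len(result.mqtls) == 2
        positions = sorted(m.position for m in result.mqtls)
        assert positions[0] == pytest.approx(20.0, abs=2.0)
        assert positions[1] == pytest.approx(120.0, abs=2.0)

    def test_groups_stratified_by_trait_class(self):
        projected = [
            _projected(30.0, (25.0, 35.0), pop=f"P{j}", qtl_id=f"gy{j}", trait="GY")
            for j in range(2)
        ] + [
            _projected(30.0, (25.0, 35.0), pop=f"P{j}", qtl_id=f"gpc{j}", trait="GPC")
            for j in range(2)
        ]
        result = run_meta_analysis(projected)
        assert len(result.mqtls) == 2
        assert {m.trait_class for m in result.mqtls} == {"GY", "GPC"}
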